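import numpy as np
import pandas as pd
import pytest

from hybridscan import cnv
from hybridscan import synthetic_population as sp
from hybridscan import variant_io
from hybridscan.cnv import (
    SUBGENOME_MODES,
    core_accessory,
    detect_aneuploidy,
    expected_allele_fraction,
    gene_copy_number,
    normalize_ratios,
    segment_cn,
    subgenome_attribution,
)
from hybridscan.variant_io import CoverageTrack, GeneModel


def flat_track(lengths, depth=100):
    return CoverageTrack({k: np.full(v, depth) for k, v in lengths.items()})


def segment_balances(calls, seg):
    sub = calls[
        (calls.scaffold == seg.scaffold)
        & (calls.pos - 1 >= seg.start)
        & (calls.pos - 1 < seg.end)
        & (calls.genotype_class != "hom_ref")
    ]
    return variant_io.allele_balance(sub).dropna().to_numpy()


class TestTemplates:
    def test_haploid_duplication_half(self):
        # 2 of 4 copies after duplicating the haploid-derived copy
        assert expected_allele_fraction(2, 4) == 0.5
        assert SUBGENOME_MODES["2:2"] == (0.5,)

    def test_diploid_duplication_quarter(self):
        # minor allele on 1 of 4 copies after duplicating a diploid haplotype
        assert expected_allele_fraction(1, 4) == 0.25
        assert SUBGENOME_MODES["3:1"] == (0.25, 0.75)

    def test_haploid_deletion_one(self):
        # remaining 2 of 2 copies agree after deleting the haploid copy
        assert expected_allele_fraction(2, 2) == 1.0
        assert SUBGENOME_MODES["2:0"] == (1.0,)

    def test_diploid_deletion_half(self):
        assert SUBGENOME_MODES["1:1"] == (0.5,)

    def test_invalid_copies(self):
        with pytest.raises(ValueError):
            expected_allele_fraction(3, 2)


class TestNormalizeRatios:
    def test_constant_depth_unity(self):
        ratios = normalize_ratios(flat_track({"s": 50_000}))
        assert np.allclose(ratios.ratio, 1.0)

    def test_doubled_window(self):
        arr = np.full(50_000, 100)
        arr[20_000:21_000] = 200
        ratios = normalize_ratios(CoverageTrack({"s": arr}))
        hit = ratios[(ratios.start == 20_000)]
        assert hit.ratio.iloc[0] == pytest.approx(2.0)

    def test_brute_force_oracle(self, rng):
        arr = rng.integers(50, 150, size=40_000)
        ratios = normalize_ratios(CoverageTrack({"s": arr}))
        included = ratios[~ratios.excluded]
        means = []
        for row in included.itertuples(index=False):
            means.append(arr[row.start : row.end].mean())
        median = np.median(means)
        for row, mean in zip(included.itertuples(index=False), means):
            assert row.ratio == pytest.approx(mean / median)

    def test_edge_windows_flagged(self):
        ratios = normalize_ratios(flat_track({"s": 30_000}))
        assert ratios[ratios.start < 6_000].excluded.all()
        assert ratios[ratios.end > 24_000].excluded.all()

    def test_short_scaffold_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            normalize_ratios(flat_track({"s": 10_000}))

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            normalize_ratios(CoverageTrack({"s": np.zeros(50_000, dtype=int)}))


class TestSegmentCn:
    def test_constant_coverage_single_neutral(self):
        segs = segment_cn(normalize_ratios(flat_track({"a": 60_000, "b": 40_000})), 2)
        assert len(segs) == 2
        for s in segs:
            assert (s.copy_number, s.klass) == (2, "neutral")

    def test_tiling_conservation(self, rng):
        arr = rng.poisson(100, size=80_000)
        arr[30_000:55_000] = rng.poisson(150, size=25_000)
        segs = segment_cn(normalize_ratios(CoverageTrack({"s": arr})), 2)
        segs = sorted(segs, key=lambda s: s.start)
        assert segs[0].start == 6_000
        assert segs[-1].end == 74_000
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_diploid_gain_boundaries(self, small_ref):
        spec = sp.IsolateSpec(
            ploidy=2,
            het_rate=5,
            depth=60,
            seed=71,
            cnv_events=[sp.CNVEvent("scaffold_1", 100_000, 200_000, +1, "diploid")],
        )
        truth = sp.simulate_isolate(small_ref, spec)
        track = sp.simulate_depth_track(truth)
        segs = segment_cn(normalize_ratios(track), 2)
        gains = [s for s in segs if s.klass == "gain"]
        assert len(gains) == 1
        assert gains[0].copy_number == 3
        assert abs(gains[0].start - 100_000) <= 2_000
        assert abs(gains[0].end - 200_000) <= 2_000

    def test_triploid_loss(self, small_ref):
        spec = sp.IsolateSpec(
            ploidy=3,
            het_rate=5,
            subgenome_divergence=0.01,
            depth=60,
            seed=72,
            cnv_events=[sp.CNVEvent("scaffold_2", 80_000, 180_000, -1, "haploid")],
        )
        truth = sp.simulate_isolate(small_ref, spec)
        segs = segment_cn(normalize_ratios(sp.simulate_depth_track(truth)), 3)
        losses = [s for s in segs if s.klass == "loss"]
        assert len(losses) == 1
        assert losses[0].copy_number == 2

    def test_recall_and_boundary_error(self):
        # truth CNVs >= 50 kb at depth >= 40x: recall >= 95%, boundary <= 2 kb
        ref = sp.generate_reference(2, 400_000, gc=0.4, seed=5)
        found, total, boundary_errors = 0, 0, []
        for rep in range(20):
            rng = np.random.default_rng(4000 + rep)
            events = []
            for scaf in ("scaffold_1", "scaffold_2"):
                start = int(rng.integers(20_000, 250_000))
                length = int(rng.integers(50_000, 120_000))
                delta = int(rng.choice([-1, 1]))
                events.append(sp.CNVEvent(scaf, start, start + length, delta, "diploid"))
            spec = sp.IsolateSpec(
                ploidy=2, het_rate=5, depth=40, seed=4100 + rep, cnv_events=events
            )
            truth = sp.simulate_isolate(ref, spec)
            segs = segment_cn(normalize_ratios(sp.simulate_depth_track(truth)), 2)
            for ev in events:
                total += 1
                for s in segs:
                    if (
                        s.scaffold == ev.scaffold
                        and s.klass != "neutral"
                        and s.copy_number == 2 + ev.delta_copies
                        and min(s.end, ev.end) - max(s.start, ev.start)
                        > 0.5 * (ev.end - ev.start)
                    ):
                        found += 1
                        boundary_errors.append(abs(s.start - ev.start))
                        boundary_errors.append(abs(s.end - ev.end))
                        break
        assert found / total >= 0.95
        assert np.max(boundary_errors) <= 2_000


class TestDetectAneuploidy:
    def test_all_euploid(self):
        calls = detect_aneuploidy(flat_track({"a": 200_000, "b": 200_000}), 2)
        assert set(calls.values()) == {"euploid"}

    def test_whole_scaffold_gain(self):
        track = CoverageTrack(
            {
                "a": np.full(300_000, 100),
                "b": np.full(300_000, 100),
                "c": np.full(150_000, 150),
            }
        )
        calls = detect_aneuploidy(track, 2)
        assert calls == {"a": "euploid", "b": "euploid", "c": "gain"}

    def test_segmental_not_aneuploid(self):
        arr = np.full(300_000, 100)
        arr[:90_000] = 150  # 30% of the scaffold
        track = CoverageTrack({"a": arr, "b": np.full(300_000, 100)})
        assert detect_aneuploidy(track, 2)["a"] == "euploid"


class TestGeneCopyNumber:
    def _seg(self, start, end, copies, ploidy=2):
        klass = "gain" if copies > ploidy else ("loss" if copies < ploidy else "neutral")
        return cnv.CNVSegment("s", start, end, copies, klass, copies / ploidy)

    def test_gene_inside_gain(self):
        segs = [self._seg(0, 10_000, 3), self._seg(10_000, 50_000, 2)]
        genes = [GeneModel("g", "s", 2_001, 3_000)]
        out = gene_copy_number(segs, genes, 2)
        assert out.loc["g", "copy_number"] == 3

    def test_forty_percent_overlap_unchanged(self):
        segs = [self._seg(0, 1_400, 3), self._seg(1_400, 50_000, 2)]
        genes = [GeneModel("g", "s", 1_001, 2_000)]  # 40% inside the gain
        out = gene_copy_number(segs, genes, 2)
        assert out.loc["g", "copy_number"] == 2

    def test_majority_homozygous_deletion(self):
        segs = [self._seg(0, 1_510, 0), self._seg(1_510, 50_000, 2)]
        genes = [GeneModel("g", "s", 1_001, 2_000)]  # 51% at CN 0
        out = gene_copy_number(segs, genes, 2)
        assert out.loc["g", "copy_number"] == 0

    def test_uncovered_gene_flagged(self):
        segs = [self._seg(6_000, 50_000, 2)]
        genes = [GeneModel("g", "s", 5_001, 7_000)]
        out = gene_copy_number(segs, genes, 2)
        assert bool(out.loc["g", "flagged"])


class TestSubgenomeAttribution:
    @pytest.mark.parametrize(
        "delta,subgenome,expect",
        [
            (+1, "diploid", "3:1"),
            (+1, "haploid", "2:2"),
            (-1, "diploid", "1:1"),
            (-1, "haploid", "2:0"),
        ],
    )
    def test_simulated_configurations(self, small_ref, delta, subgenome, expect):
        # 10 replicates per configuration at depth 100, >= 50 sites
        for rep in range(10):
            spec = sp.IsolateSpec(
                ploidy=3,
                het_rate=10,
                subgenome_divergence=0.024,
                depth=100,
                seed=5000 + rep,
                cnv_events=[
                    sp.CNVEvent("scaffold_1", 100_000, 200_000, delta, subgenome)
                ],
            )
            truth = sp.simulate_isolate(small_ref, spec)
            segs = segment_cn(normalize_ratios(sp.simulate_depth_track(truth)), 3)
            seg = next(s for s in segs if s.klass != "neutral")
            calls = sp.simulate_calls(truth)
            got = subgenome_attribution(seg, segment_balances(calls, seg))
            assert got == expect, f"rep {rep}"

    def test_too_few_sites_unresolved(self):
        seg = cnv.CNVSegment("s", 0, 1000, 4, "gain", 1.33)
        assert subgenome_attribution(seg, np.array([0.5] * 5)) == "unresolved"

    def test_gain_bimodal(self):
        seg = cnv.CNVSegment("s", 0, 1000, 4, "gain", 1.33)
        balances = np.concatenate([np.full(30, 0.25), np.full(30, 0.75)])
        assert subgenome_attribution(seg, balances) == "3:1"

    def test_gain_unimodal(self):
        seg = cnv.CNVSegment("s", 0, 1000, 4, "gain", 1.33)
        assert subgenome_attribution(seg, np.full(60, 0.5)) == "2:2"

    def test_loss_near_one(self):
        seg = cnv.CNVSegment("s", 0, 1000, 2, "loss", 0.66)
        assert subgenome_attribution(seg, np.full(60, 0.99)) == "2:0"

    def test_neutral_rejected(self):
        seg = cnv.CNVSegment("s", 0, 1000, 3, "neutral", 1.0)
        with pytest.raises(ValueError):
            subgenome_attribution(seg, np.full(60, 0.5))


class TestCoreAccessory:
    def test_all_present(self):
        m = pd.DataFrame({"i1": [2, 2], "i2": [3, 1]}, index=["g1", "g2"])
        core, acc, table = core_accessory(m)
        assert (core, acc) == (2, 0)

    def test_one_absent(self):
        m = pd.DataFrame({"i1": [2, 0], "i2": [3, 1]}, index=["g1", "g2"])
        core, acc, table = core_accessory(m)
        assert (core, acc) == (1, 1)
        assert table.loc["g2", "class"] == "accessory"

    def test_min_over_isolates_oracle(self, rng):
        m = pd.DataFrame(
            rng.integers(0, 4, size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"i{j}" for j in range(8)],
        )
        core, acc, table = core_accessory(m)
        oracle = (m.min(axis=1) >= 1).sum()
        assert core == oracle
        assert acc == 50 - oracle

    def test_incomplete_matrix_rejected(self):
        m = pd.DataFrame({"i1": [2, np.nan]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            core_accessory(m)


class TestCnvBurdenContrast:
    def test_triploids_exceed_diploids_every_replicate(self):
        # qualitative direction check: triploids get 3 events, diploids 1
        ref = sp.generate_reference(2, 400_000, gc=0.4, seed=6)
        genes = sp.tile_genes(ref)
        for rep in range(5):
            rng = np.random.default_rng(6000 + rep)

            def random_events(n, ploidy):
                events = []
                for _ in range(n):
                    scaf = f"scaffold_{rng.integers(1, 3)}"
                    start = int(rng.integers(20_000, 300_000))
                    subg = "haploid" if ploidy == 3 and rng.random() < 0.5 else "diploid"
                    events.append(
                        sp.CNVEvent(scaf, start, start + 60_000, int(rng.choice([-1, 1])), subg)
                    )
                return events

            counts = {}
            for ploidy_level, n_events, name in ((2, 1, "dip"), (3, 3, "tri")):
                spec = sp.IsolateSpec(
                    ploidy=ploidy_level,
                    het_rate=6,
                    subgenome_divergence=0.02 if ploidy_level == 3 else None,
                    depth=60,
                    seed=6100 + rep * 10 + ploidy_level,
                    cnv_events=random_events(n_events, ploidy_level),
                )
                truth = sp.simulate_isolate(ref, spec)
                segs = segment_cn(
                    normalize_ratios(sp.simulate_depth_track(truth)), ploidy_level
                )
                gcn = gene_copy_number(segs, genes, ploidy_level)
                counts[name] = int((gcn.copy_number != ploidy_level).sum())
            assert counts["tri"] > counts["dip"], f"rep {rep}: {counts}"
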