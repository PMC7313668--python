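"""Synthetic cohort generator.

Simulates isolates at the variant-call level (genotypes, depths, quality
scores) on a randomly generated reference genome, together with the ground
truth needed for parameter-recovery tests: heterozygous-site placement with
per-copy allele assignment, loss-of-heterozygosity (LOH) blocks, copy-number
events and whole-scaffold aneuploidies.

The genome model distinguishes three haplotypes: two "diploid-subgenome"
haplotypes (``A`` and ``B``) that share heterozygous sites at ``het_rate``,
and — for triploids — one divergent haploid subgenome (``H``) that differs
from the diploid pair at rate ``subgenome_divergence``.  Copy-number events
duplicate or delete a single haplotype (``A`` for the diploid subgenome,
``H`` for the haploid one), which is what produces the characteristic
allele-balance shifts of segmental events in allotriploids.
"""

from __future__ import annotations

import dataclasses
import os
import textwrap
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import variant_io
from .variant_io import CoverageTrack, GeneModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# haplotype bitmask codes for allele carriers
HAP_A = 1
HAP_B = 2
HAP_H = 4

SITE_HET = "het"            # heterozygous within the diploid subgenome
SITE_SUBGENOME = "subgenome"  # distinguishes haploid from diploid subgenome
SITE_HOM = "hom"            # homozygous difference vs the reference


class CNVEvent(NamedTuple):
    """A segmental copy-number event affecting one haplotype."""

    scaffold: str
    start: int          # 0-based, inclusive
    end: int            # 0-based, exclusive
    delta_copies: int   # +1 duplication, -1 deletion of the affected copy
    subgenome: str = "diploid"   # {"diploid", "haploid"}


class TruthCNV(NamedTuple):
    scaffold: str
    start: int
    end: int
    copy_number: int
    subgenome: str
    config: str | None  # 3:1 / 2:2 / 1:1 / 2:0 for triploids, else None


@dataclasses.dataclass(frozen=True)
class ReferenceGenome:
    """An in-memory reference: ordered ``(name, sequence)`` scaffolds."""

    scaffolds: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        for name, seq in self.scaffolds:
            if len(seq) == 0:
                raise ValueError(f"scaffold {name!r} has an empty sequence")
            if set(seq) - set("ACGT"):
                raise ValueError(f"scaffold {name!r} contains non-ACGT characters")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.scaffolds]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.scaffolds}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)

    def sequence(self, name: str) -> str:
        for n, s in self.scaffolds:
            if n == name:
                return s
        raise KeyError(name)


@dataclasses.dataclass
class IsolateSpec:
    """Parameters for one simulated isolate."""

    ploidy: int
    het_rate: float                       # expected het sites per kb outside LOH
    subgenome_divergence: float | None = None  # per-site, triploids only
    loh_fraction: float = 0.0
    loh_block_length: float = 200_000.0   # mean block size (bases)
    loh_block_min: float = 100_000.0      # minimum block size (bases)
    hom_rate: float = 0.0                 # homozygous variants per kb vs reference
    cnv_events: list[CNVEvent] = dataclasses.field(default_factory=list)
    aneuploid_scaffolds: list[tuple[str, int]] = dataclasses.field(default_factory=list)
    depth: float = 60.0
    qual_fail_fraction: float = 0.0       # fraction of calls drawn below the QUAL filter
    seed: int = 0
    name: str | None = None
    extra_hom_sites: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3):
            raise ValueError(f"ploidy must be 2 or 3, got {self.ploidy}")
        if self.het_rate < 0:
            raise ValueError("het_rate must be >= 0")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ValueError("loh_fraction must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.ploidy == 3 and self.subgenome_divergence is None:
            raise ValueError("subgenome_divergence is required for triploid isolates")
        if self.ploidy == 2 and self.subgenome_divergence not in (None, 0, 0.0):
            raise ValueError("subgenome_divergence only applies to triploid isolates")


@dataclasses.dataclass
class IsolateTruth:
    """Ground truth for a simulated isolate.

    ``sites`` has one row per true variant site with 0-based ``pos``,
    ``klass`` in {het, subgenome, hom}, a ``carriers`` haplotype bitmask and
    the per-site ``alt_copies`` / ``total_copies`` after applying CNV and
    aneuploidy events.
    """

    spec: IsolateSpec
    reference: ReferenceGenome
    sites: pd.DataFrame
    loh_blocks: pd.DataFrame            # scaffold, start, end (0-based half-open)
    cnv_segments: list[TruthCNV]

    @property
    def name(self) -> str:
        return self.spec.name or f"isolate_seed{self.spec.seed}"

    def het_positions(self) -> dict[str, np.ndarray]:
        """0-based positions that are truly heterozygous given current copies."""
        het = self.sites[
            (self.sites.alt_copies > 0)
            & (self.sites.alt_copies < self.sites.total_copies)
        ]
        return {
            scaf: np.sort(grp.pos.to_numpy())
            for scaf, grp in het.groupby("scaffold", sort=True)
        }


def generate_reference(
    n_scaffolds: int,
    lengths: int | Sequence[int],
    gc: float,
    seed: int,
) -> ReferenceGenome:
    """Generate a random reference with the requested per-scaffold lengths."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)] * n_scaffolds
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_scaffolds:
        raise ValueError("lengths must match n_scaffolds")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    scaffolds = []
    for i, length in enumerate(lengths):
        name = f"scaffold_{i + 1}"
        if length <= 0:
            raise ValueError(f"non-positive length for {name}: {length}")
        idx = rng.choice(4, size=length, p=p)
        scaffolds.append((name, _BASES[idx].tobytes().decode("ascii")))
    return ReferenceGenome(tuple(scaffolds))


def _place_loh_blocks(
    ref: ReferenceGenome, spec: IsolateSpec, rng: np.random.Generator
) -> pd.DataFrame:
    target = int(round(spec.loh_fraction * ref.total_length))
    rows: list[tuple[str, int, int]] = []
    if target <= 0:
        return pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    names = ref.names
    lens = np.array([ref.lengths[n] for n in names], dtype=float)
    probs = lens / lens.sum()
    placed = 0
    min_len = int(min(spec.loh_block_min, target))
    scale = max(spec.loh_block_length - spec.loh_block_min, 1.0)
    max_block = int(0.9 * lens.max())
    tries = 0
    by_scaffold: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    while target - placed >= min_len:
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not place LOH blocks without overlap")
        length = int(min_len + rng.exponential(scale))
        length = min(length, max_block, target - placed)
        si = rng.choice(len(names), p=probs)
        scaf, L = names[si], int(lens[si])
        if length >= L:
            continue
        start = int(rng.integers(0, L - length + 1))
        end = start + length
        if any(start < e and s < end for s, e in by_scaffold[scaf]):
            continue
        by_scaffold[scaf].append((start, end))
        rows.append((scaf, start, end))
        placed += length
    # a sub-minimum remainder extends an existing block instead of becoming
    # a block too short for the downstream window scan to ever flag
    remaining = target - placed
    if remaining > 0 and rows:
        for i, (scaf, start, end) in enumerate(rows):
            L = ref.lengths[scaf]
            others = [iv for iv in by_scaffold[scaf] if iv != (start, end)]
            right_room = min(L, *(s for s, _ in others if s >= end)) if any(
                s >= end for s, _ in others
            ) else L
            if end + remaining <= right_room:
                rows[i] = (scaf, start, end + remaining)
                break
            left_room = max(0, *(e for _, e in others if e <= start)) if any(
                e <= start for _, e in others
            ) else 0
            if start - remaining >= left_room:
                rows[i] = (scaf, start - remaining, end)
                break
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    return df.sort_values(["scaffold", "start"], ignore_index=True)


def _validate_intervals(ref: ReferenceGenome, spec: IsolateSpec) -> None:
    lengths = ref.lengths
    for ev in spec.cnv_events:
        if ev.scaffold not in lengths:
            raise ValueError(f"CNV event on unknown scaffold {ev.scaffold!r}")
        if not (0 <= ev.start < ev.end <= lengths[ev.scaffold]):
            raise ValueError(
                f"CNV event {ev.scaffold}:{ev.start}-{ev.end} outside scaffold bounds"
            )
        if ev.subgenome not in ("diploid", "haploid"):
            raise ValueError(f"unknown subgenome {ev.subgenome!r}")
        if ev.subgenome == "haploid" and spec.ploidy != 3:
            raise ValueError("haploid-subgenome events require a triploid isolate")
    for scaf, _delta in spec.aneuploid_scaffolds:
        if scaf not in lengths:
            raise ValueError(f"aneuploidy on unknown scaffold {scaf!r}")


def _hap_multiplicities(
    spec: IsolateSpec, scaffold: str, positions: np.ndarray
) -> dict[int, np.ndarray]:
    """Copy count of each haplotype at the given positions of one scaffold."""
    mult = {
        HAP_A: np.ones(len(positions), dtype=np.int64),
        HAP_B: np.ones(len(positions), dtype=np.int64),
    }
    if spec.ploidy == 3:
        mult[HAP_H] = np.ones(len(positions), dtype=np.int64)
    for ev in spec.cnv_events:
        if ev.scaffold != scaffold:
            continue
        hap = HAP_H if ev.subgenome == "haploid" else HAP_A
        mask = (positions >= ev.start) & (positions < ev.end)
        mult[hap][mask] += ev.delta_copies
    for scaf, delta in spec.aneuploid_scaffolds:
        if scaf == scaffold:
            mult[HAP_A] += delta
    for arr in mult.values():
        np.clip(arr, 0, None, out=arr)
    return mult


def _truth_config(spec: IsolateSpec, ev: CNVEvent) -> str | None:
    if spec.ploidy != 3:
        return None
    if ev.delta_copies > 0:
        return "3:1" if ev.subgenome == "diploid" else "2:2"
    if ev.delta_copies < 0:
        return "1:1" if ev.subgenome == "diploid" else "2:0"
    return None


def simulate_isolate(ref: ReferenceGenome, spec: IsolateSpec) -> IsolateTruth:
    """Place variant sites and structural events; return ground truth."""
    _validate_intervals(ref, spec)
    rng = np.random.default_rng(spec.seed)
    loh = _place_loh_blocks(ref, spec, rng)

    frames = []
    for scaf, seq in ref.scaffolds:
        L = len(seq)
        occupied = np.zeros(L, dtype=bool)
        loh_mask = np.zeros(L, dtype=bool)
        for _, row in loh[loh.scaffold == scaf].iterrows():
            loh_mask[row.start : row.end] = True
        for s, p, _a in spec.extra_hom_sites:
            if s == scaf:
                occupied[p] = True

        def draw(n: int, allowed: np.ndarray) -> np.ndarray:
            free = np.flatnonzero(allowed & ~occupied)
            n = min(n, len(free))
            if n == 0:
                return np.array([], dtype=np.int64)
            pos = rng.choice(free, size=n, replace=False)
            occupied[pos] = True
            return np.sort(pos)

        non_loh = ~loh_mask
        n_het = rng.poisson(spec.het_rate / 1000.0 * non_loh.sum())
        het_pos = draw(n_het, non_loh)
        sub_pos = np.array([], dtype=np.int64)
        if spec.ploidy == 3 and spec.subgenome_divergence:
            n_sub = rng.poisson(spec.subgenome_divergence * non_loh.sum())
            sub_pos = draw(n_sub, non_loh)
        n_hom = rng.poisson(spec.hom_rate / 1000.0 * L)
        hom_pos = draw(n_hom, np.ones(L, dtype=bool))

        all_hom = (HAP_A | HAP_B | HAP_H) if spec.ploidy == 3 else (HAP_A | HAP_B)
        parts = [
            (het_pos, SITE_HET, rng.choice([HAP_A, HAP_B], size=len(het_pos))),
            (
                sub_pos,
                SITE_SUBGENOME,
                rng.choice([HAP_H, HAP_A | HAP_B], size=len(sub_pos)),
            ),
            (hom_pos, SITE_HOM, np.full(len(hom_pos), all_hom)),
        ]
        extra = [(p, a) for s, p, a in spec.extra_hom_sites if s == scaf]
        for pos, klass, carriers in parts:
            if len(pos) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": scaf,
                        "pos": pos,
                        "klass": klass,
                        "carriers": carriers,
                    }
                )
            )
        if extra:
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": scaf,
                        "pos": [p for p, _ in extra],
                        "klass": SITE_HOM,
                        "carriers": all_hom,
                        "alt_fixed": [a for _, a in extra],
                    }
                )
            )

    if frames:
        sites = pd.concat(frames, ignore_index=True)
    else:
        sites = pd.DataFrame(
            columns=["scaffold", "pos", "klass", "carriers"]
        ).astype({"pos": np.int64, "carriers": np.int64})
    sites = sites.sort_values(["scaffold", "pos"], ignore_index=True)

    # reference / alternate alleles
    refs, alts = [], []
    for scaf, grp in sites.groupby("scaffold", sort=False):
        seq = np.frombuffer(ref.sequence(scaf).encode("ascii"), dtype="S1")
        bases = seq[grp.pos.to_numpy()].astype("U1")
        shift = rng.integers(1, 4, size=len(grp))
        base_idx = np.searchsorted(_BASES.astype("U1"), bases)
        alt = _BASES.astype("U1")[(base_idx + shift) % 4]
        if "alt_fixed" in grp.columns:
            fixed = grp["alt_fixed"].notna().to_numpy()
            alt[fixed] = grp.loc[grp["alt_fixed"].notna(), "alt_fixed"].to_numpy()
        refs.append(pd.Series(bases, index=grp.index))
        alts.append(pd.Series(alt, index=grp.index))
    if refs:
        sites["ref"] = pd.concat(refs)
        sites["alt"] = pd.concat(alts)
    else:
        sites["ref"] = pd.Series(dtype=str)
        sites["alt"] = pd.Series(dtype=str)
    sites = sites.drop(columns=["alt_fixed"], errors="ignore")

    # per-site copy counts after CNV / aneuploidy
    alt_copies = np.zeros(len(sites), dtype=np.int64)
    total_copies = np.zeros(len(sites), dtype=np.int64)
    for scaf, grp in sites.groupby("scaffold", sort=False):
        mult = _hap_multiplicities(spec, scaf, grp.pos.to_numpy())
        tot = sum(mult.values())
        carriers = grp.carriers.to_numpy()
        alt = np.zeros(len(grp), dtype=np.int64)
        for hap, m in mult.items():
            alt += m * ((carriers & hap) > 0)
        alt_copies[grp.index] = alt
        total_copies[grp.index] = tot
    sites["alt_copies"] = alt_copies
    sites["total_copies"] = total_copies

    cnv_truth = [
        TruthCNV(
            ev.scaffold,
            ev.start,
            ev.end,
            spec.ploidy + ev.delta_copies,
            ev.subgenome,
            _truth_config(spec, ev),
        )
        for ev in spec.cnv_events
    ]
    return IsolateTruth(spec, ref, sites, loh, cnv_truth)


def simulate_calls(truth: IsolateTruth) -> pd.DataFrame:
    """Draw depths, allele counts and QUAL for every true variant site.

    Depth at a site is Poisson(mean depth x local copies / ploidy); the
    alternate read count is Binomial(depth, alt copies / total copies).  The
    genotype is re-called at ploidy 2 from the observed allele balance
    (<=0.2 hom_ref, >=0.8 hom_alt, het in between), mirroring a caller run
    with a fixed diploid model.  Sites drawing zero reads are dropped.
    """
    spec = truth.spec
    rng = np.random.default_rng([spec.seed, 1])
    sites = truth.sites
    if len(sites) == 0:
        return variant_io.empty_calls()
    lam = spec.depth * sites.total_copies.to_numpy() / spec.ploidy
    depth = rng.poisson(lam)
    frac = np.divide(
        sites.alt_copies.to_numpy(),
        sites.total_copies.to_numpy(),
        out=np.zeros(len(sites)),
        where=sites.total_copies.to_numpy() > 0,
    )
    alt_depth = rng.binomial(np.maximum(depth, 0), frac)
    fail = rng.random(len(sites)) < spec.qual_fail_fraction
    qual = np.where(
        fail, rng.uniform(0.0, 25.0, len(sites)), 25.0 + rng.gamma(2.0, 15.0, len(sites))
    )
    keep = depth > 0
    balance = np.zeros(len(sites))
    balance[keep] = alt_depth[keep] / depth[keep]
    genotype = np.where(
        balance <= 0.2, "hom_ref", np.where(balance >= 0.8, "hom_alt", "het")
    )
    calls = pd.DataFrame(
        {
            "scaffold": sites.scaffold,
            "pos": sites.pos + 1,  # 1-based, as in VCF
            "ref": sites.ref,
            "alt": sites.alt,
            "genotype_class": genotype,
            "depth": depth,
            "alt_depth": alt_depth,
            "qual": qual,
        }
    )
    return calls[keep].reset_index(drop=True)


def simulate_depth_track(truth: IsolateTruth) -> CoverageTrack:
    """Per-position Poisson depth track reflecting copy-number structure."""
    spec = truth.spec
    rng = np.random.default_rng([spec.seed, 2])
    depths: dict[str, np.ndarray] = {}
    for scaf, seq in truth.reference.scaffolds:
        L = len(seq)
        positions = np.arange(L)
        mult = _hap_multiplicities(spec, scaf, positions)
        copies = sum(mult.values())
        lam = spec.depth * copies / spec.ploidy
        depths[scaf] = rng.poisson(lam).astype(np.int64)
    return CoverageTrack(depths=depths, bin_size=1)


def simulate_neutral_cohort(
    ref: ReferenceGenome,
    n_isolates: int,
    pi: float,
    seed: int,
    depth: int = 100,
) -> dict[str, pd.DataFrame]:
    """Cohort of homozygous call tables with a neutral frequency spectrum.

    Segregating sites receive a derived-allele count k drawn with weight
    1/k (the neutral expectation), so windowed Tajima's D centres on zero
    and genome-wide pairwise diversity equals ``pi`` in expectation.
    """
    if n_isolates < 2:
        raise ValueError("need at least two isolates")
    rng = np.random.default_rng(seed)
    n = n_isolates
    k = np.arange(1, n)
    w = (1.0 / k) / (1.0 / k).sum()
    e_k = 2.0 * k * (n - k) / (n * (n - 1))
    e_mismatch = float((w * e_k).sum())
    total = ref.total_length
    m = int(round(pi * total / e_mismatch))

    offsets = np.cumsum([0] + [ref.lengths[nm] for nm in ref.names])
    flat = rng.choice(total, size=min(m, total), replace=False)
    flat.sort()
    scaf_idx = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[scaf_idx]
    counts = rng.choice(k, size=len(flat), p=w)

    names = [f"iso_{i:02d}" for i in range(n)]
    per_iso_rows: dict[str, list] = {nm: [] for nm in names}
    for j in range(len(flat)):
        scaf = ref.names[scaf_idx[j]]
        refbase = ref.sequence(scaf)[pos[j]]
        alt = rng.choice([b for b in "ACGT" if b != refbase])
        carriers = rng.choice(n, size=counts[j], replace=False)
        for c in carriers:
            per_iso_rows[names[c]].append((scaf, int(pos[j]) + 1, refbase, alt))
    cohort = {}
    for nm in names:
        rows = per_iso_rows[nm]
        df = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
        df["genotype_class"] = "hom_alt"
        df["depth"] = depth
        df["alt_depth"] = depth
        df["qual"] = 60.0
        cohort[nm] = df.sort_values(["scaffold", "pos"], ignore_index=True)
    return cohort


def tile_genes(
    ref: ReferenceGenome, gene_length: int = 1000, spacing: int = 2000
) -> list[GeneModel]:
    """Evenly tiled gene models for fixture GFF3s (1-based inclusive)."""
    genes = []
    i = 0
    for scaf, seq in ref.scaffolds:
        start = spacing // 4
        while start + gene_length <= len(seq):
            i += 1
            genes.append(
                GeneModel(
                    id=f"gene_{i:05d}",
                    scaffold=scaf,
                    start=start + 1,
                    end=start + gene_length,
                    strand="+" if i % 2 else "-",
                )
            )
            start += spacing
    return genes


def write_fasta(ref: ReferenceGenome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.scaffolds:
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 60))
            fh.write("\n")


def write_fixture_set(
    cohort: list[IsolateTruth],
    outdir: str | os.PathLike,
    gene_length: int = 1000,
    gene_spacing: int = 2000,
    with_depth: bool = True,
) -> dict[str, object]:
    """Write FASTA / per-isolate VCF + depth TSV / truth BEDs / GFF3."""
    if not cohort:
        raise ValueError("empty cohort")
    ref = cohort[0].reference
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, object] = {}
    fasta = os.path.join(outdir, "reference.fa")
    write_fasta(ref, fasta)
    manifest["reference"] = fasta
    gff = os.path.join(outdir, "genes.gff3")
    variant_io.write_gff3(tile_genes(ref, gene_length, gene_spacing), gff)
    manifest["genes"] = gff
    manifest["isolates"] = {}
    for truth in cohort:
        name = truth.name
        paths: dict[str, str] = {}
        calls = simulate_calls(truth)
        paths["vcf"] = os.path.join(outdir, f"{name}.vcf")
        variant_io.write_vcf(calls, paths["vcf"], contigs=ref.lengths, sample=name)
        if with_depth:
            paths["depth"] = os.path.join(outdir, f"{name}.depth.tsv")
            simulate_depth_track(truth).to_tsv(paths["depth"])
        paths["loh_bed"] = os.path.join(outdir, f"{name}.loh.bed")
        with open(paths["loh_bed"], "w") as fh:
            for _, row in truth.loh_blocks.iterrows():
                fh.write(f"{row.scaffold}\t{row.start}\t{row.end}\tLOH\n")
        paths["cnv_bed"] = os.path.join(outdir, f"{name}.cnv.bed")
        with open(paths["cnv_bed"], "w") as fh:
            for seg in truth.cnv_segments:
                label = f"CN{seg.copy_number}:{seg.subgenome}:{seg.config or 'NA'}"
                fh.write(f"{seg.scaffold}\t{seg.start}\t{seg.end}\t{label}\n")
        manifest["isolates"][name] = paths  # type: ignore[index]
    return manifest
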