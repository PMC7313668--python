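"""Headline-metric recomputation on synthetic cohorts.

Each function regenerates its inputs from a seed, runs the relevant part of
the analysis pipeline, and returns ``{"value": ..., "n": ...}`` where ``n``
is the problem size used.  Values are on the scale the survey reports them
(percent where percent, per-kb rates where per-kb rates).

The generator parameters mirror the survey's reported cohort structure:
diploids with ~7 het SNPs/kb outside LOH and ~13% of the genome under LOH;
allotriploids combining a heterozygous diploid subgenome with a haploid
subgenome at 2.4% divergence, for ~34 het SNPs/kb outside LOH.
"""

from __future__ import annotations

import math

import numpy as np

from . import diversity, loh, ploidy, synthetic_population as sp, variant_io
from .cnv import SUBGENOME_MODES, expected_allele_fraction

GENOME_SCAFFOLDS = 4
SCAFFOLD_LENGTH = 500_000  # 4 x 500 kb = 2 Mb

DIPLOID_HET_RATE = 7.1      # het SNPs per kb outside LOH, diploid mean
TRIPLOID_HET_RATE = 10.0    # diploid-subgenome het rate in triploids
SUBGENOME_DIVERGENCE = 0.024
LOH_FRACTION = 0.13
TARGET_PI = 1.2e-2


def _genome(seed: int) -> sp.ReferenceGenome:
    return sp.generate_reference(
        GENOME_SCAFFOLDS, SCAFFOLD_LENGTH, gc=0.40, seed=seed
    )


def _het_calls(truth: sp.IsolateTruth):
    calls = variant_io.filter_calls(sp.simulate_calls(truth))
    return calls[calls["genotype_class"] == "het"]


def _loh_spec_kwargs() -> dict:
    # a single block of the full target extent per 2-Mb genome keeps every
    # block detectable by the 50-kb scan while hitting the fraction exactly
    extent = LOH_FRACTION * GENOME_SCAFFOLDS * SCAFFOLD_LENGTH
    return {
        "loh_fraction": LOH_FRACTION,
        "loh_block_length": extent,
        "loh_block_min": extent,
    }


def diploid_balance_mode(seed: int) -> dict:
    """t1: modal allele-balance bin centre of a simulated diploid at 100x."""
    ref = _genome(seed)
    spec = sp.IsolateSpec(ploidy=2, het_rate=7.0, depth=100, seed=seed + 1)
    het = _het_calls(sp.simulate_isolate(ref, spec))
    hist = ploidy.balance_histogram(het)
    mode = float(hist.bin_centers()[np.argmax(hist.counts)])
    return {"value": mode, "n": int(hist.n_sites)}


def triploid_lower_mode(seed: int) -> dict:
    """t2: lower modal bin centre of a simulated allotriploid at 100x."""
    ref = _genome(seed)
    spec = sp.IsolateSpec(
        ploidy=3,
        het_rate=TRIPLOID_HET_RATE,
        subgenome_divergence=SUBGENOME_DIVERGENCE,
        depth=100,
        seed=seed + 2,
    )
    het = _het_calls(sp.simulate_isolate(ref, spec))
    hist = ploidy.balance_histogram(het)
    lower, _upper = ploidy.histogram_modes(hist)
    return {"value": float(lower), "n": int(hist.n_sites)}


def template_haploid_duplication() -> dict:
    """t3: allele fraction with 2 of 4 copies (haploid copy duplicated)."""
    value = expected_allele_fraction(2, 4)
    assert value in SUBGENOME_MODES["2:2"]
    return {"value": value, "n": 1}


def template_diploid_duplication_minor() -> dict:
    """t4: minor allele fraction with 1 of 4 copies (diploid copy duplicated)."""
    value = expected_allele_fraction(1, 4)
    assert value in SUBGENOME_MODES["3:1"]
    return {"value": value, "n": 1}


def template_haploid_deletion() -> dict:
    """t5: allele fraction with 2 of 2 agreeing copies (haploid copy deleted)."""
    value = expected_allele_fraction(2, 2)
    assert value in SUBGENOME_MODES["2:0"]
    return {"value": value, "n": 1}


def _het_rate_excluding_loh(ref, spec) -> float:
    truth = sp.simulate_isolate(ref, spec)
    calls = variant_io.filter_calls(sp.simulate_calls(truth))
    het = calls[calls["genotype_class"] == "het"]
    het_pos = {
        scaf: np.sort(grp["pos"].to_numpy() - 1)
        for scaf, grp in het.groupby("scaffold", sort=True)
    }
    regions = loh.scan_loh(het_pos, ref)
    return loh.heterozygosity_excluding_loh(het_pos, regions, ref)


def diploid_het_rate(seed: int, n_isolates: int = 10) -> dict:
    """t6: mean het SNPs/kb outside detected LOH over simulated diploids."""
    ref = _genome(seed)
    rates = [
        _het_rate_excluding_loh(
            ref,
            sp.IsolateSpec(
                ploidy=2,
                het_rate=DIPLOID_HET_RATE,
                depth=60,
                seed=seed * 100 + i,
                **_loh_spec_kwargs(),
            ),
        )
        for i in range(n_isolates)
    ]
    return {"value": float(np.mean(rates)), "n": n_isolates}


def triploid_het_rate(seed: int, n_isolates: int = 10) -> dict:
    """t7: mean het SNPs/kb outside detected LOH over simulated triploids.

    True non-LOH het density is the diploid-subgenome het rate plus the
    subgenome-distinguishing site density: 10/kb + 24/kb = 34/kb.
    """
    ref = _genome(seed)
    rates = [
        _het_rate_excluding_loh(
            ref,
            sp.IsolateSpec(
                ploidy=3,
                het_rate=TRIPLOID_HET_RATE,
                subgenome_divergence=SUBGENOME_DIVERGENCE,
                depth=60,
                seed=seed * 100 + 50 + i,
                **_loh_spec_kwargs(),
            ),
        )
        for i in range(n_isolates)
    ]
    return {"value": float(np.mean(rates)), "n": n_isolates}


def subgenome_divergence_recovery(seed: int, n_isolates: int = 5) -> dict:
    """t9: subgenome divergence (%) re-estimated from balance classes."""
    ref = _genome(seed)
    estimates = []
    for i in range(n_isolates):
        spec = sp.IsolateSpec(
            ploidy=3,
            het_rate=TRIPLOID_HET_RATE,
            subgenome_divergence=SUBGENOME_DIVERGENCE,
            depth=100,
            seed=seed * 100 + 80 + i,
        )
        het = _het_calls(sp.simulate_isolate(ref, spec))
        estimates.append(
            ploidy.subgenome_divergence_estimate(het, ref.total_length)
        )
    return {"value": float(np.mean(estimates)) * 100.0, "n": n_isolates}


def loh_fraction_recovery(seed: int, n_isolates: int = 10) -> dict:
    """t10: mean detected LOH genome fraction (%) over simulated diploids."""
    ref = _genome(seed)
    fractions = []
    for i in range(n_isolates):
        spec = sp.IsolateSpec(
            ploidy=2,
            het_rate=7.0,
            depth=60,
            seed=seed * 100 + 30 + i,
            **_loh_spec_kwargs(),
        )
        truth = sp.simulate_isolate(ref, spec)
        calls = variant_io.filter_calls(sp.simulate_calls(truth))
        het = calls[calls["genotype_class"] == "het"]
        het_pos = {
            scaf: np.sort(grp["pos"].to_numpy() - 1)
            for scaf, grp in het.groupby("scaffold", sort=True)
        }
        regions = loh.scan_loh(het_pos, ref)
        fractions.append(loh.loh_genome_fraction(regions, ref))
    return {"value": float(np.mean(fractions)) * 100.0, "n": n_isolates}


def hom_rate_for_target_pi(pi_target: float, het_rate_per_kb: float) -> float:
    """Homozygous-variant rate (per kb) whose cohort π equals ``pi_target``.

    Per pair and site, het sites contribute their density h (each het
    column adds an expected mismatch of 0.5 against either haplotype, and
    either member of the pair may hold it), and independent homozygous
    variants at per-site rate mu contribute 2*mu*(1-mu).
    """
    c = pi_target - het_rate_per_kb / 1000.0
    if c < 0:
        raise ValueError("target pi below the heterozygosity floor")
    mu = (1.0 - math.sqrt(1.0 - 2.0 * c)) / 2.0
    return mu * 1000.0


def cohort_pi(seed: int, n_isolates: int = 6) -> dict:
    """Criterion: genome-wide π of a diploid cohort generated for π = 0.012."""
    ref = sp.generate_reference(2, 500_000, gc=0.40, seed=seed)
    hom_rate = hom_rate_for_target_pi(TARGET_PI, DIPLOID_HET_RATE)
    cohort = {}
    for i in range(n_isolates):
        spec = sp.IsolateSpec(
            ploidy=2,
            het_rate=DIPLOID_HET_RATE,
            hom_rate=hom_rate,
            depth=60,
            seed=seed * 100 + 60 + i,
            name=f"iso_{i}",
        )
        cohort[f"iso_{i}"] = variant_io.filter_calls(
            sp.simulate_calls(sp.simulate_isolate(ref, spec))
        )
    aln = diversity.build_alignment(cohort, ref)
    total = 0.0
    for scaf, mat in aln.seqs.items():
        total += diversity.mismatch_profile(mat).sum()
    return {"value": total / ref.total_length, "n": n_isolates}


ALL_TARGETS = {
    "t1": diploid_balance_mode,
    "t2": triploid_lower_mode,
    "t3": lambda seed: template_haploid_duplication(),
    "t4": lambda seed: template_diploid_duplication_minor(),
    "t5": lambda seed: template_haploid_deletion(),
    "t6": diploid_het_rate,
    "t7": triploid_het_rate,
    "t9": subgenome_divergence_recovery,
    "t10": loh_fraction_recovery,
}
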