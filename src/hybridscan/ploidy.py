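"""Ploidy classification from the allele-balance distribution at het sites.

Diploid isolates concentrate heterozygous allele balances around 0.5; an
allotriploid (heterozygous diploid subgenome plus a divergent haploid
subgenome) shows twin enrichments around 1/3 and 2/3.  Classification
compares the histogram mass inside a diploid band with the mass inside the
two triploid bands.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .variant_io import allele_balance

N_BINS = 100

DIPLOID_BAND = (0.45, 0.55)
TRIPLOID_BANDS = ((0.28, 0.38), (0.62, 0.72))
DEFAULT_MARGIN = 1.5
DEFAULT_MIN_SITES = 500


@dataclasses.dataclass
class BalanceHistogram:
    bin_edges: np.ndarray  # 101 edges tiling [0, 1]
    counts: np.ndarray
    n_sites: int

    @property
    def empty(self) -> bool:
        return self.n_sites == 0

    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclasses.dataclass
class PloidyCall:
    label: str                      # diploid / triploid / ambiguous
    mass_diploid: float
    mass_triploid: float
    modes: tuple[float, ...]        # detected peak centres
    n_sites: int
    reason: str = ""


def balance_histogram(het_calls: pd.DataFrame) -> BalanceHistogram:
    """0.01-wide histogram of allele balances at heterozygous calls.

    Zero-depth records (undefined balance) are excluded from the counts.
    """
    if len(het_calls) and not (het_calls["genotype_class"] == "het").all():
        raise ValueError("balance_histogram expects het records only")
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    balances = allele_balance(het_calls).dropna().to_numpy() if len(het_calls) else []
    counts, _ = np.histogram(balances, bins=edges)
    return BalanceHistogram(bin_edges=edges, counts=counts, n_sites=int(counts.sum()))


def _band_mass(hist: BalanceHistogram, lo: float, hi: float) -> int:
    lower = hist.bin_edges[:-1]
    sel = (lower >= lo - 1e-12) & (lower < hi - 1e-12)
    return int(hist.counts[sel].sum())


def histogram_modes(hist: BalanceHistogram) -> tuple[float, float]:
    """Modal bin centres of the lower ([0,0.5)) and upper ([0.5,1]) halves."""
    centers = hist.bin_centers()
    lower = centers < 0.5
    lo_mode = centers[lower][np.argmax(hist.counts[lower])]
    hi_mode = centers[~lower][np.argmax(hist.counts[~lower])]
    return float(lo_mode), float(hi_mode)


def classify_ploidy(
    hist: BalanceHistogram,
    min_sites: int = DEFAULT_MIN_SITES,
    margin: float = DEFAULT_MARGIN,
    diploid_band: tuple[float, float] = DIPLOID_BAND,
    triploid_bands: tuple[tuple[float, float], ...] = TRIPLOID_BANDS,
) -> PloidyCall:
    """Call diploid vs triploid from band masses of the balance histogram.

    ``mass_diploid`` is the site fraction inside ``diploid_band``,
    ``mass_triploid`` the fraction inside the union of ``triploid_bands``.
    The label requires one mass to exceed ``margin`` times the other;
    anything else — including too few sites — is ambiguous.
    """
    if hist.n_sites < min_sites:
        return PloidyCall(
            label="ambiguous",
            mass_diploid=float("nan"),
            mass_triploid=float("nan"),
            modes=(),
            n_sites=hist.n_sites,
            reason=f"only {hist.n_sites} het sites (< {min_sites})",
        )
    m_dip = _band_mass(hist, *diploid_band) / hist.n_sites
    m_tri = sum(_band_mass(hist, lo, hi) for lo, hi in triploid_bands) / hist.n_sites
    # compare per-unit-width densities so a flat distribution ties the bands
    w_dip = diploid_band[1] - diploid_band[0]
    w_tri = sum(hi - lo for lo, hi in triploid_bands)
    dens_dip = m_dip / w_dip
    dens_tri = m_tri / w_tri
    centers = hist.bin_centers()
    if dens_dip > margin * dens_tri:
        label = "diploid"
        modes = (float(centers[np.argmax(hist.counts)]),)
    elif dens_tri > margin * dens_dip:
        label = "triploid"
        modes = histogram_modes(hist)
    else:
        label = "ambiguous"
        modes = ()
    reason = "" if label != "ambiguous" else "band masses within margin"
    return PloidyCall(
        label=label,
        mass_diploid=m_dip,
        mass_triploid=m_tri,
        modes=modes,
        n_sites=hist.n_sites,
    reason=reason,
    )


def subgenome_divergence_estimate(
    het_calls: pd.DataFrame, genome_length: int
) -> float:
    """Per-site divergence of the haploid from the diploid subgenome.

    Heterozygous sites with allele balance above 0.5 in a triploid are those
    where the two diploid-subgenome copies carry the variant and the haploid
    copy does not (expected balance 2/3).  Under symmetric placement of
    subgenome-distinguishing variants, these are half of them, so the
    divergence is twice their per-site density.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    balances = allele_balance(het_calls).dropna()
    n_upper = int((balances > 0.5).sum())
    return 2.0 * n_upper / genome_length


def ploidy_report(calls_by_isolate: dict[str, pd.DataFrame], **kwargs) -> pd.DataFrame:
    """TSV-ready summary: isolate, n_het_sites, masses, label."""
    rows = []
    for name, calls in sorted(calls_by_isolate.items()):
        het = calls[calls["genotype_class"] == "het"]
        call = classify_ploidy(balance_histogram(het), **kwargs)
        rows.append(
            (name, call.n_sites, call.mass_diploid, call.mass_triploid, call.label)
        )
    return pd.DataFrame(
        rows, columns=["isolate", "n_het_sites", "mass_diploid", "mass_triploid", "label"]
    )
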