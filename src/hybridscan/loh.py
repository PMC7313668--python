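"""Loss-of-heterozygosity detection by sliding-window scan.

A genome is scanned in 50-kb windows advancing by 25 kb; windows holding at
most ``max_het`` heterozygous sites are flagged, and overlapping or
book-ended flagged windows merge into maximal LOH regions.  Heterozygosity
is then re-estimated with those regions (sites and bases) excluded.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

DEFAULT_WINDOW = 50_000
DEFAULT_STEP = 25_000
DEFAULT_MAX_HET = 10


class LOHCoversGenomeError(ValueError):
    """Raised when LOH regions leave no genome to estimate a rate on."""


@dataclasses.dataclass(frozen=True)
class LOHRegion:
    scaffold: str
    start: int   # 0-based, inclusive
    end: int     # exclusive
    n_windows_merged: int
    het_sites_inside: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def _count_in(positions: np.ndarray, start: int, end: int) -> int:
    return int(
        np.searchsorted(positions, end, side="left")
        - np.searchsorted(positions, start, side="left")
    )


def scan_loh(
    het_positions: Mapping[str, np.ndarray],
    genome,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_het: int = DEFAULT_MAX_HET,
    refine_boundaries: bool = True,
) -> list[LOHRegion]:
    """Flag and merge low-heterozygosity windows into LOH regions.

    ``het_positions`` maps scaffold name to sorted 0-based het-site
    positions; scaffolds absent from the mapping are treated as having no
    het sites.  Trailing partial windows use a threshold prorated by their
    length fraction, rounded down.

    With ``refine_boundaries`` (default), each merged region is extended to
    the nearest het site on either side: bases between a flagged window
    edge and the first flanking het site carry no evidence of
    heterozygosity, and the step-quantised window union alone misses up to
    ``step`` bases of a true LOH block at each boundary.
    """
    regions: list[LOHRegion] = []
    for scaf, length in genome.lengths.items():
        pos = np.asarray(het_positions.get(scaf, np.array([], dtype=np.int64)))
        flagged: list[tuple[int, int]] = []
        for start in range(0, length, step):
            end = min(start + window, length)
            wlen = end - start
            threshold = max_het if wlen == window else int(max_het * wlen / window)
            if _count_in(pos, start, end) <= threshold:
                flagged.append((start, end))
        # merge overlapping / book-ended flagged windows
        merged: list[list[int]] = []  # [start, end, n_windows]
        for start, end in flagged:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] += 1
            else:
                merged.append([start, end, 1])
        if refine_boundaries:
            for run in merged:
                below = np.searchsorted(pos, run[0], side="left")
                run[0] = int(pos[below - 1]) + 1 if below > 0 else 0
                above = np.searchsorted(pos, run[1], side="left")
                run[1] = int(pos[above]) if above < len(pos) else length
        for start, end, n_win in merged:
            regions.append(
                LOHRegion(
                    scaffold=scaf,
                    start=start,
                    end=end,
                    n_windows_merged=n_win,
                    het_sites_inside=_count_in(pos, start, end),
                )
            )
    return regions


def _check_disjoint(regions: list[LOHRegion]) -> None:
    by_scaf: dict[str, list[LOHRegion]] = {}
    for r in regions:
        by_scaf.setdefault(r.scaffold, []).append(r)
    for scaf, rs in by_scaf.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping LOH regions on {scaf}")


def heterozygosity_excluding_loh(
    het_positions: Mapping[str, np.ndarray],
    regions: list[LOHRegion],
    genome,
) -> float:
    """Het sites per kb outside LOH, over the genome minus LOH bases."""
    _check_disjoint(regions)
    loh_len = sum(r.length for r in regions)
    denom_bases = genome.total_length - loh_len
    if denom_bases <= 0:
        raise LOHCoversGenomeError("LOH regions cover the entire genome")
    n_outside = 0
    for scaf, length in genome.lengths.items():
        pos = np.asarray(het_positions.get(scaf, np.array([], dtype=np.int64)))
        inside = sum(
            _count_in(pos, r.start, r.end) for r in regions if r.scaffold == scaf
        )
        n_outside += len(pos) - inside
    return n_outside / (denom_bases / 1000.0)


def loh_genome_fraction(regions: list[LOHRegion], genome) -> float:
    """Fraction of the genome covered by (disjoint) LOH regions."""
    _check_disjoint(regions)
    return sum(r.length for r in regions) / genome.total_length


def loh_summary(
    het_positions: Mapping[str, np.ndarray],
    regions: list[LOHRegion],
    genome,
) -> dict[str, float]:
    try:
        rate = heterozygosity_excluding_loh(het_positions, regions, genome)
    except LOHCoversGenomeError:
        rate = float("nan")
    return {
        "n_regions": len(regions),
        "total_kb": sum(r.length for r in regions) / 1000.0,
        "fraction": loh_genome_fraction(regions, genome),
        "het_rate_excluding_loh": rate,
    }


def write_bed(regions: list[LOHRegion], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.scaffold, r.start)):
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\tLOH\t{r.het_sites_inside}\n")
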