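"""Read-depth copy-number analysis.

Median-normalised 1-kb window ratios (200-bp step, 6-kb scaffold-end
exclusion) are rounded to integer copy numbers and merged into segments;
whole-scaffold deviations are called from 20-kb window means.  For
triploids, the allele balances inside a segment attribute the event to the
haploid- or diploid-derived subgenome (2:2 / 3:1 for gains, 2:0 / 1:1 for
losses).  Gene copy numbers follow the majority (>50% length) rule, and the
gene x isolate matrix yields the core/accessory split.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import CoverageTrack, GeneModel

DEFAULT_WINDOW = 1_000
DEFAULT_STEP = 200
DEFAULT_EDGE_EXCLUSION = 6_000
DEFAULT_MIN_SPAN = 10_000
DEFAULT_MIN_SITES = 20


def expected_allele_fraction(alt_copies: int, total_copies: int) -> float:
    """Expected allele balance for a site with the given copy configuration."""
    if total_copies <= 0 or not 0 <= alt_copies <= total_copies:
        raise ValueError("require 0 <= alt_copies <= total_copies, total > 0")
    return float(Fraction(alt_copies, total_copies))


# Allele-balance modes expected at subgenome-distinguishing het sites for
# each copy configuration of a triploid segment (diploid:haploid copies).
SUBGENOME_MODES: dict[str, tuple[float, ...]] = {
    # supplemental copy of one diploid-subgenome haplotype: the minor allele
    # sits on 1 of 4 copies, the major on 3 of 4
    "3:1": (expected_allele_fraction(1, 4), expected_allele_fraction(3, 4)),
    # duplicated haploid copy: either allele occupies 2 of 4 copies
    "2:2": (expected_allele_fraction(2, 4),),
    # one diploid copy lost: remaining alleles split 1 of 2
    "1:1": (expected_allele_fraction(1, 2),),
    # haploid copy lost: the remaining 2 of 2 copies agree
    "2:0": (expected_allele_fraction(2, 2),),
}


@dataclasses.dataclass(frozen=True)
class CNVSegment:
    scaffold: str
    start: int    # 0-based inclusive
    end: int      # exclusive
    copy_number: int
    klass: str    # gain / loss / neutral
    mean_ratio: float
    config: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_ratios(
    track: CoverageTrack,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    edge_exclusion: int = DEFAULT_EDGE_EXCLUSION,
) -> pd.DataFrame:
    """Sliding-window depth ratios against the genome-wide median.

    Windows whose span touches the ``edge_exclusion`` zone at either
    scaffold end are flagged ``excluded`` and the median is computed from
    the remaining windows only.
    """
    if track.bin_size != 1:
        raise ValueError("normalize_ratios expects a per-base track")
    rows = []
    for scaf, arr in track.depths.items():
        L = len(arr)
        if L < 2 * edge_exclusion:
            raise ValueError(
                f"scaffold {scaf!r} shorter than twice the edge exclusion"
            )
        csum = np.concatenate([[0.0], np.cumsum(arr, dtype=float)])
        starts = np.arange(0, L - window + 1, step)
        ends = starts + window
        means = (csum[ends] - csum[starts]) / window
        excluded = (starts < edge_exclusion) | (ends > L - edge_exclusion)
        rows.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": starts,
                    "end": ends,
                    "mean_depth": means,
                    "excluded": excluded,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    median = float(df.loc[~df.excluded, "mean_depth"].median())
    if median <= 0:
        raise ValueError("zero median window depth; cannot normalise")
    df["ratio"] = df["mean_depth"] / median
    return df


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def segment_cn(
    ratios: pd.DataFrame,
    ploidy: int,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[CNVSegment]:
    """Merge equal-copy windows into segments; absorb spans below min_span.

    Per-window copy number is round(ratio x ploidy).  Segments tile the
    non-excluded span of each scaffold; short segments are absorbed into
    the flanking segment with the closer copy number, playing the role of a
    break-point penalty.
    """
    segments: list[CNVSegment] = []
    for scaf, grp in ratios.groupby("scaffold", sort=False):
        grp = grp[~grp.excluded].sort_values("start")
        if not len(grp):
            continue
        starts = grp["start"].to_numpy()
        ratio = grp["ratio"].to_numpy()
        cn = _round_half_up(ratio * ploidy)
        span_start = int(starts[0])
        span_end = int(grp["end"].to_numpy()[-1])
        centers = starts + (grp["end"].to_numpy() - starts) / 2.0

        # runs of constant window CN
        change = np.flatnonzero(cn[1:] != cn[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(cn)]])
        runs = []  # [start, end, cn, ratio_sum, n_windows]
        for a, b in zip(bounds[:-1], bounds[1:]):
            left = span_start if a == 0 else int((centers[a - 1] + centers[a]) / 2.0)
            right = span_end if b == len(cn) else int((centers[b - 1] + centers[b]) / 2.0)
            runs.append([left, right, int(cn[a]), float(ratio[a:b].sum()), b - a])

        # absorb short runs into the flank with the closer copy number
        while len(runs) > 1:
            lengths = [r[1] - r[0] for r in runs]
            shortest = int(np.argmin(lengths))
            if lengths[shortest] >= min_span:
                break
            neighbours = []
            if shortest > 0:
                neighbours.append(shortest - 1)
            if shortest < len(runs) - 1:
                neighbours.append(shortest + 1)
            target = min(
                neighbours, key=lambda k: abs(runs[k][2] - runs[shortest][2])
            )
            a, b = sorted((shortest, target))
            runs[a] = [
                runs[a][0],
                runs[b][1],
                runs[target][2],
                runs[a][3] + runs[b][3],
                runs[a][4] + runs[b][4],
            ]
            del runs[b]
        # merge any now-adjacent equal-CN runs
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
                merged[-1][3] += r[3]
                merged[-1][4] += r[4]
            else:
                merged.append(r)

        for left, right, c, rsum, nwin in merged:
            klass = "gain" if c > ploidy else ("loss" if c < ploidy else "neutral")
            segments.append(
                CNVSegment(
                    scaffold=scaf,
                    start=left,
                    end=right,
                    copy_number=c,
                    klass=klass,
                    mean_ratio=rsum / nwin,
                )
            )
    return segments


def detect_aneuploidy(
    track: CoverageTrack,
    ploidy: int,
    window: int = 20_000,
    min_windows: int = 5,
    consistency: float = 0.9,
) -> dict[str, str]:
    """Whole-scaffold gain/loss calls from 20-kb window copy numbers.

    A scaffold is called gained (lost) when at least ``consistency`` of its
    windows round to a copy number above (below) the isolate ploidy.
    """
    from .variant_io import coverage_windows

    win = coverage_windows(track, window)
    win = win[~win.partial] if (~win.partial).sum() else win
    median = float(win["mean_depth"].median())
    if median <= 0:
        raise ValueError("zero median window depth")
    cn = _round_half_up(win["mean_depth"].to_numpy() / median * ploidy)
    calls = {}
    for scaf in track.depths:
        mask = (win["scaffold"] == scaf).to_numpy()
        if mask.sum() < min_windows:
            calls[scaf] = "euploid"
            continue
        sub = cn[mask]
        if (sub > ploidy).mean() >= consistency:
            calls[scaf] = "gain"
        elif (sub < ploidy).mean() >= consistency:
            calls[scaf] = "loss"
        else:
            calls[scaf] = "euploid"
    return calls


def gene_copy_number(
    segments: Sequence[CNVSegment],
    genes: Iterable[GeneModel],
    ploidy: int,
) -> pd.DataFrame:
    """Per-gene copy number by the >50%-of-length overlap rule.

    A gene takes the copy number of the segment class covering more than
    half of its length; otherwise it keeps the isolate ploidy.  Genes not
    fully covered by segments (scaffold-end exclusion zones) are flagged.
    """
    by_scaf: dict[str, list[CNVSegment]] = {}
    for seg in segments:
        by_scaf.setdefault(seg.scaffold, []).append(seg)
    rows = []
    for g in genes:
        start0, end0 = g.start - 1, g.end
        cover: dict[int, int] = {}
        covered = 0
        for seg in by_scaf.get(g.scaffold, []):
            ovl = min(end0, seg.end) - max(start0, seg.start)
            if ovl > 0:
                cover[seg.copy_number] = cover.get(seg.copy_number, 0) + ovl
                covered += ovl
        cn = ploidy
        for candidate, bases in sorted(cover.items()):
            if bases > 0.5 * g.length:
                cn = candidate
        rows.append((g.id, cn, covered < g.length))
    return pd.DataFrame(rows, columns=["gene", "copy_number", "flagged"]).set_index(
        "gene"
    )


def subgenome_attribution(
    segment: CNVSegment,
    het_balances: np.ndarray,
    min_sites: int = DEFAULT_MIN_SITES,
    band_halfwidth: float = 0.10,
    margin: float = 0.10,
) -> str:
    """Attribute a triploid CNV segment to a subgenome configuration.

    Balances of variant sites inside the segment are compared against the
    analytic templates in :data:`SUBGENOME_MODES`.  Gains separate 3:1
    (bimodal at 0.25/0.75) from 2:2 (unimodal at 0.5) by the difference of
    the site fractions in the outer vs central bands; losses separate 2:0
    (mass near 1.0) from 1:1 (mass near 0.5) by the high-balance fraction.
    Calls inside the margin are returned as ``unresolved``.
    """
    balances = np.asarray(het_balances, dtype=float)
    balances = balances[np.isfinite(balances)]
    if len(balances) < min_sites:
        return "unresolved"
    if segment.klass == "gain":
        lo_31, hi_31 = SUBGENOME_MODES["3:1"]
        (mid_22,) = SUBGENOME_MODES["2:2"]
        outer = (
            (np.abs(balances - lo_31) <= band_halfwidth)
            | (np.abs(balances - hi_31) <= band_halfwidth)
        ).mean()
        central = (np.abs(balances - mid_22) <= band_halfwidth * 0.75).mean()
        if outer - central > margin:
            return "3:1"
        if central - outer > margin:
            return "2:2"
        return "unresolved"
    if segment.klass == "loss":
        (one,) = SUBGENOME_MODES["2:0"]
        (half,) = SUBGENOME_MODES["1:1"]
        f_high = (balances >= one - 0.15).mean()
        f_mid = (np.abs(balances - half) <= band_halfwidth).mean()
        if f_high >= 0.2 and f_high > f_mid * 0.25:
            return "2:0"
        if f_high <= 0.1:
            return "1:1"
        return "unresolved"
    raise ValueError("subgenome attribution applies to gain/loss segments only")


def core_accessory(matrix: pd.DataFrame) -> tuple[int, int, pd.DataFrame]:
    """Classify genes as core (copy number >= 1 in every isolate) or accessory.

    ``matrix`` is genes x isolates of integer copy numbers.  Returns core
    and accessory counts plus a per-gene table with the presence/absence
    pattern.
    """
    if matrix.isna().any().any():
        raise ValueError("copy-number matrix must be complete")
    presence = matrix >= 1
    core = presence.all(axis=1)
    table = pd.DataFrame(
        {
            "class": np.where(core, "core", "accessory"),
            "n_present": presence.sum(axis=1),
        },
        index=matrix.index,
    )
    return int(core.sum()), int((~core).sum()), table


def write_segments_bed(segments: Sequence[CNVSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in sorted(segments, key=lambda s: (s.scaffold, s.start)):
            name = f"CN{seg.copy_number}:{seg.klass}:{seg.config or 'NA'}"
            fh.write(f"{seg.scaffold}\t{seg.start}\t{seg.end}\t{name}\n")
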