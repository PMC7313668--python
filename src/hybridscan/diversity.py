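"""Windowed nucleotide-diversity statistics on IUPAC-encoded alignments.

Each isolate contributes a single sequence: the reference with homozygous
substitutions applied and heterozygous sites written as IUPAC ambiguity
characters.  Pairwise comparisons resolve ambiguity codes as
equal-probability mixtures over their bases, so a column with 'A' against
'R' contributes an expected mismatch of 0.5.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .variant_io import GeneModel

DEFAULT_WINDOW = 10_000

# character set: 4 bases, 6 two-base codes, 4 three-base codes, N
ALPHABET = "ACGTRYSWKMBDHVN"
_CODE_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
IUPAC_FOR = {frozenset(v): k for k, v in _CODE_BASES.items()}

_CHAR_TO_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_INDEX[ord(_c)] = _i

_PROBS = np.zeros((len(ALPHABET), 4))
for _i, _c in enumerate(ALPHABET):
    for _b in _CODE_BASES[_c]:
        _PROBS[_i, "ACGT".index(_b)] = 1.0 / len(_CODE_BASES[_c])

# EXPECTED_MISMATCH[i, j] = 1 - sum_b p_i(b) p_j(b)
EXPECTED_MISMATCH = 1.0 - _PROBS @ _PROBS.T


def encode(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Map an IUPAC string to alphabet indices (uint8)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(bytes(seq), dtype=np.uint8)
    idx = _CHAR_TO_INDEX[arr]
    if (idx < 0).any():
        bad = chr(arr[idx < 0][0])
        raise ValueError(f"character {bad!r} is not an IUPAC nucleotide code")
    return idx.astype(np.uint8)


def decode(idx: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in idx)


def iupac_char(ref: str, alt: str) -> str:
    return IUPAC_FOR[frozenset(ref + alt)]


@dataclasses.dataclass
class Alignment:
    """One IUPAC sequence per isolate, per scaffold, as index matrices."""

    names: list[str]
    seqs: dict[str, np.ndarray]  # scaffold -> (n_isolates, L) uint8

    @property
    def n(self) -> int:
        return len(self.names)

    def scaffold_length(self, scaffold: str) -> int:
        return self.seqs[scaffold].shape[1]


def build_alignment(
    calls_by_isolate: Mapping[str, pd.DataFrame], genome
) -> Alignment:
    """Apply per-isolate calls to the reference, het sites as IUPAC codes.

    Raises on conflicting records (same isolate, same position, different
    resulting state).
    """
    names = sorted(calls_by_isolate)
    seqs: dict[str, np.ndarray] = {}
    for scaf, refseq in genome.scaffolds:
        ref_idx = encode(refseq)
        mat = np.tile(ref_idx, (len(names), 1))
        seqs[scaf] = mat
    for row, name in enumerate(names):
        calls = calls_by_isolate[name]
        for scaf, grp in calls.groupby("scaffold", sort=False):
            if scaf not in seqs:
                raise ValueError(f"{name}: unknown scaffold {scaf!r}")
            pos0 = grp["pos"].to_numpy() - 1
            chars = np.empty(len(grp), dtype=np.uint8)
            for i, rec in enumerate(grp.itertuples(index=False)):
                if rec.genotype_class == "hom_ref":
                    chars[i] = _CHAR_TO_INDEX[ord(rec.ref)]
                elif rec.genotype_class == "hom_alt":
                    chars[i] = _CHAR_TO_INDEX[ord(rec.alt)]
                else:
                    chars[i] = _CHAR_TO_INDEX[ord(iupac_char(rec.ref, rec.alt))]
            order = np.argsort(pos0, kind="stable")
            pos_sorted = pos0[order]
            dup = np.flatnonzero(pos_sorted[1:] == pos_sorted[:-1])
            for d in dup:
                if chars[order][d] != chars[order][d + 1]:
                    raise ValueError(
                        f"conflicting records for {name} at {scaf}:{pos_sorted[d] + 1}"
                    )
            seqs[scaf][row, pos0] = chars
    return Alignment(names=names, seqs=seqs)


def mismatch_profile(mat: np.ndarray) -> np.ndarray:
    """Per-column expected mismatch averaged over all sequence pairs."""
    n, L = mat.shape
    if n < 2:
        raise ValueError("need at least two sequences")
    total = np.zeros(L)
    for i, j in itertools.combinations(range(n), 2):
        total += EXPECTED_MISMATCH[mat[i], mat[j]]
    return total / (n * (n - 1) / 2)


def segregating_columns(mat: np.ndarray) -> np.ndarray:
    """True where any two sequences differ in allele content."""
    return ~(mat == mat[0]).all(axis=0)


def pairwise_pi(mat: np.ndarray, start: int = 0, end: int | None = None) -> float:
    """Average pairwise diversity per site over [start, end)."""
    end = mat.shape[1] if end is None else end
    if end <= start:
        raise ValueError("empty interval")
    return float(mismatch_profile(mat[:, start:end]).sum() / (end - start))


def masked_pi(mat: np.ndarray, mask: np.ndarray) -> float:
    """π restricted to columns where ``mask`` is True."""
    if mask.sum() == 0:
        raise ValueError("empty mask")
    return float(mismatch_profile(mat)[mask].sum() / mask.sum())


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a1 * L)."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    if L <= 0:
        raise ValueError("L must be positive")
    return S / (harmonic(n) * L)


def tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs.

    ``pi_total`` is the average number of pairwise differences (not per
    site).  Returns NaN when S == 0 (undefined, flagged — never zero).
    """
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:  # variance degenerates at n = 2
        return float("nan")
    return (pi_total - S / a1) / denom


def window_scan(
    alignment: Alignment, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Nonoverlapping windowed S, π, θ_w and Tajima's D per scaffold."""
    if window <= 0:
        raise ValueError("window must be positive")
    n = alignment.n
    rows = []
    for scaf in alignment.seqs:
        mat = alignment.seqs[scaf]
        profile = mismatch_profile(mat)
        seg = segregating_columns(mat)
        L = mat.shape[1]
        for start in range(0, L, window):
            end = min(start + window, L)
            S = int(seg[start:end].sum())
            pi_total = float(profile[start:end].sum())
            rows.append(
                (
                    scaf,
                    start,
                    end,
                    S,
                    n,
                    pi_total / (end - start),
                    watterson_theta(S, n, end - start),
                    tajimas_d(n, S, pi_total),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "S", "n", "pi", "theta_w", "tajima_d"],
    )


def partition_sites(
    genes: list[GeneModel], genome
) -> dict[str, np.ndarray]:
    """Coding masks per scaffold (True = coding); overlaps union as coding."""
    masks = {scaf: np.zeros(len(seq), dtype=bool) for scaf, seq in genome.scaffolds}
    for g in genes:
        if g.scaffold not in masks:
            raise ValueError(f"gene {g.id} on unknown scaffold {g.scaffold!r}")
        if g.end > len(masks[g.scaffold]):
            raise ValueError(f"gene {g.id} extends beyond scaffold end")
        masks[g.scaffold][g.start - 1 : g.end] = True
    return masks
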