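"""Variant, coverage and gene-model I/O plus the call-level filters.

Variant tables are plain :class:`pandas.DataFrame` objects with the columns
in :data:`CALL_COLUMNS`; ``pos`` is 1-based as in VCF.  Genotype classes are
the strings ``hom_ref`` / ``het`` / ``hom_alt``.
"""

from __future__ import annotations

import dataclasses
import os
from collections import Counter

import numpy as np
import pandas as pd

CALL_COLUMNS = [
    "scaffold",
    "pos",
    "ref",
    "alt",
    "genotype_class",
    "depth",
    "alt_depth",
    "qual",
]

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP call in one isolate."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype_class: str
    depth: int
    alt_depth: int
    qual: float

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(f"bad genotype_class {self.genotype_class!r}")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError("require 0 <= alt_depth <= depth")

    @property
    def allele_balance(self) -> float:
        if self.depth == 0:
            raise ValueError("allele balance undefined at zero depth")
        return self.alt_depth / self.depth


def empty_calls() -> pd.DataFrame:
    df = pd.DataFrame(columns=CALL_COLUMNS)
    return df.astype(
        {"pos": np.int64, "depth": np.int64, "alt_depth": np.int64, "qual": float}
    )


def allele_balance(calls: pd.DataFrame) -> pd.Series:
    """Per-record alt_depth / depth; NaN (distinct signal) at zero depth."""
    depth = calls["depth"].to_numpy(dtype=float)
    alt = calls["alt_depth"].to_numpy(dtype=float)
    out = np.divide(alt, depth, out=np.full(len(calls), np.nan), where=depth > 0)
    return pd.Series(out, index=calls.index, name="allele_balance")


def filter_calls(
    calls: pd.DataFrame, min_depth: int = 10, min_qual: float = 25.0
) -> pd.DataFrame:
    """Remove calls with coverage < min_depth or quality < min_qual.

    Removal uses strict inequality, so boundary values are kept.
    """
    keep = (calls["depth"] >= min_depth) & (calls["qual"] >= min_qual)
    return calls[keep].reset_index(drop=True)


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a single-sample VCF into a call table.

    Only biallelic SNPs with GT, DP, AD and QUAL present are kept; skipped
    records are counted in ``df.attrs['skipped']``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    skipped: Counter[str] = Counter()
    rows = []
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped["non_biallelic_snp"] += 1
            continue
        gt_type = v.gt_types[0]
        if gt_type == 2:  # unknown / missing genotype
            skipped["missing_genotype"] += 1
            continue
        ad = v.format("AD")
        dp = v.format("DP")
        if ad is None or dp is None or v.QUAL is None:
            skipped["missing_fields"] += 1
            continue
        genotype = {0: "hom_ref", 1: "het", 3: "hom_alt"}[gt_type]
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                genotype,
                int(dp[0][0]) if dp.ndim == 2 else int(dp[0]),
                int(ad[0][1]),
                float(v.QUAL),
            )
        )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS) if rows else empty_calls()
    df.attrs["skipped"] = dict(skipped)
    return df


def write_vcf(
    calls: pd.DataFrame,
    path: str | os.PathLike,
    contigs: dict[str, int],
    sample: str = "sample",
) -> None:
    """Write a call table as a minimal single-sample VCF 4.2."""
    gt_map = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
    calls = calls.sort_values(["scaffold", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridscan\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for row in calls.itertuples(index=False):
            ad = f"{int(row.depth) - int(row.alt_depth)},{int(row.alt_depth)}"
            fh.write(
                f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.2f}\t.\t.\tGT:DP:AD\t"
                f"{gt_map[row.genotype_class]}:{int(row.depth)}:{ad}\n"
            )


@dataclasses.dataclass
class CoverageTrack:
    """Per-scaffold depth arrays at fixed step ``bin_size`` (1 = per base)."""

    depths: dict[str, np.ndarray]
    bin_size: int = 1

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"depth array for {name!r} must be 1-D")
            if len(arr) and arr.min() < 0:
                raise ValueError(f"negative depths in {name!r}")
            self.depths[name] = arr

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold\tpos\tdepth\n")
            for name in self.depths:
                arr = self.depths[name]
                pos = np.arange(len(arr)) * self.bin_size + 1
                block = pd.DataFrame({"scaffold": name, "pos": pos, "depth": arr})
                block.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, bin_size: int = 1) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t")
        depths = {}
        for name, grp in df.groupby("scaffold", sort=False):
            grp = grp.sort_values("pos")
            depths[str(name)] = grp["depth"].to_numpy(dtype=np.int64)
        return cls(depths=depths, bin_size=bin_size)


def coverage_windows(track: CoverageTrack, window: int) -> pd.DataFrame:
    """Mean depth in nonoverlapping windows tiled from each scaffold start.

    The final partial window is kept and flagged with ``partial=True``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window % track.bin_size:
        raise ValueError("window must be a multiple of the track bin size")
    per_win = window // track.bin_size
    rows = []
    for scaf, arr in track.depths.items():
        csum = np.concatenate([[0.0], np.cumsum(arr, dtype=float)])
        n = len(arr)
        for start_bin in range(0, n, per_win):
            end_bin = min(start_bin + per_win, n)
            mean = (csum[end_bin] - csum[start_bin]) / (end_bin - start_bin)
            rows.append(
                (
                    scaf,
                    start_bin * track.bin_size,
                    end_bin * track.bin_size,
                    mean,
                    end_bin - start_bin < per_win,
                )
            )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "mean_depth", "partial"])


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene interval; coordinates are 1-based inclusive as in GFF3."""

    id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\thybridscan\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}")
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(
                    id=gid,
                    scaffold=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes
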