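"""Cohort orchestration: filter -> ploidy -> LOH -> diversity -> tree -> CNV.

Configuration is a YAML/dict with paths (reference FASTA, VCF directory,
optional depth directory, GFF3, output directory) and thresholds.  Every
stage writes its artifact before the next stage starts, and the whole run
is a pure function of the configuration, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import diversity, loh, phylo, ploidy, variant_io
from .phylo import Tree
from .synthetic_population import ReferenceGenome

log = logging.getLogger("hybridscan")

DEFAULT_PARAMS: dict[str, Any] = {
    "min_depth": 10,
    "min_qual": 25.0,
    "loh_window": 50_000,
    "loh_step": 25_000,
    "loh_max_het": 10,
    "diversity_window": 10_000,
    "cnv_window": 1_000,
    "cnv_step": 200,
    "cnv_edge_exclusion": 6_000,
    "cnv_min_span": 10_000,
    "gene_overlap": 0.5,
    "n_clusters": None,
    "seed": 0,
}


@dataclasses.dataclass
class CohortReport:
    per_isolate: pd.DataFrame
    diversity_windows: pd.DataFrame
    tree_newick: str | None
    clusters: dict[str, int]
    core_genes: int | None
    accessory_genes: int | None

    def to_json(self) -> str:
        payload = {
            "per_isolate": self.per_isolate.to_dict(orient="records"),
            "clusters": self.clusters,
            "core_genes": self.core_genes,
            "accessory_genes": self.accessory_genes,
            "tree_newick": self.tree_newick,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    scaffolds: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    scaffolds.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        scaffolds.append((name, "".join(chunks)))
    return ReferenceGenome(tuple(scaffolds))


def load_config(path_or_dict) -> dict[str, Any]:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    for key in ("reference", "vcf_dir", "gff", "outdir"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
    return cfg


def cluster_assign(tree: Tree, k: int) -> dict[str, int]:
    """Leaf clusters obtained by cutting the k-1 longest branches.

    Cluster indices are ordered by the smallest leaf name they contain.
    Singletons arise naturally when a pendant branch is among the longest.
    """
    leaves = tree.leaf_names()
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds the {len(leaves)} leaves")
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = tree.edges()
    order = sorted(
        range(len(edges)),
        key=lambda e: (-edges[e][2], min(l.name for l in edges[e][1].leaves())),
    )
    cut = set(order[: k - 1])

    signature: dict[str, frozenset[int]] = {}

    def walk(node, sig: frozenset[int]) -> None:
        for child in node.children:
            eid = edge_id[(id(node), id(child))]
            child_sig = sig | {eid} if eid in cut else sig
            if child.is_leaf():
                signature[child.name] = child_sig
            else:
                walk(child, child_sig)

    edge_id = {(id(p), id(c)): i for i, (p, c, _l) in enumerate(edges)}
    walk(tree.root, frozenset())
    groups: dict[frozenset[int], list[str]] = {}
    for leaf, sig in signature.items():
        groups.setdefault(sig, []).append(leaf)
    ordered = sorted(groups.values(), key=lambda ls: min(ls))
    return {leaf: i for i, ls in enumerate(ordered) for leaf in ls}


def _het_positions(calls: pd.DataFrame) -> dict[str, np.ndarray]:
    het = calls[calls["genotype_class"] == "het"]
    return {
        scaf: np.sort(grp["pos"].to_numpy() - 1)
        for scaf, grp in het.groupby("scaffold", sort=True)
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, isolate: str | None, cause: Exception):
        self.stage = stage
        self.isolate = isolate
        who = f" (isolate {isolate})" if isolate else ""
        super().__init__(f"stage {stage!r}{who} failed: {cause}")


def run_pipeline(config) -> CohortReport:
    cfg = load_config(config)
    params = cfg["params"]
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)

    genome = read_fasta(cfg["reference"])
    genes = variant_io.read_gff3(cfg["gff"])

    vcf_dir = cfg["vcf_dir"]
    vcfs = sorted(f for f in os.listdir(vcf_dir) if f.endswith(".vcf"))
    if not vcfs:
        raise ValueError(f"no .vcf files found in {vcf_dir}")
    depth_dir = cfg.get("depth_dir")

    calls_by_isolate: dict[str, pd.DataFrame] = {}
    counts = {}
    for fname in vcfs:
        name = fname[: -len(".vcf")]
        try:
            raw = variant_io.read_vcf(os.path.join(vcf_dir, fname))
            kept = variant_io.filter_calls(
                raw, min_depth=params["min_depth"], min_qual=params["min_qual"]
            )
        except Exception as exc:  # malformed input is a hard error
            raise StageError("filter", name, exc) from exc
        calls_by_isolate[name] = kept
        n_het = int((kept["genotype_class"] == "het").sum())
        n_hom = int((kept["genotype_class"] == "hom_alt").sum())
        counts[name] = {
            "n_records": len(raw),
            "n_filtered": len(raw) - len(kept),
            "n_SNPs": n_het + n_hom,
            "n_het": n_het,
            "n_hom": n_hom,
        }
        log.info("%s: %d records, %d kept", name, len(raw), len(kept))
    names = sorted(calls_by_isolate)

    # ploidy
    ploidy_rows = {}
    for name in names:
        het = calls_by_isolate[name][
            calls_by_isolate[name]["genotype_class"] == "het"
        ]
        call = ploidy.classify_ploidy(ploidy.balance_histogram(het))
        ploidy_rows[name] = call
    ploidy_df = pd.DataFrame(
        [
            (
                n,
                c.n_sites,
                c.mass_diploid,
                c.mass_triploid,
                c.label,
            )
            for n, c in ploidy_rows.items()
        ],
        columns=["isolate", "n_het_sites", "mass_diploid", "mass_triploid", "label"],
    )
    ploidy_df.to_csv(os.path.join(outdir, "ploidy.tsv"), sep="\t", index=False)

    # LOH
    loh_summaries = {}
    for name in names:
        try:
            het_pos = _het_positions(calls_by_isolate[name])
            regions = loh.scan_loh(
                het_pos,
                genome,
                window=params["loh_window"],
                step=params["loh_step"],
                max_het=params["loh_max_het"],
            )
            loh.write_bed(regions, os.path.join(outdir, f"{name}.loh.bed"))
            loh_summaries[name] = loh.loh_summary(het_pos, regions, genome)
        except Exception as exc:
            raise StageError("loh", name, exc) from exc

    # tree + clusters
    tree_newick = None
    clusters: dict[str, int] = {name: 0 for name in names}
    if len(names) >= 3:
        try:
            pm = phylo.polymorphic_matrix(calls_by_isolate, genome)
            dm = phylo.distance_matrix(pm)
            dm.to_frame().to_csv(os.path.join(outdir, "distances.tsv"), sep="\t")
            tree = phylo.nj_tree(dm)
            phylo.write_newick(tree, os.path.join(outdir, "tree.nwk"))
            tree_newick = tree.newick()
            k = params["n_clusters"] or 1
            clusters = cluster_assign(tree, k)
        except Exception as exc:
            raise StageError("tree", None, exc) from exc

    # diversity, cohort-wide and per cluster
    div_frames = []
    try:
        aln = diversity.build_alignment(calls_by_isolate, genome)
        if aln.n >= 2:
            dw = diversity.window_scan(aln, window=params["diversity_window"])
            dw["cluster"] = "all"
            div_frames.append(dw)
        for cl in sorted(set(clusters.values())):
            members = [n for n in names if clusters[n] == cl]
            if len(members) < 2:
                continue
            sub = {n: calls_by_isolate[n] for n in members}
            aln_c = diversity.build_alignment(sub, genome)
            dw = diversity.window_scan(aln_c, window=params["diversity_window"])
            dw["cluster"] = f"C{cl}"
            div_frames.append(dw)
    except Exception as exc:
        raise StageError("diversity", None, exc) from exc
    div_df = (
        pd.concat(div_frames, ignore_index=True)
        if div_frames
        else pd.DataFrame(
            columns=[
                "scaffold", "start", "end", "S", "n", "pi", "theta_w",
                "tajima_d", "cluster",
            ]
        )
    )
    div_df.to_csv(os.path.join(outdir, "diversity.tsv"), sep="\t", index=False)

    # CNV per isolate (requires a depth track)
    gene_cn: dict[str, pd.Series] = {}
    cnv_summaries: dict[str, dict] = {}
    if depth_dir:
        for name in names:
            dpath = os.path.join(depth_dir, f"{name}.depth.tsv")
            if not os.path.exists(dpath):
                raise StageError(
                    "cnv", name, FileNotFoundError(f"missing depth file {dpath}")
                )
            try:
                track = variant_io.CoverageTrack.from_tsv(dpath)
                iso_ploidy = 3 if ploidy_rows[name].label == "triploid" else 2
                ratios = cnv_mod.normalize_ratios(
                    track,
                    window=params["cnv_window"],
                    step=params["cnv_step"],
                    edge_exclusion=params["cnv_edge_exclusion"],
                )
                segments = cnv_mod.segment_cn(
                    ratios, iso_ploidy, min_span=params["cnv_min_span"]
                )
                if iso_ploidy == 3:
                    segments = [
                        dataclasses.replace(
                            seg,
                            config=cnv_mod.subgenome_attribution(
                                seg, _segment_balances(calls_by_isolate[name], seg)
                            ),
                        )
                        if seg.klass != "neutral"
                        else seg
                        for seg in segments
                    ]
                cnv_mod.write_segments_bed(
                    segments, os.path.join(outdir, f"{name}.cnv.bed")
                )
                aneu = cnv_mod.detect_aneuploidy(track, iso_ploidy)
                gcn = cnv_mod.gene_copy_number(segments, genes, iso_ploidy)
                gene_cn[name] = gcn["copy_number"]
                cnv_summaries[name] = {
                    "n_gains": sum(s.klass == "gain" for s in segments),
                    "n_losses": sum(s.klass == "loss" for s in segments),
                    "n_aneuploid_scaffolds": sum(
                        v != "euploid" for v in aneu.values()
                    ),
                }
            except StageError:
                raise
            except Exception as exc:
                raise StageError("cnv", name, exc) from exc

    core = accessory = None
    if gene_cn:
        matrix = pd.DataFrame(gene_cn)
        matrix.to_csv(os.path.join(outdir, "gene_cn_matrix.tsv"), sep="\t")
        core, accessory, table = cnv_mod.core_accessory(matrix)
        table.to_csv(os.path.join(outdir, "core_accessory.tsv"), sep="\t")

    rows = []
    for name in names:
        summ = loh_summaries[name]
        cs = cnv_summaries.get(name, {})
        rows.append(
            {
                "isolate": name,
                "ploidy": ploidy_rows[name].label,
                **counts[name],
                "loh_regions": summ["n_regions"],
                "loh_fraction": summ["fraction"],
                "het_rate_excluding_loh": summ["het_rate_excluding_loh"],
                "cluster": clusters.get(name, 0),
                "n_gains": cs.get("n_gains"),
                "n_losses": cs.get("n_losses"),
                "n_aneuploid_scaffolds": cs.get("n_aneuploid_scaffolds"),
            }
        )
    per_isolate = pd.DataFrame(rows)
    per_isolate.to_csv(os.path.join(outdir, "report.tsv"), sep="\t", index=False)
    report = CohortReport(
        per_isolate=per_isolate,
        diversity_windows=div_df,
        tree_newick=tree_newick,
        clusters=clusters,
        core_genes=core,
        accessory_genes=accessory,
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    return report


def _segment_balances(calls: pd.DataFrame, seg) -> np.ndarray:
    sub = calls[
        (calls["scaffold"] == seg.scaffold)
        & (calls["pos"] - 1 >= seg.start)
        & (calls["pos"] - 1 < seg.end)
        & (calls["genotype_class"] != "hom_ref")
    ]
    return variant_io.allele_balance(sub).dropna().to_numpy()
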