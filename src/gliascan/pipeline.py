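"""End-to-end orchestration: FASTQ pairs -> epitope counts, toxicity, tree.

This is the glue the CLI and the reproduction script call; every stage is
an importable function from the stage modules, so nothing here is more
than bookkeeping plus output writing.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .catalogue import EpitopeRecord
from .cluster import ProteinCluster, dedup_clusters, filter_pseudogenes, top_clusters, translate_cds
from .preprocess import PreprocessLog, run_preprocess
from .quantify import EpitopeCountMatrix, count_matrix, discover_variants, intact_33mer, presence_matrix
from .report import LineTree, align_star, alignment_profile, build_line_tree, consensus
from .toxicity import toxicity_scores


@dataclass
class PipelineResult:
    """Everything one analysis run produces."""

    log: PreprocessLog
    clusters_by_line: dict[str, list[ProteinCluster]]
    counts: EpitopeCountMatrix
    presence: pd.DataFrame
    presence_totals: pd.Series
    intact_33mer: pd.Series
    toxicity: pd.DataFrame | None
    novel_variants: pd.DataFrame
    consensuses: dict[str, str] = field(default_factory=dict)
    tree: LineTree | None = None
    pseudogenes_discarded: int = 0


def proteins_from_cds(cds_counts: Mapping[str, int]) -> tuple[Counter, int]:
    """Translate a CDS multiset into a protein multiset, dropping stops.

    Returns the retained protein counter and the number of stop-containing
    (pseudogene-like) sequences discarded, copies included.
    """
    proteins: Counter = Counter()
    discarded = 0
    for cds, copies in cds_counts.items():
        protein = translate_cds(cds)
        if "*" in protein:
            discarded += copies
        else:
            proteins[protein] += copies
    return proteins, discarded


def cluster_lines(
    per_line_cds: Mapping[str, Mapping[str, int]], min_members: int = 20
) -> tuple[dict[str, list[ProteinCluster]], int]:
    """Translate, stop-filter and cluster every line's CDS multiset."""
    clusters_by_line: dict[str, list[ProteinCluster]] = {}
    discarded_total = 0
    for line, cds_counts in per_line_cds.items():
        proteins, discarded = proteins_from_cds(cds_counts)
        discarded_total += discarded
        clusters_by_line[line] = dedup_clusters(proteins, min_members, line)
    return clusters_by_line, discarded_total


def analyze(
    r1_path: str | Path,
    r2_path: str | Path,
    barcodes: Mapping[str, str],
    records: Sequence[EpitopeRecord],
    *,
    min_members: int = 20,
    max_mismatch: int = 1,
    top_n: int = 10,
    bootstrap_replicates: int = 1000,
    seed: int = 0,
    max_barcode_mismatch: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on one paired-end FASTQ dataset."""
    per_line_cds, log = run_preprocess(
        r1_path, r2_path, barcodes, max_barcode_mismatch=max_barcode_mismatch
    )
    clusters_by_line, discarded = cluster_lines(per_line_cds, min_members)

    counts = count_matrix(clusters_by_line, records, max_mismatch)
    presence, totals = presence_matrix(counts)
    mer33 = intact_33mer(clusters_by_line)

    try:
        tox = toxicity_scores(counts, records)
    except ValueError:
        tox = None

    novel_rows = []
    seen: set[tuple[str, str]] = set()
    for line, clusters in sorted(clusters_by_line.items()):
        for cl in clusters:
            for nv in discover_variants(cl.representative, records, max_mismatch):
                key = (line, nv.peptide)
                if key not in seen:
                    seen.add(key)
                    novel_rows.append(
                        {
                            "line_id": line,
                            "peptide": nv.peptide,
                            "nearest_canonical": nv.nearest_canonical,
                            "distance": nv.distance,
                        }
                    )
    novel = pd.DataFrame(novel_rows, columns=["line_id", "peptide", "nearest_canonical", "distance"])

    consensuses: dict[str, str] = {}
    for line, clusters in sorted(clusters_by_line.items()):
        if clusters:
            consensuses[line] = consensus(top_clusters(clusters, top_n), line).consensus
    tree = None
    if len(consensuses) >= 3:
        aligned = dict(zip(consensuses, align_star(list(consensuses.values()))))
        tree = build_line_tree(aligned, bootstrap_replicates, seed)

    result = PipelineResult(
        log=log,
        clusters_by_line=clusters_by_line,
        counts=counts,
        presence=presence,
        presence_totals=totals,
        intact_33mer=mer33,
        toxicity=tox,
        novel_variants=novel,
        consensuses=consensuses,
        tree=tree,
        pseudogenes_discarded=discarded,
    )
    if out_dir is not None:
        write_outputs(
            result,
            out_dir,
            params={
                "min_members": min_members,
                "max_mismatch": max_mismatch,
                "top_n": top_n,
                "bootstrap_replicates": bootstrap_replicates,
                "seed": seed,
                "max_barcode_mismatch": max_barcode_mismatch,
            },
        )
    return result


def clusters_to_frame(clusters_by_line: Mapping[str, Sequence[ProteinCluster]]) -> pd.DataFrame:
    rows = [
        {"line_id": c.line_id, "rank": c.rank, "members": c.members, "representative": c.representative}
        for line in sorted(clusters_by_line)
        for c in clusters_by_line[line]
    ]
    return pd.DataFrame(rows, columns=["line_id", "rank", "members", "representative"])


def frame_to_clusters(df: pd.DataFrame) -> dict[str, list[ProteinCluster]]:
    out: dict[str, list[ProteinCluster]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["line_id"]), []).append(
            ProteinCluster(
                line_id=str(row["line_id"]),
                representative=str(row["representative"]),
                members=int(row["members"]),
                rank=int(row["rank"]),
            )
        )
    return out


def write_outputs(result: PipelineResult, out_dir: str | Path, params: dict | None = None) -> None:
    """Write all tables, the tree and the run-summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clusters_to_frame(result.clusters_by_line).to_csv(out / "clusters.tsv", sep="\t", index=False)
    result.counts.write(out)
    result.presence.to_csv(out / "presence.tsv", sep="\t")
    result.presence_totals.to_frame().T.to_csv(out / "presence_totals.tsv", sep="\t")
    result.intact_33mer.to_frame().to_csv(out / "intact_33mer.tsv", sep="\t")
    if result.toxicity is not None:
        result.toxicity.to_csv(out / "toxicity.tsv", sep="\t")
    result.novel_variants.to_csv(out / "novel_variants.tsv", sep="\t", index=False)
    if result.consensuses:
        with open(out / "consensus.fasta", "w") as fh:
            for line, seq in result.consensuses.items():
                fh.write(f">{line}\n{seq}\n")
        aligned = dict(zip(result.consensuses, align_star(list(result.consensuses.values()))))
        alignment_profile(aligned).to_csv(out / "logo_matrix.tsv", sep="\t")
    if result.tree is not None:
        (out / "line_tree.nwk").write_text(result.tree.newick + "\n")
    summary = {
        "version": __version__,
        "params": params or {},
        "read_fates": result.log.as_dict(),
        "pseudogenes_discarded": result.pseudogenes_discarded,
        "depths": {str(k): int(v) for k, v in result.counts.depths.items()},
        "count_metadata": result.counts.metadata,
        "bootstrap_replicates_used": result.tree.n_replicates if result.tree else 0,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
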