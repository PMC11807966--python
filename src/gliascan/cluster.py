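"""Translation, pseudogene filtering and exact-identity protein clustering.

Alpha-gliadin transcript families contain a large pseudogene fraction whose
hallmark is an internal stop codon; those translations are discarded before
any epitope counting.  The remaining proteins are collapsed at 100%
identity into abundance-ranked clusters, and only clusters with at least a
minimum number of members (default 20) enter the downstream analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq


@dataclass(frozen=True)
class ProteinCluster:
    """A unique protein sequence and its per-line abundance."""

    line_id: str
    representative: str
    members: int
    rank: int

    def __post_init__(self) -> None:
        if self.members < 1:
            raise ValueError("cluster must have at least one member")


def translate_cds(cds: str) -> str:
    """Standard-code frame-0 translation; stops rendered as ``*``.

    A 3' remainder that does not fill a codon is trimmed (the caller logs
    how many sequences needed it via ``len(cds) % 3``).
    """
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def filter_pseudogenes(proteins: Iterable[str]) -> tuple[list[str], int]:
    """Drop proteins containing internal stops; returns (retained, discarded)."""
    retained: list[str] = []
    discarded = 0
    for protein in proteins:
        if "*" in protein:
            discarded += 1
        else:
            retained.append(protein)
    return retained, discarded


def dedup_clusters(
    proteins: Iterable[str] | Mapping[str, int],
    min_members: int = 20,
    line_id: str = "",
) -> list[ProteinCluster]:
    """Collapse identical proteins into ranked clusters.

    Equivalent to 100%-identity clustering of equal-region amplicon
    proteins: identical strings share a cluster, nothing else is merged.
    Clusters below ``min_members`` are dropped; survivors are ranked by
    member count descending, ties broken by lexicographic representative.
    """
    counts = Counter(proteins) if not isinstance(proteins, Mapping) else Counter(proteins)
    survivors = sorted(
        ((rep, n) for rep, n in counts.items() if n >= min_members),
        key=lambda item: (-item[1], item[0]),
    )
    return [
        ProteinCluster(line_id=line_id, representative=rep, members=n, rank=i + 1)
        for i, (rep, n) in enumerate(survivors)
    ]


def top_clusters(clusters: Sequence[ProteinCluster], n: int = 10) -> list[ProteinCluster]:
    """The ``n`` most prevalent clusters (all of them when fewer exist)."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(clusters, key=lambda c: c.rank)
    return list(ranked[:n])
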