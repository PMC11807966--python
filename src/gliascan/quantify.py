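"""Mismatch-tolerant epitope scanning and cluster-weighted quantification.

The scanner slides a window of every catalogued epitope length along a
protein and attributes each window to the catalogue entry with the fewest
mismatches (exact matches always win; remaining ties go to catalogue
order), so a window is never double-counted as both a canonical and one of
its near-variants.  Occurrences are positional: overlapping copies count
separately, which is what makes the intact 33-mer contribute six epitope
hits (1× DQ2.5-Glia-α1a, 2× α1b, 3× α2).

Counts are cluster-weighted (occurrences in a representative × its member
count), summed per line, normalized per million retained coding sequences
and log2-transformed with a pseudocount of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import THIRTY_THREE_MER, EpitopeRecord, scannable
from .cluster import ProteinCluster


@dataclass(frozen=True)
class EpitopeHit:
    """One window attributed to one catalogued epitope."""

    epitope: str
    start: int
    length: int
    mismatches: int


@dataclass
class EpitopeCountMatrix:
    """Epitope × line count matrix with raw, normalized and log2 layers."""

    raw: pd.DataFrame
    depths: pd.Series
    pseudocount: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def normalized(self) -> pd.DataFrame:
        """Counts per million retained CDSs of the line."""
        depths = self.depths.replace(0, np.nan)
        return (self.raw * 1e6).div(depths, axis=1).fillna(0.0)

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.normalized + self.pseudocount)

    def write(self, out_dir: str | Path, prefix: str = "epitope_counts") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.raw.to_csv(out / f"{prefix}_raw.tsv", sep="\t")
        self.normalized.to_csv(out / f"{prefix}_normalized.tsv", sep="\t")
        self.log2.to_csv(out / f"{prefix}_log2.tsv", sep="\t")


def _hamming_capped(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def scan_sequence(
    protein: str, records: Sequence[EpitopeRecord], max_mismatch: int = 1
) -> list[EpitopeHit]:
    """All qualifying epitope windows in a protein, overlaps included.

    Window comparisons are vectorized per epitope length: every window is
    Hamming-compared to every catalogued peptide of that length and
    attributed to the minimum-mismatch entry (argmin returns the first,
    i.e. catalogue-order, entry on ties; an exact match is always the
    minimum, so it always wins).
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    recs = scannable(records)
    by_length: dict[int, list[EpitopeRecord]] = {}
    for rec in recs:
        by_length.setdefault(len(rec.peptide), []).append(rec)

    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
    hits: list[EpitopeHit] = []
    for length, of_len in sorted(by_length.items()):
        if len(arr) < length:
            continue
        peptides = np.frombuffer(
            "".join(r.peptide for r in of_len).encode("ascii"), dtype=np.uint8
        ).reshape(len(of_len), length)
        windows = np.lib.stride_tricks.sliding_window_view(arr, length)
        mismatches = (windows[:, None, :] != peptides[None, :, :]).sum(axis=2)
        best_idx = mismatches.argmin(axis=1)
        best_mm = mismatches[np.arange(len(best_idx)), best_idx]
        for start in np.nonzero(best_mm <= max_mismatch)[0]:
            hits.append(
                EpitopeHit(of_len[best_idx[start]].name, int(start), length, int(best_mm[start]))
            )
    hits.sort(key=lambda h: (h.length, h.start))
    return hits


def occurrence_counts(
    protein: str, records: Sequence[EpitopeRecord], max_mismatch: int = 1
) -> dict[str, int]:
    """Epitope name -> positional occurrence count within one protein."""
    counts: dict[str, int] = {}
    for hit in scan_sequence(protein, records, max_mismatch):
        counts[hit.epitope] = counts.get(hit.epitope, 0) + 1
    return counts


@dataclass(frozen=True)
class NovelVariant:
    """A window near a canonical epitope that the catalogue does not list."""

    peptide: str
    nearest_canonical: str
    distance: int
    positions: tuple[int, ...]


def discover_variants(
    protein: str, records: Sequence[EpitopeRecord], max_mismatch: int = 1
) -> list[NovelVariant]:
    """Length-9 windows within ``max_mismatch`` of a canonical but uncatalogued."""
    canonicals = [r for r in scannable(records) if r.canonical and len(r.peptide) == 9]
    known = {r.peptide for r in scannable(records)}
    found: dict[str, tuple[str, int, list[int]]] = {}
    if len(protein) < 9 or not canonicals:
        return []
    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
    peptides = np.frombuffer(
        "".join(r.peptide for r in canonicals).encode("ascii"), dtype=np.uint8
    ).reshape(len(canonicals), 9)
    windows = np.lib.stride_tricks.sliding_window_view(arr, 9)
    mismatches = (windows[:, None, :] != peptides[None, :, :]).sum(axis=2)
    best_idx = mismatches.argmin(axis=1)
    best_mm = mismatches[np.arange(len(best_idx)), best_idx]
    for start in np.nonzero(best_mm <= max_mismatch)[0]:
        window = protein[start : start + 9]
        if window in known:
            continue
        if window in found:
            found[window][2].append(int(start))
        else:
            found[window] = (canonicals[best_idx[start]].name, int(best_mm[start]), [int(start)])
    return [
        NovelVariant(pep, name, mm, tuple(pos))
        for pep, (name, mm, pos) in sorted(found.items())
    ]


def count_matrix(
    clusters_by_line: Mapping[str, Sequence[ProteinCluster]],
    records: Sequence[EpitopeRecord],
    max_mismatch: int = 1,
    all_rows: bool = False,
) -> EpitopeCountMatrix:
    """Cluster-weighted raw counts per epitope and line, with depth layers.

    raw[e, line] = Σ over the line's (thresholded) clusters of
    occurrences(e, representative) × members.  The depth used for per-million
    normalization is the line's retained CDS count after all filters, i.e.
    the member sum of the clusters given here.
    """
    lines = sorted(clusters_by_line)
    names = [r.name for r in records]
    raw = pd.DataFrame(0, index=names, columns=lines, dtype=np.int64)
    depths = pd.Series(0, index=lines, dtype=np.int64)
    scan_cache: dict[str, dict[str, int]] = {}
    for line in lines:
        for cl in clusters_by_line[line]:
            occ = scan_cache.get(cl.representative)
            if occ is None:
                occ = occurrence_counts(cl.representative, records, max_mismatch)
                scan_cache[cl.representative] = occ
            depths[line] += cl.members
            for name, k in occ.items():
                raw.loc[name, line] += k * cl.members
    if not all_rows:
        raw = raw.loc[raw.sum(axis=1) > 0]
    return EpitopeCountMatrix(
        raw=raw,
        depths=depths,
        metadata={
            "max_mismatch": max_mismatch,
            "depth": "retained CDSs after all filters (member sum of thresholded clusters)",
            "pseudocount": 1.0,
        },
    )


def presence_matrix(raw: pd.DataFrame | EpitopeCountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Binary epitope × line matrix and its per-line totals row."""
    if isinstance(raw, EpitopeCountMatrix):
        raw = raw.raw
    presence = (raw > 0).astype(int)
    totals = presence.sum(axis=0)
    totals.name = "total_epitopes"
    return presence, totals


def intact_33mer(
    clusters_by_line: Mapping[str, Sequence[ProteinCluster]]
) -> pd.Series:
    """Per-line abundance of clusters containing the intact 33-mer.

    Exact-substring containment only: a single substitution inside the
    33-mer disqualifies the cluster, by contract.
    """
    lines = sorted(clusters_by_line)
    out = pd.Series(0, index=lines, dtype=np.int64, name="intact_33mer")
    for line in lines:
        for cl in clusters_by_line[line]:
            if THIRTY_THREE_MER in cl.representative:
                out[line] += cl.members
    return out
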