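"""Consensus proteins, alignment profiles and the line phylogeny.

Each line is summarized by the cluster-size-weighted consensus of its most
prevalent protein clusters; the consensuses are aligned, reduced to
pairwise p-distances and joined into a neighbor-joining tree whose splits
carry bootstrap support from alignment-column resampling.

Representatives of one amplicon are near-identical, so a center-star
progressive alignment with a simple scheme (match 1, mismatch 0, linear
gap −1) is adequate; no substitution matrix is needed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj

from .cluster import ProteinCluster

GAP = "-"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def align_star(seqs: Sequence[str]) -> list[str]:
    """Center-star multiple alignment around the longest sequence.

    Every sequence is pairwise-aligned to the center; gaps opened in the
    center by any pairwise alignment are propagated to all rows, giving one
    rectangular alignment in the input order.
    """
    if not seqs:
        return []
    if len(set(seqs)) == 1:
        return list(seqs)
    center = max(seqs, key=lambda s: (len(s), s))
    m = len(center)
    aligner = _aligner()

    gapped: list[tuple[str, str] | None] = []
    gaps_before = np.zeros((len(seqs), m + 1), dtype=int)
    for k, seq in enumerate(seqs):
        if seq == center:
            gapped.append(None)
            continue
        aln = aligner.align(center, seq)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        gapped.append((c_row, s_row))
        i = 0
        for ch in c_row:
            if ch == GAP:
                gaps_before[k, i] += 1
            else:
                i += 1
    master = gaps_before.max(axis=0)

    out: list[str] = []
    for k, seq in enumerate(seqs):
        if gapped[k] is None:
            row = []
            for i in range(m):
                row.append(GAP * master[i] + center[i])
            row.append(GAP * master[m])
            out.append("".join(row))
            continue
        c_row, s_row = gapped[k]
        row = []
        i = 0  # center residue index
        block = []  # other-sequence chars inside the current center gap run
        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == GAP:
                block.append(s_ch)
            else:
                insert = "".join(block)
                row.append(insert + GAP * (master[i] - len(insert)) + s_ch)
                block = []
                i += 1
        insert = "".join(block)
        row.append(insert + GAP * (master[m] - len(insert)))
        out.append("".join(row))
    assert len({len(r) for r in out}) == 1
    return out


@dataclass
class ConsensusProfile:
    """Weighted consensus of a line's top clusters plus its logo matrix."""

    line_id: str
    consensus: str
    column_frequencies: pd.DataFrame  # positions × residues (incl. gap), rows sum to 1


def consensus(clusters: Sequence[ProteinCluster], line_id: str | None = None) -> ConsensusProfile:
    """Cluster-size-weighted majority consensus of the representatives.

    Ties between residues go to the alphabetically smaller residue; columns
    where the gap outweighs every residue are dropped from the consensus
    string but kept in the frequency table.
    """
    if not clusters:
        raise ValueError("consensus requires at least one cluster")
    if line_id is None:
        line_id = clusters[0].line_id
    reps = [c.representative for c in clusters]
    weights = np.array([c.members for c in clusters], dtype=float)
    aligned = align_star(reps)
    n_cols = len(aligned[0])

    alphabet = sorted({ch for row in aligned for ch in row})
    freq = pd.DataFrame(0.0, index=range(n_cols), columns=alphabet)
    for row, w in zip(aligned, weights):
        for pos, ch in enumerate(row):
            freq.loc[pos, ch] += w
    freq /= weights.sum()

    chars = []
    for pos in range(n_cols):
        col = freq.loc[pos]
        residues = col.drop(GAP, errors="ignore")
        best = residues.idxmax()  # ties -> first index, i.e. alphabetical
        gap_w = col.get(GAP, 0.0)
        if gap_w > residues[best]:
            continue
        chars.append(best)
    return ConsensusProfile(line_id, "".join(chars), freq)


def alignment_profile(aligned: Mapping[str, str]) -> pd.DataFrame:
    """Unweighted column-frequency (logo) matrix of an alignment."""
    rows = list(aligned.values())
    n_cols = len(rows[0])
    alphabet = sorted({ch for row in rows for ch in row})
    freq = pd.DataFrame(0.0, index=range(n_cols), columns=alphabet)
    for row in rows:
        for pos, ch in enumerate(row):
            freq.loc[pos, ch] += 1.0
    return freq / len(rows)


def p_distance(a: str, b: str) -> float:
    """Fraction of differing columns among pairwise non-gap columns."""
    if len(a) != len(b):
        raise ValueError("p-distance requires aligned (equal-length) sequences")
    compared = mismatched = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatched += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns")
    return mismatched / compared


def distance_matrix(aligned: Mapping[str, str]) -> pd.DataFrame:
    """All pairwise p-distances of an aligned sequence set."""
    taxa = list(aligned)
    dm = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            d = p_distance(aligned[a], aligned[b])
            dm.loc[a, b] = dm.loc[b, a] = d
    return dm


def nj_tree(dm: pd.DataFrame):
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch-length estimates (a known NJ artifact) are clamped to 0.
    Returns an unrooted skbio TreeNode.
    """
    if dm.shape[0] != dm.shape[1] or dm.shape[0] < 3:
        raise ValueError("distance matrix must be square with at least 3 taxa")
    if not np.allclose(dm.values, dm.values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dm.values), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    tree = nj(DistanceMatrix(dm.values, ids=[str(t) for t in dm.index]))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_splits(tree, taxa: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, orientation-normalized."""
    universe = frozenset(taxa)
    ref = min(universe)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            splits.add(side)
    return splits


@dataclass
class LineTree:
    """NJ tree over the lines with per-split bootstrap support."""

    taxa: list[str]
    newick: str
    supports: dict[frozenset, float]
    tree: object
    n_replicates: int = 0


def build_line_tree(
    aligned: Mapping[str, str],
    bootstrap_replicates: int = 1000,
    seed: int = 0,
) -> LineTree:
    """NJ tree of aligned per-line consensuses with bootstrap support.

    Bootstrap: alignment columns are resampled with replacement, the
    p-distance matrix and NJ tree recomputed, and each split's support is
    the percentage of replicates containing it.  Deterministic under seed.
    """
    taxa = list(aligned)
    tree = nj_tree(distance_matrix(aligned))
    splits = tree_splits(tree, taxa)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    n_cols = len(next(iter(aligned.values())))
    rows = {t: np.array(list(aligned[t])) for t in taxa}
    used = 0
    for _ in range(bootstrap_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {t: "".join(rows[t][cols]) for t in taxa}
        try:
            rep_tree = nj_tree(distance_matrix(resampled))
        except ValueError:
            continue
        used += 1
        rep_splits = tree_splits(rep_tree, taxa)
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {
        s: (100.0 * c / used if used else 0.0) for s, c in counts.items()
    }

    universe = frozenset(taxa)
    ref = min(universe)
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = universe - side
        if side in supports:
            node.name = f"{supports[side]:.0f}"
    buf = io.StringIO()
    tree.write(buf)
    return LineTree(taxa, buf.getvalue().strip(), supports, tree, used)
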