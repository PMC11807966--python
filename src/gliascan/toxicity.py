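"""Per-line immunotoxicity load from class-stratified epitope counts.

Epitopes are grouped by reported toxicity class; the normalized counts of
the toxic (T), decreased-toxicity (RT) and highly-likely-toxic (*T)
classes are weighted 3/2/1 and summed into a line score.  The line with
the highest score defines 100% and every other line is expressed relative
to it.  Non-toxic, highly-likely-not-toxic and unknown classes carry
weight 0, so e.g. the ubiquitous but non-toxic DQ2.5-Glia-α3 (var1)
FPPQQPYPQ never inflates a line's load.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .catalogue import EpitopeRecord, ToxicityWeights
from .quantify import EpitopeCountMatrix

SCORED_CLASSES = ("T", "RT", "STAR_T")


def toxicity_scores(
    counts: EpitopeCountMatrix | pd.DataFrame,
    records: Sequence[EpitopeRecord],
    weights: ToxicityWeights = ToxicityWeights(),
) -> pd.DataFrame:
    """Weighted toxicity load and relative percentage per line.

    Parameters
    ----------
    counts:
        An :class:`EpitopeCountMatrix` (its normalized layer is used) or a
        plain epitope × line DataFrame already on the comparison scale.
    records:
        Catalogue records; every matrix row must map to one (hard error
        otherwise).

    Returns
    -------
    DataFrame indexed by line with columns count_T, count_RT, count_STAR_T,
    weighted_score, relative_percent (one decimal) and rank.  Exactly one
    line has relative_percent 100.0.
    """
    matrix = counts.normalized if isinstance(counts, EpitopeCountMatrix) else counts
    class_of: Mapping[str, str] = {r.name: r.toxicity_class for r in records}
    missing = [name for name in matrix.index if name not in class_of]
    if missing:
        raise KeyError(f"matrix rows absent from catalogue: {missing}")

    lines = list(matrix.columns)
    out = pd.DataFrame(index=lines, dtype=float)
    for cls in SCORED_CLASSES:
        rows = [name for name in matrix.index if class_of[name] == cls]
        out[f"count_{cls}"] = matrix.loc[rows].sum(axis=0) if rows else 0.0
    out["weighted_score"] = (
        weights.weight_T * out["count_T"]
        + weights.weight_RT * out["count_RT"]
        + weights.weight_STAR_T * out["count_STAR_T"]
    )
    top = out["weighted_score"].max()
    if not top > 0:
        raise ValueError("all lines have zero toxicity load; no reference line")
    out["relative_percent"] = (100.0 * out["weighted_score"] / top).round(1)
    order = out["weighted_score"].sort_values(ascending=False, kind="stable")
    out["rank"] = pd.Series(
        range(1, len(order) + 1), index=order.index, dtype=int
    )
    return out
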