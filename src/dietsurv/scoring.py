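"""Per-sample pathway scores, group fold-changes and heatmap scaling.

A pathway score is the mean, over the panel genes present in the matrix,
of the incremented log2-transformed expression of each sample — one
number per (sample, pathway).  Heatmap values put each gene's FPKM on a
log2 scale relative to the average FPKM of the reference gene panel in
the same sample, so a sample's panel satisfies mean(2**H) == 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, ValidationError, from_log2p1, to_log2p1

logger = logging.getLogger(__name__)

__all__ = [
    "pathway_score",
    "group_log2fc",
    "heatmap_values",
    "HeatmapMatrix",
    "per_sample_sum_normalize",
]


def _panel_present(m: ExpressionMatrix, gs: GeneSet) -> list[str]:
    present = [g for g in gs.members if g in m.values.index]
    if not present:
        raise ValidationError(f"gene set {gs.name!r} shares no genes with the matrix")
    absent = [g for g in gs.members if g not in m.values.index]
    if absent:
        logger.warning(
            "gene set %r: %d/%d member(s) absent from matrix and dropped: %s",
            gs.name, len(absent), len(gs.members), absent[:10],
        )
    return present


def pathway_score(
    m: ExpressionMatrix,
    gene_sets: GeneSet | Sequence[GeneSet],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Score each sample for each pathway panel.

    The matrix is converted to the log2p1 scale if needed; the score is
    the unweighted mean of the panel genes present in the matrix.
    Returns a samples-x-pathways DataFrame.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    if m.scale == "fpkm":
        m = to_log2p1(m, pseudocount)
    scores = {}
    for gs in gene_sets:
        present = _panel_present(m, gs)
        scores[gs.name] = m.values.loc[present].mean(axis=0)
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    return out


def group_log2fc(
    m: ExpressionMatrix,
    annotations: pd.DataFrame,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold-change of group A over group B.

    Both groups are taken from the annotation table's ``group`` column
    and must contain at least two samples; the fold-change is the
    difference of group means on the log2p1 scale.
    """
    if m.scale == "fpkm":
        m = to_log2p1(m, pseudocount)
    out = {}
    cols = {}
    for g in (group_a, group_b):
        ids = annotations.index[annotations["group"] == g]
        ids = [s for s in ids if s in m.values.columns]
        if len(ids) < 2:
            raise ValidationError(f"group {g!r} has {len(ids)} sample(s); need >= 2")
        cols[g] = ids
    fc = m.values[cols[group_a]].mean(axis=1) - m.values[cols[group_b]].mean(axis=1)
    fc.name = f"log2fc_{group_a}_vs_{group_b}"
    return fc


@dataclass
class HeatmapMatrix:
    """Gene-x-sample log2-ratio values scaled against a reference panel."""

    values: pd.DataFrame
    panel: str


def heatmap_values(
    m: ExpressionMatrix,
    gs: GeneSet,
    epsilon: float = 0.0,
    reference: str = "panel",
    pseudocount: float = 1.0,
) -> HeatmapMatrix:
    """Per-sample relative expression for heatmap display.

    ``H(g, s) = log2((FPKM(g, s) + eps) / (mean_ref(s) + eps))`` where
    the per-sample reference mean runs over the panel genes
    (``reference="panel"``) or over all matrix genes
    (``reference="all"``).  With ``eps = 0`` the per-sample mean of
    ``2**H`` over the panel equals 1 exactly.
    """
    if m.scale == "log2p1":
        m = from_log2p1(m, pseudocount)
    present = _panel_present(m, gs)
    panel = m.values.loc[present]
    ref = panel.mean(axis=0) if reference == "panel" else m.values.mean(axis=0)
    if epsilon == 0.0 and (ref == 0).any():
        bad = ref.index[ref == 0][0]
        raise ValidationError(
            f"sample {bad!r} has zero reference mean; pass epsilon > 0 to guard"
        )
    h = np.log2((panel + epsilon).div(ref + epsilon, axis=1))
    return HeatmapMatrix(values=h, panel=gs.name)


def per_sample_sum_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its sum so columns sum to one.

    Mirrors the per-sample normalization applied to FPKM-UQ values
    before embedding; requires the fpkm scale.
    """
    if m.scale != "fpkm":
        raise ValidationError("per_sample_sum_normalize requires the fpkm scale")
    sums = m.values.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValidationError(f"sample {bad!r} has all-zero expression; cannot normalize")
    return ExpressionMatrix(m.values.div(sums, axis=1), "fpkm")
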