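"""t-SNE embedding of panel expression, cluster-wise survival, and
ranking of the transcripts most determinant of the cluster patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.manifold import TSNE

from .io import ExpressionMatrix, GeneSet, RunConfig, ValidationError
from .scoring import _panel_present, per_sample_sum_normalize
from .stratify import StratumAssignment
from .survival import LogRankResult, logrank, pairwise_logrank

__all__ = ["EmbeddingResult", "embed", "cluster_survival", "rank_cluster_determinants"]


@dataclass
class EmbeddingResult:
    """2-D sample coordinates plus the parameters that produced them."""

    coordinates: pd.DataFrame  # samples x (tsne1, tsne2)
    params: dict


def embed(
    m: ExpressionMatrix,
    gs: GeneSet,
    config: RunConfig | None = None,
) -> EmbeddingResult:
    """Embed samples in 2-D from the panel genes via t-SNE.

    On the fpkm scale each sample is first normalized to its column sum
    (the per-sample normalization applied upstream of the embedding);
    log2p1 input is used as-is.  Deterministic given ``config.seed``.
    The sample count must be at least three times the perplexity.
    """
    config = config or RunConfig()
    n = len(m.sample_ids)
    if n < 3 * config.perplexity:
        suggested = max(2.0, (n - 1) / 3)
        raise ValidationError(
            f"{n} samples is too few for perplexity {config.perplexity}; "
            f"try perplexity <= {suggested:.0f}"
        )
    if m.scale == "fpkm":
        m = per_sample_sum_normalize(m)
    present = _panel_present(m, gs)
    x = m.values.loc[present].T.to_numpy(dtype=float)
    tsne = TSNE(
        n_components=2,
        perplexity=config.perplexity,
        learning_rate=config.learning_rate,
        max_iter=max(250, int(config.n_iter)),
        init="pca",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(x)
    out = pd.DataFrame(coords, index=pd.Index(m.sample_ids, name="sample_id"),
                       columns=["tsne1", "tsne2"])
    if not np.isfinite(coords).all():
        raise ValidationError("t-SNE produced non-finite coordinates")
    params = {
        "perplexity": config.perplexity,
        "learning_rate": config.learning_rate,
        "n_iter": int(config.n_iter),
        "seed": config.seed,
        "panel": gs.name,
        "n_panel_genes": len(present),
    }
    return EmbeddingResult(coordinates=out, params=params)


def cluster_survival(
    assignment: StratumAssignment,
    survival_table: pd.DataFrame,
) -> tuple[LogRankResult, dict]:
    """Omnibus and pairwise log-rank across cluster strata.

    ``survival_table`` is indexed by sample_id with columns
    ``time``/``event`` (as produced by ``derive_survival_table``).
    Samples missing from either side are dropped; a single non-empty
    cluster is an error.
    """
    common = assignment.labels.index.intersection(survival_table.index)
    labels = assignment.labels.loc[common]
    surv = survival_table.loc[common]
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValidationError(f"need >= 2 strata with survival data, got {names}")
    groups = []
    for name in names:
        ids = labels.index[labels == name]
        groups.append((surv.loc[ids, "time"].to_numpy(), surv.loc[ids, "event"].to_numpy()))
    omnibus = logrank(groups, names)
    pairwise = pairwise_logrank(groups, names)
    return omnibus, pairwise


def rank_cluster_determinants(
    m: ExpressionMatrix,
    gs: GeneSet,
    assignment: StratumAssignment,
    seed: int = 0,
    n_repeats: int = 20,
    n_estimators: int = 200,
) -> pd.DataFrame:
    """Rank panel genes by how strongly they determine the cluster labels.

    Fits a random-forest classifier predicting the cluster labels from
    panel expression and scores each gene by permutation importance (the
    mean accuracy drop over ``n_repeats`` shuffles of that gene's
    column).  Returns genes sorted by decreasing importance with the
    permutation standard deviation; deterministic given the seed.
    """
    present = _panel_present(m, gs)
    common = assignment.labels.index.intersection(m.values.columns)
    y = assignment.labels.loc[common].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("cluster labels are degenerate (single class)")
    x = m.values.loc[present, common].T.to_numpy(dtype=float)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(x, y)
    imp = permutation_importance(clf, x, y, n_repeats=n_repeats, random_state=seed)
    out = pd.DataFrame(
        {
            "importance": imp.importances_mean,
            "importance_sd": imp.importances_std,
        },
        index=pd.Index(present, name="gene"),
    )
    out["method"] = "random_forest_permutation"
    return out.sort_values("importance", ascending=False, kind="stable")
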