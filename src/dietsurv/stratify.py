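"""Sample stratification: median splits, score quadrants, cluster strata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import ValidationError

__all__ = ["StratumAssignment", "median_split", "quadrant_groups", "cluster_strata"]


@dataclass
class StratumAssignment:
    """Per-sample categorical labels plus the rule that produced them.

    ``labels`` maps sample_id -> label; ``rule`` names the assignment
    rule and ``thresholds`` records the cutoffs used, verbatim, so any
    assignment can be audited or re-derived.
    """

    labels: pd.Series
    rule: str
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValidationError("duplicate sample_id in stratum assignment")
        self.labels = self.labels.rename("label")
        self.labels.index.name = "sample_id"

    @property
    def label_set(self) -> list[str]:
        return sorted(self.labels.unique())

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.to_frame()
        out["rule"] = self.rule
        out["thresholds"] = repr(self.thresholds)
        return out


def median_split(scores: pd.DataFrame, pathway: str) -> StratumAssignment:
    """Split samples into high/low at the cohort median pathway score.

    Scores strictly above the median are "high"; ties at the median go
    to "low" (deterministic, and conservative for the high-expression
    group).  An all-identical score vector admits no informative split
    and is an error.
    """
    if pathway not in scores.columns:
        raise ValidationError(f"pathway {pathway!r} not in score table")
    s = scores[pathway]
    if len(s) < 2:
        raise ValidationError("median split needs at least 2 samples")
    if s.nunique() == 1:
        raise ValidationError(f"all {pathway!r} scores identical; no informative split")
    med = float(s.median())
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
    return StratumAssignment(labels, rule=f"median_split[{pathway}]", thresholds={"median": med})


def quadrant_groups(
    scores: pd.DataFrame,
    fao_name: str = "FAO",
    gly_name: str = "glycolysis",
    rule: str = "median",
) -> StratumAssignment:
    """Concurrent two-pathway stratification.

    With the default median rule a sample is ``FAO_high_gly_low`` when
    it is above the FAO median and at-or-below the glycolysis median,
    ``FAO_low_gly_high`` in the mirror case, and ``other`` otherwise
    (medians computed independently per pathway).  The stricter
    ``rule="quartile"`` variant uses the outer quartiles of each score
    instead of the medians.
    """
    for name in (fao_name, gly_name):
        if name not in scores.columns:
            raise ValidationError(f"pathway {name!r} not in score table")
    fao, gly = scores[fao_name], scores[gly_name]
    if rule == "median":
        fao_hi_cut = fao_lo_cut = float(fao.median())
        gly_hi_cut = gly_lo_cut = float(gly.median())
    elif rule == "quartile":
        fao_hi_cut, fao_lo_cut = float(fao.quantile(0.75)), float(fao.quantile(0.25))
        gly_hi_cut, gly_lo_cut = float(gly.quantile(0.75)), float(gly.quantile(0.25))
    else:
        raise ValidationError(f"unknown quadrant rule {rule!r}")
    fao_high = fao > fao_hi_cut
    fao_low = fao <= fao_lo_cut
    gly_high = gly > gly_hi_cut
    gly_low = gly <= gly_lo_cut
    labels = pd.Series("other", index=scores.index)
    labels[fao_high & gly_low] = "FAO_high_gly_low"
    labels[fao_low & gly_high] = "FAO_low_gly_high"
    return StratumAssignment(
        labels,
        rule=f"quadrant[{rule}]",
        thresholds={
            f"{fao_name}_high_cut": fao_hi_cut,
            f"{fao_name}_low_cut": fao_lo_cut,
            f"{gly_name}_high_cut": gly_hi_cut,
            f"{gly_name}_low_cut": gly_lo_cut,
        },
    )


def cluster_strata(
    data: pd.DataFrame,
    k: int | str = "auto",
    seed: int = 0,
) -> StratumAssignment:
    """K-means strata on an embedding or a samples-x-features matrix.

    ``k="auto"`` picks the k in 2..6 maximizing mean silhouette.  Labels
    ``cluster_1..cluster_k`` are ordered by decreasing cluster size
    (ties broken by the fitted cluster index), so the largest cluster is
    always ``cluster_1``; deterministic given the seed.
    """
    x = data.to_numpy(dtype=float)
    n = len(data)
    if k == "auto":
        upper = min(6, n - 1)
        if upper < 2:
            raise ValidationError(f"{n} samples cannot be clustered")
        best_k, best_sil = None, -np.inf
        for kk in range(2, upper + 1):
            fit = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(x)
            sil = silhouette_score(x, fit.labels_)
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k
    k = int(k)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < k:
        raise ValidationError(f"{n} samples cannot form {k} clusters")
    fit = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    sizes = np.bincount(fit.labels_, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # decreasing size, stable
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = pd.Series(
        [f"cluster_{rank[l] + 1}" for l in fit.labels_], index=data.index
    )
    return StratumAssignment(labels, rule="kmeans", thresholds={"k": k, "seed": seed})
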