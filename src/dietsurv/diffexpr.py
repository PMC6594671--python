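"""Two-group differential expression, directional overlap, and the
diet-normalization (rescue) classifier.

The default test is a per-gene Welch unequal-variance t-test on
log2p1-scale values with Benjamini-Hochberg q-values; significance
additionally requires ``|log2FC| >= log2fc_gate``.  The rescue index of
a tumor-dysregulated gene under a diet is

    r = (mean_HFD_tumor - mean_NFD_tumor) / (mean_liver - mean_NFD_tumor)

on the log2 scale: r = 0 means no movement back toward the liver
baseline, r = 1 means complete normalization, r beyond the overshoot
bound means the diet pushed expression past the liver level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, RunConfig, ValidationError, to_log2p1

__all__ = [
    "adjust_pvalues",
    "de_test",
    "overlap_sets",
    "overlap_percentage",
    "OverlapSummary",
    "classify_normalization",
]


def adjust_pvalues(p, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg q-values (default)
    or Bonferroni, as used by :func:`de_test`."""
    if method not in ("fdr_bh", "bonferroni"):
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(np.asarray(p, dtype=float), method=method)[1]


def _group_columns(m: ExpressionMatrix, annotations: pd.DataFrame, group: str) -> list[str]:
    ids = [s for s in annotations.index[annotations["group"] == group] if s in m.values.columns]
    if len(ids) < 3:
        raise ValidationError(f"group {group!r} has {len(ids)} sample(s); need >= 3")
    return ids


def de_test(
    m: ExpressionMatrix,
    annotations: pd.DataFrame,
    group_a: str,
    group_b: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of group A versus group B.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (A - B
    mean difference on the log2p1 scale), ``p``, ``q`` (BH by default,
    Bonferroni via config), ``direction`` and ``significant``
    (q < q_threshold and |log2fc| >= log2fc_gate).  Genes constant in
    both groups are flagged ``degenerate`` with p = 1 when the group
    means agree (p = 0 when they are constant but different).
    """
    config = config or RunConfig()
    if m.scale == "fpkm":
        m = to_log2p1(m, config.pseudocount)
    a = m.values[_group_columns(m, annotations, group_a)].to_numpy()
    b = m.values[_group_columns(m, annotations, group_b)].to_numpy()

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)

    q = adjust_pvalues(p, config.p_adjust)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": (q < config.q_threshold) & (np.abs(log2fc) >= config.log2fc_gate),
            "degenerate": degenerate,
        },
        index=m.values.index.rename("gene"),
    )
    return out


@dataclass
class OverlapSummary:
    """Directional overlap of two differentially expressed gene sets."""

    a_only: set
    b_only: set
    shared_same_direction: set
    shared_opposite_direction: set

    @property
    def n_union(self) -> int:
        return (
            len(self.a_only)
            + len(self.b_only)
            + len(self.shared_same_direction)
            + len(self.shared_opposite_direction)
        )

    @property
    def percent_shared_same_direction(self) -> float:
        """Shared-same-direction genes as a percentage of the union.

        NaN when both sets are empty (no genes to overlap).
        """
        if self.n_union == 0:
            return float("nan")
        return overlap_percentage(len(self.shared_same_direction), self.n_union)


def overlap_percentage(n_shared_same_direction: int, n_union: int) -> float:
    """Overlap percentage: shared same-direction count over the union size."""
    if n_union <= 0:
        raise ValidationError("union is empty")
    if n_shared_same_direction > n_union:
        raise ValidationError("shared count exceeds union size")
    return 100.0 * n_shared_same_direction / n_union


def overlap_sets(set_a: pd.Series | dict, set_b: pd.Series | dict) -> OverlapSummary:
    """Summarize the overlap of two gene -> direction mappings.

    Directions must be 'up' or 'down' for every member; shared genes are
    split by direction agreement.
    """
    a = dict(set_a)
    b = dict(set_b)
    for d in (a, b):
        bad = {g for g, v in d.items() if v not in ("up", "down")}
        if bad:
            raise ValidationError(f"missing/invalid direction for gene(s) {sorted(bad)[:5]}")
    shared = set(a) & set(b)
    return OverlapSummary(
        a_only=set(a) - shared,
        b_only=set(b) - shared,
        shared_same_direction={g for g in shared if a[g] == b[g]},
        shared_opposite_direction={g for g in shared if a[g] != b[g]},
    )


_DIET_TUMOR_GROUPS = {"MC_HFD": "tumor_MC_HFD", "LC_HFD": "tumor_LC_HFD"}


def classify_normalization(
    m: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Call, per gene, whether each high-fat diet rescued its tumor dysregulation.

    A gene is *dysregulated* when NFD-tumor vs NFD-liver is significant.
    For each diet, *rescue* requires the HFD-tumor vs NFD-tumor contrast
    to be significant with the opposite sign to the dysregulation, and
    the category follows the rescue index r: below ``r_partial`` ->
    unrescued, [r_partial, r_complete) -> partial, [r_complete,
    r_overshoot] -> complete, beyond -> overshoot.
    ``normalized_by_both`` holds when both diets land in
    {partial, complete}.  Dysregulated genes whose liver and NFD-tumor
    means coincide (undefined r) are flagged and excluded from calls.
    """
    config = config or RunConfig()
    if m.scale == "fpkm":
        m = to_log2p1(m, config.pseudocount)
    required = {"liver_NFD", "tumor_NFD", "tumor_MC_HFD", "tumor_LC_HFD"}
    have = set(annotations["group"].unique())
    missing = required - have
    if missing:
        raise ValidationError(f"missing group(s) for normalization calling: {sorted(missing)}")

    de_tumor = de_test(m, annotations, "tumor_NFD", "liver_NFD", config)
    dysregulated = de_tumor["significant"]
    dys_sign = np.sign(de_tumor["log2fc"])

    mean_liver = m.values[_group_columns(m, annotations, "liver_NFD")].mean(axis=1)
    mean_nfd_tumor = m.values[_group_columns(m, annotations, "tumor_NFD")].mean(axis=1)
    denom = mean_liver - mean_nfd_tumor
    r_undefined = dysregulated & (denom.abs() < 1e-9)

    out = pd.DataFrame(
        {
            "dysregulated": dysregulated,
            "direction": np.where(dys_sign >= 0, "up", "down"),
            "log2fc_tumor": de_tumor["log2fc"],
            "q_tumor": de_tumor["q"],
            "r_undefined": r_undefined,
        },
        index=m.values.index.rename("gene"),
    )
    out.loc[~dysregulated, "direction"] = "none"

    categories = {}
    for diet, group in _DIET_TUMOR_GROUPS.items():
        de_diet = de_test(m, annotations, group, "tumor_NFD", config)
        mean_hfd = m.values[_group_columns(m, annotations, group)].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (mean_hfd - mean_nfd_tumor) / denom
        rescue_sig = de_diet["significant"] & (
            np.sign(de_diet["log2fc"]) == -dys_sign
        )
        cat = pd.Series("unrescued", index=m.values.index)
        eligible = dysregulated & rescue_sig & ~r_undefined
        cat[eligible & (r >= config.r_partial) & (r < config.r_complete)] = "partial"
        cat[eligible & (r >= config.r_complete) & (r <= config.r_overshoot)] = "complete"
        cat[eligible & (r > config.r_overshoot)] = "overshoot"
        cat[~dysregulated] = "not_applicable"
        cat[r_undefined] = "undefined"
        out[f"r_{diet}"] = r.where(~r_undefined)
        out[f"category_{diet}"] = cat
        categories[diet] = cat

    out["normalized_by_both"] = (
        dysregulated
        & ~r_undefined
        & categories["MC_HFD"].isin(["partial", "complete"])
        & categories["LC_HFD"].isin(["partial", "complete"])
    )
    return out
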