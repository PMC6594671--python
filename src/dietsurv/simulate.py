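"""Synthetic cohorts and mouse-style designs with planted structure.

Two generators back the whole test surface:

* :func:`simulate_cohort` — a tumor cohort on the incremented-log2 scale
  with correlated pathway panels (fatty-acid oxidation, glycolysis, a
  background block), optional cluster substructure, and exponentially
  distributed censored survival whose log-hazard is linear in the true
  (latent) panel scores;
* :func:`simulate_mouse_design` — a six-group design
  ({liver, tumor} x {NFD, MC_HFD, LC_HFD}) with planted
  tumor-dysregulated genes, subsets rescued by one or both high-fat
  diets, and diet-by-transformation synergy genes.

Both return a truth table sufficient to score any downstream call; both
are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, SurvivalRecord, ValidationError

__all__ = ["CohortSimSpec", "MouseSimSpec", "simulate_cohort", "simulate_mouse_design"]


@dataclass
class CohortSimSpec:
    """Parameters of the tumor-cohort simulator.

    Expression is generated on the log2p1 scale as

        x[g, s] = mu_g + shift[cluster(s), g] + sd * (sqrt(rho) * F_p(s)
                                                      + sqrt(1 - rho) * e[g, s])

    where ``F_p`` is a shared standard-normal factor per pathway panel
    (the sample's *true standardized panel score*) and ``e`` is
    independent noise.  Survival times are exponential with per-sample
    hazard ``lambda0 * exp(beta_gly * S_gly + beta_fao * S_fao)`` and are
    censored by an independent exponential follow-up clock.
    """

    n_samples: int = 400
    n_fao: int = 15
    n_gly: int = 15
    n_background: int = 70
    baseline_mean: float = 6.0     # log2p1 units; per-gene means drawn +/- 2 around this
    baseline_sd: float = 1.0
    rho: float = 0.5               # within-panel correlation
    n_clusters: int = 1
    cluster_shift: float = 0.0     # sd of per-cluster per-gene mean offsets (log2 units)
    lambda0: float = math.log(2) / 730.0   # baseline hazard per day (median ~2 y)
    beta_gly: float = 0.0          # log-hazard per unit glycolysis score (>= 0)
    beta_fao: float = 0.0          # log-hazard per unit FAO score (<= 0)
    censoring_hazard: float = 4e-4  # independent follow-up hazard per day (~30% censored at null)
    cluster_informative_genes: int | None = None  # None -> cluster shifts hit all genes;
    # an integer k restricts them to the first k FAO-panel genes (the "driver" genes)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_fao, self.n_gly, self.n_background) < 1:
            raise ValidationError("all cohort sizes must be >= 1")
        if not (0 <= self.rho < 1):
            raise ValidationError("rho must lie in [0, 1)")
        if self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.beta_gly < 0 or self.beta_fao > 0:
            raise ValidationError("expected beta_gly >= 0 and beta_fao <= 0")


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[ExpressionMatrix, list[SurvivalRecord], pd.DataFrame]:
    """Generate (expression, clinical records, truth table) for a cohort.

    The truth table records, per sample: cluster id, true FAO and
    glycolysis scores, the hazard, the uncensored event time, and the
    observed (time, event) pair after censoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    panels = {
        "FAO": [f"FAO{i:03d}" for i in range(1, spec.n_fao + 1)],
        "glycolysis": [f"GLY{i:03d}" for i in range(1, spec.n_gly + 1)],
        "background": [f"BG{i:04d}" for i in range(1, spec.n_background + 1)],
    }
    genes = panels["FAO"] + panels["glycolysis"] + panels["background"]
    n_genes = len(genes)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    mu = spec.baseline_mean + rng.uniform(-2.0, 2.0, size=n_genes)
    mu = np.clip(mu, 1.0, None)

    clusters = rng.integers(0, spec.n_clusters, size=n)
    shift = (
        rng.normal(0.0, spec.cluster_shift, size=(spec.n_clusters, n_genes))
        if spec.cluster_shift > 0
        else np.zeros((spec.n_clusters, n_genes))
    )
    if spec.cluster_informative_genes is not None:
        k_inf = int(spec.cluster_informative_genes)
        if not (0 <= k_inf <= spec.n_fao):
            raise ValidationError("cluster_informative_genes must lie in [0, n_fao]")
        mask = np.zeros(n_genes, dtype=bool)
        mask[:k_inf] = True
        shift = shift * mask[None, :]

    s_fao = rng.standard_normal(n)
    s_gly = rng.standard_normal(n)
    noise = rng.standard_normal((n_genes, n))

    x = mu[:, None] + shift[clusters].T + spec.baseline_sd * math.sqrt(1 - spec.rho) * noise
    factor = math.sqrt(spec.rho) * spec.baseline_sd
    nf, ng = spec.n_fao, spec.n_gly
    x[:nf, :] += factor * s_fao[None, :]
    x[nf : nf + ng, :] += factor * s_gly[None, :]
    x = np.clip(x, 0.0, None)

    hazard = spec.lambda0 * np.exp(spec.beta_gly * s_gly + spec.beta_fao * s_fao)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / spec.censoring_hazard, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    days = np.rint(observed).astype(int)

    records = [
        SurvivalRecord(
            sample_id=s,
            days_to_death=int(d) if e else None,
            days_to_last_followup=None if e else int(d),
        )
        for s, d, e in zip(samples, days, event)
    ]

    truth = pd.DataFrame(
        {
            "cluster": clusters + 1,
            "score_fao": s_fao,
            "score_gly": s_gly,
            "hazard": hazard,
            "uncensored_time": event_time,
            "time": days,
            "event": event,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples), scale="log2p1"
    )
    return matrix, records, truth


def cohort_gene_sets(spec: CohortSimSpec) -> list[GeneSet]:
    """The FAO and glycolysis panels matching a simulated cohort's gene ids."""
    return [
        GeneSet("FAO", [f"FAO{i:03d}" for i in range(1, spec.n_fao + 1)]),
        GeneSet("glycolysis", [f"GLY{i:03d}" for i in range(1, spec.n_gly + 1)]),
    ]


# ---------------------------------------------------------------------------
# mouse design

_MOUSE_GROUPS = [
    ("liver", "NFD"),
    ("liver", "MC_HFD"),
    ("liver", "LC_HFD"),
    ("tumor", "NFD"),
    ("tumor", "MC_HFD"),
    ("tumor", "LC_HFD"),
]


@dataclass
class MouseSimSpec:
    """Parameters of the six-group mouse-design simulator.

    Planted gene categories (disjoint):

    ``dysregulated``   tumor effect ``+/- delta_t`` (log2) in all tumors,
                       unchanged by diet;
    ``rescued_both``   tumor effect in NFD tumors; in each HFD-tumor
                       group the mean is pulled a fraction ``r_true`` of
                       the way back toward the liver mean;
    ``rescued_mc`` / ``rescued_lc``  same rescue, single diet only;
    ``synergy``        tumor effect plus a diet main effect ``delta_d``
                       in HFD livers, and an extra ``delta_s`` on top of
                       both only in HFD tumors;
    ``background``     no planted effect.

    Planted effect signs alternate up/down within each category.
    Residuals are Gaussian with sd ``sigma`` on the log2p1 scale.
    """

    n_rep: int = 5
    n_dysregulated: int = 60
    n_rescued_both: int = 40
    n_rescued_mc: int = 20
    n_rescued_lc: int = 20
    n_synergy: int = 20
    n_background: int = 200
    delta_t: float = 2.0
    r_true: float = 0.9
    delta_d: float = 0.6
    delta_s: float = 1.0
    sigma: float = 0.25
    baseline_mean: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rep < 3:
            raise ValidationError("n_rep must be >= 3")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not (0 <= self.r_true):
            raise ValidationError("r_true must be non-negative")


_CATEGORIES = (
    "dysregulated",
    "rescued_both",
    "rescued_mc",
    "rescued_lc",
    "synergy",
    "background",
)


def simulate_mouse_design(
    spec: MouseSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (expression, annotations, truth table) for the mouse design.

    The truth table has one row per gene with its category, planted
    direction (+1/-1/0) and the planted group means for all six groups.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    counts = {
        "dysregulated": spec.n_dysregulated,
        "rescued_both": spec.n_rescued_both,
        "rescued_mc": spec.n_rescued_mc,
        "rescued_lc": spec.n_rescued_lc,
        "synergy": spec.n_synergy,
        "background": spec.n_background,
    }
    genes: list[str] = []
    categories: list[str] = []
    prefixes = {
        "dysregulated": "DYS",
        "rescued_both": "RSB",
        "rescued_mc": "RSM",
        "rescued_lc": "RSL",
        "synergy": "SYN",
        "background": "BG",
    }
    for cat in _CATEGORIES:
        for i in range(1, counts[cat] + 1):
            genes.append(f"{prefixes[cat]}{i:04d}")
            categories.append(cat)
    if len(set(genes)) != len(genes):  # planted sets must stay disjoint
        raise ValidationError("planted gene sets overlap")
    n_genes = len(genes)

    baseline = spec.baseline_mean + rng.uniform(-2.0, 2.0, size=n_genes)
    baseline = np.clip(baseline, 1.0, None)
    direction = np.zeros(n_genes)
    for cat in _CATEGORIES:
        idx = [i for i, c in enumerate(categories) if c == cat]
        if cat != "background":
            direction[idx] = [1 if j % 2 == 0 else -1 for j in range(len(idx))]

    # planted group means, genes x 6 groups
    means = {}
    tumor_shift = direction * spec.delta_t
    cat_arr = np.array(categories)
    for tissue, diet in _MOUSE_GROUPS:
        m = baseline.copy()
        if tissue == "tumor":
            m = m + np.where(cat_arr != "background", tumor_shift, 0.0)
            rescued = np.zeros(n_genes, dtype=bool)
            if diet == "MC_HFD":
                rescued = np.isin(cat_arr, ["rescued_both", "rescued_mc"])
            elif diet == "LC_HFD":
                rescued = np.isin(cat_arr, ["rescued_both", "rescued_lc"])
            # pull rescued genes back toward the liver baseline
            m = np.where(rescued, m + spec.r_true * (baseline - m), m)
            if diet in ("MC_HFD", "LC_HFD"):
                syn = cat_arr == "synergy"
                m = m + np.where(syn, direction * (spec.delta_d + spec.delta_s), 0.0)
        else:
            if diet in ("MC_HFD", "LC_HFD"):
                syn = cat_arr == "synergy"
                m = m + np.where(syn, direction * spec.delta_d, 0.0)
        m = np.clip(m, 0.0, None)
        means[f"{tissue}_{diet}"] = m

    sample_ids, tissues, diets, cols = [], [], [], []
    for tissue, diet in _MOUSE_GROUPS:
        for r in range(1, spec.n_rep + 1):
            sid = f"{tissue}_{diet}_{r:02d}"
            sample_ids.append(sid)
            tissues.append(tissue)
            diets.append(diet)
            cols.append(
                np.clip(means[f"{tissue}_{diet}"] + rng.normal(0, spec.sigma, n_genes), 0, None)
            )
    values = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(values, scale="log2p1")

    annotations = pd.DataFrame(
        {"tissue": tissues, "diet": diets},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    annotations["group"] = annotations["tissue"] + "_" + annotations["diet"]

    truth = pd.DataFrame(
        {"category": categories, "direction": direction.astype(int)},
        index=pd.Index(genes, name="gene"),
    )
    for key, m in means.items():
        truth[f"mean_{key}"] = m
    truth["r_true"] = np.where(
        np.isin(cat_arr, ["rescued_both", "rescued_mc", "rescued_lc"]), spec.r_true, 0.0
    )
    return matrix, annotations, truth
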