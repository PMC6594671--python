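"""Core domain types and file readers/writers.

The pipeline consumes three plain-text formats:

* expression matrices — TSV, genes in rows, samples in columns, first
  column gene identifiers, header row sample identifiers.  Values are
  either FPKM-like non-negative reals (``scale="fpkm"``) or incremented
  log2-transformed values ``log2(fpkm + pseudocount)``
  (``scale="log2p1"``);
* gene sets — standard GMT (name, description, members, tab-separated);
* clinical tables — TSV with columns ``sample_id``, ``days_to_death``,
  ``days_to_last_followup`` where an empty cell means "not recorded".

Survival time for every downstream analysis is the maximum of the two
day fields, with the event indicator set only when a days-to-death value
is present (censored otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "GeneSet",
    "SurvivalRecord",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotations",
    "write_annotations",
    "read_clinical",
    "write_clinical",
    "derive_survival",
    "derive_survival_table",
    "to_log2p1",
    "from_log2p1",
    "load_config",
]


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


_SCALES = ("fpkm", "log2p1")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers
        as columns.  All entries must be finite and non-negative.
    scale
        ``"fpkm"`` for raw FPKM-like values or ``"log2p1"`` for
        incremented log2-transformed values.
    """

    values: pd.DataFrame
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value for gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value for gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present].copy(), self.scale)


@dataclass
class GeneSet:
    """A named pathway panel: gene identifiers with no duplicates."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        seen = set()
        for m in self.members:
            if m in seen:
                raise ValidationError(f"gene set {self.name!r} lists {m!r} twice")
            seen.add(m)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SurvivalRecord:
    """Per-sample clinical follow-up.

    At least one of ``days_to_death`` / ``days_to_last_followup`` must be
    present; day values of 0 are valid (same-day event).
    """

    sample_id: str
    days_to_death: int | None = None
    days_to_last_followup: int | None = None

    def __post_init__(self) -> None:
        if self.days_to_death is None and self.days_to_last_followup is None:
            raise ValidationError(f"sample {self.sample_id!r}: both day fields absent")
        for name in ("days_to_death", "days_to_last_followup"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"sample {self.sample_id!r}: negative {name} ({v})")


def derive_survival(rec: SurvivalRecord) -> tuple[int, int]:
    """Derive (time_days, event_flag) from a clinical record.

    Time is the maximum of the day fields that are present; the event
    flag is 1 exactly when a days-to-death value was recorded, and the
    record is censored otherwise.
    """
    days = [d for d in (rec.days_to_death, rec.days_to_last_followup) if d is not None]
    time = max(days)
    event = 1 if rec.days_to_death is not None else 0
    return time, event


def derive_survival_table(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Tabulate derived (time, event) pairs, indexed by sample id."""
    rows = {}
    for rec in records:
        if rec.sample_id in rows:
            raise ValidationError(f"duplicate clinical record for sample {rec.sample_id!r}")
        rows[rec.sample_id] = derive_survival(rec)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["time", "event"])
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# scale conversion

def to_log2p1(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Incremented log2 transform: v -> log2(v + pseudocount).

    A matrix already on the log2p1 scale is returned unchanged with a
    logged warning (no double transform).
    """
    if m.scale == "log2p1":
        logger.warning("to_log2p1 called on a matrix already on the log2p1 scale; no-op")
        return m
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(m.values + pseudocount), "log2p1")


def from_log2p1(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse transform: v -> 2**v - pseudocount (clipped at zero)."""
    if m.scale == "fpkm":
        logger.warning("from_log2p1 called on a matrix already on the fpkm scale; no-op")
        return m
    back = np.power(2.0, m.values) - pseudocount
    # round-off below zero from the subtraction is clipped, not an error
    back = back.clip(lower=0.0)
    return ExpressionMatrix(back, "fpkm")


# ---------------------------------------------------------------------------
# file I/O

def read_expression(path: str | Path, scale: str = "fpkm") -> ExpressionMatrix:
    """Read a genes-x-samples TSV with the declared scale.

    Malformed numeric cells (including literal ``NA``/empty cells — the
    analyses assume complete matrices) raise :class:`ParseError` naming
    the gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        g, s = bad[0]
        raise ParseError(
            f"{path}: cell for gene {df.index[g]!r}, sample {df.columns[s]!r} "
            f"is not numeric ({df.iat[g, s]!r})"
        )
    return ExpressionMatrix(numeric, scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, _desc, *members = fields
            members = [m for m in members if m]
            try:
                sets.append(GeneSet(name, members))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return sets


def write_gene_sets(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.members]) + "\n")


_TISSUES = ("liver", "tumor", "normal_adjacent")
_DIETS = ("NFD", "MC_HFD", "LC_HFD", "NA")


def read_annotations(path: str | Path, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read sample annotations (sample_id, tissue, diet[, cohort]).

    When a companion matrix is given, every annotated sample must appear
    in it.  A convenience ``group`` column (``tissue_diet``) is added.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_annotations(df, matrix)


def validate_annotations(df: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    for col in ("sample_id", "tissue", "diet"):
        if col not in df.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in annotations")
    bad_t = set(df["tissue"]) - set(_TISSUES)
    if bad_t:
        raise ValidationError(f"unknown tissue value(s) {sorted(bad_t)}")
    bad_d = set(df["diet"]) - set(_DIETS)
    if bad_d:
        raise ValidationError(f"unknown diet value(s) {sorted(bad_d)}")
    df = df.set_index("sample_id") if df.index.name != "sample_id" else df
    if matrix is not None:
        missing = set(df.index) - set(matrix.sample_ids)
        if missing:
            raise ValidationError(f"annotated sample(s) absent from matrix: {sorted(missing)[:5]}")
    df = df.copy()
    df["group"] = df["tissue"] + "_" + df["diet"]
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.drop(columns=["group"], errors="ignore")
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical TSV; empty cells mean the day field is absent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "days_to_death", "days_to_last_followup"):
        if col not in df.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        def _parse(cell: str, col: str) -> int | None:
            if cell == "":
                return None
            try:
                return int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: sample {row['sample_id']!r}: non-integer {col} ({cell!r})"
                ) from None
        records.append(
            SurvivalRecord(
                sample_id=row["sample_id"],
                days_to_death=_parse(row["days_to_death"], "days_to_death"),
                days_to_last_followup=_parse(row["days_to_last_followup"], "days_to_last_followup"),
            )
        )
    return records


def write_clinical(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdays_to_death\tdays_to_last_followup\n")
        for rec in records:
            d = "" if rec.days_to_death is None else str(rec.days_to_death)
            f = "" if rec.days_to_last_followup is None else str(rec.days_to_last_followup)
            fh.write(f"{rec.sample_id}\t{d}\t{f}\n")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Tunable knobs shared by the pipeline stages.

    ``r_partial``/``r_complete``/``r_overshoot`` bound the rescue-index
    categories for the normalization caller; ``q_threshold`` and
    ``log2fc_gate`` gate differential-expression significance;
    embedding parameters feed t-SNE.
    """

    pseudocount: float = 1.0
    q_threshold: float = 0.05
    log2fc_gate: float = 1.0
    r_partial: float = 0.3
    r_complete: float = 0.8
    r_overshoot: float = 1.5
    epsilon: float = 0.0               # zero-guard for heatmap ratios
    heatmap_reference: str = "panel"   # "panel" or "all"
    quadrant_rule: str = "median"      # "median" or "quartile"
    p_adjust: str = "fdr_bh"           # or "bonferroni"
    perplexity: float = 30.0
    learning_rate: float = 200.0
    n_iter: int = 10000
    n_clusters: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1):
            raise ValidationError("q_threshold must lie in (0, 1)")
        if not (0 < self.r_partial < self.r_complete <= 1.5):
            raise ValidationError("need 0 < r_partial < r_complete <= 1.5")
        if self.r_overshoot < self.r_complete:
            raise ValidationError("r_overshoot must be >= r_complete")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.n_clusters != "auto" and int(self.n_clusters) < 2:
            raise ValidationError("n_clusters must be >= 2 or 'auto'")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML key-value file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)
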