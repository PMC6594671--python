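"""End-to-end workflows and reproducible run manifests.

Two composite workflows mirror the study's analysis arms:

* the *cohort* workflow scores a tumor cohort for the FAO and glycolysis
  panels, stratifies by median split and concurrent quadrants, compares
  survival by log-rank, then embeds the panel expression, clusters the
  embedding, compares survival across clusters and ranks the
  cluster-determining transcripts;
* the *mouse* workflow computes the five diet/transformation contrasts,
  their directional overlaps, per-gene diet-normalization calls and the
  panel heatmap matrices.

Every run writes a JSON manifest capturing the config, the SHA-256 of
each input file, the seed, and the output paths, so any run can be
reproduced bit-for-bit (deterministic stages) or seed-for-seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import classify_normalization, de_test, overlap_sets
from .embedding import cluster_survival, embed, rank_cluster_determinants
from .io import (
    ExpressionMatrix,
    GeneSet,
    RunConfig,
    SurvivalRecord,
    ValidationError,
    derive_survival_table,
)
from .scoring import group_log2fc, heatmap_values, pathway_score
from .stratify import cluster_strata, median_split, quadrant_groups
from .survival import km_estimate, logrank, median_survival

logger = logging.getLogger(__name__)

__all__ = ["run_cohort_workflow", "run_mouse_workflow"]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _km_frame(times, events) -> pd.DataFrame:
    c = km_estimate(times, events)
    return pd.DataFrame(
        {"time": c.times, "survival": c.survival, "at_risk": c.at_risk, "events": c.events}
    )


def _logrank_report(result, pairwise=None) -> dict:
    rep = {
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
        "groups": result.group_names,
        "observed": result.observed.tolist(),
        "expected": result.expected.tolist(),
    }
    if pairwise:
        rep["pairwise"] = {
            f"{a}|{b}": {"statistic": r.statistic, "p_value": r.p_value}
            for (a, b), r in pairwise.items()
        }
    return rep


def _groups_from_labels(labels: pd.Series, surv: pd.DataFrame, wanted=None):
    names = [n for n in sorted(labels.unique()) if wanted is None or n in wanted]
    groups, kept = [], []
    for name in names:
        ids = labels.index[labels == name].intersection(surv.index)
        if len(ids):
            groups.append((surv.loc[ids, "time"].to_numpy(), surv.loc[ids, "event"].to_numpy()))
            kept.append(name)
    return groups, kept


def _write_manifest(out_dir: Path, workflow: str, config: RunConfig, inputs: dict,
                    outputs: dict, started: float) -> dict:
    manifest = {
        "workflow": workflow,
        "package_version": __version__,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "seed": config.seed,
        "elapsed_s": round(time.time() - started, 3),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_cohort_workflow(
    matrix: ExpressionMatrix,
    records: list[SurvivalRecord],
    gene_sets: list[GeneSet],
    config: RunConfig,
    out_dir: str | Path,
    fao_name: str = "FAO",
    gly_name: str = "glycolysis",
    input_paths: dict | None = None,
) -> dict:
    """Score -> stratify -> survival -> embed -> cluster -> importance."""
    started = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "score"
        scores = pathway_score(matrix, gene_sets, config.pseudocount)
        outputs["scores"] = out_dir / "pathway_scores.tsv"
        scores.to_csv(outputs["scores"], sep="\t")

        stage = "survival_derivation"
        surv = derive_survival_table(records)

        stage = "stratify"
        strata = {}
        for gs in gene_sets:
            strata[gs.name] = median_split(scores, gs.name)
        quad = quadrant_groups(scores, fao_name, gly_name, rule=config.quadrant_rule)
        frames = [a.to_frame() for a in strata.values()] + [quad.to_frame()]
        outputs["strata"] = out_dir / "strata.tsv"
        pd.concat(frames).to_csv(outputs["strata"], sep="\t")

        stage = "km_logrank"
        reports = {}
        km_frames = []
        for name, a in {**strata, "quadrant": quad}.items():
            wanted = None
            if name == "quadrant":
                wanted = ["FAO_high_gly_low", "FAO_low_gly_high"]
            groups, kept = _groups_from_labels(a.labels, surv, wanted)
            for g_name, (t, e) in zip(kept, groups):
                kf = _km_frame(t, e)
                kf.insert(0, "stratum", f"{name}:{g_name}")
                med = median_survival(km_estimate(t, e))
                kf.insert(1, "median_survival", np.nan if med is None else med)
                km_frames.append(kf)
            if len(groups) >= 2:
                res = logrank(groups, kept)
                reports[name] = _logrank_report(res)
        outputs["km_curves"] = out_dir / "km_curves.tsv"
        pd.concat(km_frames, ignore_index=True).to_csv(outputs["km_curves"], sep="\t", index=False)
        outputs["logrank"] = out_dir / "logrank.json"
        outputs["logrank"].write_text(json.dumps(reports, indent=2) + "\n")

        stage = "embed"
        panel = next(gs for gs in gene_sets if gs.name == fao_name)
        emb = embed(matrix, panel, config)
        outputs["embedding"] = out_dir / "embedding.tsv"
        emb.coordinates.to_csv(outputs["embedding"], sep="\t")

        stage = "cluster"
        clusters = cluster_strata(emb.coordinates, config.n_clusters, config.seed)
        outputs["clusters"] = out_dir / "clusters.tsv"
        clusters.to_frame().to_csv(outputs["clusters"], sep="\t")

        stage = "cluster_survival"
        omnibus, pairwise = cluster_survival(clusters, surv)
        outputs["cluster_logrank"] = out_dir / "cluster_logrank.json"
        outputs["cluster_logrank"].write_text(
            json.dumps(_logrank_report(omnibus, pairwise), indent=2) + "\n"
        )

        stage = "importance"
        importance = rank_cluster_determinants(matrix, panel, clusters, seed=config.seed)
        outputs["importance"] = out_dir / "importance.tsv"
        importance.to_csv(outputs["importance"], sep="\t")
    except Exception as exc:
        raise RuntimeError(f"cohort workflow failed at stage {stage!r}: {exc}") from exc

    inputs = {k: _sha256(v) for k, v in (input_paths or {}).items()}
    manifest = _write_manifest(out_dir, "cohort", config, inputs, outputs, started)
    return {
        "scores": scores,
        "strata": strata,
        "quadrant": quad,
        "logrank": reports,
        "embedding": emb,
        "clusters": clusters,
        "cluster_logrank": omnibus,
        "importance": importance,
        "manifest": manifest,
    }


_MOUSE_CONTRASTS = [
    ("liver_MC_HFD", "liver_NFD"),
    ("liver_LC_HFD", "liver_NFD"),
    ("tumor_NFD", "liver_NFD"),
    ("tumor_MC_HFD", "tumor_NFD"),
    ("tumor_LC_HFD", "tumor_NFD"),
]


def run_mouse_workflow(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    gene_sets: list[GeneSet],
    config: RunConfig,
    out_dir: str | Path,
    input_paths: dict | None = None,
) -> dict:
    """DE contrasts -> overlaps -> normalization calls -> heatmaps."""
    started = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    required = {f"{t}_{d}" for t in ("liver", "tumor") for d in ("NFD", "MC_HFD", "LC_HFD")}
    missing = required - set(annotations["group"].unique())
    if missing:
        raise ValidationError(f"mouse workflow missing group(s): {sorted(missing)}")

    stage = "setup"
    try:
        stage = "de"
        de_tables = {}
        for a, b in _MOUSE_CONTRASTS:
            name = f"{a}_vs_{b}"
            de = de_test(matrix, annotations, a, b, config)
            de_tables[name] = de
            outputs[f"de_{name}"] = out_dir / f"de_{name}.tsv"
            de.to_csv(outputs[f"de_{name}"], sep="\t")

        stage = "fold_changes"
        fcs = pd.DataFrame(
            {f"{a}_vs_{b}": group_log2fc(matrix, annotations, a, b, config.pseudocount)
             for a, b in _MOUSE_CONTRASTS}
        )
        outputs["log2fc"] = out_dir / "log2fc.tsv"
        fcs.to_csv(outputs["log2fc"], sep="\t")

        stage = "overlaps"
        def _sig_directions(de: pd.DataFrame) -> pd.Series:
            return de.loc[de["significant"], "direction"]

        overlaps = {
            "liver_MC_vs_LC": overlap_sets(
                _sig_directions(de_tables["liver_MC_HFD_vs_liver_NFD"]),
                _sig_directions(de_tables["liver_LC_HFD_vs_liver_NFD"]),
            ),
            "tumor_MC_vs_LC": overlap_sets(
                _sig_directions(de_tables["tumor_MC_HFD_vs_tumor_NFD"]),
                _sig_directions(de_tables["tumor_LC_HFD_vs_tumor_NFD"]),
            ),
        }
        overlap_json = {
            name: {
                "a_only": len(o.a_only),
                "b_only": len(o.b_only),
                "shared_same_direction": len(o.shared_same_direction),
                "shared_opposite_direction": len(o.shared_opposite_direction),
                "union": o.n_union,
                "percent_shared_same_direction": o.percent_shared_same_direction,
            }
            for name, o in overlaps.items()
        }
        outputs["overlaps"] = out_dir / "overlaps.json"
        outputs["overlaps"].write_text(json.dumps(overlap_json, indent=2) + "\n")

        stage = "normalization_calls"
        calls = classify_normalization(matrix, annotations, config)
        outputs["normalization_calls"] = out_dir / "normalization_calls.tsv"
        calls.to_csv(outputs["normalization_calls"], sep="\t")

        stage = "heatmaps"
        heatmaps = {}
        for gs in gene_sets:
            try:
                hm = heatmap_values(matrix, gs, config.epsilon, config.heatmap_reference,
                                    config.pseudocount)
            except ValidationError as exc:
                logger.warning("heatmap for panel %r skipped: %s", gs.name, exc)
                continue
            heatmaps[gs.name] = hm
            path = out_dir / f"heatmap_{gs.name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# panel: {gs.name}\n")
                hm.values.to_csv(fh, sep="\t")
            outputs[f"heatmap_{gs.name}"] = path
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"mouse workflow failed at stage {stage!r}: {exc}") from exc

    inputs = {k: _sha256(v) for k, v in (input_paths or {}).items()}
    manifest = _write_manifest(out_dir, "mouse", config, inputs, outputs, started)
    return {
        "de": de_tables,
        "log2fc": fcs,
        "overlaps": overlaps,
        "normalization_calls": calls,
        "heatmaps": heatmaps,
        "manifest": manifest,
    }
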