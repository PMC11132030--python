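"""Configuration-driven orchestration and an end-to-end synthetic demo.

A run is described by a YAML/dict config (seed, output directory, stage
selection, per-stage parameter blocks). All randomness is routed through
seeds derived deterministically from the run seed, results go to files,
and a manifest (parameters, package version, seed, SHA-256 of every
written artifact) makes runs reproducible: two runs with the same config
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, enrichment, explant, lri, morph3d, state_score, survival, synth

logger = logging.getLogger(__name__)

STAGES = ("volumes", "counts", "qpcr", "lri", "explant", "survival")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "cafstate_run",
    "stages": list(STAGES),
    "volumes": {"noise_sd": 4.0, "volume_shape": [48, 72, 72]},
    "counts": {
        "n_cells_per_subset": 25,
        "n_genes": 400,
        "markers_per_subset": 15,
        "effect_log2fc": 2.0,
        "n_perm": 200,
    },
    "qpcr": {"ct_noise_sd": 0.2, "n_replicates": 3},
    "lri": {"n_patients": 6, "noise_rate": 0.0},
    "explant": {"n_cells_per_group": 1000, "shift_percent": 7.7},
    "survival": {
        "n_per_stratum": 100,
        "strata_hazards": {"low": 0.03, "medium": 0.01, "high": 0.02},
        "censor_rate": 0.2,
    },
}


class ConfigError(ValueError):
    """Raised when a run config fails schema validation."""


def validate_config(config: dict) -> dict:
    """Merge a config over the defaults and validate it field by field."""
    merged = {**DEFAULT_CONFIG, **(config or {})}
    for stage in STAGES:
        block = {**DEFAULT_CONFIG[stage], **(config.get(stage, {}) if config else {})}
        merged[stage] = block
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed: must be an integer")
    unknown = set(merged["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"stages: unknown stage(s) {sorted(unknown)}")
    for key in ("input_counts", "input_ct", "input_cohort"):
        if key in merged and not Path(merged[key]).exists():
            raise ConfigError(f"{key}: path {merged[key]!r} does not exist")
    return merged


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_volumes(params: dict, seed: int, out: Path) -> dict:
    shape = tuple(params["volume_shape"])
    specs = [
        synth.ShapeSpec(kind="ball", center=(shape[0] / 2, 20, 20), radius=9),
        synth.ShapeSpec(kind="prolate", center=(shape[0] / 2, 22, 52),
                        semi_axes=(8, 8, 16)),
        synth.ShapeSpec(kind="dendritic", center=(shape[0] / 2, 52, 36), radius=8,
                        n_protrusions=2, protrusion_length=10, protrusion_width=5),
    ]
    data = synth.gen_cell_volume(specs, volume_shape=shape,
                                 noise_sd=params["noise_sd"], seed=seed)
    tifffile.imwrite(out / "cytoskeleton.tif", data["cytoskeleton"].astype(np.float32))
    tifffile.imwrite(out / "nuclei.tif", data["nuclei"].astype(np.float32))
    labeled, audit = morph3d.segment_volume(data["cytoskeleton"], data["nuclei"])
    tifffile.imwrite(out / "labels.tif", labeled.astype(np.int32))
    shapes = morph3d.shape_table(labeled, audit=audit)
    _write_csv(shapes, out / "shape_table.csv")
    _write_csv(data["truth_shapes"], out / "truth_shapes.csv")
    kept = shapes[shapes["kept"] == True]  # noqa: E712
    return {
        "n_cells_detected": int(labeled.max()),
        "n_cells_kept": int(len(kept)),
        "sphericity_range": [float(shapes["sphericity"].min()),
                             float(shapes["sphericity"].max())],
    }


def _run_counts(params: dict, seed: int, out: Path) -> dict:
    truth = synth.gen_scrnaseq_counts(
        n_cells_per_subset=params["n_cells_per_subset"],
        n_genes=params["n_genes"],
        markers_per_subset=params["markers_per_subset"],
        effect_log2fc=params["effect_log2fc"],
        seed=seed,
    )
    truth.counts.to_csv(out / "counts.csv")
    signatures = enrichment.build_signatures(truth.counts, truth.labels)
    enrichment.signatures_to_gmt(signatures, out / "signatures.gmt")

    # rank genes by myCAF-vs-rest log2FC and score every subset signature
    norm = truth.counts / truth.counts.sum(axis=0) * 1e4
    in_my = (truth.labels == "myCAF").to_numpy()
    lfc = np.log2((norm.loc[:, in_my].mean(axis=1) + 1.0)
                  / (norm.loc[:, ~in_my].mean(axis=1) + 1.0))
    ranked = lfc.astype(float)
    scores = {}
    for name, sig in signatures.items():
        if sig.up and sig.down:
            s = enrichment.caf_subset_score(ranked, sig, n_perm=params["n_perm"],
                                            seed=_stage_seed(seed, f"score:{name}"))
            scores[name] = s.score
    _write_csv(
        pd.DataFrame(sorted(scores.items()), columns=["subset", "caf_subset_score"]),
        out / "subset_scores.csv",
    )
    recovered = (
        len(set(truth.markers["myCAF"]) & signatures["myCAF"].up)
        / len(truth.markers["myCAF"])
    )
    return {"marker_recovery_myCAF": recovered, "subset_scores": scores}


def _run_qpcr(params: dict, seed: int, out: Path) -> dict:
    effects = {
        "D/IB": {g: 1.0 for g in state_score.MYCAF_GENES},
        "nD/IB": {g: 1.0 for g in state_score.ILICAF_GENES},
        "D/nIB": {},
    }
    table = synth.gen_qpcr_table(
        conditions=["D/nIB", "D/IB", "nD/IB"], effects_log2=effects,
        ct_noise_sd=params["ct_noise_sd"], n_replicates=params["n_replicates"],
        seed=seed,
    )
    _write_csv(table, out / "qpcr_ct.csv")
    scores, meta = state_score.score_table(table, baseline="D/nIB")
    _write_csv(scores, out / "state_scores.csv")
    stats_table = state_score.compare_state_scores(scores)
    _write_csv(stats_table, out / "state_score_tests.csv")
    means = scores.groupby("condition")["score"].mean().to_dict()
    return {"strategy": meta["strategy"], "mean_scores": {k: float(v) for k, v in means.items()}}


def _run_lri(params: dict, seed: int, out: Path) -> dict:
    trues = [
        ("TGFB1", "TGFBR2", "cancer", "myCAF"),
        ("IL1B", "IL1R1", "macrophage", "IL-iCAF"),
        ("PDGFB", "PDGFRB", "cancer", "myCAF"),
    ]
    tables = synth.gen_lri_outputs(trues, n_patients=params["n_patients"],
                                   noise_rate=params["noise_rate"], seed=seed)
    cons = lri.consensus(tables["cpdb"], tables["natmi"], tables["scriabin"])
    _write_csv(cons, out / "lri_consensus.csv")
    true_counts = cons.set_index(lri.KEY).loc[
        [tuple(t) for t in tables["truth"]["true"]], "method_count"
    ]
    return {"n_interactions": int(len(cons)),
            "true_method_counts": [int(c) for c in true_counts]}


def _run_explant(params: dict, seed: int, out: Path) -> dict:
    cells = synth.gen_cell_marker_table(
        n_cells_per_group=params["n_cells_per_group"],
        shift_percent=params["shift_percent"], seed=seed,
    )
    _write_csv(cells, out / "cell_measurements.csv")
    bounds = explant.QcBounds(10.0, 120.0, 500.0, 1500.0)
    kept = explant.qc_filter(cells, bounds)
    thr_marker = explant.otsu_threshold(kept["marker_total"])
    thr_pdpn = explant.otsu_threshold(kept["pdpn_total"])
    calls = explant.classify_positive(
        kept, {"pdpn_total": thr_pdpn, "marker_total": thr_marker}
    )
    _write_csv(calls, out / "positivity_calls.csv")
    res = explant.percent_change_stat(
        kept.loc[kept["group"] == "treated", "marker_total"],
        kept.loc[kept["group"] == "control", "marker_total"],
    )
    (out / "percent_change.json").write_text(json.dumps(res, indent=2, sort_keys=True))
    return {"median_percent_change": res["median_percent_change"],
            "p_value": res["p_value_intensity"],
            "otsu_threshold_marker": thr_marker}


def _run_survival(params: dict, seed: int, out: Path) -> dict:
    truth = synth.gen_survival_cohort(
        n_per_stratum=params["n_per_stratum"],
        strata_hazards=params["strata_hazards"],
        censor_rate=params["censor_rate"], seed=seed,
    )
    # map synthetic strata onto relative-abundance scores so the stratifier
    # reconstructs them: score difference increases low -> high
    score_map = {"low": -1.0, "medium": 0.0, "high": 1.0}
    rng = np.random.default_rng(_stage_seed(seed, "survival-scores"))
    tbl = truth.table.copy()
    tbl["myCAF_score"] = tbl["stratum"].map(score_map) + rng.uniform(-0.3, 0.3, len(tbl))
    tbl["ILiCAF_score"] = 0.0
    _write_csv(tbl, out / "cohort.csv")
    report = survival.stratified_km_report(tbl, "myCAF_score", "ILiCAF_score")
    _write_csv(report["curves"], out / "km_curves.csv")
    _write_csv(report["pairwise_logrank"], out / "pairwise_logrank.csv")
    return {"logrank_p": report["logrank"]["p_value"],
            "median_survival": report["median_survival"]}


_RUNNERS = {
    "volumes": _run_volumes,
    "counts": _run_counts,
    "qpcr": _run_qpcr,
    "lri": _run_lri,
    "explant": _run_explant,
    "survival": _run_survival,
}


def run(config: dict) -> dict:
    """Execute the selected stages and write a deterministic run manifest."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]

    summary: dict = {}
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        logger.info("running stage %s", stage)
        summary[stage] = _RUNNERS[stage](cfg[stage], _stage_seed(seed, stage), stage_dir)

    artifacts = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: cfg[k] for k in ("stages", *STAGES)},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def demo_end_to_end(seed: int, out_dir) -> dict:
    """Run every stage on synthetic data and check the module invariants.

    Returns the manifest extended with a ``checks`` block; raises
    AssertionError if any invariant fails.
    """
    manifest = run({"seed": seed, "out_dir": str(out_dir), "stages": list(STAGES)})
    s = manifest["summary"]
    checks = {
        "cells_detected": s["volumes"]["n_cells_detected"] >= 3,
        "markers_recovered": s["counts"]["marker_recovery_myCAF"] >= 0.8,
        "mycaf_score_positive": s["qpcr"]["mean_scores"]["D/IB"] > 0,
        "ilicaf_score_negative": s["qpcr"]["mean_scores"]["nD/IB"] < 0,
        "true_lri_full_consensus": all(c == 3 for c in s["lri"]["true_method_counts"]),
        "explant_shift_detected": s["explant"]["p_value"] < 0.05,
        "survival_strata_detected": s["survival"]["logrank_p"] < 0.05,
    }
    failed = [k for k, ok in checks.items() if not ok]
    manifest["checks"] = checks
    report_path = Path(out_dir) / "demo_report.json"
    report_path.write_text(json.dumps({"seed": seed, "checks": checks},
                                      indent=2, sort_keys=True))
    if failed:
        raise AssertionError(f"demo invariants failed: {failed}")
    return manifest
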