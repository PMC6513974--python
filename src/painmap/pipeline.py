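"""End-to-end pipeline orchestration and standard-format io.

``run_pipeline`` drives generation → preprocessing → feature extraction →
selection (all requested classification problems) → topological chart →
interaction analysis from a single serializable :class:`RunConfig`, writing
CSV tables, a GraphML chart, and a ``manifest.json`` with SHA-256 hashes of
every artifact so that full-run determinism is a checkable property.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chart import annotate_feature_sets, build_feature_chart, export_chart
from .featurebank import (
    FEATURE_NAMES,
    META_COLUMNS,
    FeatureConfig,
    FeatureMatrix,
    build_feature_matrix,
    zscore_normalize,
)
from .interaction import interaction_table
from .preprocess import PreprocessConfig
from .selection import ClassificationProblem, run_problem
from .synthgen import GeneratorConfig, make_roster

logger = logging.getLogger("painmap")


@dataclass
class RunConfig:
    """Everything a full run needs, serializable round-trip stable."""

    n_subjects: int = 85
    trials_per_level: int = 20
    master_seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_epochs: int = 100
    sfs_iters: int = 8
    curve_max_n: int = 10
    svm_c: float = 1.0
    problems: tuple[str, ...] = (
        "pain_threshold",
        "pain_tolerance",
        "three_class",
        "five_class",
    )
    chart_k: int = 2
    chart_n: int = 4
    chart_l: float = 0.5
    feature_sets: dict = field(default_factory=dict)  # name → list of features

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for key, typ in (
            ("generator", GeneratorConfig),
            ("preprocess", PreprocessConfig),
            ("features", FeatureConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for f in dataclasses.fields(typ):
                    if f.name in d and isinstance(d[f.name], list):
                        d[f.name] = tuple(d[f.name])
                raw[key] = typ(**d)
        if "problems" in raw:
            raw["problems"] = tuple(raw["problems"])
        return cls(**raw)

    @classmethod
    def tiny(cls, master_seed: int = 0) -> "RunConfig":
        """Desk-scale smoke configuration (reduced rate, few subjects/epochs)."""
        return cls(
            n_subjects=4,
            trials_per_level=4,
            master_seed=master_seed,
            generator=GeneratorConfig().reduced_rate(),
            n_epochs=5,
            sfs_iters=3,
            curve_max_n=4,
        )


# ---------------------------------------------------------------------------
# Feature matrix CSV io
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """CSV with metadata columns first, then the 155 registry columns."""
    df = pd.concat([matrix.meta.reset_index(drop=True), matrix.values.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path, normalization: str = "raw") -> FeatureMatrix:
    """Read a feature-matrix CSV, canonicalizing column order to the registry.

    Raises a format error naming any missing metadata or feature columns.
    """
    df = pd.read_csv(path)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"feature matrix file missing metadata columns: {missing_meta}")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix file missing feature columns: {missing}")
    return FeatureMatrix(
        values=df[FEATURE_NAMES].astype(float),
        meta=df[list(META_COLUMNS)].astype(str),
        normalization=normalization,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    t0 = time.time()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    stage("generate")
    roster = make_roster(config.n_subjects, config.trials_per_level, config.master_seed)

    stage("extract")
    matrix = build_feature_matrix(roster, config.generator, config.preprocess, config.features)
    fm_path = out / "features.csv"
    write_feature_matrix(matrix, fm_path)
    files.append(fm_path)

    stage("select")
    summary_rows = []
    for prob_name in config.problems:
        problem = ClassificationProblem[prob_name]
        res = run_problem(
            matrix,
            problem,
            n_epochs=config.n_epochs,
            seed=config.master_seed + 1,
            sfs_iters=config.sfs_iters,
            curve_max_n=config.curve_max_n,
            C=config.svm_c,
        )
        rank_df = pd.DataFrame(
            {
                "rank": np.arange(1, len(res.ranking.order) + 1),
                "feature": res.ranking.order,
                "mean_F": res.ranking.mean_f[res.ranking.order].to_numpy(),
            }
        )
        p = out / f"{prob_name}_ufs_ranking.csv"
        rank_df.to_csv(p, index=False, float_format="%.17g")
        files.append(p)

        vote_rows = []
        for i, counts in enumerate(res.vote_table.votes):
            for featname, cnt in sorted(counts.items(), key=lambda kv: -kv[1]):
                vote_rows.append(
                    {
                        "iteration": i + 1,
                        "feature": featname,
                        "votes_pct": 100.0 * cnt / len(res.vote_table.per_epoch),
                        "mean_val_accuracy": res.vote_table.accuracies[i].get(featname, np.nan),
                    }
                )
        p = out / f"{prob_name}_sfs_votes.csv"
        pd.DataFrame(vote_rows).to_csv(p, index=False, float_format="%.17g")
        files.append(p)

        for tag, curve in (("ufs", res.ufs_curve), ("sfs", res.sfs_curve)):
            cdf = pd.DataFrame(
                {
                    "n_features": curve.n_features,
                    "feature_added": curve.features,
                    "accuracy_mean": curve.mean,
                    "accuracy_sd": curve.sd,
                }
            )
            p = out / f"{prob_name}_{tag}_curve.csv"
            cdf.to_csv(p, index=False, float_format="%.17g")
            files.append(p)
            summary_rows.append(
                {
                    "problem": prob_name,
                    "selector": tag,
                    "local_max_n": curve.local_max_n,
                    "global_max_n": curve.global_max_n,
                    "accuracy_at_local_pct": 100.0 * curve.mean[curve.local_max_n - 1],
                    "accuracy_at_global_pct": 100.0 * curve.mean[curve.global_max_n - 1],
                }
            )
    p = out / "selection_summary.csv"
    pd.DataFrame(summary_rows).to_csv(p, index=False, float_format="%.17g")
    files.append(p)

    stage("chart")
    zmatrix = zscore_normalize(matrix)
    chart = build_feature_chart(zmatrix, config.chart_k, config.chart_n, config.chart_l)
    if config.feature_sets:
        annotate_feature_sets(chart, dict(config.feature_sets))
    export_chart(chart, out / "chart.graphml", out / "chart.json")
    files += [out / "chart.graphml", out / "chart.json"]

    stage("interact")
    wide, long = interaction_table(matrix)
    wide.to_csv(out / "interaction_table.csv")
    long.to_csv(out / "interaction_long.csv", index=False, float_format="%.17g")
    files += [out / "interaction_table.csv", out / "interaction_long.csv"]

    cfg_path = out / "config.json"
    cfg_path.write_text(config.to_json())
    files.append(cfg_path)

    manifest = {
        "master_seed": config.master_seed,
        "n_trials": roster.n_trials,
        "n_features": len(FEATURE_NAMES),
        "artifacts": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    stage("done")
    return manifest
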