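"""End-to-end orchestration: load, resample, superimpose, score, compare.

:func:`run_pipeline` turns a landmark file into a directory of CSV results
(per-suture complexity scores, shape and complexity-score PCAs, correlation
tables, heatmap bins) plus a YAML manifest that records the configuration,
package version and input checksum so a run can be re-executed and verified
byte-for-byte on its deterministic outputs.

A single degenerate outline must not abort a multi-specimen run: metric
failures are isolated per specimen, logged to ``errors.csv``, and the run
continues with the remaining curves.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import LandmarkCurve, read_landmarks, resample_equidistant, write_scores
from .metrics import ComplexityScores, MetricConfig, compute_all
from .procrustes import ProcrustesSet, gpa
from .stats import (
    PcaResult,
    bin_scores,
    correlation_report,
    metric_shape_alignment,
    num_pcs_for,
    pca,
)

logger = logging.getLogger("suturemetrics")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "score_curves"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    input: str
    out_dir: str
    dialect: str = "csv"
    metrics: MetricConfig = field(default_factory=MetricConfig)
    standardize_score_pca: bool = True
    top_fraction: float = 0.05  # shape-PC retention threshold for alignment
    n_bins: int = 10
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = self.metrics.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "metrics" in raw:
            raw["metrics"] = MetricConfig.from_dict(raw["metrics"])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory results of a pipeline run (everything also lands on disk)."""

    out_dir: Path
    scores: pd.DataFrame
    shape_pca: PcaResult
    score_pca: PcaResult
    metric_correlations: object
    shape_alignment: object
    procrustes: ProcrustesSet
    errors: pd.DataFrame
    n_specimens: int


def score_curves(
    curves: list[LandmarkCurve],
    cfg: MetricConfig | None = None,
    gpa_tol: float = 1e-8,
    gpa_max_iter: int = 100,
) -> tuple[pd.DataFrame, ProcrustesSet, pd.DataFrame]:
    """Resample, superimpose and score a set of curves.

    Returns the score table (indexed by specimen_id), the Procrustes set,
    and an error table for specimens that failed metric computation.
    """
    cfg = cfg or MetricConfig()
    resampled = [resample_equidistant(c, cfg.resample_n) for c in curves]
    pset = gpa([c.coords for c in resampled], tol=gpa_tol, max_iter=gpa_max_iter)
    if not pset.converged:
        logger.warning("GPA did not converge (residual %.3g)", pset.residual)
    records: list[ComplexityScores] = []
    errors: list[dict] = []
    for curve, aligned in zip(resampled, pset.shapes):
        try:
            records.append(compute_all(curve.with_coords(aligned), cfg))
        except Exception as exc:  # noqa: BLE001 - isolate per-specimen failures
            logger.error("metric failure for %s: %s", curve.specimen_id, exc)
            errors.append({"specimen_id": curve.specimen_id, "error": str(exc)})
    scores = pd.DataFrame([r.to_dict() for r in records]).set_index("specimen_id")
    err_df = pd.DataFrame(errors, columns=["specimen_id", "error"])
    return scores, pset, err_df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full workflow described by ``cfg``.

    Writes under ``cfg.out_dir``: ``scores.csv``, ``shape_pca/{scores,
    variance,loadings}.csv``, ``complexity_pca/{scores,variance,loadings,
    contributions}.csv``, ``correlations.csv``, ``metric_shape_correlations
    .csv``, ``bins.csv``, ``manifest.yaml`` and, if any specimen failed,
    ``errors.csv``.
    """
    in_path = Path(cfg.input)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    curves = read_landmarks(in_path, dialect=cfg.dialect)
    logger.info("read %d curves from %s", len(curves), in_path)
    scores, pset, errors = score_curves(
        curves, cfg.metrics, gpa_tol=cfg.gpa_tol, gpa_max_iter=cfg.gpa_max_iter
    )
    write_scores(scores, out / "scores.csv")
    if len(errors):
        errors.to_csv(out / "errors.csv", index=False)

    ids = [c.specimen_id for c in curves if c.specimen_id in scores.index]
    kept = np.array([c.specimen_id in scores.index for c in curves])
    flat = pset.shapes[kept].reshape(kept.sum(), -1)
    cols = [f"{ax}{i}" for i in range(cfg.metrics.resample_n) for ax in ("x", "y")]
    shape_table = pd.DataFrame(flat, index=pd.Index(ids, name="specimen_id"), columns=cols)
    shape_res = pca(shape_table, standardize=False)

    shp = out / "shape_pca"
    shp.mkdir(exist_ok=True)
    shape_res.scores.to_csv(shp / "scores.csv")
    shape_res.loadings.to_csv(shp / "loadings.csv")
    pd.DataFrame(
        {
            "pc": shape_res.scores.columns,
            "variance_fraction": shape_res.variance_fraction,
        }
    ).to_csv(shp / "variance.csv", index=False)

    metric_table = scores[list(ComplexityScores.METRIC_COLUMNS)]
    score_res = pca(metric_table, standardize=cfg.standardize_score_pca)
    cpx = out / "complexity_pca"
    cpx.mkdir(exist_ok=True)
    score_res.scores.to_csv(cpx / "scores.csv")
    score_res.loadings.to_csv(cpx / "loadings.csv")
    score_res.contributions.to_csv(cpx / "contributions.csv")
    pd.DataFrame(
        {
            "pc": score_res.scores.columns,
            "variance_fraction": score_res.variance_fraction,
        }
    ).to_csv(cpx / "variance.csv", index=False)

    metric_corr = correlation_report(metric_table)
    metric_corr.to_long().to_csv(out / "correlations.csv", index=False)
    alignment = metric_shape_alignment(metric_table, shape_res, cfg.top_fraction)
    alignment.to_long().to_csv(out / "metric_shape_correlations.csv", index=False)

    bins = pd.DataFrame(
        {m: bin_scores(metric_table[m].to_numpy(), cfg.n_bins) for m in metric_table},
        index=metric_table.index,
    )
    bins.to_csv(out / "bins.csv")

    manifest = {
        "package": {"name": "suturemetrics", "version": __version__},
        "config": cfg.to_dict(),
        "input": {"path": str(in_path), "sha256": _sha256(in_path)},
        "n_specimens": int(scores.shape[0]),
        "n_failed": int(errors.shape[0]),
        "gpa": {
            "iterations": pset.iterations,
            "residual": float(pset.residual),
            "converged": bool(pset.converged),
        },
        "shape_pca": {
            "pcs_for_99pct": num_pcs_for(0.99, shape_res),
            "pc_variance_pct": [
                round(float(f) * 100, 4) for f in shape_res.variance_fraction[:6]
            ],
        },
        "psd_normalization": cfg.metrics.psd_normalization,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return RunResult(
        out_dir=out,
        scores=scores,
        shape_pca=shape_res,
        score_pca=score_res,
        metric_correlations=metric_corr,
        shape_alignment=alignment,
        procrustes=pset,
        errors=errors,
        n_specimens=len(curves),
    )
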