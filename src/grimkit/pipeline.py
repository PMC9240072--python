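"""End-to-end orchestration: ingest -> aggregate -> rankings -> models -> severity.

One :func:`run_all` call executes every stage on either a raw per-image CSV
or the synthetic "paper" preset and emits a single versioned JSON report
(plus per-stage CSV tables). Identical configuration and seeds produce a
byte-identical report; every stochastic stage's seed is recorded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from grimkit import io as gio
from grimkit import lasso as glasso
from grimkit import mixed as gmixed
from grimkit import mobps as gmobps
from grimkit import severity as gsev
from grimkit.simulate import GeneratorConfig, simulate

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: stages a complete report must contain
REQUIRED_STAGES = (
    "dataset_summary",
    "mobps_ranking",
    "lasso",
    "mixed_models",
    "severity",
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: str | None = None  # raw per-image CSV; None -> simulate
    preset: str = "paper"
    aggregation: str = "scaled_sum"
    sim_seed: int = 0
    cv_seed: int = 0
    boot_seed: int = 0
    n_boot: int = 10_000
    effect_kind: str = "r"
    contrast_treatment: str | None = "CCl4"
    adjust: str = "fdr"
    df_method: str = "satterthwaite"
    output_dir: str | None = None
    column_map: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _ingest(cfg: RunConfig) -> tuple[gio.Dataset, str]:
    if cfg.input_path is not None:
        images = gio.read_image_scores(cfg.input_path, cfg.column_map or None)
        source = str(cfg.input_path)
    else:
        images, _ = simulate(GeneratorConfig(seed=cfg.sim_seed))
        source = f"synthetic preset {cfg.preset!r} seed {cfg.sim_seed}"
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(images, index=False).values.tobytes()
    ).hexdigest()[:16]
    ds = gio.aggregate_videos(images, mode=cfg.aggregation)
    ds.provenance["source"] = source
    ds.provenance["input_hash"] = digest
    return ds, digest


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the report dictionary.

    Raises :class:`StageError` naming the first failing stage. When
    ``cfg.output_dir`` is set, the report JSON and per-stage CSVs are written
    there.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(cfg),
    }
    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    ds, digest = stage("ingest", lambda: _ingest(cfg))
    logger.info("input hash %s, seed %s", digest, cfg.sim_seed)
    report["dataset_summary"] = stage(
        "dataset_summary", lambda: gio.summarize_dataset(ds)
    )

    contrast = gmobps.ContrastSpec(treatment=cfg.contrast_treatment)
    ranking = stage(
        "mobps_ranking",
        lambda: gmobps.rank_combinations(ds, contrast, kind=cfg.effect_kind),
    )
    tables["mobps_ranking"] = ranking
    report["mobps_ranking"] = {
        "contrast": {
            "treatment": cfg.contrast_treatment,
            "groups": ["pre", "post"],
            "weeks": [1, 2, 3, 4],
        },
        "effect_kind": cfg.effect_kind,
        "entries": _jsonable(ranking.round(6).to_dict(orient="records")),
    }

    def lasso_stage():
        out = {}
        for treatment in ("Oil", "CCl4"):
            fit = glasso.fit_treatment(ds, treatment, seed=cfg.cv_seed)
            out[treatment] = {
                "lambda_min": fit.lambda_min,
                "lambda_1se": fit.lambda_1se,
                "n_obs": fit.n_obs,
                "seed": fit.seed,
                "ranking": [
                    {"term": name, "beta": b}
                    for name, b in glasso.rank_coefficients(fit)
                ],
            }
            tables[f"lasso_cv_{treatment}"] = pd.DataFrame(
                {
                    "lambda": fit.lambda_grid,
                    "cv_mse": fit.cv_mean,
                    "cv_se": fit.cv_se,
                }
            )
        return out

    report["lasso"] = _jsonable(stage("lasso", lasso_stage))

    def mixed_stage():
        out = {}
        for mid in ("I", "II", "III"):
            fit = gmixed.fit_model(ds, mid, df_method=cfg.df_method)
            table = gmixed.coefficient_table(fit)
            tables[f"mixed_model_{mid}"] = table
            out[mid] = {
                "coefficients": _jsonable(table.round(6).to_dict(orient="records")),
                "variance_components": fit.variance_components,
                "sigma2": fit.sigma2,
                "icc": fit.icc,
                "variance_shares": fit.variance_shares,
                "estimator": fit.estimator,
                "df_method": fit.df_method,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "boundary": fit.boundary,
            }
        return out

    report["mixed_models"] = _jsonable(stage("mixed", mixed_stage))

    def severity_stage():
        counts = gsev.severity_counts(ds)
        tables["severity_counts"] = counts.reset_index()
        out = {
            "counts": {
                f"{t}/{i}": list(map(int, row))
                for (t, i), row in counts.iterrows()
            },
            "grand_total": int(counts.to_numpy().sum()),
        }
        for treatment in ("Oil", "CCl4"):
            sub = counts.loc[treatment]
            stat, dof, p = gsev.chi_square(sub)
            posthoc = gsev.posthoc_pairwise(sub, adjust=cfg.adjust)
            out[treatment] = {
                "chi2": {"statistic": stat, "df": dof, "p": p},
                "posthoc": _jsonable(posthoc.round(6).to_dict(orient="records")),
            }
            # Fig-5-style strata: per week and intervention, days pooled
            medians = {}
            strata = ds.records[ds.records["treatment"] == treatment].groupby(
                ["week", "intervention"], observed=True
            )
            for (week, iv), sel in strata:
                est = gsev.bootstrap_median(
                    sel["ot_score"], n_boot=cfg.n_boot, seed=cfg.boot_seed
                )
                medians[f"week{week}/{iv}"] = {
                    "median": est.median,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": int(len(sel)),
                }
            out[treatment]["bootstrap_medians"] = medians
            res, prov = gsev.mann_whitney_contrast(
                ds,
                {"treatment": treatment, "week": 0},
                {"treatment": treatment, "week": 1, "intervention": "post"},
            )
            out[treatment]["baseline_vs_week1_post"] = {
                "W": res.statistic_w,
                "r": res.r,
                "p": res.p,
                "provenance": prov,
            }
            corr = gsev.correlation_matrix(ds, treatment)
            tables[f"correlations_{treatment}"] = corr
            out[treatment]["fau_correlations"] = _jsonable(
                corr.round(6).to_dict(orient="index")
            )
        res, prov = gsev.mann_whitney_contrast(
            ds, {"treatment": "Oil", "week": 0}, {"treatment": "CCl4", "week": 0}
        )
        out["baseline_oil_vs_ccl4"] = {
            "W": res.statistic_w,
            "r": res.r,
            "p": res.p,
            "provenance": prov,
        }
        out["bootstrap"] = {"n_boot": cfg.n_boot, "seed": cfg.boot_seed}
        return out

    report["severity"] = _jsonable(stage("severity", severity_stage))
    validate_report(report)

    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report_json(report))
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.csv")
        gio.write_dataset(ds, outdir / "videos.csv")
    return report


def report_json(report: dict) -> str:
    """Canonical (sorted, fixed-format) JSON serialization of a report."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)


def validate_report(report: dict) -> None:
    """Schema check: version plus every required stage present."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("missing or unsupported schema_version")
    missing = [s for s in REQUIRED_STAGES if s not in report]
    if missing:
        raise ValueError(f"report missing stage(s): {missing}")
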