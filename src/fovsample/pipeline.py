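"""End-to-end orchestration: normalize -> heterogeneity -> field-count selection.

Each stage writes a machine-readable JSON report carrying a provenance
block (package version, master seed, config hash) so a rerun with the same
config and seed produces byte-identical outputs.  Stages are skippable:
without an index-array file normalization is skipped with a warning, and
heterogeneity is skipped (not fatal) for tables without ROI labels, where
an intra-tumor coefficient of variation is not computable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data_model import FovScoreTable, read_fov_table, read_index_arrays, write_fov_table
from .errors import ConfigurationError, UnsupportedStructureError
from .heterogeneity import compute_cov, cov_confidence_interval, fit_mixed_model
from .normalization import normalize_table
from .selection import SelectionConfig, run_selection

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline, flat per stage."""

    scores: str
    outdir: str
    index: str | None = None
    run_id: str | None = None
    baseline_run: str | None = None
    heteroscedastic: bool = False
    n_boot: int = 200
    cov_refit: str = "reml"  # bootstrap refit engine; "anova" = fast balanced-design path
    cov_include_subject: bool = False
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.scores).exists():
            raise ConfigurationError(f"score file not found: {self.scores}")
        if self.index is not None and not Path(self.index).exists():
            raise ConfigurationError(f"index-array file not found: {self.index}")
        if self.index is not None and self.run_id is None:
            raise ConfigurationError("normalization needs --run: which run produced the subject scores")
        self.selection.validate()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {"package": "fovsample", "version": __version__, "seed": config.seed, "config_hash": _config_hash(config)}


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the paths of the written reports.

    Stage failures raise with a stage-labeled message; nothing is written
    for a stage that failed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    written: dict[str, str] = {}

    table = read_fov_table(config.scores)
    log.info("read %d records / %d subjects from %s", table.n_records, table.n_subjects, config.scores)

    # ---- normalization ---------------------------------------------------
    if config.index is not None:
        try:
            arrays = read_index_arrays(config.index, baseline_run=config.baseline_run)
            log.info("baseline run: %s", arrays.baseline_run)
            table, report = normalize_table(table, arrays, config.run_id)
        except Exception as exc:
            raise type(exc)(f"[normalize] {exc}") from exc
        out = outdir / "normalized_scores.csv"
        write_fov_table(table, out)
        _dump({"provenance": prov, **report}, outdir / "normalization_report.json")
        written["normalized_scores"] = str(out)
        written["normalization_report"] = str(outdir / "normalization_report.json")
    else:
        log.warning("no index-array file given; normalization skipped")

    # ---- heterogeneity ---------------------------------------------------
    if table.has_roi:
        try:
            vc = fit_mixed_model(table, heteroscedastic=config.heteroscedastic)
            est = cov_confidence_interval(
                table, vc, n_boot=config.n_boot, seed=config.seed,
                refit=config.cov_refit, include_subject=config.cov_include_subject,
            )
        except UnsupportedStructureError as exc:
            log.warning("heterogeneity stage skipped: %s", exc)
        except Exception as exc:
            raise type(exc)(f"[heterogeneity] {exc}") from exc
        else:
            _dump(
                {
                    "provenance": prov,
                    "beta0": vc.beta0,
                    "sd_subject": vc.sd_subject,
                    "sd_roi": vc.sd_roi,
                    "sd_resid": vc.sd_resid,
                    "het_power": vc.het_power,
                    "loglik": vc.loglik,
                    "n_obs": vc.n_obs,
                    "cov_percent": est.cov_percent,
                    "cov_ci_low": est.ci_low,
                    "cov_ci_high": est.ci_high,
                    "n_boot": est.n_boot,
                },
                outdir / "heterogeneity_report.json",
            )
            written["heterogeneity_report"] = str(outdir / "heterogeneity_report.json")
    else:
        log.warning("table has no ROI labels; heterogeneity stage skipped (CoV not computable)")

    # ---- field-count selection ------------------------------------------
    sel_cfg = dataclasses.replace(config.selection, seed=config.seed)
    try:
        res = run_selection(table, sel_cfg)
    except Exception as exc:
        raise type(exc)(f"[select-fovs] {exc}") from exc
    _dump(
        {
            "provenance": prov,
            "design": sel_cfg.design,
            "sampling_mode": sel_cfg.sampling_mode,
            "optimal_m": res.optimal_m,
            "optimal_m_int": res.optimal_m_int,
            "optimal_m_sd_over_repeats": res.optimal_m_sd,
            "se_outer_mean": res.se_outer_mean,
            "avg_first_local_min": res.avg_first_local_min,
            "avg_abs_std_score": None if np.isnan(res.avg_abs_std_score) else res.avg_abs_std_score,
            "per_repeat_m": res.per_repeat_m.tolist(),
            "pe_curve": {
                "m": res.test_pe_curve.m.tolist(),
                "mean_pe": res.test_pe_curve.mean_pe.tolist(),
                "se_pe": res.test_pe_curve.se_pe.tolist(),
            },
        },
        outdir / "selection_report.json",
    )
    written["selection_report"] = str(outdir / "selection_report.json")
    return written
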