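"""End-to-end orchestration: herd -> labels -> LASSO -> fits -> evaluation.

``run_pipeline`` executes the full workflow on a single configuration:

1. simulate a herd (or load one from CSV),
2. compute THI and the binary abnormal-temperature outcome,
3. rank the eight candidate factors with the LASSO path,
4. fit the four ABTP families on the top-ranked factor by MLE,
5. evaluate them (AUC/accuracy/AIC/Brier/HL/calibration),
6. fit the effective-index model and export iso-probability contours,
7. write CSV/JSON reports and figures, stamped with the config hash and
   seed so identical configurations yield byte-identical artifacts.
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
import yaml

from . import effective, evaluation, herd, io, lasso, models, thi

logger = logging.getLogger("abtp")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on."""

    herd: herd.HerdConfig = field(default_factory=herd.HerdConfig)
    input_csv: str | None = None           # when set, load instead of simulate
    label_rule: thi.LabelRule = field(default_factory=thi.LabelRule)
    bands: thi.TriageBands = field(default_factory=thi.TriageBands)
    families: tuple[str, ...] = models.FAMILIES
    lasso_n_lambdas: int = 100
    lasso_folds: int = 10
    evaluation_bins: int = 10
    baseline_model: str = "LKB"
    effective_dose: str = "reference"
    output_dir: str = "abtp_output"
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one model family must be selected")
        for fam in self.families:
            if fam not in models.FAMILIES:
                raise ValueError(f"unknown model family {fam!r}")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = _to_jsonable(self)
        payload.pop("output_dir", None)
        payload.pop("make_plots", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    kwargs = dict(raw)
    if "herd" in kwargs:
        herd_kwargs = dict(kwargs["herd"])
        for name in ("eye_temp", "ambient_temp", "humidity", "age",
                     "days_in_milk", "parity", "body_weight", "milk_yield"):
            if name in herd_kwargs:
                herd_kwargs[name] = herd.Moment(*herd_kwargs[name])
        if "ground_truth" in herd_kwargs and herd_kwargs["ground_truth"] is not None:
            herd_kwargs["ground_truth"] = models.ABTPParams(**herd_kwargs["ground_truth"])
        kwargs["herd"] = herd.HerdConfig(**herd_kwargs)
    if "label_rule" in kwargs:
        kwargs["label_rule"] = thi.LabelRule(**kwargs["label_rule"])
    if "bands" in kwargs:
        kwargs["bands"] = thi.TriageBands(**kwargs["bands"])
    if "families" in kwargs:
        kwargs["families"] = tuple(kwargs["families"])
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    """In-memory view of one pipeline run's outputs."""

    dataset: thi.LabeledDataset
    ranking: list[str]
    fits: dict[str, models.ModelFit]
    report: evaluation.EvaluationReport
    effective_model: effective.EffectiveIndexModel
    contours: pd.DataFrame
    artifacts: dict[str, str]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; any failure raises with the stage name attached."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        # -- data ----------------------------------------------------------
        stage = "data"
        t0 = _stage(stage)
        if config.input_csv is not None:
            records, _meta = io.read_herd_csv(config.input_csv)
        else:
            records = herd.generate_herd(
                dataclasses.replace(config.herd, seed=config.seed))
        herd_csv = out_dir / "herd.csv"
        io.write_herd_csv(records, herd_csv)
        artifacts["herd_csv"] = str(herd_csv)

        # -- THI + labels --------------------------------------------------
        stage = "labeling"
        dataset = thi.label_abnormal(records, config.label_rule)
        if config.herd.label_mechanism == "bernoulli_direct" and config.input_csv is None:
            y = herd.generate_labels_direct(
                dataset.X["thi"].to_numpy(), config.herd.ground_truth,
                seed=config.seed + 1)
            dataset = thi.LabeledDataset(X=dataset.X, y=y,
                                         metadata={**dataset.metadata,
                                                   "mechanism": "bernoulli_direct"})
        labeled_csv = out_dir / "labeled.csv"
        labeled = dataset.X.copy()
        labeled["abnormal"] = dataset.y
        labeled.to_csv(labeled_csv, index=False, float_format="%.17g")
        artifacts["labeled_csv"] = str(labeled_csv)

        # -- LASSO ranking -------------------------------------------------
        stage = "lasso"
        _stage(stage)
        path = lasso.fit_lasso_path(dataset, n_lambdas=config.lasso_n_lambdas,
                                    seed=config.seed)
        path.selected_lambda = lasso.select_lambda_cv(
            dataset, folds=config.lasso_folds, seed=config.seed,
            n_lambdas=config.lasso_n_lambdas)
        ranking = lasso.rank_factors(path)
        top_factor = ranking[0]
        ranking_json = out_dir / "ranking.json"
        io.dump_json({**stamp, "ranking": ranking,
                      "selected_lambda": path.selected_lambda}, ranking_json)
        artifacts["ranking_json"] = str(ranking_json)

        # -- ABTP fits -----------------------------------------------------
        stage = "fit"
        _stage(stage)
        n_values = dataset.X[top_factor].to_numpy()
        fits = {fam: models.fit_abtp(fam, n_values, dataset.y, seed=config.seed)
                for fam in config.families}
        fits_json = out_dir / "fits.json"
        io.dump_json({**stamp, "top_factor": top_factor,
                      "fits": {k: io.fit_to_dict(v) for k, v in fits.items()}},
                     fits_json)
        artifacts["fits_json"] = str(fits_json)

        # -- evaluation ----------------------------------------------------
        stage = "evaluation"
        _stage(stage)
        preds = {fam: np.asarray(models.predict(fit.params, n_values))
                 for fam, fit in fits.items()}
        report = evaluation.evaluate_models(
            dataset.y, preds, fits, baseline=config.baseline_model,
            bins=config.evaluation_bins)
        report_csv = out_dir / "report.csv"
        report.table.to_csv(report_csv, float_format="%.17g")
        report_json = out_dir / "report.json"
        io.dump_json({**stamp, "baseline": report.baseline_model,
                      "rows": report.table.reset_index().to_dict(orient="records")},
                     report_json)
        artifacts["report_csv"] = str(report_csv)
        artifacts["report_json"] = str(report_json)

        # -- effective index -----------------------------------------------
        stage = "effective_index"
        _stage(stage)
        eye = dataset.metadata.get("eye_temp")
        eff = effective.fit_effective_index(
            n_values, eye, dataset.y, dose=config.effective_dose,
            seed=config.seed)
        temps = np.linspace(36.5, 41.0, 46)
        rows = []
        for q in (0.2, 0.5):
            t, thi_vals, ok = effective.iso_probability_contour(eff, q, temps)
            for ti, ni, oki in zip(t, thi_vals, ok):
                rows.append({"q": q, "eye_temp": ti, "thi": ni, "reachable": bool(oki)})
        contours = pd.DataFrame(rows)
        contours_csv = out_dir / "contours.csv"
        contours.to_csv(contours_csv, index=False, float_format="%.17g")
        eff_json = out_dir / "effective_index.json"
        io.dump_json({**stamp, "tn50_at_unit": eff.tn50_at_unit, "c": eff.c,
                      "m": eff.m, "n_ref": eff.n_ref, "dose": eff.dose,
                      "log_likelihood": eff.metadata.get("log_likelihood")},
                     eff_json)
        artifacts["contours_csv"] = str(contours_csv)
        artifacts["effective_index_json"] = str(eff_json)

        # -- plots ----------------------------------------------------------
        if config.make_plots:
            stage = "plots"
            _stage(stage)
            from . import plots

            plots.plot_lasso_path(path, out_dir / "lasso_path.png")
            plots.plot_sigmoids(fits, out_file=out_dir / "sigmoids.png")
            plots.plot_triage_chart(eff, config.bands, out_dir / "triage.png")
            artifacts["plots"] = str(out_dir)
    except Exception as exc:
        marker = out_dir / "INVALID"
        marker.write_text(f"pipeline failed during stage {stage!r}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(dataset=dataset, ranking=ranking, fits=fits,
                          report=report, effective_model=eff,
                          contours=contours, artifacts=artifacts)
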