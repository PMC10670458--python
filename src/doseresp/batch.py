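"""Batch pipeline: ingest -> summarise -> fit -> metrics -> quality -> outputs."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .conventions import PERCENT_INHIBITION, ResponseConvention
from .io import ColumnSchema, read_batch, results_frame, write_results
from .metrics import MetricConfig, compute_metrics
from .model import FourParamLogistic
from .quality import quality_report
from .series import DoseResponseSeries, summarize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BatchRecord", "analyze_series", "run_batch"]


@dataclass
class RunConfig:
    """Everything one batch run needs; all fields have usable defaults."""

    input: str = ""
    output_dir: str = "doseresp_out"
    convention: ResponseConvention = PERCENT_INHIBITION
    schema: ColumnSchema = field(default_factory=ColumnSchema)
    sheet: int | str = 0
    auc_baseline: float = 10.0
    xepto_window: float = 2.0
    dss_threshold: float = 10.0
    remove_outliers: bool = False
    alpha: float = 0.05
    plots: bool = False
    min_r2: float | None = None
    log_level: str = "INFO"
    seed: int = 0

    def metric_config(self, tested_range=None) -> MetricConfig:
        return MetricConfig(
            auc_baseline=self.auc_baseline,
            xepto_window=self.xepto_window,
            dss_threshold=self.dss_threshold,
            tested_range=tested_range,
        )


@dataclass
class BatchRecord:
    """Everything computed for one series; ``error`` set when analysis itself failed."""

    series: DoseResponseSeries
    summary: object = None
    fit: object = None
    metrics: object = None
    quality: object = None
    low_quality: bool = False
    error: str = ""


def analyze_series(series: DoseResponseSeries, config: RunConfig) -> BatchRecord:
    """Fit and score one series; failures are captured, never propagated."""
    rec = BatchRecord(series=series)
    try:
        rec.summary = summarize(
            series, remove_outliers=config.remove_outliers, alpha=config.alpha
        )
        model = FourParamLogistic.from_summary(rec.summary)
        rec.fit = model.fit()
        if rec.fit.converged:
            rec.metrics = compute_metrics(rec.fit, config.metric_config())
            rec.quality = quality_report(rec.fit)
            if config.min_r2 is not None and rec.quality.r2 is not None:
                rec.low_quality = rec.quality.r2 < config.min_r2
        else:
            logger.warning(
                "series %s/%s did not converge: %s",
                series.sample_id,
                series.drug_id,
                rec.fit.reason,
            )
    except Exception as exc:  # isolate pathological series from the batch
        logger.error("series %s/%s failed: %s", series.sample_id, series.drug_id, exc)
        rec.error = str(exc)
    return rec


def run_batch(config: RunConfig):
    """Run the full pipeline; returns (exit_status, records).

    Exit status 0 when at least one series converged, 1 when none did,
    2 on malformed input.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out_dir / "run.log")
    try:
        series_list = read_batch(
            config.input, convention=config.convention, schema=config.schema, sheet=config.sheet
        )
    except Exception as exc:
        logger.error("could not read input %s: %s", config.input, exc)
        return 2, []

    records = [analyze_series(s, config) for s in series_list]
    frame = results_frame(records)
    write_results(frame, out_dir / "results.csv")
    logger.info("wrote %s (%d series)", out_dir / "results.csv", len(records))

    if config.plots:
        from .plotting import save_record_plot

        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for rec in records:
            save_record_plot(rec, plot_dir)

    n_ok = sum(1 for r in records if r.fit is not None and r.fit.converged)
    logger.info("%d/%d series converged", n_ok, len(records))
    return (0 if n_ok >= 1 else 1), records


def _setup_logging(level: str, logfile: Path) -> None:
    root = logging.getLogger("doseresp")
    root.setLevel(getattr(logging, str(level).upper(), logging.INFO))
    # replace handlers so repeated runs in one process do not duplicate output
    for h in list(root.handlers):
        if getattr(h, "_doseresp", False):
            root.removeHandler(h)
            h.close()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    stream = logging.StreamHandler()
    stream.setFormatter(fmt)
    stream._doseresp = True
    fileh = logging.FileHandler(logfile, encoding="utf-8")
    fileh.setFormatter(fmt)
    fileh._doseresp = True
    root.addHandler(stream)
    root.addHandler(fileh)
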