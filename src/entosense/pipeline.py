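"""End-to-end orchestration: recording -> events -> features -> activity.

Each stage logs its in/out counts so that removal bookkeeping (e.g. the
fraction of events dropped for lacking a wingbeat frequency) is always
available, and every stage's output can be written and reloaded
independently of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .activity import ComparisonResult, StudySummary, align_trap_schedule, \
    bin_events, compare_methods, summarize_study
from .config import PipelineConfig, config_to_dict
from .errors import EntosenseError
from .extract import BaselineModel, InsectEvent, extract_events
from .features import EventFeatures, extract_features, features_table
from .io import config_hash
from .recording import RawRecording

logger = logging.getLogger("entosense")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    events: list[InsectEvent]
    baseline_model: BaselineModel
    features: list[EventFeatures]
    features_df: pd.DataFrame
    activity: pd.DataFrame | None = None
    comparison: ComparisonResult | None = None
    summary: StudySummary | None = None
    config_hash: str = ""
    stage_counts: dict = field(default_factory=dict)

    def report(self) -> dict:
        """JSON-serialisable run report (deterministic under fixed config)."""
        rep = {
            "config_hash": self.config_hash,
            "stage_counts": self.stage_counts,
        }
        if self.comparison is not None:
            rep["comparison"] = self.comparison.to_dict()
        if self.summary is not None:
            rep["summary"] = self.summary.to_dict()
        return rep


def run_pipeline(
    config: PipelineConfig,
    recording: RawRecording,
    rain: bool = False,
    uptime: pd.DataFrame | None = None,
    traps: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run extraction and feature stages (and, when uptime/trap tables are
    given, aggregation and comparison) on one recording.

    Any stage failure aborts with the stage name attached.
    """
    config.validate()
    chash = config_hash(config_to_dict(config))

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except EntosenseError as exc:
            raise EntosenseError(f"stage {name!r} failed: {exc}") from exc

    events, model = _stage("extract", extract_events, recording,
                           config.detection)
    logger.info("extract: %d samples in, %d events out",
                recording.n_samples, len(events))

    feats = [
        _stage("features", extract_features, ev, config.features, rain)
        for ev in events
    ]
    n_valid = sum(f.valid for f in feats)
    logger.info("features: %d events in, %d valid out", len(feats), n_valid)
    fdf = features_table(feats)
    if len(fdf):
        start = pd.Timestamp(recording.start_time)
        fdf["timestamp"] = start + pd.to_timedelta(fdf["start_time_s"],
                                                   unit="s")

    result = PipelineResult(
        events=events, baseline_model=model, features=feats,
        features_df=fdf, config_hash=chash,
        stage_counts={
            "samples": recording.n_samples,
            "events": len(events),
            "valid_events": int(n_valid),
        },
    )

    if uptime is not None:
        if len(fdf):
            result.activity = _stage(
                "aggregate", bin_events, fdf, uptime, config.bin,
                config.exclude_dates,
            )
        else:
            result.activity = pd.DataFrame(
                columns=["device_id", "bin", "date", "count", "fraction",
                         "normalized"]
            )
        logger.info("aggregate: %d bins", len(result.activity))
        if traps is not None and len(result.activity):
            aligned = _stage("traps", align_trap_schedule, traps)
            result.comparison = _stage(
                "compare", compare_methods, result.activity, aligned,
                config.exclude_dates,
            )
            result.summary = _stage(
                "summarize", summarize_study, result.activity, aligned
            )
    return result
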