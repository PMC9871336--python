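"""Orchestration: file I/O, configuration, and the end-to-end pipeline.

Composes the other modules into the simulate -> censor -> fit -> race ->
regress chain and renders per-construct summary tables. Configuration is a
validated pydantic model serialized as JSON with an explicit seed; every
stochastic stage draws from an independent child stream of that seed, so a
fixed (config, seed) pair reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .datasets import charge_run_length_points, table1_frame
from .errors import ValidationError
from .estimate import RateEstimate, Unit
from .fits import fit_exponential_truncated, fit_linear
from .race import (
    race_table,
    race_table_frame,
    render_race_table,
    round_half_up,
    tethered_head_on_rate,
)
from .simulate import (
    CycleRates,
    DetectionSettings,
    DwellMixture,
    EventRecord,
    apply_detection_censoring,
    events_to_frame,
    frame_to_events,
    simulate_dwell_times,
    simulate_processive_runs,
)

__all__ = [
    "PipelineConfig",
    "RunSimulationConfig",
    "DwellSimulationConfig",
    "SummaryReport",
    "load_event_table",
    "run_race_report",
    "charge_runlength_report",
    "run_full_pipeline",
]

log = logging.getLogger("kinrace.pipeline")


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class RunSimulationConfig(BaseModel):
    """Processive-run simulation block."""

    k_on_TH: float = Field(gt=0)
    k_detach: float = Field(ge=0)
    k_step: float = Field(gt=0)
    step_size_nm: float = Field(default=8.0, gt=0)
    n_events: int = Field(ge=0)

    def cycle_rates(self) -> CycleRates:
        return CycleRates(self.k_on_TH, self.k_detach, self.k_step, self.step_size_nm)


class DwellSimulationConfig(BaseModel):
    """Dwell-time mixture simulation block."""

    components: list[tuple[float, float]]
    n_events: int = Field(ge=0)

    def mixture(self) -> DwellMixture:
        return DwellMixture(self.components)


class DetectionConfig(BaseModel):
    pixel_size_um: float = Field(default=0.0567, gt=0)
    frame_interval_s: float = Field(default=0.1, gt=0)
    min_pixels: int = Field(default=3, gt=0)
    min_frames: int = Field(default=3, gt=0)

    def settings(self) -> DetectionSettings:
        return DetectionSettings(
            self.pixel_size_um, self.frame_interval_s, self.min_pixels, self.min_frames
        )


class RaceInputRow(BaseModel):
    # "construct" collides with a deprecated BaseModel method, hence the alias
    model_config = ConfigDict(populate_by_name=True)

    name: str = Field(alias="construct")
    dwell_s: float
    dwell_ci: float = 0.0
    run_length_um: float
    run_length_ci: float = 0.0


class PipelineConfig(BaseModel):
    """Validated configuration for :func:`run_full_pipeline`."""

    seed: int | None = None
    runs: RunSimulationConfig | None = None
    dwells: DwellSimulationConfig | None = None
    detection: DetectionConfig = DetectionConfig()
    race_inputs: list[RaceInputRow] = []
    regression_buffers: list[str] = []
    output_dir: str | None = None

    @model_validator(mode="after")
    def _seed_required_for_stochastic(self) -> "PipelineConfig":
        if (self.runs or self.dwells) and self.seed is None:
            raise ValueError("seed is required when any simulation block is enabled")
        return self

    def config_hash(self) -> str:
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_event_table(path: str | Path) -> list[EventRecord]:
    """Read a CSV event table; validation errors name the offending row."""
    frame = pd.read_csv(path)
    return frame_to_events(frame)


# ---------------------------------------------------------------------------
# report sections
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    """Bundle of report sections plus provenance.

    ``sections`` maps section name to a DataFrame (full precision);
    ``rendered`` holds the display-rounded variants; ``provenance`` records
    config hash, seed and package version; ``failures`` lists stages that
    errored (earlier outputs are preserved).
    """

    sections: dict[str, pd.DataFrame] = field(default_factory=dict)
    rendered: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.sections.items():
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
        for name, frame in self.rendered.items():
            p = out / f"{name}_rendered.tsv"
            frame.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / "provenance.json"
        p.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        written.append(p)
        return written


def run_race_report(
    inputs: Sequence[Mapping[str, Any]] | pd.DataFrame,
    step_size_nm: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Race-model section: full-precision and display-rounded tables.

    ``inputs`` rows carry construct, dwell_s, dwell_ci, run_length_um,
    run_length_ci. Invalid rows are flagged in the ``error`` column rather
    than aborting the batch.
    """
    frame = inputs if isinstance(inputs, pd.DataFrame) else pd.DataFrame(list(inputs))
    full = race_table_frame(frame, step_size_nm)
    rows = []
    for rec in frame.to_dict("records"):
        try:
            rows.append(
                {
                    "construct": rec["construct"],
                    "dwell": RateEstimate(
                        float(rec["dwell_s"]),
                        float(rec.get("dwell_ci", 0.0) or 0.0),
                        Unit.SECOND,
                    ),
                    "run_length": RateEstimate(
                        float(rec["run_length_um"]),
                        float(rec.get("run_length_ci", 0.0) or 0.0),
                        Unit.MICROMETER,
                    ),
                }
            )
        except Exception:
            rows.append({"construct": rec.get("construct", "")})
    rendered = render_race_table(race_table(rows, step_size_nm))
    return full, rendered


def charge_runlength_report(
    run_lengths_by_buffer: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-buffer linear regression of run length on loop-12 net charge.

    Expects per-buffer frames with ``net_charge`` and ``run_length_um``
    columns; rows with missing run length (non-processive constructs) are
    excluded and counted. Defaults to the packaged construct series.
    Unweighted OLS is the primary mode, matching how such charge scans are
    conventionally summarized.
    """
    if run_lengths_by_buffer is None:
        run_lengths_by_buffer = {
            name: charge_run_length_points(name) for name in ("BRB12", "BRB80")
        }
    records = []
    for name, frame in run_lengths_by_buffer.items():
        usable = frame.dropna(subset=["run_length_um"])
        excluded = sorted(
            set(frame.get("construct", pd.Series(dtype=str)).astype(str))
            - set(usable.get("construct", pd.Series(dtype=str)).astype(str))
        )
        if len(usable) < 2:
            records.append(
                {"buffer": name, "skipped": True,
                 "note": f"only {len(usable)} usable points", "excluded": ";".join(excluded)}
            )
            continue
        fit = fit_linear(usable["net_charge"], usable["run_length_um"])
        records.append(
            {
                "buffer": name,
                "skipped": False,
                "slope_um_per_charge": fit.slope,
                "slope_ci95": fit.slope_ci95,
                "intercept_um": fit.intercept,
                "intercept_ci95": fit.intercept_ci95,
                "n_points": fit.n,
                "excluded": ";".join(excluded),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_full_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute simulate -> censor -> fit -> race -> regress for one config.

    Stages are independent: a failing stage is recorded in
    ``report.failures`` and later stages still run. Fixed (config, seed)
    pairs give identical reports.
    """
    report = SummaryReport(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.model_dump(),
        }
    )
    root = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    run_seed, dwell_seed = root.spawn(2)
    settings = config.detection.settings()

    if config.runs is not None:
        try:
            rates = config.runs.cycle_rates()
            events = simulate_processive_runs(rates, config.runs.n_events, run_seed)
            kept, removed = apply_detection_censoring(events, settings, "distance")
            log.info(
                "runs: simulated %d, censored %d below %.3f um",
                len(events), removed, settings.distance_cutoff_um,
            )
            report.sections["events"] = events_to_frame(events)
            fit = fit_exponential_truncated(
                [ev.run_length_um for ev in kept if ev.run_length_um > 0],
                cutoff=settings.distance_cutoff_um,
            )
            steps_est = RateEstimate(
                fit.tau, fit.tau_ci95[0], Unit.MICROMETER
            ).scaled(1000.0 / rates.step_size_nm).with_unit(Unit.DIMENSIONLESS)
            kon_th = tethered_head_on_rate(
                RateEstimate(rates.k_detach, 0.0, Unit.PER_SECOND), steps_est
            )
            report.sections["run_length_fit"] = pd.DataFrame(
                [
                    {
                        "n_simulated": len(events),
                        "n_censored": removed,
                        "n_used": fit.n_used,
                        "cutoff_um": settings.distance_cutoff_um,
                        "run_length_um": fit.tau,
                        "run_length_ci": fit.tau_ci95[0],
                        "k_on_TH_true": rates.k_on_TH,
                        "k_on_TH_recovered": kon_th.value,
                        "k_on_TH_recovered_ci": kon_th.ci95,
                    }
                ]
            )
        except Exception as exc:  # stage isolation, deliberately broad
            log.exception("run simulation stage failed")
            report.failures["runs"] = str(exc)

    if config.dwells is not None:
        try:
            dwells = simulate_dwell_times(
                config.dwells.mixture(), config.dwells.n_events, dwell_seed
            )
            kept, removed = apply_detection_censoring(dwells, settings, "time")
            fit = fit_exponential_truncated(kept, cutoff=settings.time_cutoff_s)
            log.info("dwells: simulated %d, censored %d", len(dwells), removed)
            report.sections["dwell_fit"] = pd.DataFrame(
                [
                    {
                        "n_simulated": len(dwells),
                        "n_censored": removed,
                        "n_used": fit.n_used,
                        "cutoff_s": settings.time_cutoff_s,
                        "dwell_s": fit.tau,
                        "dwell_ci": fit.tau_ci95[0],
                        "off_rate_s": 1.0 / fit.tau,
                    }
                ]
            )
        except Exception as exc:
            log.exception("dwell simulation stage failed")
            report.failures["dwells"] = str(exc)

    if config.race_inputs:
        try:
            frame = pd.DataFrame(
                [r.model_dump(by_alias=True) for r in config.race_inputs]
            )
            full, rendered = run_race_report(frame)
            report.sections["race"] = full
            report.rendered["race"] = rendered
        except Exception as exc:
            log.exception("race stage failed")
            report.failures["race"] = str(exc)

    if config.regression_buffers:
        try:
            points = {
                name: charge_run_length_points(name)
                for name in config.regression_buffers
            }
            report.sections["charge_regression"] = charge_runlength_report(points)
        except Exception as exc:
            log.exception("regression stage failed")
            report.failures["charge_regression"] = str(exc)

    if config.output_dir:
        report.write(config.output_dir)
    return report


def default_race_inputs() -> pd.DataFrame:
    """The packaged per-construct (dwell, run length) measurement table."""
    return table1_frame()
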