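"""Seeded Monte-Carlo generator of single-molecule motility observables.

Emulates every data type the estimators consume, at the level of the
underlying chemomechanical cycle rather than of images:

* processive runs from the per-cycle kinetic race (geometric step counts,
  8-nm steps, exponential cycle times),
* dwell-time draws from single- or multi-component exponential mixtures,
* stopped-flow observed rates linear in microtubule concentration,
* ATP-triggered half-site-release saturation (Michaelis-Menten) curves,
* microtubule-pelleting Langmuir binding curves,
* the pixel/frame detection censor that removes traces shorter than
  3 pixels (distance) or 3 frames (time), as applied to kymograph data.

All generators take an explicit seed and are reproducible bit-for-bit;
noiseless modes evaluate the closed-form curves exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .race import DEFAULT_STEP_SIZE_NM

__all__ = [
    "CycleRates",
    "EventRecord",
    "DwellMixture",
    "DetectionSettings",
    "KineticsCurve",
    "simulate_processive_runs",
    "simulate_dwell_times",
    "apply_detection_censoring",
    "simulate_bimolecular_rates",
    "simulate_half_site_release",
    "simulate_pelleting",
    "events_to_frame",
    "frame_to_events",
]


@dataclass(frozen=True)
class CycleRates:
    """Rates of the stepping cycle used to generate processive runs.

    ``k_on_TH`` and ``k_detach`` (s^-1) set the per-cycle race; ``k_step``
    (s^-1) is the overall stepping rate that sets cycle durations (velocity =
    k_step * step_size). Step size in nm, default 8.
    """

    k_on_TH: float
    k_detach: float
    k_step: float
    step_size_nm: float = DEFAULT_STEP_SIZE_NM

    def __post_init__(self) -> None:
        if self.k_on_TH <= 0:
            raise DomainError("k_on_TH must be > 0")
        if self.k_detach < 0:
            raise DomainError("k_detach must be >= 0")
        if self.k_step <= 0:
            raise DomainError("k_step must be > 0")
        if self.step_size_nm <= 0:
            raise DomainError("step_size_nm must be > 0")

    @property
    def p_detach(self) -> float:
        return self.k_detach / (self.k_on_TH + self.k_detach)


@dataclass(frozen=True)
class EventRecord:
    """One simulated (or observed) processive run."""

    event_id: int
    n_steps: int
    run_length_um: float
    duration_s: float
    velocity_um_s: float
    censored: bool = False


@dataclass(frozen=True)
class DwellMixture:
    """Exponential dwell-time mixture: [(weight, tau_s), ...], taus ascending."""

    components: tuple[tuple[float, float], ...]

    def __init__(self, components: Iterable[tuple[float, float]]):
        comps = tuple(sorted(((float(w), float(t)) for w, t in components), key=lambda c: c[1]))
        if not comps:
            raise ValidationError("mixture needs at least one component")
        if any(t <= 0 for _, t in comps):
            raise ValidationError("all taus must be > 0")
        if any(w < 0 for w, _ in comps):
            raise ValidationError("weights must be >= 0")
        total = sum(w for w, _ in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {total}")
        object.__setattr__(self, "components", comps)

    @property
    def mean(self) -> float:
        return sum(w * t for w, t in self.components)


@dataclass(frozen=True)
class DetectionSettings:
    """Pixel/frame detection limits of the imaging system.

    Defaults: pixel size 0.0567 um so that the 3-pixel distance cutoff is the
    conventional 0.17 um, and 0.1 s frame interval (10 fps) so the 3-frame
    time cutoff is 0.3 s; 0.02 s and 0.2 s intervals correspond to 50 fps and
    5 fps acquisition.
    """

    pixel_size_um: float = 0.0567
    frame_interval_s: float = 0.1
    min_pixels: int = 3
    min_frames: int = 3

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.frame_interval_s) <= 0:
            raise DomainError("pixel size and frame interval must be > 0")
        if self.min_pixels <= 0 or self.min_frames <= 0:
            raise DomainError("min_pixels and min_frames must be > 0")

    @property
    def distance_cutoff_um(self) -> float:
        return self.min_pixels * self.pixel_size_um

    @property
    def time_cutoff_s(self) -> float:
        return self.min_frames * self.frame_interval_s


@dataclass(frozen=True)
class KineticsCurve:
    """Paired (concentration, response) series with optional per-point noise SD."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    x_name: str = "x"
    y_name: str = "y"
    y_sd: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "y_sd": [self.y_sd] * len(self.x)}
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_processive_runs(
    rates: CycleRates,
    n: int,
    seed: int | np.random.SeedSequence,
    max_steps: int | None = None,
) -> list[EventRecord]:
    """Draw ``n`` processive runs from the kinetic race.

    Each cycle resolves to a forward step with probability
    ``k_on_TH / (k_on_TH + k_detach)``, otherwise the run ends, so the step
    count is geometric with support >= 0 (a run may detach before its first
    step; such sub-resolution events are what the detection censor later
    removes). The run duration is the sum of ``n_steps + 1`` exponential
    cycle times at rate ``k_step``.
    """
    if n < 0:
        raise DomainError("n must be >= 0")
    if rates.k_detach == 0 and max_steps is None:
        raise DomainError(
            "k_detach = 0 never terminates; supply max_steps as a guard"
        )
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    if rates.k_detach > 0:
        # numpy geometric counts trials to first success (support >= 1)
        n_steps = rng.geometric(rates.p_detach, size=n) - 1
    else:
        n_steps = np.full(n, max_steps, dtype=np.int64)
    if max_steps is not None:
        n_steps = np.minimum(n_steps, max_steps)
    durations = rng.gamma(shape=n_steps + 1, scale=1.0 / rates.k_step, size=n)
    run_lengths = n_steps * rates.step_size_nm / 1000.0
    velocities = np.where(durations > 0, run_lengths / durations, 0.0)
    return [
        EventRecord(i, int(k), float(rl), float(d), float(v))
        for i, (k, rl, d, v) in enumerate(
            zip(n_steps, run_lengths, durations, velocities)
        )
    ]


def simulate_dwell_times(
    mix: DwellMixture, n: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Draw ``n`` dwell times from an exponential mixture (seeded)."""
    if n < 0:
        raise DomainError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    weights = np.array([w for w, _ in mix.components])
    taus = np.array([t for _, t in mix.components])
    which = rng.choice(len(taus), size=n, p=weights)
    return rng.exponential(taus[which])


def apply_detection_censoring(
    events: Sequence[EventRecord] | Sequence[float] | np.ndarray,
    settings: DetectionSettings,
    axis: Literal["distance", "time"],
) -> tuple[list, int]:
    """Remove events below the pixel (distance) or frame (time) cutoff.

    Accepts either :class:`EventRecord` sequences (distance axis compares run
    length, time axis compares duration) or plain numeric samples (dwell
    times or run lengths compared directly). Kept events are returned
    unchanged; ``kept + removed == input`` always, and the operation is
    idempotent.
    """
    if axis == "distance":
        cutoff = settings.distance_cutoff_um
    elif axis == "time":
        cutoff = settings.time_cutoff_s
    else:
        raise DomainError(f"unknown axis {axis!r}; expected 'distance' or 'time'")

    def measure(ev) -> float:
        if isinstance(ev, EventRecord):
            return ev.run_length_um if axis == "distance" else ev.duration_s
        return float(ev)

    kept = [ev for ev in events if measure(ev) >= cutoff]
    return kept, len(events) - len(kept)


def _noisy(y: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if noise_sd == 0:
        return y
    return y + rng.normal(0.0, noise_sd, size=y.shape)


def simulate_bimolecular_rates(
    mt_concentrations_uM: Sequence[float],
    k_on_Mt: float,
    k_basal: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> KineticsCurve:
    """Stopped-flow observed rates: k_obs = k_on_Mt * [Mt] + k_basal (+ noise)."""
    mt = np.asarray(mt_concentrations_uM, dtype=float)
    if np.any(mt < 0):
        raise DomainError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    k_obs = _noisy(k_on_Mt * mt + k_basal, noise_sd, rng)
    return KineticsCurve(tuple(mt), tuple(k_obs), "mt_uM", "k_obs_per_s", noise_sd)


def simulate_half_site_release(
    atp_concentrations_uM: Sequence[float],
    k_max: float,
    K_M: float,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> KineticsCurve:
    """ATP-triggered half-site release: k_obs = k_max*[ATP]/(K_M+[ATP]) (+ noise)."""
    if k_max <= 0:
        raise DomainError("k_max must be > 0")
    if K_M <= 0:
        raise DomainError("K_M must be > 0")
    atp = np.asarray(atp_concentrations_uM, dtype=float)
    if np.any(atp < 0):
        raise DomainError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    k_obs = _noisy(k_max * atp / (K_M + atp), noise_sd, rng)
    return KineticsCurve(tuple(atp), tuple(k_obs), "atp_uM", "k_obs_per_s", noise_sd)


def simulate_pelleting(
    mt_concentrations_uM: Sequence[float],
    K_D: float,
    V_max: float,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> KineticsCurve:
    """Microtubule pelleting fractions from a Langmuir isotherm.

    fraction = V_max*[Mt]/(K_D+[Mt]) + noise, clipped at 0. Fractions are on
    the AMPPNP-normalized scale, so V_max slightly above 1 is tolerated
    (normalization noise can push points past 100%).
    """
    if K_D <= 0:
        raise DomainError("K_D must be > 0")
    if not 0 < V_max <= 1.2:
        raise DomainError("V_max must be in (0, 1.2]")
    mt = np.asarray(mt_concentrations_uM, dtype=float)
    if np.any(mt < 0):
        raise DomainError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    frac = np.clip(_noisy(V_max * mt / (K_D + mt), noise_sd, rng), 0.0, None)
    return KineticsCurve(tuple(mt), tuple(frac), "mt_uM", "fraction_pellet", noise_sd)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "event_id",
    "n_steps",
    "run_length_um",
    "duration_s",
    "velocity_um_s",
    "censored",
]


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "n_steps": ev.n_steps,
                "run_length_um": ev.run_length_um,
                "duration_s": ev.duration_s,
                "velocity_um_s": ev.velocity_um_s,
                "censored": ev.censored,
            }
            for ev in events
        ],
        columns=_EVENT_COLUMNS,
    )


def frame_to_events(frame: pd.DataFrame) -> list[EventRecord]:
    missing = [c for c in ("event_id", "run_length_um", "duration_s") if c not in frame]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    events = []
    for i, rec in enumerate(frame.to_dict("records")):
        try:
            duration = float(rec["duration_s"])
            if duration <= 0:
                raise ValueError("duration must be > 0")
            events.append(
                EventRecord(
                    event_id=int(rec["event_id"]),
                    n_steps=int(rec.get("n_steps", 0) or 0),
                    run_length_um=float(rec["run_length_um"]),
                    duration_s=duration,
                    velocity_um_s=float(
                        rec.get("velocity_um_s", rec["run_length_um"] / duration)
                    ),
                    censored=bool(rec.get("censored", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return events
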