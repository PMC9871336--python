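"""The kinetic race: from single-molecule observables to cycle rate constants.

During each mechanochemical cycle a kinesin dimer passes through a vulnerable
one-head-bound (1HB) state that resolves in one of two ways: the tethered
head attaches to the next tubulin site (rate ``k_on_TH``), completing a step,
or the bound head detaches from the microtubule (rate ``k_detach``), ending
the run. Processivity is set by this race:

    p_detach = k_detach / (k_on_TH + k_detach)  ≈  k_detach / k_on_TH
    steps per run = 1 / p_detach
    k_on_TH = k_detach * steps per run

Combined with the definition K_D = k_detach / k_on_Mt, these identities let
measured dwell times, run lengths, pelleting affinities, and stopped-flow
on-rates be converted into the full set of cycle rate constants. All CI
propagation uses relative-error quadrature via :class:`~kinrace.estimate.RateEstimate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, UndefinedRaceError, UnitError
from .estimate import RateEstimate, Unit

__all__ = [
    "RaceParameters",
    "KineticRaceResult",
    "detach_probability",
    "run_length_in_steps_from_p",
    "steps_from_run_length",
    "off_rate_from_dwell",
    "tethered_head_on_rate",
    "detach_rate_from_affinity",
    "stepping_rate_from_velocity",
    "fold_change",
    "race_table",
    "race_table_frame",
    "render_race_table",
    "round_half_up",
    "round_sig",
]

DEFAULT_STEP_SIZE_NM = 8.0


@dataclass(frozen=True)
class RaceParameters:
    """Rates of the per-cycle kinetic race plus the motor step size (nm)."""

    k_detach: RateEstimate
    k_on_TH: RateEstimate
    step_size_nm: float = DEFAULT_STEP_SIZE_NM

    def __post_init__(self) -> None:
        if self.step_size_nm <= 0:
            raise DomainError("step_size_nm must be > 0")
        for name in ("k_detach", "k_on_TH"):
            est = getattr(self, name)
            if est.unit is not Unit.PER_SECOND:
                raise UnitError(f"{name} must be per_second, got {est.unit.value}")


@dataclass(frozen=True)
class KineticRaceResult:
    """One construct's race bookkeeping: dwell -> off-rate -> steps -> k_on_TH.

    ``error`` is set (and the derived fields are None) for rows whose inputs
    were invalid; batch processing never aborts on a single bad row.
    """

    construct: str
    dwell: RateEstimate | None
    off_rate: RateEstimate | None
    run_length: RateEstimate | None
    steps: RateEstimate | None
    k_on_TH: RateEstimate | None
    error: str | None = None


# ---------------------------------------------------------------------------
# scalar race algebra
# ---------------------------------------------------------------------------

def detach_probability(
    k_detach: float, k_on_TH: float, approximate: bool = False
) -> float:
    """Per-cycle probability that the race resolves by detachment.

    Exact form ``k_detach / (k_on_TH + k_detach)``; the approximate form
    ``k_detach / k_on_TH`` is the commonly quoted first-order version, valid
    when detachment is rare.
    """
    if k_detach < 0 or k_on_TH < 0:
        raise DomainError("rates must be >= 0")
    if k_detach == 0 and k_on_TH == 0:
        raise UndefinedRaceError("both race rates are zero; outcome undefined")
    if approximate:
        if k_on_TH == 0:
            raise DomainError("approximate form requires k_on_TH > 0")
        return k_detach / k_on_TH
    return k_detach / (k_on_TH + k_detach)


def run_length_in_steps_from_p(p_detach: float) -> float:
    """Mean number of steps per run: the reciprocal of the detach probability."""
    if not 0 < p_detach <= 1:
        raise DomainError(f"p_detach must be in (0, 1], got {p_detach}")
    return 1.0 / p_detach


def steps_from_run_length(
    run_length: RateEstimate, step_size_nm: float = DEFAULT_STEP_SIZE_NM
) -> RateEstimate:
    """Convert a run length (micrometer) into a step count (run length / 8 nm)."""
    if run_length.unit is not Unit.MICROMETER:
        raise UnitError(f"run_length must be micrometer, got {run_length.unit.value}")
    if run_length.value <= 0:
        raise DomainError("run_length must be > 0")
    if step_size_nm <= 0:
        raise DomainError("step_size_nm must be > 0")
    return run_length.scaled(1000.0 / step_size_nm).with_unit(Unit.DIMENSIONLESS)


def off_rate_from_dwell(dwell: RateEstimate) -> RateEstimate:
    """Microtubule off-rate as the reciprocal of the mean dwell time.

    The relative CI is preserved, the first-order propagation for a
    reciprocal.
    """
    if dwell.unit is not Unit.SECOND:
        raise UnitError(f"dwell must be second, got {dwell.unit.value}")
    if dwell.value <= 0:
        raise DomainError("dwell must be > 0")
    return dwell.reciprocal()


def tethered_head_on_rate(off_rate: RateEstimate, steps: RateEstimate) -> RateEstimate:
    """k_on_TH = off-rate x mean steps per run (CI by quadrature)."""
    if off_rate.unit is not Unit.PER_SECOND:
        raise UnitError(f"off_rate must be per_second, got {off_rate.unit.value}")
    if steps.unit is not Unit.DIMENSIONLESS:
        raise UnitError(f"steps must be dimensionless, got {steps.unit.value}")
    if off_rate.value <= 0 or steps.value <= 0:
        raise DomainError("off_rate and steps must be > 0")
    return off_rate * steps


def detach_rate_from_affinity(
    k_d: RateEstimate, k_on_Mt: RateEstimate
) -> RateEstimate:
    """k_detach = K_D x k_on_Mt, from the definition K_D = k_detach / k_on_Mt."""
    if k_d.unit is not Unit.MICROMOLAR:
        raise UnitError(f"K_D must be micromolar, got {k_d.unit.value}")
    if k_on_Mt.unit is not Unit.PER_MICROMOLAR_PER_SECOND:
        raise UnitError(
            f"k_on_Mt must be per_micromolar_per_second, got {k_on_Mt.unit.value}"
        )
    if k_d.value <= 0 or k_on_Mt.value <= 0:
        raise DomainError("K_D and k_on_Mt must be > 0")
    return k_d * k_on_Mt


def stepping_rate_from_velocity(
    velocity_um_s: float, step_size_nm: float = DEFAULT_STEP_SIZE_NM
) -> float:
    """Overall stepping rate (s^-1) from velocity (um/s) and step size (nm)."""
    if step_size_nm <= 0:
        raise DomainError("step_size_nm must be > 0")
    if velocity_um_s < 0:
        raise DomainError("velocity must be >= 0")
    return velocity_um_s * 1000.0 / step_size_nm


def fold_change(a: RateEstimate, b: RateEstimate) -> RateEstimate:
    """Dimensionless ratio a/b of two estimates with matching units."""
    if a.unit is not b.unit:
        raise UnitError(f"unit mismatch: {a.unit.value} vs {b.unit.value}")
    if b.value <= 0:
        raise DomainError("denominator must be > 0")
    return a / b


# ---------------------------------------------------------------------------
# batch: one Table-1-style row per construct
# ---------------------------------------------------------------------------

def _race_row(
    construct: str,
    dwell: RateEstimate,
    run_length: RateEstimate,
    step_size_nm: float,
) -> KineticRaceResult:
    off = off_rate_from_dwell(dwell)
    steps = steps_from_run_length(run_length, step_size_nm)
    kon = tethered_head_on_rate(off, steps)
    return KineticRaceResult(construct, dwell, off, run_length, steps, kon)


def race_table(
    rows: Iterable[Mapping[str, object]],
    step_size_nm: float = DEFAULT_STEP_SIZE_NM,
) -> list[KineticRaceResult]:
    """Compute off-rate, step count and k_on_TH for each (dwell, run length) row.

    Each row is a mapping with keys ``construct``, ``dwell`` (RateEstimate,
    second) and ``run_length`` (RateEstimate, micrometer). Invalid rows yield
    a flagged result with ``error`` set; processing continues.
    """
    out: list[KineticRaceResult] = []
    for row in rows:
        construct = str(row.get("construct", ""))
        try:
            dwell = row["dwell"]
            run_length = row["run_length"]
            if not isinstance(dwell, RateEstimate) or not isinstance(
                run_length, RateEstimate
            ):
                raise DomainError("dwell and run_length must be RateEstimate")
            out.append(_race_row(construct, dwell, run_length, step_size_nm))
        except (KeyError, DomainError, UnitError) as exc:
            out.append(
                KineticRaceResult(construct, None, None, None, None, None, str(exc))
            )
    return out


def race_table_frame(
    frame: pd.DataFrame, step_size_nm: float = DEFAULT_STEP_SIZE_NM
) -> pd.DataFrame:
    """Tabular wrapper around :func:`race_table`.

    Expects columns ``construct, dwell_s, dwell_ci, run_length_um,
    run_length_ci`` (CI columns optional, default 0) and appends
    ``off_rate_s, off_rate_ci, steps, steps_ci, kon_th_s, kon_th_ci, error``.
    """
    rows = []
    for _, rec in frame.iterrows():
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
        except (DomainError, ValueError) as exc:
            rows.append({"construct": rec.get("construct", ""), "bad": str(exc)})
    results = race_table(
        [r if "bad" not in r else {"construct": r["construct"]} for r in rows],
        step_size_nm,
    )
    # restore original validation messages where row construction itself failed
    results = [
        res
        if "bad" not in raw
        else KineticRaceResult(res.construct, None, None, None, None, None, raw["bad"])
        for raw, res in zip(rows, results)
    ]
    records = []
    for raw, res in zip(frame.to_dict("records"), results):
        rec = dict(raw)
        rec.update(
            off_rate_s=res.off_rate.value if res.off_rate else None,
            off_rate_ci=res.off_rate.ci95 if res.off_rate else None,
            steps=res.steps.value if res.steps else None,
            steps_ci=res.steps.ci95 if res.steps else None,
            kon_th_s=res.k_on_TH.value if res.k_on_TH else None,
            kon_th_ci=res.k_on_TH.ci95 if res.k_on_TH else None,
            error=res.error,
        )
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# render-time rounding (full precision is retained everywhere upstream)
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 rounds away from zero), for table display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures with half-up ties."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    exponent = d.adjusted()  # position of the leading digit
    return float(round_half_up(x, sig - 1 - exponent))


def render_race_table(results: Sequence[KineticRaceResult]) -> pd.DataFrame:
    """Display-rounded race table: off-rates to 2 significant figures (CIs to
    1), steps and k_on_TH to the nearest integer — the precision used when
    these quantities are conventionally reported."""
    records = []
    for res in results:
        if res.error is not None:
            records.append({"construct": res.construct, "error": res.error})
            continue
        records.append(
            {
                "construct": res.construct,
                "dwell_s": res.dwell.value,
                "dwell_ci": res.dwell.ci95,
                "off_rate_s": round_sig(res.off_rate.value, 2),
                "off_rate_ci": round_sig(res.off_rate.ci95, 1),
                "steps": round_half_up(res.steps.value),
                "steps_ci": round_half_up(res.steps.ci95),
                "kon_th_s": round_half_up(res.k_on_TH.value),
                "kon_th_ci": round_half_up(res.k_on_TH.ci95),
                "error": None,
            }
        )
    return pd.DataFrame(records)
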