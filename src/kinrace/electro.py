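"""Peptide net charge and buffer electrostatics.

The K-loop story is electrostatic: a lysine-rich insertion in loop-12 binds
the glutamate-rich tubulin C-terminal tail, and the interaction is screened
by buffer ions. This module provides the bookkeeping for both sides:

* integer per-residue net charge at pH ~6.9 (K/R +1, D/E -1, histidine 0
  since its pKa ~6 leaves it mostly neutral; no fractional titration),
* validation of a construct charge ledger against mutation deltas and
  optional user-supplied sequences,
* generic ionic strength I = 1/2 sum(c_i z_i^2) and the Debye screening
  length lambda_D = sqrt(eps0*eps_r*kB*T / (2*NA*e^2*I)), about
  0.304 nm / sqrt(I[M]) in water at 25 C,
* the two standard PIPES microtubule buffers as presets with their
  published ionic strengths (speciation of PIPES/EGTA/ATP is user input,
  not recomputed here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy import constants

from .datasets import loop12_ledger, reference_data
from .errors import DomainError, ValidationError

__all__ = [
    "ChargeModel",
    "ChargeLedgerEntry",
    "BufferSpec",
    "LedgerReport",
    "peptide_net_charge",
    "validate_charge_ledger",
    "ionic_strength",
    "debye_length",
    "buffer_presets",
    "packaged_ledger",
]

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
_DEFAULT_CHARGES = {"K": 1, "R": 1, "D": -1, "E": -1, "H": 0}


@dataclass(frozen=True)
class ChargeModel:
    """Integer per-residue charges at a nominal pH (default 6.9).

    Unlisted residues are neutral. Charges must be integers in [-1, +1];
    this is deliberately not a Henderson-Hasselbalch titration.
    """

    residue_charge: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHARGES)
    )
    ph_label: str = "6.9"

    def __post_init__(self) -> None:
        for res, q in self.residue_charge.items():
            if res not in _STANDARD_RESIDUES:
                raise ValidationError(f"unknown residue code {res!r} in charge model")
            if q not in (-1, 0, 1):
                raise ValidationError(f"charge for {res} must be -1, 0 or +1, got {q}")


class ChargeResult(NamedTuple):
    net_charge: int
    lysine_count: int


@dataclass(frozen=True)
class ChargeLedgerEntry:
    """One construct's loop-12 bookkeeping.

    ``parent`` names the construct this one derives from by point
    substitutions between lysine and neutral residues (None for loop swaps
    or the wild type); for such entries the net-charge delta must equal the
    lysine-count delta.
    """

    construct: str
    lysine_count: int
    net_charge: int
    parent: str | None = None


@dataclass(frozen=True)
class BufferSpec:
    """A motility buffer with its (stored, not recomputed) ionic strength."""

    name: str
    ionic_strength_mM: float
    species: tuple[tuple[float, int], ...] = ()
    temperature_K: float = 298.15
    relative_permittivity: float = 78.5
    note: str = ""

    def __post_init__(self) -> None:
        if self.ionic_strength_mM < 0:
            raise DomainError("ionic strength must be >= 0")

    def debye_length_nm(self) -> float:
        return debye_length(
            self.ionic_strength_mM / 1000.0,
            self.temperature_K,
            self.relative_permittivity,
        )


# ---------------------------------------------------------------------------
# sequence charge
# ---------------------------------------------------------------------------

def peptide_net_charge(
    sequence: str, model: ChargeModel | None = None
) -> ChargeResult:
    """Net integer charge and lysine count of a peptide segment.

    Termini are ignored: the segments of interest (loops, coiled-coils) are
    internal stretches of a folded protein, not free peptides. Raises
    :class:`ValidationError` naming the first offending position for
    non-standard residue codes.
    """
    model = model or ChargeModel()
    seq = sequence.strip().upper()
    for i, res in enumerate(seq):
        if res not in _STANDARD_RESIDUES:
            raise ValidationError(f"unknown residue {res!r} at position {i + 1}")
    charge = sum(model.residue_charge.get(res, 0) for res in seq)
    return ChargeResult(net_charge=charge, lysine_count=seq.count("K"))


@dataclass(frozen=True)
class LedgerReport:
    """Outcome of a ledger validation run (discrepancies, never exceptions)."""

    ok: bool
    checks: tuple[str, ...]
    discrepancies: tuple[str, ...]


def validate_charge_ledger(
    entries: Sequence[ChargeLedgerEntry],
    sequences: Mapping[str, str] | None = None,
    model: ChargeModel | None = None,
) -> LedgerReport:
    """Check a charge ledger for internal and sequence consistency.

    Two classes of check: (1) for entries with a recorded parent, the
    net-charge delta must equal the lysine-count delta (K <-> neutral point
    substitutions change both one-for-one); (2) when a sequence is supplied
    for a construct, its recomputed net charge and lysine count must match
    the ledger. Mismatches are itemized in the report, not raised.
    """
    if not entries:
        raise ValidationError("ledger is empty")
    by_name = {e.construct: e for e in entries}
    checks: list[str] = []
    problems: list[str] = []
    for entry in entries:
        if entry.parent is not None:
            parent = by_name.get(entry.parent)
            if parent is None:
                problems.append(
                    f"{entry.construct}: parent {entry.parent!r} not in ledger"
                )
                continue
            dq = entry.net_charge - parent.net_charge
            dk = entry.lysine_count - parent.lysine_count
            if dq == dk:
                checks.append(
                    f"{entry.construct} vs {parent.construct}: "
                    f"delta charge {dq:+d} == delta lysines {dk:+d}"
                )
            else:
                problems.append(
                    f"{entry.construct} vs {parent.construct}: "
                    f"delta charge {dq:+d} != delta lysines {dk:+d}"
                )
    for name, seq in (sequences or {}).items():
        entry = by_name.get(name)
        if entry is None:
            problems.append(f"sequence for unknown construct {name!r}")
            continue
        try:
            got = peptide_net_charge(seq, model)
        except ValidationError as exc:
            problems.append(f"{name}: {exc}")
            continue
        if got.net_charge != entry.net_charge:
            problems.append(
                f"{name}: sequence net charge {got.net_charge} != "
                f"ledger {entry.net_charge}"
            )
        elif got.lysine_count != entry.lysine_count:
            problems.append(
                f"{name}: sequence lysine count {got.lysine_count} != "
                f"ledger {entry.lysine_count}"
            )
        else:
            checks.append(f"{name}: sequence matches ledger")
    return LedgerReport(not problems, tuple(checks), tuple(problems))


def packaged_ledger() -> list[ChargeLedgerEntry]:
    """The bundled loop-12 construct ledger (WT, SuperK, K1L12, 4Q, 5Q)."""
    return [ChargeLedgerEntry(**e) for e in loop12_ledger()]


# ---------------------------------------------------------------------------
# buffer electrostatics
# ---------------------------------------------------------------------------

def ionic_strength(species: Iterable[tuple[float, float]]) -> float:
    """I = 1/2 sum(c_i z_i^2) in mM for (concentration mM, charge z) pairs."""
    total = 0.0
    for conc, z in species:
        if conc < 0:
            raise DomainError(f"negative concentration {conc}")
        total += conc * z * z
    return 0.5 * total


def debye_length(
    ionic_strength_M: float,
    temperature_K: float = 298.15,
    relative_permittivity: float = 78.5,
) -> float:
    """Debye screening length in nm for an electrolyte of given ionic strength.

    lambda_D = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)), with I
    converted to mol/m^3. At the defaults this is ~0.304 nm / sqrt(I[M]).
    """
    if ionic_strength_M <= 0:
        raise DomainError("ionic strength must be > 0")
    if temperature_K <= 0 or relative_permittivity <= 0:
        raise DomainError("temperature and permittivity must be > 0")
    i_mol_m3 = ionic_strength_M * 1000.0
    lam_m = math.sqrt(
        constants.epsilon_0
        * relative_permittivity
        * constants.k
        * temperature_K
        / (2.0 * constants.N_A * constants.e**2 * i_mol_m3)
    )
    return lam_m * 1e9


def buffer_presets() -> list[BufferSpec]:
    """The standard PIPES microtubule buffers with published ionic strengths."""
    specs = []
    for raw in reference_data()["buffers"]:
        specs.append(
            BufferSpec(
                name=raw["name"],
                ionic_strength_mM=float(raw["ionic_strength_mM"]),
                note=raw.get("note", ""),
            )
        )
    return specs
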