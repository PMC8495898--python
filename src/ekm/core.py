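"""Domain types, constants, and reference-ladder statistics.

The kinetic method determines the gas-phase acidity (GA) of an analyte acid
AH from the competitive collision-induced dissociation of proton-bound
heterodimers [A·H·A_ref(i)]⁻ formed with a *ladder* of reference acids of
known deprotonation thermochemistry.  Everything downstream of the
instrument works in three quantities:

* deprotonation enthalpy  ΔacidH°  (kJ/mol)
* deprotonation entropy   ΔacidS°  (J/(mol·K))
* gas-phase acidity       GA = ΔacidG° = ΔacidH° − T·ΔacidS°  at 298.15 K

Units follow the conventions of the thermochemical literature: enthalpies
and free energies in kJ/mol, entropies in J/(mol·K).  The J→kJ conversion
is applied exactly once, inside :func:`ga_from_enthalpy_entropy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_J",
    "R_KJ",
    "T_STD",
    "EKMError",
    "SchemaError",
    "IdentifiabilityError",
    "ConvergenceError",
    "ReferenceAcid",
    "LadderSummary",
    "EKMResult",
    "ladder_summary",
    "ga_from_enthalpy_entropy",
]

#: Universal gas constant, J/(mol·K).  Used exactly as 8.3145 everywhere.
R_J = 8.3145
#: Gas constant in kJ/(mol·K), for slopes expressed per kJ/mol.
R_KJ = R_J / 1000.0
#: Standard thermodynamic temperature for GA derivations, K.
T_STD = 298.15


class EKMError(Exception):
    """Base class for pipeline errors."""


class SchemaError(EKMError):
    """Malformed or cross-inconsistent input tables."""


class IdentifiabilityError(EKMError):
    """The experimental design cannot separate the requested parameters."""


class ConvergenceError(EKMError):
    """An iterative fit failed to converge."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ReferenceAcid:
    """One rung of the acidity ladder.

    Parameters
    ----------
    name
        Compound identifier.
    dH
        Deprotonation enthalpy ΔacidH°_ref, kJ/mol.
    dS
        Deprotonation entropy ΔacidS°_ref, J/(mol·K).
    dH_unc, dS_unc
        Standard (1σ) uncertainties in the same units.
    ga
        Optional gas-phase acidity, kJ/mol.  If given it must be consistent
        with ΔH − T·ΔS at 298.15 K to within 1 kJ/mol (literature rounding).
    """

    name: str
    dH: float
    dS: float
    dH_unc: float = 0.0
    dS_unc: float = 0.0
    ga: float | None = None

    def __post_init__(self) -> None:
        _require_finite(dH=self.dH, dS=self.dS)
        if self.dH <= 0:
            raise ValueError(f"{self.name}: deprotonation enthalpy must be positive")
        if self.dH_unc < 0 or self.dS_unc < 0:
            raise ValueError(f"{self.name}: uncertainties must be non-negative")
        if self.ga is not None:
            implied = ga_from_enthalpy_entropy(self.dH, self.dS)
            if abs(self.ga - implied) > 1.0:
                raise ValueError(
                    f"{self.name}: GA {self.ga} inconsistent with "
                    f"dH - T*dS = {implied:.2f} kJ/mol (>1 kJ/mol apart)"
                )

    @property
    def ga_implied(self) -> float:
        """GA computed from ΔH and ΔS at 298.15 K."""
        return ga_from_enthalpy_entropy(self.dH, self.dS)


@dataclass(frozen=True)
class LadderSummary:
    """Arithmetic means of a reference ladder's thermochemistry.

    ``dH_avg_unc``/``dS_avg_unc`` are the standard uncertainties of the
    averages, obtained by quadrature combination of the rung uncertainties
    (√Σu²/n, treating rungs as independent).
    """

    dH_avg: float
    dS_avg: float
    n_refs: int
    dH_avg_unc: float = 0.0
    dS_avg_unc: float = 0.0

    def __post_init__(self) -> None:
        if self.n_refs < 2:
            raise IdentifiabilityError("a reference ladder needs at least 2 rungs")


@dataclass(frozen=True)
class EKMResult:
    """Final analyte thermochemistry from the two-stage regression.

    ``ddS`` is the entropic correction Δ(ΔS°) = ΔacidS° − ΔacidS°_ref^avg,
    the quantity the extended method resolves beyond the simple kinetic
    method.  The stored ``ga`` always satisfies GA = ΔH − T·ΔS/1000 exactly
    as computed at ``temperature``.
    """

    dH: float
    dH_unc: float
    dS: float
    dS_unc: float
    ga: float
    ga_unc: float
    ddS: float
    site_label: str = ""
    temperature: float = T_STD

    def __post_init__(self) -> None:
        if self.ga_unc < 0 or self.dH_unc < 0 or self.dS_unc < 0:
            raise ValueError("uncertainties must be non-negative")
        identity = ga_from_enthalpy_entropy(self.dH, self.dS, self.temperature)
        if abs(self.ga - identity) >= 1e-9:
            raise ValueError(
                f"GA {self.ga} violates the dG = dH - T*dS identity "
                f"({identity} at T = {self.temperature} K)"
            )


def ladder_summary(refs: list[ReferenceAcid]) -> LadderSummary:
    """Unweighted arithmetic means of the ladder's ΔH and ΔS.

    Raises
    ------
    IdentifiabilityError
        If fewer than 2 references are supplied (the centered regression
        would be degenerate).
    """
    if len(refs) < 2:
        raise IdentifiabilityError(
            f"need at least 2 reference acids, got {len(refs)}"
        )
    n = len(refs)
    for r in refs:
        _require_finite(**{f"{r.name}.dH": r.dH, f"{r.name}.dS": r.dS})
    dH_avg = sum(r.dH for r in refs) / n
    dS_avg = sum(r.dS for r in refs) / n
    dH_avg_unc = math.sqrt(sum(r.dH_unc**2 for r in refs)) / n
    dS_avg_unc = math.sqrt(sum(r.dS_unc**2 for r in refs)) / n
    return LadderSummary(dH_avg, dS_avg, n, dH_avg_unc, dS_avg_unc)


def ga_from_enthalpy_entropy(dH: float, dS: float, T: float = T_STD) -> float:
    """Gas-phase acidity ΔG = ΔH − T·ΔS, with ΔS converted J→kJ.

    Parameters
    ----------
    dH : kJ/mol
    dS : J/(mol·K)
    T : K, defaults to 298.15

    Returns
    -------
    float
        GA in kJ/mol.
    """
    _require_finite(dH=dH, dS=dS, T=T)
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return dH - T * dS / 1000.0
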