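"""Buffer ionic strength with Davies activity corrections, and unit conversions.

Tris buffers are prepared by titrating Tris base with HCl to the working pH, so
the ionic species are the protonated TrisH+ cation and an equal amount of Cl-.
The acid/base split depends on the activity coefficient of TrisH+, which itself
depends on the ionic strength -- the speciation is therefore solved as a damped
fixed point.  The Davies equation,

    log10(gamma) = -A z^2 (sqrt(I)/(1 + sqrt(I)) - 0.3 I),   I in mol/l,

with A = 0.509 at 25 degC, is used for all charged species; neutral species are
assigned unit activity.

Also houses the small unit conversions used throughout the package: base-pair
molarity from a mass concentration, contour length from a base-pair count at
the B-form rise, and the base-pair spacing of bound protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "DAVIES_A",
    "TRIS_PK",
    "Species",
    "BufferSpec",
    "SpeciationResult",
    "ConvergenceError",
    "davies_log_gamma",
    "speciate_tris",
    "ionic_strength",
    "bp_molarity",
    "contour_from_bp",
    "bp_per_interspersion",
]

#: Davies constant at 25 degC (dimensionless, decadic log form).
DAVIES_A = 0.509

#: Dissociation constant of the TrisH+ / Tris couple.
TRIS_PK = 8.08


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate: Optional["SpeciationResult"] = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class Species:
    """One buffer component.

    ``charge`` is the charge of the (protonated) cation for weak bases with a
    ``pK``, or the cation charge of a fully dissociating salt otherwise; the
    counterion is assumed monovalent (Cl-, Glu-, ...).
    """

    name: str
    conc_mM: float
    charge: int = 1
    pK: Optional[float] = None

    def __post_init__(self):
        if self.conc_mM < 0:
            raise ValueError(f"negative concentration for {self.name!r}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer (cation charge)")


@dataclass(frozen=True)
class BufferSpec:
    species: tuple[Species, ...]
    pH: float

    def __init__(self, species: Sequence[Species], pH: float):
        if not 0.0 < pH < 14.0:
            raise ValueError("pH must lie in (0, 14)")
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "pH", float(pH))


@dataclass(frozen=True)
class SpeciationResult:
    """Self-consistent acid/base split of a weak base titrated with HCl."""

    acid_mM: float
    base_mM: float
    ionic_strength_mM: float
    davies_log_gamma: float
    n_iter: int = 0

    @property
    def total_mM(self) -> float:
        return self.acid_mM + self.base_mM


def davies_log_gamma(ionic_strength_mM: float, charge: int = 1) -> float:
    """Decadic log of the single-ion activity coefficient (Davies equation)."""
    if ionic_strength_mM < 0:
        raise ValueError("ionic strength must be non-negative")
    I = ionic_strength_mM * 1e-3  # mol/l
    s = math.sqrt(I)
    return -DAVIES_A * charge**2 * (s / (1.0 + s) - 0.3 * I)


def speciate_tris(
    total_mM: float,
    pH: float,
    pK: float = TRIS_PK,
    *,
    activity_correction: bool = True,
    background_ionic_strength_mM: float = 0.0,
    tol_mM: float = 1e-6,
    max_iter: int = 500,
    damping: float = 0.5,
) -> SpeciationResult:
    """Split total Tris into TrisH+ ("Tris-Cl") and neutral Tris at a given pH.

    The equilibrium TrisH+ <-> Tris + H+ with activity corrections gives

        [Tris]/[TrisH+] = 10**(pH - pK) * gamma(TrisH+),

    and since the ionic strength entering gamma is I = [TrisH+] (+ background;
    TrisH+ and the Cl- introduced by titration contribute equally), the split
    is iterated to |dI| < ``tol_mM`` with damping factor ``damping``.

    With ``activity_correction=False`` this reduces to the closed-form
    Henderson-Hasselbalch split.
    """
    if total_mM <= 0:
        raise ValueError("total concentration must be positive")
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")

    def split(I_mM: float) -> tuple[float, float]:
        lg = davies_log_gamma(I_mM) if activity_correction else 0.0
        ratio = 10.0 ** (pH - pK + lg)  # base/acid
        acid = total_mM / (1.0 + ratio)
        return acid, lg

    # Start from the ideal-solution split.
    acid, lg = split(background_ionic_strength_mM)
    I = acid + background_ionic_strength_mM
    if not activity_correction:
        return SpeciationResult(acid, total_mM - acid, I, 0.0, n_iter=0)

    for it in range(1, max_iter + 1):
        acid, lg = split(I)
        I_new = acid + background_ionic_strength_mM
        dI = I_new - I
        I = I + damping * dI
        if abs(dI) < tol_mM:
            return SpeciationResult(acid, total_mM - acid, I, lg, n_iter=it)
    raise ConvergenceError(
        f"Tris speciation did not converge in {max_iter} iterations",
        last_iterate=SpeciationResult(acid, total_mM - acid, I, lg, n_iter=max_iter),
    )


def _salt_contribution_mM(sp: Species) -> float:
    # Cation of charge z plus z monovalent counterions: I = c z (z + 1) / 2.
    return 0.5 * sp.conc_mM * sp.charge * (sp.charge + 1)


def ionic_strength(spec: BufferSpec, *, activity_correction: bool = True) -> float:
    """Total ionic strength (mM) of a buffer, I = 1/2 sum c_i z_i^2.

    Fully dissociated salts contribute directly; weak bases with a ``pK`` are
    speciated self-consistently against the full ionic background (the
    protonated fraction and its titration counterion each contribute once).
    """
    background = sum(_salt_contribution_mM(s) for s in spec.species if s.pK is None)
    I = background
    for s in spec.species:
        if s.pK is None:
            continue
        if s.charge != 1:
            raise NotImplementedError("only monovalent weak-base speciation is supported")
        res = speciate_tris(
            s.conc_mM,
            spec.pH,
            s.pK,
            activity_correction=activity_correction,
            background_ionic_strength_mM=background,
        )
        I += res.acid_mM  # TrisH+ and Cl- together: 1/2 (c + c) = c
    return I


def speciation_table(spec: BufferSpec, *, activity_correction: bool = True) -> list[dict]:
    """Per-species breakdown backing the CLI report."""
    background = sum(_salt_contribution_mM(s) for s in spec.species if s.pK is None)
    rows = []
    for s in spec.species:
        if s.pK is None:
            rows.append(
                {
                    "name": s.name,
                    "conc_mM": s.conc_mM,
                    "charge": s.charge,
                    "I_mM": _salt_contribution_mM(s),
                }
            )
        else:
            res = speciate_tris(
                s.conc_mM,
                spec.pH,
                s.pK,
                activity_correction=activity_correction,
                background_ionic_strength_mM=background,
            )
            rows.append(
                {
                    "name": s.name,
                    "conc_mM": s.conc_mM,
                    "charge": s.charge,
                    "acid_mM": res.acid_mM,
                    "base_mM": res.base_mM,
                    "log_gamma": res.davies_log_gamma,
                    "I_mM": res.acid_mM,
                }
            )
    return rows


# --- unit / ratio arithmetic -------------------------------------------------

#: Average molar mass of a base pair as the sodium salt (g/mol).
BP_MOLAR_MASS = 650.0

#: Rise per base pair of B-form DNA (nm).
BP_RISE_NM = 0.34


def bp_molarity(mass_conc_g_per_l: float, mw_bp: float = BP_MOLAR_MASS) -> float:
    """Base-pair molarity (uM) of a DNA mass concentration (g/l)."""
    if mass_conc_g_per_l < 0:
        raise ValueError("mass concentration must be non-negative")
    if mw_bp <= 0:
        raise ValueError("molar mass must be positive")
    return mass_conc_g_per_l / mw_bp * 1e6


def contour_from_bp(n_bp: float, rise_nm: float = BP_RISE_NM) -> float:
    """Contour length (nm) of ``n_bp`` base pairs at the given rise."""
    if n_bp < 0:
        raise ValueError("base-pair count must be non-negative")
    return n_bp * rise_nm


def bp_per_interspersion(
    distance_nm: float, rise_nm: float = BP_RISE_NM, rounding: str = "nearest-10"
) -> float:
    """Base pairs spanned by a contour distance, e.g. between bound proteins.

    ``rounding``: ``"none"`` returns the raw quotient, ``"nearest"`` the
    nearest integer, ``"nearest-10"`` the nearest multiple of ten (the
    convention under which a 10 nm spacing reads as 30 bp).
    """
    if distance_nm <= 0:
        raise ValueError("distance must be positive")
    value = distance_nm / rise_nm
    if rounding == "none":
        return value
    if rounding == "nearest":
        return float(round(value))
    if rounding == "nearest-10":
        return 10.0 * round(value / 10.0)
    raise ValueError(f"unknown rounding convention {rounding!r}")
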