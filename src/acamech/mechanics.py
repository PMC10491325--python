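"""Thin-wall biaxial mechanics of extension-inflation myograph recordings.

A pressure myograph records transmural pressure P (mmHg), deformed outer
diameter (mm) and axial force fT (mN) while a cannulated artery segment is
held at a fixed axial stretch and inflated/deflated.  Together with the
unloaded reference geometry (outer/inner radii from ring perimeters, and the
suture-to-suture length), incompressibility gives the deformed inner radius,

    ri = sqrt(ro^2 - (Ro^2 - Ri^2) / lambda_z),

the mid-wall circumferential stretch is lambda_theta = (ro + ri)/(Ro + Ri),
and thin-wall equilibrium gives the mean wall stresses

    sigma_theta = P * ri / (ro - ri)
    sigma_z     = (fT + P * pi * ri^2) / (pi * (ro - ri) * (ri + ro)).

With P in kPa, forces in mN and lengths in mm these come out in kPa directly.
Circumferential stretch is normalized by its value at zero pressure in the
same cycle, the normalized stress-stretch response is fitted with a
stiffening exponential sigma = a*(exp(b*(lambda-1)) - 1), and the tangent
stiffness is the analytic derivative a*b*exp(b*(lambda-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateWallError,
    ExtrapolationError,
    FitError,
    InfeasibleGeometryError,
    InvalidGeometryError,
    NormalizationAnchorError,
)

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322

#: Default half-width (mmHg) of the window accepted as the zero-pressure anchor.
ZERO_PRESSURE_TOL_MMHG = 0.5


@dataclass(frozen=True)
class ReferenceGeometry:
    """Unloaded vessel geometry: outer/inner radius and length, all in mm."""

    Ro: float
    Ri: float
    L: float

    def __post_init__(self) -> None:
        if not (0 < self.Ri < self.Ro):
            raise InvalidGeometryError(
                f"need 0 < Ri < Ro, got Ri={self.Ri}, Ro={self.Ro}"
            )
        if self.L <= 0:
            raise InvalidGeometryError(f"need L > 0, got L={self.L}")

    @property
    def wall_area(self) -> float:
        """Undeformed wall cross-section area pi*(Ro^2 - Ri^2) in mm^2."""
        return math.pi * (self.Ro**2 - self.Ri**2)


@dataclass
class MyographRecording:
    """One loading or unloading cycle at a fixed axial stretch.

    Parameters
    ----------
    pressure : transmural pressures, mmHg.
    outer_diameter : deformed outer diameters, mm (ro = outer_diameter / 2).
    axial_force : transducer axial force fT, mN.
    stretched_length : cannula-to-cannula stretched length l, mm.
    cycle_label : free-form tag, e.g. "unloading-3".
    """

    pressure: np.ndarray
    outer_diameter: np.ndarray
    axial_force: np.ndarray
    stretched_length: float
    cycle_label: str = "unloading"

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.outer_diameter = np.asarray(self.outer_diameter, dtype=float)
        self.axial_force = np.asarray(self.axial_force, dtype=float)
        n = len(self.pressure)
        if not (len(self.outer_diameter) == len(self.axial_force) == n):
            raise ValueError("pressure, diameter and force series must align")
        if n < 1:
            raise ValueError("recording is empty")
        if np.any(self.pressure < -ZERO_PRESSURE_TOL_MMHG) or np.any(
            self.pressure > 200
        ):
            raise ValueError("pressures must lie within [0, 200] mmHg")
        if np.any(self.outer_diameter <= 0):
            raise ValueError("outer diameters must be positive")

    def __len__(self) -> int:
        return len(self.pressure)


@dataclass(frozen=True)
class DeformedState:
    """Per-point deformed geometry, stretches and stresses."""

    ro: float
    ri: float
    lambda_z: float
    lambda_theta: float
    sigma_theta: float
    sigma_z: float


@dataclass
class StressStretchCurve:
    """Processed biaxial response, stretch normalized to 1 at 0 mmHg."""

    normalized_lambda_theta: np.ndarray
    sigma_theta: np.ndarray
    sigma_z: np.ndarray
    pressure: np.ndarray
    states: list[DeformedState] = field(default_factory=list)


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of sigma = a*(exp(b*(lambda-1)) - 1) plus residual RMSE."""

    a: float
    b: float
    rmse: float


def radii_from_perimeters(
    outer_perimeter: float, inner_perimeter: float, L: float
) -> ReferenceGeometry:
    """Convert measured ring perimeters (mm) to reference radii.

    Perimeters are traced on cut rings; radii follow as perimeter / (2*pi).
    """
    if outer_perimeter <= 0 or inner_perimeter <= 0:
        raise InvalidGeometryError("perimeters must be positive")
    if inner_perimeter >= outer_perimeter:
        raise InvalidGeometryError(
            f"inner perimeter {inner_perimeter} must be smaller than outer "
            f"perimeter {outer_perimeter}"
        )
    return ReferenceGeometry(
        Ro=outer_perimeter / (2 * math.pi), Ri=inner_perimeter / (2 * math.pi), L=L
    )


def axial_stretch(l: float, L: float) -> float:
    """Axial stretch ratio lambda_z = l / L from stretched and unloaded lengths."""
    if l <= 0 or L <= 0:
        raise ValueError(f"lengths must be positive, got l={l}, L={L}")
    return l / L


def deformed_inner_radius(
    ro: float, geom: ReferenceGeometry, lambda_z: float
) -> float:
    """Deformed inner radius from incompressibility.

    The wall volume per unit reference length is conserved, so
    ri = sqrt(ro^2 - (Ro^2 - Ri^2)/lambda_z).
    """
    if lambda_z <= 0:
        raise ValueError("axial stretch must be positive")
    radicand = ro**2 - (geom.Ro**2 - geom.Ri**2) / lambda_z
    if radicand <= 0:
        raise InfeasibleGeometryError(
            f"ro={ro} too small for wall area at lambda_z={lambda_z}: "
            "wall thicker than the lumen allows"
        )
    return math.sqrt(radicand)


def circumferential_stretch(ro: float, ri: float, geom: ReferenceGeometry) -> float:
    """Mid-wall circumferential stretch (ro + ri) / (Ro + Ri)."""
    if not 0 < ri < ro:
        raise ValueError(f"need 0 < ri < ro, got ri={ri}, ro={ro}")
    return (ro + ri) / (geom.Ro + geom.Ri)


def wall_stresses(
    P: float, ro: float, ri: float, fT: float
) -> tuple[float, float]:
    """Mean circumferential and axial wall stress in kPa.

    P is given in mmHg and converted internally; radii in mm and force in mN
    yield stresses in mN/mm^2, i.e. kPa.
    """
    if ro == ri:
        raise DegenerateWallError("zero wall thickness: ro == ri")
    if not 0 < ri < ro:
        raise ValueError(f"need 0 < ri < ro, got ri={ri}, ro={ro}")
    if P < 0:
        raise ValueError("transmural pressure must be non-negative")
    p_kpa = P * MMHG_TO_KPA
    sigma_theta = p_kpa * ri / (ro - ri)
    sigma_z = (fT + p_kpa * math.pi * ri**2) / (math.pi * (ro - ri) * (ri + ro))
    return sigma_theta, sigma_z


def process_recording(
    rec: MyographRecording,
    geom: ReferenceGeometry,
    zero_pressure_tol: float = ZERO_PRESSURE_TOL_MMHG,
) -> StressStretchCurve:
    """Chain kinematics and equilibrium over a recording.

    Computes per-point deformed states (ri from incompressibility, mid-wall
    stretch, thin-wall stresses) and normalizes the circumferential stretch by
    its value at the zero-pressure point of the same cycle, so the normalized
    stretch is exactly 1 at 0 mmHg.

    Raises
    ------
    NormalizationAnchorError
        if no recorded pressure falls within ``zero_pressure_tol`` of 0 mmHg.
    """
    lam_z = axial_stretch(rec.stretched_length, geom.L)
    anchor_candidates = np.flatnonzero(np.abs(rec.pressure) <= zero_pressure_tol)
    if anchor_candidates.size == 0:
        raise NormalizationAnchorError(
            f"no point within {zero_pressure_tol} mmHg of zero pressure; "
            "cannot anchor stretch normalization"
        )
    anchor = anchor_candidates[np.argmin(np.abs(rec.pressure[anchor_candidates]))]

    states: list[DeformedState] = []
    for P, d, fT in zip(rec.pressure, rec.outer_diameter, rec.axial_force):
        ro = d / 2.0
        ri = deformed_inner_radius(ro, geom, lam_z)
        lam_t = circumferential_stretch(ro, ri, geom)
        s_t, s_z = wall_stresses(max(P, 0.0), ro, ri, fT)
        states.append(DeformedState(ro, ri, lam_z, lam_t, s_t, s_z))

    lam = np.array([s.lambda_theta for s in states])
    lam_norm = lam / lam[anchor]
    lam_norm[anchor] = 1.0  # exact by construction
    return StressStretchCurve(
        normalized_lambda_theta=lam_norm,
        sigma_theta=np.array([s.sigma_theta for s in states]),
        sigma_z=np.array([s.sigma_z for s in states]),
        pressure=rec.pressure.copy(),
        states=states,
    )


def _exp_model(lam: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * (np.exp(b * (lam - 1.0)) - 1.0)


def fit_exponential(
    curve: StressStretchCurve,
    direction: Literal["circumferential", "longitudinal"] = "circumferential",
    initial_guess: tuple[float, float] = (1.0, 1.0),
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> ExponentialFit:
    """Least-squares fit of sigma = a*(exp(b*(lambda-1)) - 1).

    The form passes through (1, 0), matching the zero-stress state at the
    normalized zero-pressure anchor.  Both stress components are fitted
    against the normalized circumferential stretch axis; ``direction``
    selects which stress series is used.  The fixed initial guess and
    tolerance make the fit deterministic.
    """
    lam = np.asarray(curve.normalized_lambda_theta, dtype=float)
    sigma = np.asarray(
        curve.sigma_theta if direction == "circumferential" else curve.sigma_z,
        dtype=float,
    )
    if lam.size < 3:
        raise FitError(f"need at least 3 points to fit, got {lam.size}")
    if np.ptp(lam) == 0:
        raise FitError("stretches are all identical; fit is underdetermined")

    def resid(theta: np.ndarray) -> np.ndarray:
        return _exp_model(lam, theta[0], theta[1]) - sigma

    sol = optimize.least_squares(
        resid,
        x0=np.asarray(initial_guess, dtype=float),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    if not sol.success and rmse > 1e-5 * max(1.0, float(np.ptp(sigma))):
        # near-linear data walks the a*b ~ const ridge (a -> inf, b -> 0)
        # without formally converging; a negligible residual is still a fit
        raise FitError(f"exponential fit did not converge: {sol.message}")
    return ExponentialFit(a=float(sol.x[0]), b=float(sol.x[1]), rmse=rmse)


def tangent_stiffness(fit: ExponentialFit, lam: float) -> float:
    """Analytic tangent stiffness d(sigma)/d(lambda) = a*b*exp(b*(lambda-1))."""
    return fit.a * fit.b * math.exp(fit.b * (lam - 1.0))


def stiffness_at_pressure(
    curve: StressStretchCurve, fit: ExponentialFit, P: float
) -> float:
    """Tangent stiffness evaluated at the stretch reached at pressure P (mmHg).

    The normalized stretch at P is located by linear interpolation between
    recorded points (the curve is sorted by pressure first).
    """
    order = np.argsort(curve.pressure)
    p_sorted = curve.pressure[order]
    lam_sorted = curve.normalized_lambda_theta[order]
    if P < p_sorted[0] or P > p_sorted[-1]:
        raise ExtrapolationError(
            f"P={P} mmHg outside recorded range "
            f"[{p_sorted[0]}, {p_sorted[-1]}] mmHg"
        )
    lam_at_p = float(np.interp(P, p_sorted, lam_sorted))
    return tangent_stiffness(fit, lam_at_p)


def estimate_in_vivo_stretch(
    recordings: Sequence[tuple[float, MyographRecording]],
) -> float:
    """In-vivo axial stretch by the force-invariance criterion.

    Among candidate axial stretches, returns the one whose axial-force series
    varies least (smallest variance) over the pressure ramp: at the in-vivo
    stretch the axial force stays nearly constant during inflation.  Ties are
    broken toward the smaller stretch.
    """
    if len(recordings) == 0:
        raise ValueError("no candidate stretches supplied")
    best_lam, best_var = None, None
    for lam_z, rec in sorted(recordings, key=lambda t: t[0]):
        v = float(np.var(rec.axial_force))
        if best_var is None or v < best_var:
            best_lam, best_var = lam_z, v
    return float(best_lam)
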