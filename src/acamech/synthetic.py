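"""Seeded generators for every input the analysis pipeline consumes.

No raw data ship with the package, so each stage is exercised against
synthetic inputs with known ground truth:

* inflation recordings from an explicit stiffening constitutive law, solved
  point-by-point so that thin-wall equilibrium holds exactly;
* axial-stretch sweeps in which the axial force is engineered to be invariant
  at a chosen in-vivo stretch;
* two-layer wall images (media / adventitia fiber textures at target area
  fractions) with a zero-signal gap band of known width at the interface;
* cohort tables and collagen-abundance tables drawn around specified group
  compositions.

All generators take a seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import ellipse

from .mechanics import (
    MMHG_TO_KPA,
    MyographRecording,
    ReferenceGeometry,
    deformed_inner_radius,
)

DEFAULT_PRESSURES_MMHG = tuple(range(0, 90, 10))  # 0..80 in 10 mmHg steps


@dataclass(frozen=True)
class ConstitutiveParams:
    """Forward material model for the inflation generator.

    Circumferential law: sigma_theta = a_theta * (exp(b_theta*(lt - 1)) - 1),
    zero at lt = 1.  The axial force is built directly: at the in-vivo
    stretch ``lambda_z_star`` the wall carries the pressure thrust exactly and
    the force stays constant over the ramp; away from it a thrust mismatch
    proportional to ``force_coupling * (lambda_z - lambda_z_star)`` appears,
    so force variance over the ramp is minimized at the in-vivo stretch.
    """

    a_theta: float = 5.0       # kPa
    b_theta: float = 12.0
    a_z: float = 10.0          # kPa, axial prestress scale
    b_z: float = 8.0
    force_coupling: float = 1.0   # dimensionless thrust-mismatch gain
    lambda_z_star: float = 1.12

    def __post_init__(self) -> None:
        if self.a_theta <= 0 or self.b_theta <= 0:
            raise ValueError("a_theta and b_theta must be positive")

    def sigma_theta(self, lam_theta: float) -> float:
        return self.a_theta * (math.exp(self.b_theta * (lam_theta - 1.0)) - 1.0)


def _solve_outer_radius(
    geom: ReferenceGeometry, params: ConstitutiveParams, lambda_z: float, p_kpa: float
) -> float:
    """Deformed outer radius from circumferential thin-wall equilibrium.

    Root of g(ro) = sigma_theta(lambda_theta(ro)) - P*ri/(ro - ri) with ri
    from incompressibility.  g < 0 just above the incompressibility bound
    (ri -> 0, lambda_theta < 1) and g > 0 for large ro (exponential stress
    outruns the quadratic Laplace term), so the root is bracketed.
    """
    area = geom.Ro**2 - geom.Ri**2

    def g(ro: float) -> float:
        ri = math.sqrt(ro**2 - area / lambda_z)
        lam_t = (ro + ri) / (geom.Ro + geom.Ri)
        return params.sigma_theta(lam_t) - p_kpa * ri / (ro - ri)

    lo = math.sqrt(area / lambda_z) * (1 + 1e-9)
    hi = 3.0 * geom.Ro
    while g(hi) <= 0:
        hi *= 2.0
        if hi > 100 * geom.Ro:
            raise ValueError("equilibrium root not bracketed; non-physical parameters")
    return float(brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200))


def simulate_inflation(
    geom: ReferenceGeometry,
    params: ConstitutiveParams,
    lambda_z: float,
    pressures=DEFAULT_PRESSURES_MMHG,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> MyographRecording:
    """Forward-simulate one inflation cycle at a fixed axial stretch.

    For each pressure the deformed outer radius is the equilibrium root of
    the circumferential law, and the axial force is

        fT = A_w(lz) * a_z * (exp(b_z*(lz-1)) - 1)
             + force_coupling * (lz - lz*) * P * pi * ri^2

    with A_w the (constant) deformed wall cross-section.  Gaussian noise with
    SDs ``noise_sd = (diameter mm, force mN)`` is added when requested.
    """
    pressures = np.asarray(pressures, dtype=float)
    if pressures.size == 0:
        raise ValueError("need at least one pressure")
    if not np.any(np.abs(pressures) < 1e-9):
        raise ValueError("pressure protocol must include 0 mmHg")
    rng = np.random.default_rng(seed)

    wall_area = geom.wall_area / lambda_z  # deformed cross-section, mm^2
    f_base = wall_area * params.a_z * (math.exp(params.b_z * (lambda_z - 1.0)) - 1.0)

    diam, force = [], []
    for P in pressures:
        p_kpa = P * MMHG_TO_KPA
        ro = _solve_outer_radius(geom, params, lambda_z, p_kpa)
        ri = deformed_inner_radius(ro, geom, lambda_z)
        thrust = p_kpa * math.pi * ri**2
        fT = f_base + params.force_coupling * (lambda_z - params.lambda_z_star) * thrust
        diam.append(2.0 * ro)
        force.append(fT)

    diam = np.asarray(diam) + rng.normal(0.0, noise_sd[0], size=pressures.size)
    force = np.asarray(force) + rng.normal(0.0, noise_sd[1], size=pressures.size)
    return MyographRecording(
        pressure=pressures,
        outer_diameter=diam,
        axial_force=force,
        stretched_length=lambda_z * geom.L,
        cycle_label="simulated",
    )


def simulate_stretch_sweep(
    geom: ReferenceGeometry,
    params: ConstitutiveParams,
    candidates,
    pressures=DEFAULT_PRESSURES_MMHG,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> list[tuple[float, MyographRecording]]:
    """Inflation recordings at several candidate axial stretches.

    The generator's force model is flat at ``params.lambda_z_star``, so the
    force-variance criterion has its minimum at the candidate nearest the
    engineered in-vivo stretch (ground truth for recovery tests).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate stretches supplied")
    if not (min(candidates) <= params.lambda_z_star <= max(candidates)):
        raise ValueError("lambda_z_star must lie within the candidate hull")
    rng = np.random.default_rng(seed)
    out = []
    for lz in candidates:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            (lz, simulate_inflation(geom, params, lz, pressures, noise_sd, sub_seed))
        )
    return out


@dataclass
class ImageSpec:
    """Layout and texture parameters for a synthetic two-layer wall image.

    The radial axis runs left to right: intima margin, media strip, gap band
    of ``gap_width`` um, adventitia strip.  ``media_fraction`` and
    ``adventitia_fraction`` are the target foreground area fractions of the
    binarized fiber texture in each strip.
    """

    size: tuple[int, int] = (510, 510)       # rows, cols (510 = 30 * 17 px cells)
    pixel_size: float = 425.0 / 510.0        # um per px -> 425 um field of view
    media_fraction: float = 0.318
    adventitia_fraction: float = 0.478
    gap_width: float = 30.0                  # um
    gap_position: float = 212.5              # um, media/gap boundary from left
    intima_margin: float = 42.5              # um of lumen/intima before media
    fiber_length: tuple[float, float] = (10.0, 25.0)   # px semi-axis range (vertical)
    fiber_width: tuple[float, float] = (1.0, 2.5)      # px semi-axis range (radial)
    n_planes: int = 3
    noise: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.media_fraction < 1 and 0 < self.adventitia_fraction < 1):
            raise ValueError("area fractions must lie in (0, 1)")
        fov = self.size[1] * self.pixel_size
        if self.gap_position + self.gap_width >= fov:
            raise ValueError("gap does not fit inside the field of view")


@dataclass
class WallImageTruth:
    """Ground-truth annotation accompanying a simulated wall image."""

    gap_width: float                       # um
    gap_px: tuple[int, int]                # [start, stop) columns in px
    media_px: tuple[int, int]
    adventitia_px: tuple[int, int]
    region_columns: dict[str, tuple[int, int]] = field(default_factory=dict)
    achieved_fractions: dict[str, float] = field(default_factory=dict)


def _fill_strip(
    mask: np.ndarray,
    x0: int,
    x1: int,
    target: float,
    spec: ImageSpec,
    rng: np.random.Generator,
) -> None:
    """Add elongated elliptical blobs to mask[:, x0:x1] until the strip's
    foreground fraction reaches the target.  Blobs are elongated vertically,
    parallel to the wall axis."""
    h = mask.shape[0]
    strip = mask[:, x0:x1]
    area = strip.size
    guard = 0
    while strip.sum() / area < target:
        cy = rng.uniform(0, h)
        cx = rng.uniform(x0, x1)
        ry = rng.uniform(*spec.fiber_length)   # long axis vertical
        rx = rng.uniform(*spec.fiber_width)
        rr, cc = ellipse(cy, cx, ry, rx, shape=mask.shape)
        keep = (cc >= x0) & (cc < x1)          # clip to the strip
        mask[rr[keep], cc[keep]] = True
        guard += 1
        if guard > 200_000:
            raise RuntimeError("fiber fill did not reach target fraction")


def simulate_wall_image(spec: ImageSpec) -> tuple[np.ndarray, WallImageTruth]:
    """Render a z-stack of a two-layer wall with a known gap band.

    Returns the stack (n_planes, H, W), float in [0, 1], and a ground-truth
    annotation with pixel and 30-grid-column extents of each region and the
    achieved binary area fractions.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    px = spec.pixel_size

    x_media0 = int(round(spec.intima_margin / px))
    x_gap0 = int(round(spec.gap_position / px))
    x_gap1 = x_gap0 + int(round(spec.gap_width / px))
    if not (0 <= x_media0 < x_gap0 <= x_gap1 < w):
        raise ValueError("inconsistent strip layout; check gap position/width")

    mask = np.zeros((h, w), dtype=bool)
    _fill_strip(mask, x_media0, x_gap0, spec.media_fraction, spec, rng)
    _fill_strip(mask, x_gap1, w, spec.adventitia_fraction, spec, rng)
    mask[:, x_gap0:x_gap1] = False  # zero-signal band

    # distribute foreground over planes; max projection recovers the union
    stack = np.abs(rng.normal(0.0, spec.noise, size=(spec.n_planes, h, w)))
    np.clip(stack, 0.0, 0.3, out=stack)
    ys, xs = np.nonzero(mask)
    plane = rng.integers(0, spec.n_planes, size=ys.size)
    intensity = rng.uniform(0.65, 1.0, size=ys.size)
    stack[plane, ys, xs] = intensity

    col_w = w / 30  # grid columns over the full-image ROI
    def cols_inside(a: int, b: int) -> tuple[int, int]:
        lo = math.ceil(a / col_w)
        hi = math.floor(b / col_w) - 1
        return lo, hi

    truth = WallImageTruth(
        gap_width=(x_gap1 - x_gap0) * px,
        gap_px=(x_gap0, x_gap1),
        media_px=(x_media0, x_gap0),
        adventitia_px=(x_gap1, w),
        region_columns={
            "media": cols_inside(x_media0, x_gap0),
            "adventitia": cols_inside(x_gap1, w),
        },
        achieved_fractions={
            "media": float(mask[:, x_media0:x_gap0].mean()),
            "adventitia": float(mask[:, x_gap1:w].mean()),
        },
    )
    return stack, truth


#: Group-level generating parameters used by default for synthetic cohorts:
#: (n donors, age mean/SD yr, thickness mean/SD mm, inner mean/SD mm,
#: outer mean/SD mm).
DEFAULT_COHORT_SPECS = {
    "control": dict(n=8, age=(71.5, 9.8), thickness=(0.31, 0.03),
                    inner=(1.98, 0.20), outer=(2.60, 0.22)),
    "early": dict(n=6, age=(69.8, 8.2), thickness=(0.27, 0.05),
                  inner=(1.80, 0.22), outer=(2.34, 0.30)),
    "intermediate": dict(n=4, age=(75.0, 5.3), thickness=(0.30, 0.06),
                         inner=(1.80, 0.24), outer=(2.41, 0.34)),
    "advanced": dict(n=10, age=(73.0, 12.6), thickness=(0.29, 0.05),
                     inner=(1.87, 0.15), outer=(2.44, 0.22)),
}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws resampled until strictly positive (dimensions, ages)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal resampling failed; check mean/SD")


def simulate_cohort(group_specs=None, seed: int | None = None) -> pd.DataFrame:
    """Synthetic per-segment cohort table (one segment per simulated donor)."""
    specs = group_specs or DEFAULT_COHORT_SPECS
    rng = np.random.default_rng(seed)
    rows = []
    for grp, gs in specs.items():
        n = gs["n"]
        if n < 1:
            raise ValueError(f"group {grp!r} needs n >= 1")
        ages = _trunc_normal(rng, *gs["age"], n)
        thick = _trunc_normal(rng, *gs["thickness"], n)
        inner = _trunc_normal(rng, *gs["inner"], n)
        outer = _trunc_normal(rng, *gs["outer"], n)
        sexes = rng.choice(["M", "F"], size=n)
        for i in range(n):
            rows.append(
                (grp, f"{grp[:1].upper()}{i + 1}", float(ages[i]), sexes[i], "-",
                 float(thick[i]), float(inner[i]), float(outer[i]))
            )
    return pd.DataFrame(
        rows,
        columns=["group", "donor_id", "age", "sex", "braak_stage",
                 "thickness_mm", "inner_diameter_mm", "outer_diameter_mm"],
    )


def simulate_abundances(
    n_per_group: dict[str, int],
    baseline_composition: dict[str, float],
    group_shifts: dict[str, dict[str, float]] | None = None,
    dispersion: float = 0.2,
    total_abundance: float = 1e6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample collagen abundance table around a known composition.

    ``baseline_composition`` maps collagen type to percentage (sums to 100);
    ``group_shifts`` adds percentage points per group and type, renormalized.
    Abundances are lognormal with median composition * total: with
    ``dispersion`` 0 every sample's percentages equal its group composition
    exactly.
    """
    types = list(baseline_composition)
    base = np.array([baseline_composition[t] for t in types], dtype=float)
    if abs(base.sum() - 100.0) > 1e-6:
        raise ValueError(f"baseline composition sums to {base.sum()}, expected 100")
    if (base < 0).any():
        raise ValueError("composition percentages must be non-negative")
    rng = np.random.default_rng(seed)
    shifts = group_shifts or {}
    rows = []
    for grp, n in n_per_group.items():
        comp = base.copy()
        for t, dv in shifts.get(grp, {}).items():
            comp[types.index(t)] += dv
        if (comp < 0).any():
            raise ValueError(f"shifted composition negative in group {grp!r}")
        comp = 100.0 * comp / comp.sum()
        for i in range(n):
            noise = np.exp(rng.normal(0.0, dispersion, size=len(types)))
            ab = total_abundance * comp / 100.0 * noise
            rows.append({"group": grp, "sample_id": f"{grp}-{i + 1}",
                         **dict(zip(types, ab))})
    return pd.DataFrame(rows)
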