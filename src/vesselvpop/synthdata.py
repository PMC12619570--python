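"""Synthetic stand-in cohorts for the real artery populations.

No patient centerlines ship with this package, so every downstream stage is
exercised on synthetic populations that emulate the statistical structure of
the reference cohorts:

* ``BA_like`` — gently curved single arcs, ~3.1 cm long, ~1.65 mm radius,
  31-100 acquisition points per artery;
* ``ICA_like`` — S-shaped double-bend ("siphon") curves, ~8 cm long, ~2.7 mm
  radius, 101-151 points, with an undulating ("beaded") radius profile.

Each family has a fixed template course, built by integrating a smooth
curvature profile (a broad arc for BA_like; two opposite-signed bend lobes
smoothly joined for ICA_like) plus a mild out-of-plane bow.  An individual
artery is the template rescaled to a per-artery random length, bent by
modest random variations of the curvature-profile parameters, displaced by a
smooth low-order random deviation field of a few millimetres, and jittered
point-wise.  The bounded deviation field mirrors the structure of
atlas-registered vasculature, where each arterial segment stays in close
proximity to its location in other subjects; unbounded accumulation of
random heading would produce inter-subject scatter no registered cohort
shows.  Curves are parametric composites, not registered anatomy: the target
is the population statistics (length, radius, point-count distributions,
beading, S-bend, bounded coordinate scatter), not anatomical realism.

Defaults come from the reference cohort summary statistics; lengths/diameters
are Normal per artery, point counts rounded truncated-Normal within the
observed min/max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


import numpy as np

from .errors import ParameterError
from .io import Centerline

FAMILIES = ("BA_like", "ICA_like")

# Internal bend geometry per family (unit-length curve, radians / relative units).
# Means define the family template; SDs are modest per-artery bend variability.
_BEND_PARAMS = {
    "BA_like": dict(
        theta_mean=0.9, theta_sd=0.25,         # total turning angle of the arc
        bow_mean=0.05,                         # out-of-plane bow amplitude
    ),
    "ICA_like": dict(
        theta1_mean=2.8, theta1_sd=0.3,        # proximal siphon bend
        theta2_mean=2.2, theta2_sd=0.25,       # distal counter-bend
        center1_mean=0.58, center1_sd=0.015,   # bend positions along the curve
        center_gap_mean=0.20, center_gap_sd=0.012,
        width_mean=0.06, width_sd=0.008,       # bend lobe widths
        base_theta_mean=0.5, base_theta_sd=0.12,  # gentle whole-course curvature
        bow_mean=0.04,
    ),
}
# Smooth low-order deviation field around the template (mm): per coordinate,
# sum_j a_j cos(j*pi*s) with a_j ~ N(0, scatter * _DEV_WEIGHTS[j]).  Amplitudes
# emulate the few-mm inter-subject scatter of atlas-registered arteries.
_DEV_WEIGHTS = (0.4, 1.0, 0.6, 0.35, 0.2)
_DEV_SCATTER_MM = {"BA_like": 2.0, "ICA_like": 2.5}
_POSE_ANGLE_SD_RAD = 0.02  # residual whole-curve rotation after registration
# Fine-scale tortuosity: narrowband smooth wiggles (modes j in the range below,
# wavelength 2L/j) whose aggregate curvature has the rms below.  Real centerlines
# carry structured few-mm-wavelength undulation that only dense landmarking
# resolves; the rms stays within the inscribed-sphere bound (kappa <~ 1/radius).
_FINE_MODES = (10, 36)
_FINE_KAPPA_RMS = {"BA_like": 0.20, "ICA_like": 0.15}  # 1/mm


@dataclass
class SyntheticFamilySpec:
    """Parameters of one synthetic artery family.

    All lengths in mm; ``bead_amplitude`` is the relative radius modulation and
    ``bead_frequency`` the number of undulation cycles per curve;
    ``curvature_scale`` multiplies the family's bend turning angles;
    ``noise_sd_mm`` is the per-point jitter applied to positions and radii.
    """

    family: str
    n: int
    seed: int = 0
    length_mean_mm: float = 0.0
    length_sd_mm: float = 0.0
    radius_mean_mm: float = 0.0
    radius_sd_mm: float = 0.0
    bead_amplitude: float = 0.08
    bead_frequency: float = 6.0
    point_count_mean: float = 0.0
    point_count_sd: float = 0.0
    point_count_min: int = 4
    point_count_max: int = 10_000
    curvature_scale: float = 1.0
    # Positional jitter is bounded by curvature consistency: discrete curvature
    # scales like ~4*sigma/spacing^3, and a tube of radius r cannot bend tighter
    # than 1/r, so sub-voxel centroid precision (~0.015 mm) is the realistic level.
    noise_sd_mm: float = 0.015

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n < 0:
            raise ParameterError("population size must be >= 0")
        for name in ("length_sd_mm", "radius_sd_mm", "point_count_sd", "noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.bead_amplitude < 1:
            raise ParameterError("bead_amplitude must lie in [0, 1)")
        if self.point_count_min < 4:
            raise ParameterError("point_count_min must be >= 4")
        if self.point_count_max < self.point_count_min:
            raise ParameterError("point_count_max < point_count_min")


def default_spec(family: str, n: int | None = None, seed: int = 0) -> SyntheticFamilySpec:
    """Cohort defaults per family, from the reference summary statistics.

    BA_like: length 31.3 +/- 8.3 mm, radius 1.665 +/- 0.3375 mm (diameter
    3.33 +/- 0.675), 53.4 +/- 12.9 points in [31, 100], cohort size 46.
    ICA_like: length 79.2 +/- 7.2 mm, radius 2.71 +/- 0.51 mm (diameter
    5.42 +/- 1.02), 123.6 +/- 12.9 points in [101, 151], cohort size 17.
    """
    if family == "BA_like":
        return SyntheticFamilySpec(
            family=family, n=46 if n is None else n, seed=seed,
            length_mean_mm=31.3, length_sd_mm=8.3,
            radius_mean_mm=3.33 / 2, radius_sd_mm=0.675 / 2,
            bead_amplitude=0.08, bead_frequency=5.0,
            point_count_mean=53.4, point_count_sd=12.9,
            point_count_min=31, point_count_max=100,
        )
    if family == "ICA_like":
        return SyntheticFamilySpec(
            family=family, n=17 if n is None else n, seed=seed,
            length_mean_mm=79.2, length_sd_mm=7.2,
            radius_mean_mm=5.42 / 2, radius_sd_mm=1.02 / 2,
            bead_amplitude=0.08, bead_frequency=8.0,
            point_count_mean=123.6, point_count_sd=12.9,
            point_count_min=101, point_count_max=151,
        )
    raise ParameterError(f"unknown family {family!r}; choose from {FAMILIES}")


def _gauss_bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian curvature lobe normalized to unit integral over s."""
    g = np.exp(-0.5 * ((s - center) / width) ** 2)
    return g / (width * math.sqrt(2.0 * math.pi))


def _integrate_planar(s: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Integrate a planar curvature profile into (x, z) positions (unit speed)."""
    ds = np.diff(s)
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1]) * ds)])
    x = np.concatenate([[0.0], np.cumsum(0.5 * (np.cos(theta[1:]) + np.cos(theta[:-1])) * ds)])
    z = np.concatenate([[0.0], np.cumsum(0.5 * (np.sin(theta[1:]) + np.sin(theta[:-1])) * ds)])
    return np.column_stack([x, z])


def _unit_curve(spec: SyntheticFamilySpec, rng: np.random.Generator,
                n_pts: int) -> np.ndarray:
    """One unit-length 3D curve: the family template with modest bend variation."""
    s = np.linspace(0.0, 1.0, n_pts)
    p = _BEND_PARAMS[spec.family]
    cs = spec.curvature_scale
    if spec.family == "BA_like":
        theta = abs(rng.normal(p["theta_mean"], p["theta_sd"])) * cs
        kappa = np.full_like(s, theta)  # constant-curvature arc
    else:
        theta1 = max(rng.normal(p["theta1_mean"], p["theta1_sd"]), 0.5) * cs
        theta2 = max(rng.normal(p["theta2_mean"], p["theta2_sd"]), 0.4) * cs
        c1 = rng.normal(p["center1_mean"], p["center1_sd"])
        c2 = c1 + max(rng.normal(p["center_gap_mean"], p["center_gap_sd"]), 0.08)
        w1 = max(rng.normal(p["width_mean"], p["width_sd"]), 0.03)
        w2 = max(rng.normal(p["width_mean"], p["width_sd"]), 0.03)
        base = rng.normal(p["base_theta_mean"], p["base_theta_sd"]) * cs
        kappa = (theta1 * _gauss_bump(s, c1, w1)
                 - theta2 * _gauss_bump(s, c2, w2)
                 + base)
    xz = _integrate_planar(s, kappa)
    y = p["bow_mean"] * np.sin(math.pi * s + 1.0)
    return np.column_stack([xz[:, 0], y, xz[:, 1]])


def _deviation_field(spec: SyntheticFamilySpec, rng: np.random.Generator,
                     s: np.ndarray) -> np.ndarray:
    """Smooth random displacement (mm) bounded along the whole course."""
    scatter = _DEV_SCATTER_MM[spec.family]
    basis = np.stack([np.cos(j * math.pi * s) for j in range(len(_DEV_WEIGHTS))])
    amps = rng.normal(0.0, scatter, size=(3, len(_DEV_WEIGHTS))) * np.asarray(_DEV_WEIGHTS)
    return (amps @ basis).T


def _fine_tortuosity(spec: SyntheticFamilySpec, rng: np.random.Generator,
                     s: np.ndarray, length: float) -> np.ndarray:
    """Smooth narrowband wiggle field (mm) with calibrated curvature content.

    Mode j has wavelength 2*length/j; its amplitude is chosen so the aggregate
    curvature perturbation has rms ~_FINE_KAPPA_RMS, splitting the budget
    evenly across modes (curvature of mode j scales as amplitude*(j*pi/L)^2).
    """
    j_lo, j_hi = _FINE_MODES
    j = np.arange(j_lo, j_hi + 1)
    sigma = (_FINE_KAPPA_RMS[spec.family]
             * (length / (j * math.pi)) ** 2 / math.sqrt(j.size))
    amps = rng.normal(0.0, 1.0, size=(3, j.size)) * sigma
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(3, j.size))
    basis = np.cos(np.einsum("j,n->jn", j * math.pi, s)[None, :, :]
                   + phases[:, :, None])
    return np.einsum("cj,cjn->nc", amps, basis)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Small random rotation matrix (axis uniform, angle ~ N(0, pose SD))."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, _POSE_ANGLE_SD_RAD)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _one_artery(spec: SyntheticFamilySpec, rng: np.random.Generator,
                index: int) -> Centerline:
    # point count: rounded truncated Normal within the observed bounds
    while True:
        n_pts = int(round(rng.normal(spec.point_count_mean, spec.point_count_sd)))
        if spec.point_count_min <= n_pts <= spec.point_count_max:
            break
    length = max(rng.normal(spec.length_mean_mm, spec.length_sd_mm),
                 0.2 * spec.length_mean_mm)
    pts = _unit_curve(spec, rng, n_pts)
    cur_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    pts = pts * (length / cur_len)
    s = np.linspace(0.0, 1.0, n_pts)
    pts = pts @ _random_rotation(rng).T
    pts = pts + _deviation_field(spec, rng, s)
    pts = pts + _fine_tortuosity(spec, rng, s, length)
    pts = pts + rng.normal(0.0, spec.noise_sd_mm, size=pts.shape)
    # renormalize so the polyline length matches the drawn length exactly
    # (deviations and jitter otherwise perturb the length marginal)
    cur_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    pts = pts * (length / cur_len)

    s = np.linspace(0.0, 1.0, n_pts)
    r_base = max(rng.normal(spec.radius_mean_mm, spec.radius_sd_mm),
                 0.2 * spec.radius_mean_mm)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    radii = r_base * (1.0 + spec.bead_amplitude
                      * np.sin(2.0 * math.pi * spec.bead_frequency * s + phase))
    radii = np.maximum(radii + rng.normal(0.0, spec.noise_sd_mm, size=n_pts),
                       0.05 * r_base)
    label = "BA" if spec.family == "BA_like" else "ICA"
    return Centerline(points=pts, radii=radii, label=label,
                      id=f"{spec.family}_{index:03d}")


def synth_population(spec: SyntheticFamilySpec) -> list[Centerline]:
    """Draw ``spec.n`` independent synthetic arteries; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    return [_one_artery(spec, rng, i) for i in range(spec.n)]


def spec_to_dict(spec: SyntheticFamilySpec) -> dict:
    """Plain-dict form for YAML serialization."""
    return asdict(spec)


def spec_from_dict(d: dict) -> SyntheticFamilySpec:
    return SyntheticFamilySpec(**d)
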