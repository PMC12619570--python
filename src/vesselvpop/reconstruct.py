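"""B-spline reconstruction of a centerline from a landmark set.

Both observed and model-sampled landmark sets are turned back into dense
centerlines by a clamped quadratic B-spline over all four channels
(x, y, z, r), parameterized by chord length and evaluated at ``m`` parameter
values equally spaced in the spline parameter.  The default mode interpolates
the landmarks; a smoothing mode (penalized least squares with the endpoints
pinned) is available for noisy inputs.

The per-label default output counts match the average acquisition point
counts of the reference cohorts: 124 (L_ICA), 127 (R_ICA), 53 (BA), so that
real and virtual curves are compared at identical sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline

from .errors import ParameterError
from .io import Centerline
from .landmarks import LandmarkSet

#: Reconstruction point counts per artery label (cohort-average acquisition counts).
DEFAULT_RECON_POINTS = {"BA": 53, "L_ICA": 124, "R_ICA": 127, "ICA": 124}


@dataclass
class ReconstructionConfig:
    """Spline settings: degree (default quadratic), output count m, mode."""

    degree: int = 2
    m: int = 100
    mode: str = "interpolating"  # or "smoothing"
    smoothing_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ParameterError(f"spline degree must be >= 1, got {self.degree}")
        if self.m < self.degree + 1:
            raise ParameterError(
                f"output point count m={self.m} must be >= degree + 1 = {self.degree + 1}"
            )
        if self.mode not in ("interpolating", "smoothing"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.smoothing_weight < 0:
            raise ParameterError("smoothing_weight must be >= 0")


def config_for_label(label: str, **overrides) -> ReconstructionConfig:
    """Default config with ``m`` chosen by artery label (fallback 100)."""
    m = DEFAULT_RECON_POINTS.get(label, 100)
    kwargs = {"m": m}
    kwargs.update(overrides)
    return ReconstructionConfig(**kwargs)


def _chord_parameter(positions: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ParameterError("coincident consecutive landmarks; chord parameter not strictly increasing")
    return np.concatenate([[0.0], np.cumsum(seg)])


def _smoothing_coefficients(
    u: np.ndarray, t: np.ndarray, y: np.ndarray, degree: int, lam: float
) -> np.ndarray:
    """Penalized LSQ spline coefficients with first/last coefficient pinned.

    Minimizes ``|B c - y|^2 + lam |D2 c|^2`` subject to ``c_0 = y_0`` and
    ``c_-1 = y_-1`` (with a clamped knot vector these equal the end values, so
    the reconstruction keeps the landmark endpoints exactly).
    """
    B = BSpline.design_matrix(u, t, degree).toarray()
    n_c = B.shape[1]
    D2 = np.diff(np.eye(n_c), n=2, axis=0)
    A = np.vstack([B, np.sqrt(lam) * D2])
    rhs = np.vstack([y, np.zeros((D2.shape[0], y.shape[1]))])
    fixed = np.array([0, n_c - 1])
    free = np.arange(1, n_c - 1)
    c_fixed = y[[0, -1], :]
    rhs_free = rhs - A[:, fixed] @ c_fixed
    c_free, *_ = np.linalg.lstsq(A[:, free], rhs_free, rcond=None)
    c = np.empty((n_c, y.shape[1]))
    c[0], c[-1] = c_fixed
    c[free] = c_free
    return c


def bspline_curve(l: LandmarkSet, cfg: ReconstructionConfig) -> Centerline:
    """Reconstruct a dense centerline from ``l`` with a clamped B-spline.

    All four channels are splined together against the chord-length parameter
    of the landmark positions and evaluated at ``cfg.m`` equally spaced
    parameter values; the first and last output points equal the first and
    last landmarks.
    """
    if l.k < cfg.degree + 1:
        raise ParameterError(
            f"need at least degree + 1 = {cfg.degree + 1} landmarks, got k={l.k}"
        )
    data = l.landmarks
    u = _chord_parameter(data[:, :3])
    grid = np.linspace(u[0], u[-1], cfg.m)
    if cfg.mode == "interpolating":
        spl = make_interp_spline(u, data, k=cfg.degree)
        out = spl(grid)
    else:
        t = make_interp_spline(u, data, k=cfg.degree).t
        c = _smoothing_coefficients(u, t, data, cfg.degree, cfg.smoothing_weight)
        out = BSpline(t, c, cfg.degree)(grid)
    out[0] = data[0]
    out[-1] = data[-1]
    return Centerline(points=out[:, :3], radii=out[:, 3], label=l.label, id=l.id,
                      sampled=l.sampled)
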