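"""Discrete differential-geometry features of a vessel centerline.

All features follow the finite-difference Frenet-Serret approximation on the
ordered point sequence v_1..v_n:

* velocity      ``V_i = v_{i+1} - v_i``            (i = 1..n-1)
* acceleration  ``A_i = V_{i+1} - V_i``            (i = 1..n-2)
* local curvature ``kappa_i = |V_i x A_i| / |V_i|^3`` (1/mm, interior points only)
* length        ``sum_i |V_i|``                    (mm)
* distance metric ``DM = length / |v_n - v_1|``    (dimensionless tortuosity, >= 1)
* maximum local curvature ``max_i kappa_i``

Features are intended to be computed on the reconstructed dense curve, not on
the sparse landmark set, so that real and virtual arteries are measured at
identical sampling.  No endpoint padding is applied: kappa exists only at the
n-2 interior points, exactly as the finite differences dictate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .io import Centerline

logger = logging.getLogger(__name__)


@dataclass
class GeometricFeatures:
    """Per-artery scalar features plus the full local-curvature profile."""

    length_mm: float
    dm: float
    max_curvature_per_mm: float
    curvature_profile: np.ndarray
    id: str = ""
    label: str = ""


def _check_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ParameterError(f"points must be (n, 3), got {points.shape}")
    if points.shape[0] < 3:
        raise DegenerateInputError(
            f"curvature needs at least 3 points, got {points.shape[0]}"
        )
    return points


def curvature_profile(points: np.ndarray) -> np.ndarray:
    """Local curvature kappa_i = |V_i x A_i| / |V_i|^3 at the n-2 interior points."""
    points = _check_points(points)
    V = np.diff(points, axis=0)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateInputError(
            "duplicate consecutive points: |V_i| = 0 makes curvature undefined"
        )
    A = np.diff(V, axis=0)
    cross = np.cross(V[:-1], A)
    return np.linalg.norm(cross, axis=1) / norms[:-1] ** 3


def compute_features(
    points: np.ndarray, id: str = "", label: str = ""
) -> GeometricFeatures:
    """Length, distance metric and maximum local curvature of a polyline."""
    kappa = curvature_profile(points)
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    length = float(seg.sum())
    chord = float(np.linalg.norm(points[-1] - points[0]))
    if chord == 0.0:
        raise DegenerateInputError(
            "coincident endpoints: distance metric undefined (zero chord)"
        )
    return GeometricFeatures(
        length_mm=length,
        dm=length / chord,
        max_curvature_per_mm=float(kappa.max()),
        curvature_profile=kappa,
        id=id,
        label=label,
    )


def features_of(c: Centerline) -> GeometricFeatures:
    """Convenience wrapper: features of a centerline's point sequence."""
    return compute_features(c.points, id=c.id, label=c.label)


def mean_diameter(c: Centerline) -> float:
    """Mean inner diameter (mm) = 2 x arithmetic mean of the radius profile."""
    if np.any(c.radii < 0):
        logger.warning(
            "centerline %s: negative sampled radius enters the mean diameter", c.id
        )
    return float(2.0 * c.radii.mean())


def feature_table(features: Iterable[GeometricFeatures]) -> pd.DataFrame:
    """Tabulate scalar features, one artery per row."""
    rows = [
        {
            "id": f.id,
            "label": f.label,
            "length_mm": f.length_mm,
            "dm": f.dm,
            "max_curvature_per_mm": f.max_curvature_per_mm,
        }
        for f in features
    ]
    return pd.DataFrame(rows, columns=["id", "label", "length_mm", "dm",
                                       "max_curvature_per_mm"])
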