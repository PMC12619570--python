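"""Equal-arc-length landmarking and the shape-vector representation.

A centerline with an arbitrary number of acquisition points is resampled to
``k`` landmarks placed at equal arc-length intervals along the piecewise-linear
polyline, both endpoints included.  A landmark set maps to the ``4k`` shape
vector ``p = [x1..xk, y1..yk, z1..zk, r1..rk]``, and a population of such
vectors stacks into the N x 4k matrix that the Gaussian model is fitted to.

Equal arc length (rather than an equal index stride) makes the landmark
geometry independent of acquisition density, which varies per artery.  The
radius channel is interpolated linearly in arc length together with position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import Centerline

#: Landmark counts used for the reference visualisations/sweeps per label.
DEFAULT_LANDMARKS = {"BA": 30, "L_ICA": 60, "R_ICA": 60, "ICA": 60}


@dataclass
class LandmarkSet:
    """``k`` landmarks (x, y, z, r) in mm describing one artery.

    ``landmarks`` has shape ``(k, 4)``.  Sets produced by
    :func:`resample_equal_arclength` are equally spaced in arc length and share
    endpoints with their source; sets reconstructed from sampled shape vectors
    need not satisfy either property and carry ``sampled=True``.
    """

    landmarks: np.ndarray
    label: str = ""
    id: str = ""
    sampled: bool = False

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 4:
            raise ParameterError(f"landmarks must be (k, 4), got {self.landmarks.shape}")
        if self.landmarks.shape[0] < 2:
            raise ParameterError("a landmark set needs k >= 2")
        if not np.isfinite(self.landmarks).all():
            raise ParameterError(f"landmark set {self.id!r}: non-finite value")

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.landmarks[:, :3]

    @property
    def radii(self) -> np.ndarray:
        return self.landmarks[:, 3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return (
            np.array_equal(self.landmarks, other.landmarks)
            and self.label == other.label
            and self.id == other.id
        )


@dataclass
class ShapeVector:
    """The 4k-element vector [x-block, y-block, z-block, r-block] of one artery."""

    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4 * self.k,):
            raise ParameterError(
                f"shape vector length {self.values.shape} != 4k = {4 * self.k}"
            )


@dataclass
class PopulationMatrix:
    """N stacked shape vectors with a common landmark count k."""

    matrix: np.ndarray  # (N, 4k)
    k: int
    ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 * self.k:
            raise ParameterError(
                f"population matrix must be (N, {4 * self.k}), got {self.matrix.shape}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_equal_arclength(c: Centerline, k: int) -> LandmarkSet:
    """Place ``k`` landmarks at equal arc-length stations along ``c``.

    Landmark ``j`` (0-based) sits at cumulative arc length ``j * L / (k - 1)``
    with ``L`` the total polyline length; all four channels are interpolated
    linearly in arc length, and the two end landmarks coincide exactly with
    the source endpoints.
    """
    if k < 2:
        raise ParameterError(f"landmark count k must be >= 2, got {k}")
    s = arc_lengths(c.points)
    targets = np.linspace(0.0, s[-1], k)
    lm = np.empty((k, 4))
    for j in range(3):
        lm[:, j] = np.interp(targets, s, c.points[:, j])
    lm[:, 3] = np.interp(targets, s, c.radii)
    lm[0, :3], lm[0, 3] = c.points[0], c.radii[0]
    lm[-1, :3], lm[-1, 3] = c.points[-1], c.radii[-1]
    return LandmarkSet(landmarks=lm, label=c.label, id=c.id, sampled=c.sampled)


def to_shape_vector(l: LandmarkSet) -> ShapeVector:
    """Flatten a landmark set into [x1..xk, y1..yk, z1..zk, r1..rk]."""
    return ShapeVector(values=l.landmarks.T.reshape(-1).copy(), k=l.k)


def from_shape_vector(
    p: ShapeVector | np.ndarray,
    label: str = "",
    id: str = "",
    sampled: bool = False,
) -> LandmarkSet:
    """Inverse of :func:`to_shape_vector`; accepts a raw 4k vector too."""
    values = p.values if isinstance(p, ShapeVector) else np.asarray(p, dtype=float)
    if values.ndim != 1 or values.size % 4 != 0:
        raise ParameterError(f"shape vector length {values.size} is not divisible by 4")
    k = values.size // 4
    if k < 2:
        raise ParameterError(f"shape vector implies k = {k}; need k >= 2")
    return LandmarkSet(landmarks=values.reshape(4, k).T.copy(), label=label, id=id,
                       sampled=sampled)


def build_population(ls: Sequence[LandmarkSet]) -> PopulationMatrix:
    """Stack landmark sets (common k) into the N x 4k population matrix."""
    if len(ls) == 0:
        raise ParameterError("cannot build a population from an empty list")
    k = ls[0].k
    mismatched = [l.id for l in ls if l.k != k]
    if mismatched:
        raise ParameterError(
            f"mixed landmark counts: expected k={k}, offenders {mismatched}"
        )
    rows = np.stack([to_shape_vector(l).values for l in ls])
    return PopulationMatrix(matrix=rows, k=k, ids=[l.id for l in ls],
                            labels=[l.label for l in ls])
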