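"""Histogram comparison of feature distributions between two populations.

The two samples of a feature (real and virtual) are binned into relative-
frequency histograms on a shared range spanning the pooled minimum/maximum,
with 30 equal-width bins by default, and compared by a discrete
Kullback-Leibler divergence evaluated bin-wise in nats:

    KL = sum_i f_v(i) * log( f_v(i) / f_r(i) )

i.e. the virtual histogram carries the weights and appears in the numerator
of the log ratio.  (This follows the reference formulation verbatim; the
conventional orientation, weighted by the real histogram, is available via
``orientation="conventional"``.)  Empty bins are handled by adding a small
``epsilon`` to every bin of both histograms before renormalizing; the epsilon
used is always reported alongside the value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import GeometricFeatures

logger = logging.getLogger(__name__)

DEFAULT_BINS = 30
DEFAULT_EPSILON = 1e-6


@dataclass
class RelFreqHistogram:
    """Relative-frequency histogram: I+1 increasing edges, I frequencies summing to 1."""

    bin_edges: np.ndarray
    rel_freq: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rel_freq = np.asarray(self.rel_freq, dtype=float)
        if self.rel_freq.size != self.bin_edges.size - 1:
            raise ParameterError("edges/frequency size mismatch")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(self.rel_freq < 0):
            raise ParameterError("negative relative frequency")
        if abs(self.rel_freq.sum() - 1.0) > 1e-9:
            raise ParameterError(f"relative frequencies sum to {self.rel_freq.sum()}, not 1")

    @property
    def bins(self) -> int:
        return self.rel_freq.size


@dataclass
class KLResult:
    """A KL divergence value (nats) with the regularization that produced it."""

    value: float
    epsilon: float
    bins: int


def relative_histograms(
    xs_real: Sequence[float],
    xs_virtual: Sequence[float],
    bins: int = DEFAULT_BINS,
) -> tuple[RelFreqHistogram, RelFreqHistogram]:
    """Histogram both samples on shared equal-width bins over the pooled range.

    The rightmost bin is closed, so the pooled maximum is counted.  A pooled
    range of zero width (all values identical) degenerates to a single unit
    bin around the common value, with a warning.
    """
    xs_real = np.asarray(xs_real, dtype=float)
    xs_virtual = np.asarray(xs_virtual, dtype=float)
    if xs_real.size == 0 or xs_virtual.size == 0:
        raise ParameterError("cannot histogram an empty sample")
    pooled = np.concatenate([xs_real, xs_virtual])
    lo, hi = float(pooled.min()), float(pooled.max())
    edges = np.linspace(lo, hi, bins + 1)
    if lo == hi or np.any(np.diff(edges) <= 0):
        # zero (or sub-resolution) pooled range: a single unit-width bin
        logger.warning("degenerate pooled range at %g; using a single unit-width bin", lo)
        edges = np.array([lo - 0.5, hi + 0.5])
    f_r, _ = np.histogram(xs_real, bins=edges)
    f_v, _ = np.histogram(xs_virtual, bins=edges)
    return (
        RelFreqHistogram(bin_edges=edges, rel_freq=f_r / xs_real.size),
        RelFreqHistogram(bin_edges=edges, rel_freq=f_v / xs_virtual.size),
    )


def kl_divergence(
    f_real: RelFreqHistogram,
    f_virtual: RelFreqHistogram,
    epsilon: float = DEFAULT_EPSILON,
    orientation: str = "as_printed",
) -> KLResult:
    """Bin-wise KL divergence between two histograms on identical edges.

    ``epsilon`` is added to every bin of both histograms (pre-normalization
    absolute value) and each is renormalized before the sum is taken; with
    ``epsilon=0`` a zero reference bin opposite a populated bin yields
    ``inf`` with a warning.  ``orientation='as_printed'`` weights by the
    virtual histogram; ``'conventional'`` weights by the real one.
    """
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    if f_real.bin_edges.shape != f_virtual.bin_edges.shape or not np.allclose(
        f_real.bin_edges, f_virtual.bin_edges, rtol=0, atol=0
    ):
        raise ParameterError("histograms must share identical bin edges")
    if orientation not in ("as_printed", "conventional"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    r = f_real.rel_freq + epsilon
    v = f_virtual.rel_freq + epsilon
    r = r / r.sum()
    v = v / v.sum()
    if orientation == "as_printed":
        w, ref = v, r
    else:
        w, ref = r, v
    active = w > 0
    if np.any(ref[active] == 0):
        logger.warning("zero reference bin with nonzero weight and epsilon=0: KL = inf")
        value = math.inf
    else:
        value = float(np.sum(w[active] * np.log(w[active] / ref[active])))
    return KLResult(value=value, epsilon=epsilon, bins=f_real.bins)


@dataclass
class PopulationSummary:
    """Mean +/- sample SD of the scalar features of one population."""

    n: int
    length_cm_mean: float
    length_cm_sd: float
    dm_mean: float
    dm_sd: float
    max_curvature_mean: float
    max_curvature_sd: float
    diameter_mm_mean: float
    diameter_mm_sd: float
    degenerate_sd: bool = False  # single-artery population: SDs reported as 0


def population_summary(
    features: Sequence[GeometricFeatures], diameters: Sequence[float]
) -> PopulationSummary:
    """Mean and sample SD (N-1) of length (cm), DM, max curvature, diameter (mm)."""
    if len(features) == 0 or len(diameters) == 0:
        raise ParameterError("cannot summarize an empty population")
    if len(features) != len(diameters):
        raise ParameterError("features and diameters must align")
    lengths_cm = np.array([f.length_mm for f in features]) / 10.0
    dms = np.array([f.dm for f in features])
    kmax = np.array([f.max_curvature_per_mm for f in features])
    dia = np.asarray(diameters, dtype=float)
    n = len(features)
    degenerate = n < 2

    def sd(x: np.ndarray) -> float:
        return 0.0 if degenerate else float(np.std(x, ddof=1))

    return PopulationSummary(
        n=n,
        length_cm_mean=float(lengths_cm.mean()),
        length_cm_sd=sd(lengths_cm),
        dm_mean=float(dms.mean()),
        dm_sd=sd(dms),
        max_curvature_mean=float(kmax.mean()),
        max_curvature_sd=sd(kmax),
        diameter_mm_mean=float(dia.mean()),
        diameter_mm_sd=sd(dia),
        degenerate_sd=degenerate,
    )


def comparison_report(
    kl_by_feature: dict[str, KLResult], n_real: int, n_virtual: int
) -> pd.DataFrame:
    """Tabular comparison report (feature, kl, epsilon, bins, n_real, n_virtual)."""
    rows = [
        {
            "feature": name,
            "kl": res.value,
            "epsilon": res.epsilon,
            "bins": res.bins,
            "n_real": n_real,
            "n_virtual": n_virtual,
        }
        for name, res in kl_by_feature.items()
    ]
    return pd.DataFrame(rows, columns=["feature", "kl", "epsilon", "bins",
                                       "n_real", "n_virtual"])
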