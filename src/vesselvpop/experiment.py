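"""Evaluation protocol: per-trial real-vs-virtual comparison and the landmark sweep.

One *trial* at landmark count ``k`` runs the full pipeline:

1. resample every real artery to ``k`` equal-arc-length landmarks,
2. fit the Gaussian shape model to the resulting population matrix,
3. sample ``n_vp`` virtual shape vectors (seeded),
4. reconstruct with the same quadratic B-spline to the same output count
   ``m``: virtual arteries from their ``k`` sampled landmarks, real arteries
   from their full-resolution centerlines (their point counts differ, which
   is why they are re-interpolated at all; the real feature distribution is
   thereby independent of ``k`` and acts as the fixed reference the virtual
   population converges to as ``k`` grows).  ``real_from="landmarks"``
   instead pushes the real arteries through the same ``k``-landmark
   decimation as the virtual ones, which is the natural choice for
   self-consistency checks where both populations must be processed
   identically,
5. compute length, distance metric and maximum local curvature on both,
6. compare the three feature distributions with 30-bin relative-frequency
   histograms and KL divergence, and summarize each population.

The *landmark sweep* repeats this over a range of ``k`` with several
independent trials per ``k`` (the reference protocol uses 30 trials of 100
virtual arteries, i.e. 3000 virtual arteries per sweep cell) and reports the
per-``k`` mean and SD of KL per feature.  Trial ``t`` uses seed
``base_seed + t`` at every ``k``, so ``k`` is the only factor varying between
sweep columns; the reconstruction count ``m`` is held fixed while ``k``
varies.  Only model sampling is randomized: the real population and its
landmarking are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .compare import (DEFAULT_BINS, DEFAULT_EPSILON, KLResult, PopulationSummary,
                      kl_divergence, population_summary, relative_histograms)
from .errors import ParameterError, StageError
from .geometry import GeometricFeatures, feature_table, features_of, mean_diameter
from .io import Centerline
from .landmarks import build_population, from_shape_vector, resample_equal_arclength
from .mvnd import fit_mvnd, sample_vpop
from .reconstruct import ReconstructionConfig, bspline_curve, config_for_label

FEATURES = ("length", "dm", "max_curvature")

#: Reference protocol: 30 independent trials of 100 virtual arteries per cell.
DEFAULT_TRIALS = 30
DEFAULT_N_VP = 100


@dataclass
class ProtocolConfig:
    """Defaults of the evaluation protocol (30 x 100 = 3000 VPs per sweep cell)."""

    trials: int = DEFAULT_TRIALS
    n_vp: int = DEFAULT_N_VP
    bins: int = DEFAULT_BINS
    epsilon: float = DEFAULT_EPSILON

    @property
    def vps_per_cell(self) -> int:
        return self.trials * self.n_vp


@dataclass
class TrialResult:
    """Everything produced by one generation-and-comparison trial."""

    k: int
    n_vp: int
    seed: int
    features_real: pd.DataFrame
    features_virtual: pd.DataFrame
    kl: dict[str, KLResult]
    summary_real: PopulationSummary
    summary_virtual: PopulationSummary
    negative_radius_count: int
    real_centerlines: list[Centerline] = field(default_factory=list, repr=False)
    virtual_centerlines: list[Centerline] = field(default_factory=list, repr=False)


@dataclass
class SweepResult:
    """Per-k, per-trial KL divergences with per-k mean/SD per feature."""

    k_values: list[int]
    trials: int
    kl_values: np.ndarray          # (len(k_values), trials, len(FEATURES))
    kl_mean: np.ndarray            # (len(k_values), len(FEATURES))
    kl_sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURES


def _feature_column(df: pd.DataFrame, feature: str) -> np.ndarray:
    col = {"length": "length_mm", "dm": "dm",
           "max_curvature": "max_curvature_per_mm"}[feature]
    return df[col].to_numpy()


def run_trial(
    rpop: Sequence[Centerline],
    k: int,
    n_vp: int,
    recon_cfg: ReconstructionConfig | None = None,
    bins: int = DEFAULT_BINS,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
    real_from: str = "centerline",
) -> TrialResult:
    """Run one full generation-and-comparison trial at landmark count ``k``.

    ``real_from`` selects the reconstruction source for the real arteries:
    ``"centerline"`` (default) splines each real artery's full point set to
    ``m`` output points, so the real feature distribution does not depend on
    ``k``; ``"landmarks"`` splines the same ``k``-landmark decimation used to
    fit the model, processing both populations identically.

    ``n_vp = 0`` is a bypass mode that compares the real features against
    themselves (all KL exactly 0), useful as a pipeline null check.
    """
    if len(rpop) < 2:
        raise ParameterError("need at least 2 real arteries")
    if k < 3:
        raise ParameterError(f"landmark count k must be >= 3 for curvature, got {k}")
    if real_from not in ("centerline", "landmarks"):
        raise ParameterError(f"unknown real_from {real_from!r}")
    if recon_cfg is None:
        recon_cfg = config_for_label(rpop[0].label)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r}: {exc}") from exc

    real_lms = stage("landmarks", lambda: [resample_equal_arclength(c, k) for c in rpop])
    P = stage("population", build_population, real_lms)
    model = stage("fit", fit_mvnd, P)
    vpop = stage("sample", sample_vpop, model, n_vp, seed)
    virtual_lms = stage(
        "virtual-landmarks",
        lambda: [
            from_shape_vector(row, label=model.label, id=vid, sampled=True)
            for row, vid in zip(vpop.pop.matrix, vpop.pop.ids)
        ],
    )
    if real_from == "centerline":
        from .landmarks import LandmarkSet

        real_sources = [
            LandmarkSet(
                landmarks=np.column_stack([c.points, c.radii]),
                label=c.label, id=c.id, sampled=c.sampled,
            )
            for c in rpop
        ]
    else:
        real_sources = real_lms
    real_curves = stage("reconstruct-real",
                        lambda: [bspline_curve(l, recon_cfg) for l in real_sources])
    virtual_curves = stage("reconstruct-virtual",
                           lambda: [bspline_curve(l, recon_cfg) for l in virtual_lms])
    feats_real = stage("features-real", lambda: [features_of(c) for c in real_curves])
    feats_virtual = stage("features-virtual",
                          lambda: [features_of(c) for c in virtual_curves])
    if n_vp == 0:  # bypass: self-comparison
        feats_virtual = feats_real
        virtual_curves = real_curves

    kl: dict[str, KLResult] = {}
    df_real = feature_table(feats_real)
    df_virtual = feature_table(feats_virtual)
    for feature in FEATURES:
        xr = _feature_column(df_real, feature)
        xv = _feature_column(df_virtual, feature)
        f_r, f_v = stage("histogram", relative_histograms, xr, xv, bins)
        kl[feature] = stage("kl", kl_divergence, f_r, f_v, epsilon)

    dia_real = [mean_diameter(c) for c in real_curves]
    dia_virtual = [mean_diameter(c) for c in virtual_curves]
    return TrialResult(
        k=k,
        n_vp=n_vp,
        seed=seed,
        features_real=df_real,
        features_virtual=df_virtual,
        kl=kl,
        summary_real=population_summary(feats_real, dia_real),
        summary_virtual=population_summary(feats_virtual, dia_virtual),
        negative_radius_count=vpop.negative_radius_count,
        real_centerlines=real_curves,
        virtual_centerlines=virtual_curves,
    )


def landmark_sweep(
    rpop: Sequence[Centerline],
    k_values: Sequence[int],
    trials: int = DEFAULT_TRIALS,
    n_vp: int = DEFAULT_N_VP,
    recon_cfg: ReconstructionConfig | None = None,
    bins: int = DEFAULT_BINS,
    epsilon: float = DEFAULT_EPSILON,
    base_seed: int = 0,
    real_from: str = "centerline",
) -> SweepResult:
    """Sweep the landmark count, repeating ``trials`` seeded trials per ``k``."""
    k_values = list(k_values)
    if not k_values:
        raise ParameterError("k_values must be non-empty")
    if any(k < 3 for k in k_values):
        raise ParameterError("every landmark count must be >= 3")
    if trials < 1:
        raise ParameterError("trials must be >= 1")
    smallest = min(rpop, key=lambda c: c.n_points)
    k_max = max(k_values)
    if k_max > smallest.n_points:
        raise ParameterError(
            f"k={k_max} exceeds the {smallest.n_points} acquisition points of "
            f"artery {smallest.id!r}"
        )
    kl_values = np.empty((len(k_values), trials, len(FEATURES)))
    for ik, k in enumerate(k_values):
        for t in range(trials):
            res = run_trial(rpop, k, n_vp, recon_cfg, bins, epsilon,
                            seed=base_seed + t, real_from=real_from)
            kl_values[ik, t] = [res.kl[f].value for f in FEATURES]
    return SweepResult(
        k_values=k_values,
        trials=trials,
        kl_values=kl_values,
        kl_mean=kl_values.mean(axis=1),
        kl_sd=kl_values.std(axis=1, ddof=1) if trials > 1
        else np.zeros((len(k_values), len(FEATURES))),
    )


def sweep_long_frame(res: SweepResult) -> pd.DataFrame:
    """Long-format sweep table: one row per (k, trial, feature)."""
    rows = []
    for ik, k in enumerate(res.k_values):
        for t in range(res.trials):
            for jf, f in enumerate(res.feature_names):
                rows.append({"k": k, "trial": t, "feature": f,
                             "kl": res.kl_values[ik, t, jf]})
    return pd.DataFrame(rows, columns=["k", "trial", "feature", "kl"])


def sweep_summary_frame(res: SweepResult) -> pd.DataFrame:
    """Summary sweep table: one row per (k, feature) with mean and SD."""
    rows = []
    for ik, k in enumerate(res.k_values):
        for jf, f in enumerate(res.feature_names):
            rows.append({"k": k, "feature": f,
                         "kl_mean": res.kl_mean[ik, jf],
                         "kl_sd": res.kl_sd[ik, jf]})
    return pd.DataFrame(rows, columns=["k", "feature", "kl_mean", "kl_sd"])
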