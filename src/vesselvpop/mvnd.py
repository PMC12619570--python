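"""The multivariate normal model over shape vectors.

The model is the full joint Gaussian N(mu, Sigma) over the 4k landmark
variables of a population: mu is the column mean of the population matrix and
Sigma the sample covariance (N-1 denominator), with no dimensionality
reduction.  At realistic cohort sizes N << 4k, so Sigma is singular; every
operation therefore goes through its singular value decomposition:

* density evaluation uses the Moore-Penrose pseudoinverse and the
  pseudo-determinant restricted to the rank-r support,
* sampling draws ``mu + U_r diag(sqrt(s_r)) z`` with z standard normal in r
  dimensions, i.e. from the degenerate Gaussian supported on the affine
  subspace ``mu + span(U_r)``.

Sampled radius entries may be negative; they are counted and reported, never
silently altered.  An explicit post-filter (:func:`filter_negative_radii`) is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .landmarks import PopulationMatrix

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MVNDModel:
    """A fitted Gaussian shape model.

    Attributes
    ----------
    mu : (4k,) mean shape vector (mm).
    sigma : (4k, 4k) sample covariance (mm^2).
    k : landmark count.
    U : (4k, 4k) left singular vectors of sigma, columns ordered by
        nonincreasing singular value.
    s : (4k,) singular values.
    tol : rank cut-off; singular values <= tol are treated as zero.
    rank : number of singular values above tol.
    n_fit : number of arteries the model was fitted to.
    label : artery class the model describes.
    """

    mu: np.ndarray
    sigma: np.ndarray
    k: int
    U: np.ndarray
    s: np.ndarray
    tol: float
    rank: int
    n_fit: int
    label: str = ""

    @property
    def dim(self) -> int:
        return self.mu.size


def fit_mvnd(P: PopulationMatrix, tol_factor: float | None = None) -> MVNDModel:
    """Fit mean and full sample covariance to a population matrix.

    ``sigma[m, n] = 1/(N-1) * sum_i (m_i - mean_m)(n_i - mean_n)``.  The SVD of
    sigma is computed once and cached on the model; the default rank tolerance
    is ``max(4k, N) * machine_eps * s_max`` (override via ``tol_factor``, a
    multiplier on ``s_max``).
    """
    X = P.matrix
    if P.n < 2:
        raise ParameterError(f"need at least 2 arteries to fit a covariance, got {P.n}")
    if not np.isfinite(X).all():
        raise ParameterError("population matrix contains non-finite entries")
    if np.all(X == X[0]):
        # mean of identical rows is that row; summation round-off must not
        # perturb the degenerate (rank-0) contract
        mu = X[0].copy()
    else:
        mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    sigma = 0.5 * (sigma + sigma.T)  # enforce exact symmetry
    U, s, _ = np.linalg.svd(sigma, hermitian=True)
    s_max = s[0] if s.size else 0.0
    eps = np.finfo(float).eps
    d_max = max(X.shape[1], P.n)
    if tol_factor is None:
        # floor at the covariance magnitude that mean-centering round-off can
        # produce, so an identical-row population is rank 0, not rank >= 1
        scale = float(np.abs(X).max()) if X.size else 0.0
        tol = max(d_max * eps * s_max, d_max * (eps * scale) ** 2)
    else:
        tol = tol_factor * s_max
    rank = int(np.count_nonzero(s > tol))
    label = P.labels[0] if P.labels else ""
    return MVNDModel(mu=mu, sigma=sigma, k=P.k, U=U, s=s, tol=tol, rank=rank,
                     n_fit=P.n, label=label)


def pseudoinverse(model: MVNDModel) -> np.ndarray:
    """Moore-Penrose pseudoinverse of sigma from the cached SVD."""
    r = model.rank
    if r == 0:
        return np.zeros_like(model.sigma)
    Ur = model.U[:, :r]
    return (Ur / model.s[:r]) @ Ur.T


def log_density(model: MVNDModel, p: np.ndarray) -> float:
    """Gaussian log-density of a shape vector on the model's rank-r support.

    Returns ``-(r/2) log(2 pi) - (1/2) log pdet(sigma) - (1/2) d^T sigma^+ d``
    with ``d = p - mu`` and the pseudo-determinant the product of the retained
    singular values.  Points whose component orthogonal to the support exceeds
    ``tol * |d|`` have zero density: ``-inf`` is returned.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != model.mu.shape:
        raise ParameterError(f"shape vector length {p.size} != model dim {model.dim}")
    d = p - model.mu
    r = model.rank
    Ur = model.U[:, :r]
    coeff = Ur.T @ d
    resid = d - Ur @ coeff
    d_norm = np.linalg.norm(d)
    if np.linalg.norm(resid) > model.tol * d_norm:
        return float("-inf")
    if r == 0:
        return 0.0
    quad = float(coeff @ (coeff / model.s[:r]))
    log_pdet = float(np.sum(np.log(model.s[:r])))
    return -0.5 * (r * _LOG_2PI + log_pdet + quad)


@dataclass
class VirtualPopulation:
    """Shape vectors sampled from a fitted model."""

    pop: PopulationMatrix
    seed: int
    model_id: str = ""
    negative_radius_count: int = 0


def sample_vpop(model: MVNDModel, n: int, seed: int) -> VirtualPopulation:
    """Draw ``n`` virtual shape vectors; deterministic given ``seed``.

    Each row is ``mu + U_r diag(sqrt(s_r)) z`` with z ~ N(0, I_r).  Negative
    sampled radius entries are counted, flagged via ids, and kept.
    """
    if n < 0:
        raise ParameterError(f"sample size must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    r = model.rank
    z = rng.standard_normal((n, r))
    rows = model.mu + (z * np.sqrt(model.s[:r])) @ model.U[:, :r].T
    radii = rows[:, 3 * model.k:]
    neg = int(np.count_nonzero(radii < 0))
    pop = PopulationMatrix(
        matrix=rows,
        k=model.k,
        ids=[f"vp_{i:04d}" for i in range(n)],
        labels=[model.label] * n,
    )
    return VirtualPopulation(pop=pop, seed=seed, model_id=model.label,
                             negative_radius_count=neg)


def filter_negative_radii(
    vpop: VirtualPopulation, mode: str = "reject", floor: float = 0.0
) -> VirtualPopulation:
    """Optional post-filter for negative sampled radii (off by default).

    ``reject`` drops rows containing any negative radius; ``clamp`` raises
    offending entries to ``floor``.
    """
    k = vpop.pop.k
    rows = vpop.pop.matrix
    radii = rows[:, 3 * k:]
    if mode == "reject":
        keep = ~(radii < 0).any(axis=1)
        kept = rows[keep]
        ids = [i for i, ok in zip(vpop.pop.ids, keep) if ok]
        labels = [l for l, ok in zip(vpop.pop.labels, keep) if ok]
        pop = PopulationMatrix(matrix=kept, k=k, ids=ids, labels=labels)
        return VirtualPopulation(pop=pop, seed=vpop.seed, model_id=vpop.model_id,
                                 negative_radius_count=0)
    if mode == "clamp":
        out = rows.copy()
        out[:, 3 * k:] = np.maximum(radii, floor)
        pop = PopulationMatrix(matrix=out, k=k, ids=list(vpop.pop.ids),
                               labels=list(vpop.pop.labels))
        return VirtualPopulation(pop=pop, seed=vpop.seed, model_id=vpop.model_id,
                                 negative_radius_count=0)
    raise ParameterError(f"unknown filter mode {mode!r} (use 'reject' or 'clamp')")


def save_model(model: MVNDModel, path: str | Path) -> Path:
    """Persist a model to HDF5 (datasets mu, sigma, U, s; attrs k, n_fit, tol, label)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mu", data=model.mu)
        f.create_dataset("sigma", data=model.sigma)
        f.create_dataset("U", data=model.U)
        f.create_dataset("s", data=model.s)
        f.attrs["k"] = model.k
        f.attrs["n_fit"] = model.n_fit
        f.attrs["tol"] = model.tol
        f.attrs["label"] = model.label
        f.attrs["rank"] = model.rank
    return path


def load_model(path: str | Path) -> MVNDModel:
    import h5py

    with h5py.File(path, "r") as f:
        return MVNDModel(
            mu=f["mu"][()],
            sigma=f["sigma"][()],
            U=f["U"][()],
            s=f["s"][()],
            k=int(f.attrs["k"]),
            n_fit=int(f.attrs["n_fit"]),
            tol=float(f.attrs["tol"]),
            rank=int(f.attrs["rank"]),
            label=str(f.attrs["label"]),
        )
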