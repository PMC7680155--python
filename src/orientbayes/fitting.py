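"""Monte-Carlo likelihood and grid-search maximum-likelihood fitting.

The response distribution ``p(theta_e | theta, M, lam)`` of an observer
model has no closed form, so it is approximated by simulation: draw
``n_mc`` measurements (800 by default), decode each, round to the integer
response alphabet, and use class frequencies as probabilities.  The summed
log-likelihood of a trial table is then maximized over an explicit
parameter grid — sigma in [1, 8] step 0.01 for the equal-precision models,
Weber fraction in [0.1, 0.4] step 0.01 for the variable-precision models.

Two numerical conventions stabilize the procedure:

* frequencies are floored at ``1/(10 n_mc)`` before taking logs, so a
  response the finite sample never produced contributes a large penalty
  instead of ``-inf``;
* the same measurement stream (common random numbers) is reused at every
  grid point, so the likelihood surface is smooth in ``lam`` and the argmax
  is not dominated by Monte-Carlo jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._seeding import KEY_FIT, rng_for, stimulus_key
from .design import ExperimentDesign
from .estimators import MODELS, EstimatorSpec, decoder_for, _pattern_of
from .observer import TrialDataset

__all__ = [
    "DEFAULT_GRIDS",
    "EmptyDatasetError",
    "ResponseDistribution",
    "FitResult",
    "response_distribution",
    "log_likelihood",
    "fit_mle",
    "default_grid",
    "ObserverMLE",
]

#: Standard fitting-protocol parameter grids per pattern: (min, max, step).
DEFAULT_GRIDS = {"EP": (1.0, 8.0, 0.01), "VP": (0.1, 0.4, 0.01)}


class EmptyDatasetError(ValueError):
    """No reference-condition estimating-phase rows to fit."""


def default_grid(model: str) -> np.ndarray:
    lo, hi, step = DEFAULT_GRIDS[_pattern_of(model)]
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def default_smoothing(n_mc: int) -> float:
    return 1.0 / (10.0 * n_mc)


@dataclass(frozen=True)
class ResponseDistribution:
    """Monte-Carlo response distribution of one stimulus under one model."""

    stimulus: float
    classes: np.ndarray  # integer-degree response values
    probs: np.ndarray
    n_mc: int
    smoothing: float

    def prob_of(self, response) -> np.ndarray:
        """Probability of integer response(s), floored at ``smoothing``."""
        r = np.atleast_1d(np.asarray(response))
        idx = np.searchsorted(self.classes, r)
        idx = np.clip(idx, 0, len(self.classes) - 1)
        p = np.where(self.classes[idx] == r, self.probs[idx], 0.0)
        out = np.maximum(p, self.smoothing)
        return out if np.ndim(response) else float(out[0])


def _mc_measurements(alpha: float, lam: float, pattern: str, n_mc: int,
                     seed: int) -> np.ndarray:
    """Common-random-number measurement draws for one stimulus.

    The standard-normal stream depends only on (seed, alpha), so rerunning
    with a different ``lam`` rescales the same draws.
    """
    sd = lam if pattern == "EP" else lam * abs(alpha)
    z = rng_for(seed, KEY_FIT, stimulus_key(alpha)).standard_normal(n_mc)
    return alpha + sd * z


def _simulated_classes(alpha: float, spec: EstimatorSpec, n_mc: int, seed: int):
    am = _mc_measurements(alpha, spec.enc.lam, spec.enc.pattern, n_mc, seed)
    resp = np.round(np.asarray(decoder_for(spec)(am), dtype=float)).astype(int)
    return np.unique(resp, return_counts=True)


def response_distribution(alpha: float, spec: EstimatorSpec, n_mc: int = 800,
                          seed: int = 0,
                          smoothing: float | None = None) -> ResponseDistribution:
    """Frequency approximation of ``p(theta_e | alpha, M, lam)``.

    Responses are on the orientation scale and rounded to integer degrees.
    A variable-precision observer viewing the reference itself (``alpha =
    0``) responds with the reference orientation every time: point mass.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if smoothing is None:
        smoothing = default_smoothing(n_mc)
    alpha = float(alpha)
    if spec.enc.pattern == "VP" and alpha == 0.0:
        ref = int(round(spec.design.reference_deg))
        return ResponseDistribution(alpha, np.array([ref]), np.array([1.0]),
                                    n_mc, smoothing)
    classes, counts = _simulated_classes(alpha, spec, n_mc, seed)
    return ResponseDistribution(alpha, classes, counts / n_mc, n_mc, smoothing)


def _grouped_observations(dataset: TrialDataset):
    """Per-stimulus observed integer-response counts from the analysis set."""
    est = dataset.estimating()
    if len(est) == 0:
        raise EmptyDatasetError(
            "dataset has no reference-condition estimating-phase trials")
    ref = dataset.design.reference_deg
    groups = []
    for theta, sub in est.groupby("stimulus_deg"):
        alpha = float(theta) - ref
        vals, counts = np.unique(np.round(sub["response_deg"].to_numpy()).astype(int),
                                 return_counts=True)
        groups.append((alpha, vals, counts))
    return groups


def _loglik_for_spec(groups, spec: EstimatorSpec, n_mc: int, seed: int,
                     smoothing: float) -> float:
    total = 0.0
    for alpha, obs_vals, obs_counts in groups:
        rd = response_distribution(alpha, spec, n_mc=n_mc, seed=seed,
                                   smoothing=smoothing)
        total += float(obs_counts @ np.log(rd.prob_of(obs_vals)))
    return total


def log_likelihood(dataset: TrialDataset, spec: EstimatorSpec, n_mc: int = 800,
                   seed: int = 0, smoothing: float | None = None) -> float:
    """Summed log-likelihood of the trial table under one observer model.

    Sums ``log p(theta_e | theta, M, lam)`` over the reference-condition
    estimating trials, with Monte-Carlo response probabilities floored at
    ``smoothing``.  Deterministic given ``seed``; invariant to trial order.
    """
    if smoothing is None:
        smoothing = default_smoothing(n_mc)
    return _loglik_for_spec(_grouped_observations(dataset), spec, n_mc, seed,
                            smoothing)


@dataclass
class FitResult:
    """Grid-search MLE output: the best parameter and the whole surface."""

    model: str
    lambda_hat: float
    grid: np.ndarray
    loglik: np.ndarray
    n_mc: int
    seed: int
    smoothing: float

    @property
    def max_loglik(self) -> float:
        return float(np.max(self.loglik))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lambda_hat": float(self.lambda_hat),
            "grid_min": float(self.grid[0]),
            "grid_max": float(self.grid[-1]),
            "grid_step": float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 0.0,
            "n_mc": int(self.n_mc),
            "seed": int(self.seed),
            "smoothing": float(self.smoothing),
            "max_loglik": self.max_loglik,
        }

    def surface(self) -> pd.DataFrame:
        return pd.DataFrame({"lam": self.grid, "loglik": self.loglik})


def fit_mle(dataset: TrialDataset, model: str, grid: np.ndarray | None = None,
            n_mc: int = 800, seed: int = 0,
            smoothing: float | None = None) -> FitResult:
    """Maximum-likelihood noise parameter by explicit grid search.

    Evaluates the summed log-likelihood at every grid value (same
    measurement stream at each, see module docstring) and returns the
    argmax; ties break toward the smaller parameter.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if grid is None:
        grid = default_grid(model)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    if smoothing is None:
        smoothing = default_smoothing(n_mc)
    groups = _grouped_observations(dataset)
    design = dataset.design
    ll = np.empty(grid.shape)
    for i, lam in enumerate(grid):
        spec = EstimatorSpec.from_model(model, float(lam), design)
        ll[i] = _loglik_for_spec(groups, spec, n_mc, seed, smoothing)
    best = int(np.argmax(ll))  # first max = smallest lam on ties
    return FitResult(model=model, lambda_hat=float(grid[best]), grid=grid,
                     loglik=ll, n_mc=int(n_mc), seed=int(seed),
                     smoothing=float(smoothing))


class ObserverMLE(BaseEstimator):
    """Scikit-learn style wrapper around the grid-search MLE.

    Fits the single noise parameter of one Bayesian observer model to
    (stimulus, response) pairs.

    Parameters
    ----------
    model : str
        One of ``map_ep``, ``map_vp``, ``bls_ep``, ``bls_vp``.
    grid : array-like or None
        Parameter grid; defaults to the pattern's standard grid.
    n_mc : int
        Monte-Carlo draws per stimulus per grid point.
    seed : int
        Root seed of the Monte-Carlo stream.
    smoothing : float or None
        Probability floor; defaults to ``1/(10 n_mc)``.
    design : ExperimentDesign or None
        Experiment geometry; defaults to the standard design.

    Attributes
    ----------
    lambda_ : float
        Fitted noise parameter (sigma in degrees for EP, Weber fraction
        for VP).
    loglik_ : float
        Maximized summed log-likelihood.
    result_ : FitResult
        Full grid surface.
    """

    def __init__(self, model: str = "bls_vp", grid=None, n_mc: int = 800,
                 seed: int = 0, smoothing: float | None = None,
                 design: ExperimentDesign | None = None):
        self.model = model
        self.grid = grid
        self.n_mc = n_mc
        self.seed = seed
        self.smoothing = smoothing
        self.design = design

    def _dataset(self, X, y) -> TrialDataset:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be (n,) or (n, 1) stimulus orientations")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("y must hold one response per stimulus")
        design = self.design or ExperimentDesign()
        rec = pd.DataFrame({
            "subject_id": "fit", "condition": "reference", "phase": "estimating",
            "trial_index": np.arange(len(X)),
            "stimulus_deg": X, "response_deg": y,
            "reference_deg": design.reference_deg,
        })
        return TrialDataset(rec, design, {"source": "arrays"})

    def fit(self, X, y):
        ds = self._dataset(X, y)
        self.design_ = ds.design
        self.result_ = fit_mle(ds, self.model, grid=self.grid, n_mc=self.n_mc,
                               seed=self.seed, smoothing=self.smoothing)
        self.lambda_ = self.result_.lambda_hat
        self.loglik_ = self.result_.max_loglik
        self.n_features_in_ = 1
        return self

    def _spec(self) -> EstimatorSpec:
        return EstimatorSpec.from_model(self.model, self.lambda_, self.design_)

    def predict(self, X):
        """Expected reported orientation for each stimulus.

        Gauss–Hermite quadrature of the decoder over the fitted measurement
        distribution.
        """
        if not hasattr(self, "lambda_"):
            raise AttributeError("ObserverMLE is not fitted yet")
        X = np.asarray(X, dtype=float).reshape(-1)
        spec = self._spec()
        g = decoder_for(spec)
        nodes, weights = np.polynomial.hermite_e.hermegauss(101)
        weights = weights / np.sqrt(2.0 * np.pi)
        out = np.empty(X.shape)
        for i, theta in enumerate(X):
            alpha = theta - self.design_.reference_deg
            sd = self.lambda_ if spec.enc.pattern == "EP" else self.lambda_ * abs(alpha)
            out[i] = float(weights @ np.asarray(g(alpha + sd * nodes), dtype=float))
        return out

    def score(self, X, y) -> float:
        """Mean per-trial log-likelihood under the fitted parameter."""
        if not hasattr(self, "lambda_"):
            raise AttributeError("ObserverMLE is not fitted yet")
        ds = self._dataset(X, y)
        return log_likelihood(ds, self._spec(), n_mc=self.n_mc, seed=self.seed,
                              smoothing=self.smoothing) / len(ds)
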