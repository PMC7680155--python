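"""Evaluation metrics and the model-comparison report.

Per stimulus ``s_j`` with responses ``x_ji``:

* ``BIAS_j``: signed mean error, mean(x_ji) - s_j;
* ``SD_j``: population standard deviation of the responses (divisor ``n``,
  required for the exact identity below);
* ``MSE_j``: mean squared error, satisfying ``MSE_j = BIAS_j^2 + SD_j^2``.

Overall metrics are root-mean-squares of the per-stimulus values over the
stimulus grid, with ``MSE_S = BIAS^2 + SD^2`` expressing the bias/precision
trade-off.  Cross-entropy scores how well a model's Monte-Carlo response
distributions, read as a classifier over the 25 stimulus classes, identify
each trial's true stimulus (natural log; lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .estimators import EstimatorSpec
from .fitting import (EmptyDatasetError, default_smoothing, fit_mle,
                      response_distribution)
from .observer import TrialDataset, simulate_dataset

__all__ = [
    "MissingStimulusError",
    "OverallMetrics",
    "per_stimulus_metrics",
    "overall_metrics",
    "cross_entropy",
    "comparison_table",
]


class MissingStimulusError(ValueError):
    """A grid stimulus has no trials in the dataset."""


@dataclass(frozen=True)
class OverallMetrics:
    bias: float
    sd: float
    mse_s: float
    ce: float | None = None


def per_stimulus_metrics(dataset: TrialDataset) -> pd.DataFrame:
    """BIAS_j, SD_j, MSE_j and trial count for every grid stimulus.

    Columns ``stimulus_deg, bias, sd, mse, n``; raises
    :class:`MissingStimulusError` naming any grid stimulus without trials.
    """
    est = dataset.estimating()
    if len(est) == 0:
        raise EmptyDatasetError("no reference-condition estimating-phase trials")
    present = set(est["stimulus_deg"].unique())
    missing = [t for t in dataset.design.stimulus_grid if t not in present]
    if missing:
        raise MissingStimulusError(f"no trials for grid stimuli {missing}")
    rows = []
    for theta in dataset.design.stimulus_grid:
        x = est.loc[est["stimulus_deg"] == theta, "response_deg"].to_numpy(float)
        err = x - theta
        bias = float(err.mean())
        sd = float(x.std(ddof=0))
        rows.append({"stimulus_deg": theta, "bias": bias, "sd": sd,
                     "mse": float((err ** 2).mean()), "n": len(x)})
    return pd.DataFrame(rows)


def overall_metrics(rows: pd.DataFrame, ce: float | None = None) -> OverallMetrics:
    """RMS aggregation of per-stimulus metrics; ``MSE_S = BIAS^2 + SD^2``."""
    if len(rows) == 0:
        raise ValueError("empty metrics table")
    bias = float(np.sqrt(np.mean(rows["bias"].to_numpy() ** 2)))
    sd = float(np.sqrt(np.mean(rows["sd"].to_numpy() ** 2)))
    return OverallMetrics(bias=bias, sd=sd, mse_s=bias ** 2 + sd ** 2, ce=ce)


def cross_entropy(dataset: TrialDataset, spec: EstimatorSpec, n_mc: int = 800,
                  seed: int = 0, smoothing: float | None = None) -> float:
    """Cross-entropy between the data and a model's response distributions.

    Each trial's true stimulus is the one-hot target; the model's
    probability of the observed response under every candidate stimulus
    class, normalized across the classes, is the prediction.  ``CE = -(1/N)
    sum_i log p_hat(class_i | response_i)`` in natural-log units.  With
    ``smoothing > 0`` every class keeps a probability floor before
    normalization; ``smoothing=0`` scores the raw frequencies.
    """
    est = dataset.estimating()
    if len(est) == 0:
        raise EmptyDatasetError("no reference-condition estimating-phase trials")
    if smoothing is None:
        smoothing = default_smoothing(n_mc)
    design = dataset.design
    grid = list(design.stimulus_grid)
    resp = np.round(est["response_deg"].to_numpy(float)).astype(int)
    classes = np.arange(int(np.floor(design.theta_min)),
                        int(np.ceil(design.theta_max)) + 1)
    # P[k, r]: model probability of integer response r under stimulus class k
    P = np.empty((len(grid), len(classes)))
    for k, theta in enumerate(grid):
        rd = response_distribution(theta - design.reference_deg, spec,
                                   n_mc=n_mc, seed=seed, smoothing=smoothing)
        P[k] = rd.prob_of(classes) if smoothing > 0 else [
            rd.probs[rd.classes == c][0] if c in rd.classes else 0.0
            for c in classes]
    r_idx = np.clip(resp - classes[0], 0, len(classes) - 1)
    col = np.where((resp >= classes[0]) & (resp <= classes[-1]),
                   r_idx, -1)
    grid_arr = np.asarray(grid)
    stim = est["stimulus_deg"].to_numpy(float)
    stim_idx = np.searchsorted(grid_arr, stim)
    stim_idx = np.clip(stim_idx, 0, len(grid_arr) - 1)
    if np.any(grid_arr[stim_idx] != stim):
        raise MissingStimulusError("dataset contains stimuli outside the design grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(col[None, :] >= 0, P[:, col], smoothing if smoothing > 0 else 0.0)
        norm = probs.sum(axis=0)
        p_hat = probs[stim_idx, np.arange(len(resp))] / norm
        logp = np.log(p_hat)
    if not np.all(np.isfinite(logp)):
        raise ArithmeticError(
            "cross-entropy is infinite: some responses have zero probability "
            "under every class; use a positive smoothing floor")
    return float(-np.mean(logp))


def comparison_table(design: ExperimentDesign,
                     models: list[str],
                     lambdas: list[float] | None = None,
                     dataset: TrialDataset | None = None,
                     n_reps: int = 100_000, n_mc: int = 800, seed: int = 0,
                     fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Model-comparison report, one row per model (+ a DATA row).

    Each model row simulates ``n_reps`` responses per stimulus at its noise
    parameter — supplied in ``lambdas`` or fitted to ``dataset`` by
    grid-search MLE — and reports the overall metrics of those predictions.
    When a dataset is given, its own metrics appear in a DATA row and every
    model also gets two goodness-of-fit scores against the data:

    * ``ce`` — cross-entropy (see :func:`cross_entropy`);
    * ``fit_mse`` — mean squared error between the data's responses and the
      model's per-stimulus mean predictions.  A model's *own* ``mse_s``
      measures its predicted bias/precision trade-off, which a single free
      noise parameter can tune close to the data's value whether or not
      the response structure matches; ``fit_mse`` is the score that
      rewards matching the per-stimulus bias pattern itself.
    """
    if lambdas is not None and len(lambdas) != len(models):
        raise ValueError("need one lambda per model")
    if lambdas is None and dataset is None:
        raise ValueError("either lambdas or a dataset to fit is required")
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    data_rows = None
    if dataset is not None:
        data_rows = per_stimulus_metrics(dataset)
        dm = overall_metrics(data_rows)
        rows.append({"model": "data", "mle_lambda": np.nan, "mse_s": dm.mse_s,
                     "bias": dm.bias, "sd": dm.sd, "ce": np.nan,
                     "fit_mse": np.nan})
    for i, model in enumerate(models):
        if lambdas is not None:
            lam = float(lambdas[i])
        else:
            lam = fit_mle(dataset, model, n_mc=n_mc, seed=seed,
                          **fit_kwargs).lambda_hat
        spec = EstimatorSpec.from_model(model, lam, design)
        sim = simulate_dataset(design, spec, n_reps=n_reps, seed=seed)
        sim_rows = per_stimulus_metrics(sim)
        m = overall_metrics(sim_rows)
        ce = fit_mse = np.nan
        if dataset is not None:
            ce = cross_entropy(dataset, spec, n_mc=n_mc, seed=seed)
            # squared error of data responses around the model's predicted
            # per-stimulus means: SD_j(data)^2 + (mean_j(data) - pred_j)^2
            pred = sim_rows["stimulus_deg"].to_numpy() + sim_rows["bias"].to_numpy()
            data_mean = data_rows["stimulus_deg"].to_numpy() + data_rows["bias"].to_numpy()
            n_j = data_rows["n"].to_numpy()
            per_stim = data_rows["sd"].to_numpy() ** 2 + (data_mean - pred) ** 2
            fit_mse = float(np.average(per_stim, weights=n_j))
        rows.append({"model": model, "mle_lambda": lam, "mse_s": m.mse_s,
                     "bias": m.bias, "sd": m.sd, "ce": ce,
                     "fit_mse": fit_mse})
    return pd.DataFrame(rows)
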