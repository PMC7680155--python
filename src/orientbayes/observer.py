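"""Synthetic observer: generates trial tables with the structure of the
orientation-identification experiment.

A simulated subject runs through the stimulus grid, receives a noisy
measurement of each cognitive angle, decodes it with one of the four
Bayesian rules, and keys in the (by default integer-rounded) orientation.
These tables stand in for empirical data and drive the fitting and metric
modules; an arbitrary-sampler variant produces hand-constructible response
patterns for testing the metrics on known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._seeding import KEY_ARBITRARY, KEY_MEASUREMENT, KEY_SHUFFLE, rng_for, stimulus_key
from .design import DEFAULT_LEARNING_REPS, ExperimentDesign
from .encoding import draw_measurements
from .estimators import EstimatorSpec, decoder_for

__all__ = ["TRIAL_COLUMNS", "TrialDataset", "simulate_dataset", "simulate_arbitrary"]

#: Column order of the trial-table CSV dialect.
TRIAL_COLUMNS = ("subject_id", "condition", "phase", "trial_index",
                 "stimulus_deg", "response_deg", "reference_deg")


@dataclass
class TrialDataset:
    """Trial records plus the design and generator provenance.

    ``records`` is a DataFrame with the columns of :data:`TRIAL_COLUMNS`;
    ``provenance`` holds generator settings (model, lam, seed, ...) or
    ``{"source": "empirical"}`` for loaded data.
    """

    records: pd.DataFrame
    design: ExperimentDesign
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def estimating(self) -> pd.DataFrame:
        """Reference-condition estimating-phase rows (the analysis set)."""
        r = self.records
        return r[(r["condition"] == "reference") & (r["phase"] == "estimating")]

    def concat(self, other: "TrialDataset") -> "TrialDataset":
        rec = pd.concat([self.records, other.records], ignore_index=True)
        return TrialDataset(rec, self.design, {"source": "concat"})


def _assemble(design: ExperimentDesign, stims: np.ndarray, resps: np.ndarray,
              subject_id: str, condition: str, phase: str, seed: int,
              shuffle: bool) -> pd.DataFrame:
    n = len(stims)
    if shuffle:
        order = rng_for(seed, KEY_SHUFFLE).permutation(n)
        stims, resps = stims[order], resps[order]
    ref = design.reference_deg if condition == "reference" else np.nan
    return pd.DataFrame({
        "subject_id": subject_id,
        "condition": condition,
        "phase": phase,
        "trial_index": np.arange(n),
        "stimulus_deg": stims,
        "response_deg": resps,
        "reference_deg": ref,
    })


def simulate_dataset(design: ExperimentDesign, spec: EstimatorSpec,
                     n_reps: int | None = None, seed: int = 0,
                     round_responses: bool = True,
                     subject_id: str = "synthetic",
                     include_learning: bool = False,
                     learning_reps: int = DEFAULT_LEARNING_REPS,
                     lapse_hook: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
                     ) -> TrialDataset:
    """Simulate one subject of the reference condition.

    For every stimulus ``theta`` and repetition: ``alpha = theta - R``,
    ``alpha_m ~ p(alpha_m | alpha, lam)``, response ``g(alpha_m) + R``,
    rounded to the nearest integer degree when ``round_responses`` (the
    keyboard-entry convention).  Trial order is shuffled with the run seed;
    everything is reproducible from ``seed``.

    ``lapse_hook`` may post-process responses (e.g. motor noise); the
    generative model itself contains no lapse term and the hook is off by
    default.  ``include_learning`` adds feedback-phase rows generated by the
    same observer (``learning_reps`` per stimulus).
    """
    if n_reps is None:
        n_reps = design.reps_per_stimulus
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    g = decoder_for(spec)
    phases = [("estimating", int(n_reps))]
    if include_learning:
        phases = [("learning", int(learning_reps))] + phases

    frames = []
    for phase, reps in phases:
        stims, resps = [], []
        for theta in design.stimulus_grid:
            alpha = theta - design.reference_deg
            rng = rng_for(seed, KEY_MEASUREMENT, stimulus_key(theta),
                          0 if phase == "estimating" else 1)
            am = draw_measurements(alpha, spec.enc, reps, rng=rng)
            resp = np.asarray(g(am), dtype=float)
            if lapse_hook is not None:
                resp = lapse_hook(resp, rng)
            if round_responses:
                resp = np.round(resp)
            stims.append(np.full(reps, theta))
            resps.append(resp)
        frames.append(_assemble(design, np.concatenate(stims), np.concatenate(resps),
                                subject_id, "reference", phase, seed, shuffle=True))
    records = pd.concat(frames, ignore_index=True)
    prov = {"source": "simulate_dataset", "model": spec.model,
            "lam": spec.enc.lam, "seed": int(seed), "n_reps": int(n_reps),
            "round_responses": bool(round_responses)}
    return TrialDataset(records, design, prov)


def simulate_arbitrary(design: ExperimentDesign,
                       response_sampler: Mapping[float, Callable] | Callable,
                       n_reps: int = 32, seed: int = 0,
                       condition: str = "reference",
                       subject_id: str = "synthetic") -> TrialDataset:
    """Trial table with responses drawn from an arbitrary per-stimulus rule.

    ``response_sampler`` is either a callable ``f(theta, size, rng) ->
    responses`` or a mapping from stimulus to such a callable.  Used for
    non-Bayesian fixtures (e.g. identity responders) and for the
    no-reference control condition, for which the model provides no
    generative equations.
    """
    stims, resps = [], []
    for theta in design.stimulus_grid:
        sampler = response_sampler[theta] if isinstance(response_sampler, Mapping) \
            else response_sampler
        rng = rng_for(seed, KEY_ARBITRARY, stimulus_key(theta))
        r = np.asarray(sampler(theta, n_reps, rng), dtype=float)
        if r.shape != (n_reps,):
            raise ValueError("sampler must return n_reps responses")
        stims.append(np.full(n_reps, float(theta)))
        resps.append(r)
    records = _assemble(design, np.concatenate(stims), np.concatenate(resps),
                        subject_id, condition, "estimating", seed, shuffle=True)
    prov = {"source": "simulate_arbitrary", "seed": int(seed), "n_reps": int(n_reps)}
    return TrialDataset(records, design, prov)
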