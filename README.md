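# orientbayes

Bayesian observer models of orientation identification in the presence of a
known reference line.

## The problem

In a line-orientation identification task, observers judge the orientation
θ of a tilted target shown together with a reference line of known
orientation R = 45°, and key in their estimate in integer degrees.  Two
robust phenomena appear in such data: precision improves sharply near the
reference (weakening the classic oblique effect), and estimates close to
the reference are pushed *away* from it (reference repulsion).

This package implements a cue-integration account of those findings as a
two-stage Bayesian inference on the *cognitive angle* α = θ − R:

* **Encoding.**  The angle is observed through a noisy internal measurement
  α_m ~ N(α, σ²), with either **equal precision** (EP, σ = λ constant) or
  **variable precision** (VP, σ = λ·|α|, scalar variability with Weber
  fraction λ — exact at the reference itself).
* **Decoding.**  The observer combines the measurement with a uniform prior
  on [α_min, α_max] = [−23°, 23°] and reads out either the posterior mode
  (**MAP**, Dirac-delta cost) or the posterior mean (**BLS**, squared-error
  cost):

      p(α | α_m, λ) ∝ p(α_m | α, λ) · 1[α_min ≤ α ≤ α_max]
      MAP:  α_e = argmax_α p(α | α_m, λ)
      BLS:  α_e = ∫ α p(α | α_m, λ) dα        (composite Simpson rule)

  The reported orientation is θ_e = R + α_e.  MAP_EP is the clipped
  identity; MAP_VP shrinks the measurement by
  c(λ) = (−1 + √(1 + 4λ²)) / (2λ²); the BLS readouts are evaluated by
  quadrature.  Crossing the four combinations gives the model family
  MAP_EP, MAP_VP, BLS_EP, BLS_VP, each with the single free parameter λ.

The VP posterior is asymmetric — angles nearer the reference carry higher
precision — so its posterior mean is repelled from the reference, which is
why the BLS_VP observer reproduces both the near-reference precision gain
and the repulsive bias, and wins the model comparison.

## What the package provides

* `ExperimentDesign` — the task geometry (45° reference, 25 stimuli
  22°–68°, uniform prior support ±23°, 32 repetitions → 800 trials).
* `EncodingModel`, `measurement_density`, `draw_measurements` — the sensory
  stage.
* `EstimatorSpec`, `posterior_density`, `map_ep`, `map_vp`, `bls`,
  `theoretical_moments` — the decoding stage.
* `simulate_dataset` / `simulate_arbitrary` — synthetic observers that emit
  the trial-table CSV schema (`subject_id,condition,phase,trial_index,
  stimulus_deg,response_deg,reference_deg`).
* `fit_mle` / `ObserverMLE` — Monte-Carlo likelihood (800 draws per
  stimulus, frequency-matched at integer-degree resolution) maximized over
  an explicit grid (σ ∈ [1, 8] step 0.01; w ∈ [0.1, 0.4] step 0.01).
  `ObserverMLE` is a scikit-learn estimator (`fit`/`predict`/`score`).
* `per_stimulus_metrics`, `overall_metrics`, `cross_entropy`,
  `comparison_table` — the BIAS/SD/MSE decomposition
  (MSE_j = BIAS_j² + SD_j², MSE_S = BIAS² + SD²) and model comparison.
* `orientbayes` CLI with `simulate`, `fit`, `metrics`, `compare`
  subcommands.

## Worked example

```python
import orientbayes as ob

design = ob.ExperimentDesign()                      # 45° reference, 25 stimuli
spec = ob.EstimatorSpec.from_model("bls_vp", 0.23, design)
trials = ob.simulate_dataset(design, spec, seed=42) # one synthetic subject, 800 trials

fit = ob.fit_mle(trials, "bls_vp", seed=7)          # grid-search MLE of the Weber fraction
overall = ob.overall_metrics(ob.per_stimulus_metrics(trials))

print(f"recovered Weber fraction: {fit.lambda_hat:.2f}")
print(f"overall BIAS = {overall.bias:.3f} deg, SD = {overall.sd:.3f} deg, "
      f"MSE_S = {overall.mse_s:.3f} deg^2")
```

prints

```
recovered Weber fraction: 0.23
overall BIAS = 1.450 deg, SD = 1.973 deg, MSE_S = 5.992 deg^2
```

The generating Weber fraction (0.23) is recovered exactly on the fitting
grid, and the overall bias/precision pair is the signature of the BLS_VP
observer: low SD near the reference at the cost of a systematic repulsive
bias (per-stimulus biases are negative just below 45° and positive just
above it).  The same analysis from the shell:

```sh
orientbayes simulate --model bls_vp --lambda 0.23 --seed 42 --out run/
orientbayes fit --model bls_vp --trials run/trials.csv --seed 7 --out run/
orientbayes compare --models all --from-lambdas 3.6,0.27,3.75,0.23 \
    --trials run/trials.csv --out run/
```

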