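# rgcadapt

Do retinal ganglion cells (RGCs) change their spatial receptive fields when
the visual input switches between artificial white noise and natural scenes?
`rgcadapt` implements, as a fully tested pipeline on synthetic neurons, the
analysis used to answer that question: constrained linear–nonlinear (LN)
model fitting under two stimulus ensembles, out-of-domain evaluation with
frozen spatial filters, receptive-field center/surround quantification by
three independent methods, and a spectral-whitening analysis that confronts
the observed surround changes with the predictions of efficient coding.

The package is aimed at computational neuroscientists who want to reproduce,
probe or extend this style of stimulus-domain-adaptation analysis without
access to recordings: a built-in generator simulates LN–Poisson model
neurons whose ground-truth filters may differ between ensembles, so every
stage of the pipeline can be validated against known parameters.

## The models

Each cell is modeled as an LN cascade. The rank-two
**difference-of-Gaussians (DoG) LN model** builds the spatiotemporal
receptive field from two space–time separable components,

```
R(x, y, t) = G1(x, y) T1(t) − G2(x, y) T2(t),
```

where `G1`, `G2` are 2-D Gaussians constrained to share a center location
and amplitude sign (center and surround), and `T1`, `T2` are unit-norm
30-tap temporal filters. The firing rate is
`f(x) = α·ln(1 + exp(x + β))` applied to the inner product of `R` with the
preceding 30 stimulus frames, on a 15×15-pixel crop around the cell. An
unconstrained **rank-one LN model** (one free 15×15 spatial filter, one
free temporal filter) serves as a robustness check. Both are trained by
minimizing the Poisson loss `L(r, p) = Σᵢ pᵢ − rᵢ ln(pᵢ + ε)` with Adam,
early stopping on validation correlation and a reduce-on-plateau learning
rate schedule.

Receptive-field metrics: center size `S = 4π√(λ₁λ₂)` (the 2-SD ellipse area
from the center Gaussian's covariance eigenvalues λ), and the surround
amplitude read off the *surround frame* of `R` — the temporal slice near
the response peak holding the strongest opposite-polarity signal. For
rank-one filters the same quantities come from a post-hoc DoG fit and from
a nonparametric smoothing/thresholding method.

## Worked example

```python
from rgcadapt.experiments import run_population_experiment, id_ood_summary
from rgcadapt.synthetic_data import default_population_spec

results, cells, stim_wn, stim_nm = run_population_experiment(
    default_population_spec(n_per_type=10), adapt=True, seed=1
)
print(id_ood_summary(results))
```

Output (seed 1; about two minutes on one CPU; values rounded):

```
{'n_cells': 20, 'frac_id_better_nm': 0.95,
 'median_id_minus_ood_nm': 0.0091,
 'surround_wilcoxon_p': 1.9e-06, 'surround_median_diff': 0.0368,
 'size_wilcoxon_p': 0.62, 'size_median_diff': -1.55}
```

Read: for 19 of 20 simulated cells the model trained directly on the
naturalistic surrogate predicts the held-out test response better than a
white-noise-trained model whose spatial filter was frozen and whose
temporal filter/nonlinearity were re-adapted (`frac_id_better_nm`), and the
fitted surround amplitude is significantly stronger under the naturalistic
ensemble (Wilcoxon signed-rank `p ≈ 2e-6`) — the synthetic analogue of the
spatial-adaptation effect. Center size shows no population-wide shift here
because only the midget-like half of the population enlarges by
construction.

The same analysis is available end-to-end from the shell, writing HDF5
stimuli/responses, JSON parameters and CSV tables plus a summary report:

```
rgcadapt run-all --config run.toml --out results/run1 --seed 7
```

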