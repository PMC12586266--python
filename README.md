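# neuram

Gradient-free one-dimensional nonlinear dimensionality reduction for
expensive scalar models, with manifold-based sensitivity analysis and
variance-reduced multifidelity Monte Carlo.

Many outer-loop tasks in uncertainty quantification — propagating input
uncertainty, ranking parameters, estimating output means — need thousands of
evaluations of a model Q : ℝᵈ → ℝ that may take minutes or hours per run.
This package learns, from a modest sample {(xₙ, Q(xₙ))} alone (no gradients
of Q), a *neural active manifold*: an encoder E : ℝᵈ → ℝ, a decoder
D : ℝ → ℝᵈ whose image is a one-dimensional curve in input space, and a
latent surrogate S : ℝ → ℝ, trained jointly so that

    Q(x) ≈ Q(D(E(x)))  and  Q(x) ≈ S(E(x)) = Q_S(x).

Unlike an autoencoder, nothing asks D(E(x)) ≈ x — only model *values* must
survive the collapse onto the manifold. The reduction then supports:

- **Sensitivity analysis.** Local indices
  θᵢ(t) = |∂Q_S/∂xᵢ(D(t))|² / ‖∇Q_S(D(t))‖² rank the inputs *along* the
  manifold (they sum to 1 at every point); global indices Θᵢ are their
  arc-length averages. First-order Sobol′ indices of the exact model are
  available for comparison.
- **Multifidelity Monte Carlo.** For a high/low-fidelity pair, each
  fidelity's latent coordinate is pushed through its empirical CDF onto a
  shared uniform space, and the low-fidelity model is reparameterized as
  Q̃_LF(x) = Q_LF(D_LF(F_LF⁻¹(F_HF(E_HF(x))))). Q̃_LF keeps the original
  low-fidelity output distribution (so the control-variate estimator
  q̂ = mean(Q_HF) − β(mean_{N_HF}(Q̃_LF) − mean_{N_LF}(Q̃_LF)) stays unbiased)
  but is far better correlated with Q_HF, which shrinks the estimator
  variance (Var Q_HF/B)(√(1−ρ²)+√(wρ²))² under the optimal budget split.

A registry of analytic benchmark models is included (parabolic and
sine-parabolic functions, polynomial/exponential 2-D models, an exponential
high/low-fidelity pair, and the closed-form Hartmann magnetohydrodynamics
outputs with log-uniform inputs), together with the exact closed-form
minimizer of the parabolic case used as a reference oracle.

## Worked example

```python
import numpy as np
import neuram as na

# exact reference triple for Q(x) = x1^2 + x2 on U([0,1]^2)
triple = na.analytic_parabolic_neuram()
print(na.global_indices(triple, 4096))   # [0.51193904 0.48806096]

# train a reduction of sin(x1^2 + x2) from 1000 samples
spec, dist = na.get_model("sine_parabolic")
data = na.make_dataset(spec, dist, 1000, seed=101)
nam = na.train_neuram(data, na.NetworkArchitecture(),
                      na.TrainingConfig(epochs=2000, seed=1, restarts=2))
test = na.make_dataset(spec, dist, 1000, seed=900)
print(na.evaluation_errors(spec, nam, test))
# {'e1': {'mae': 0.00866..., 'mse': 0.000142...},
#  'e2': {'mae': 0.00873..., 'mse': 0.000197...}}
```

The first line reproduces the closed-form global sensitivity indices of the
parabolic manifold: x₁ carries 51.2 % of the derivative-based importance and
x₂ 48.8 %, averaged along the parabola x₂ = x₁². The trained reduction of
the sine-parabolic model reaches a mean absolute error below 0.01 both for
the pure dimensionality-reduction error e₁ = Q(x) − Q(D(E(x))) and for the
surrogate error e₂ = Q(x) − Q_S(x) — a few percent of the model's output
standard deviation (≈ 0.258).

A command-line interface mirrors the library (`neuram generate / train /
sensitivity / mf-estimate / run`); `neuram run --preset exp_pair_mf` runs
the full multifidelity pipeline on the exponential pair and reports the
original, reparameterized, and ideal correlations with the repeated
estimates.

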