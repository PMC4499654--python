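# Methods

This note documents the models implemented in `ecgdx`, the choices made
where the underlying methods leave room, and what the synthetic experiments
do and do not demonstrate.

## Backpropagation network (`ecgdx.bp_core`)

The network is the classical three-layer perceptron. With input $x_i$,
hidden activations $y_j = f(w_{oj} + \sum_i w_{ij} x_i)$ and outputs
$z_k = f(w_{ok} + \sum_j w_{jk} y_j)$, where $f(u) = 1/(1+e^{-u})$ is the
logistic sigmoid with derivative $f' = f(1-f)$. The error over a presented
set is

$$E = \tfrac12 \sum_{\text{samples}} \sum_k (t_k - z_k)^2 ,$$

and training is *online* gradient descent: for each sample, in a fresh
random order every epoch,

$$\delta_k = (t_k - z_k) f'(Y_k), \qquad \Delta w_{jk} = \alpha\, y_j \delta_k,$$
$$\Delta_j = f'(X_j) \sum_k \delta_k w_{jk}, \qquad \Delta w_{ij} = \alpha\, x_i \Delta_j,$$

with bias weights updated against a unit pseudo-input and an optional
momentum term $\eta\,\Delta w(n-1)$ added to every change. Training stops
when $E$ over the whole set drops below `e_limit` (default 0.1) or after
`max_epochs` (default 50 000, a safety cap so training always terminates).

Choices that the classical formulation leaves open:

* **Error scope.** The stopping error is the whole-set sum by default
  (the stricter reading); `error_scope="max_per_sample"` compares the worst
  single-sample error instead.
* **Initialization.** Weights start uniform on $[-0.5, 0.5]$ from a seeded
  generator (`init_scale` configurable). Fixing the seed makes the whole
  trajectory bit-reproducible.
* **Update regime.** Online (per-sample) updates; batch accumulation is not
  offered because the reference procedure shuffles and presents patterns
  one at a time.
* **Numerics.** Sigmoid outputs are clipped into the open interval (0, 1)
  at the float boundary so that extreme pre-activations saturate without
  producing exactly 0/1 (which would permanently zero the gradient).
  Gradient correctness is verified against central finite differences to
  1e-6 in the test suite.

Defaults $\alpha = 0.1$, $\eta = 0$, $E < 0.1$ reproduce the study
conditions under which the 10-10-8 recognition net reaches the stopping
criterion on the eight reference patterns within a few thousand epochs
(about 1–2 s on one CPU).

## The two classifiers (`ecgdx.classifiers`)

**Whole-cycle net (101-10-1).** One 101-sample ECG cycle per input; the
single output encodes 0 = healthy, 1 = sick. How raw cycles are scaled for
the net is not fixed by the procedure, so each series is min-max normalized
per series (the same convention as the window normalization); this is
configurable. The decision cutoff on the output is likewise unstated; 0.5
is used, with the tie assigned to sick (the conservative direction for a
screening task). Both live in `DiagnosisPolicy`.

**Sliding-window pattern net (10-10-8).** Every contiguous 10-sample
window of a cycle (92 windows per 101-sample cycle) is normalized by

$$x'_j = \frac{x_j - \min}{\max - \min}$$

and scored by a net trained on eight reference windows — H1–H4 from healthy
morphology, S1–S4 from sick morphology, one output unit each (the packaged
`data/table1.csv`). A degenerate all-equal window maps to all zeros so the
pipeline stays total. The *recognition probability* $p$ of a pattern is
operationalized as the maximum activation of its output unit over all
windows — the weakest reading consistent with "the pattern appears
somewhere in the series". The diagnosis policy tests sick first: if
$p_S \ge p$ (default 0.70) the series is sick; else if $p_H \ge p$ it is
healthy; otherwise unspecified. Consequently whenever both classes reach
the threshold the verdict is sick.

Window indices are 0-based, half-open $[start, start+10)$.

## Fuzzy transform (`ecgdx.ftransform`)

Basic functions $A_1..A_n$ on $[a,b]$ with nodes $c_1 = a < \dots < c_n = b$
form a Ruspini partition: $A_i(c_i) = 1$, support confined to
$(c_{i-1}, c_{i+1})$ with the boundary convention $c_0 = c_1$,
$c_{n+1} = c_n$, and $\sum_i A_i(x) = 1$ everywhere (verified to 1e-12).
Triangular (hat) functions are the default — the canonical choice, for
which the inverse transform is exactly the piecewise-linear interpolant
through $(c_i, F_i)$; raised-cosine functions are available behind the
`shape` flag.

Direct transform: $F_i = \sum_t f(x_t) A_i(x_t) / \sum_t A_i(x_t)$; every
basic function must cover at least one sample, otherwise an error names the
offending index. Inverse: $f_{F,n}(x) = \sum_i F_i A_i(x)$.

`decompose` treats a series as a function on $t = 1..T$ with
$[a,b] = [1,T]$: the inverse transform at the sample points is the
**trend-cycle**, the residual is the **seasonal** component, and their sum
reconstructs the input exactly (to 1e-12, by construction). The component
count defaults to $\lceil T/7 \rceil$ — roughly one node per seven samples,
which keeps wave-scale structure in the trend while smoothing sample noise;
it is a config knob because the right resolution is application-dependent.

## Linguistic fuzzy-logic forecaster (`ecgdx.lflf`)

**Evaluative expressions.** Values are described by *small / medium / big*
with hedges (extremely, significantly, very — narrowing; more-or-less,
roughly, quite-roughly, very-roughly — widening), rendered with the usual
abbreviations ("ml sm", "-me"). Memberships are trapezoids over a
normalized context [0, 1] anchored at 0 (small), 0.5 (medium) and 1 (big);
the exact breakpoints (see `_SM_SHAPES` / `_ME_SHAPES`) are package
defaults, exposed in code, since the full evaluative-expression calculus
is outside scope. Difference variables carry a sign, so their contexts are
symmetric $(-m, m)$ with the sign on the expression, plus an explicit zero
expression "ze" (narrow spike at 0, centroid exactly 0). The zero
expression is what makes a constant series forecast its own value exactly.
Two numerical guards: data ranges below 1e-9 (relative) count as constant,
and normalized signed values below 1e-9 count as exactly zero — otherwise
the ~1e-15 float jitter in the transform components of a constant series
would be stretched to full linguistic scale.

**Rule induction.** A signature such as `S(t)&dS(t) -> dS(t+1)` (S =
trend-cycle components, dS / d2S their first / second differences, with
time lags) defines one candidate rule per valid component index: each
variable is mapped to its best-matching expression. Duplicates merge with
summed support; contradictory rules (same antecedent expressions, different
consequents) keep the higher support, ties going to the earlier occurrence.
Rule order is canonicalized, so induction is deterministic.

**Deduction.** A simplified, deterministic stand-in for perception-based
logical deduction (the published method is not re-implemented): each rule
fires with the minimum membership of its antecedents at the current values;
the highest-firing rule wins (ties to the more specific rule); the output
is the centroid of its consequent expression mapped back to that variable's
context. If no rule fires, the nearest rule by antecedent-centroid distance
is used and the fallback is logged — deduction is total and never fails
silently.

**Forecasting.** Future components are generated by iterating deduction
from the end of the fitted component series; the uniform partition is
extended node by node and the inverse transform evaluated over the horizon.
The seasonal residual is forecast by a least-squares AR model without
intercept (the residual is zero-mean by construction); its order is chosen
by one-step error on the last quarter of the residual over orders 1..5
unless fixed. Trend and seasonal forecasts add up to the series forecast.

**Model selection and classification.** `select_best_predictor` fits one
model per signature in a menu (default: `S(t)->S(t+1)`, `dS(t)->dS(t+1)`,
`S(t)&dS(t)->dS(t+1)`, `S(t)&dS(t)&d2S(t)->d2S(t+1)`) and keeps the
validation-SMAPE minimizer, ties going to fewer antecedents. SMAPE is

$$\mathrm{SMAPE} = \frac{100}{T} \sum_t \frac{|F_t - A_t|}{(|A_t| + |F_t|)/2},$$

with an exactly-zero pair contributing 0. The healthy/sick classifier
appends the tested cycle to a healthy and to a sick learning series
(ten concatenated cycles, 1010 samples each), fits the best predictor on
each learning block with the tested block as validation, and declares
healthy iff SMAPE(healthy+tested) < SMAPE(sick+tested) — ties fall to
sick.

## Synthetic generator (`ecgdx.synth`)

Each cycle is a sum of five signed Gaussian deflections (P, Q, R, S, T)
plus white noise (sd 0.02 by default), 101 samples per cycle. Healthy
defaults: narrow dominant R (amplitude 1.0, sd 1.2 samples at index 42),
small P and T waves. Sick defaults: reduced and widened R (0.62, sd 1.5)
and an enlarged, widened T — the same kind of class-mean separation the
reference waveforms show, while noise keeps individual draws overlapping.
A 10-sample window across a Gaussian bump of sd ≈ 1.5 closely matches the
bump-shaped sick reference windows, and the falling edge after a narrow R
matches the edge-shaped ones, which is what makes the window classifier
exercisable end-to-end on purely synthetic data.

What the generator does **not** emulate: RR-interval variability,
multi-beat recordings, lead geometry, baseline wander, or the DC offset of
raw A/D converter output. The last point matters for interpretation: with
the baseline at zero, SMAPE values on synthetic series are large
(~120–140%) because the measure saturates near zero, whereas offset
hospital recordings give single-digit values. Classification only compares
the two SMAPEs, so the verdicts are unaffected, but absolute SMAPE
magnitudes from synthetic runs are not comparable to clinical ones.

Passing label-recovery tests on this generator therefore show that the
pipelines are implemented coherently and can separate two morphologies
whose class means differ — not that they would reach any particular
accuracy on real ECGs. On the synthetic cohorts both classifiers over-call
"sick" on healthy inputs (the pattern classifier because the healthy and
sick reference edges are nearly identical, the SMAPE classifier because
the sick learning series has lower amplitude); only sick recall is
asserted (≥70% for the window classifier, ≥8/10 for the SMAPE classifier),
and the asymmetry is reported as an observation.

`plant_pattern` writes an affine pre-image (random positive scale, random
offset) of a reference window into a series; min-max normalization is
affine-invariant, so the planted window normalizes back to the reference
row bit-for-bit.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script regenerate everything from seeds:
pattern training uses the 8 reference patterns (10 seeds for the
convergence check); the cycle net trains on 25+25 synthetic series; label
recovery uses cohorts of 20; the SMAPE classifier runs 10 sick tests
against two 1010-sample learning series; signature recovery uses 10
replicates of an 80-component planted process (second-order sustained
oscillation dX_{i+1} = dX_i − 0.3(X_i − 5), node spacing 7, noise sd 0.02).
The whole suite runs in well under a minute on one CPU.

## Known limitations

* Deduction is a simplified approximation; rule bases induced here are
  readable and deterministic but not equivalent to the published
  perception-based deduction calculus.
* Forecast horizons beyond one component step rely on iterated deduction;
  errors compound, and the fallback path (logged) becomes more likely far
  from the training range.
* The expression bank's trapezoid breakpoints are sensible defaults, not
  fitted quantities; downstream numbers (rule counts, centroids) depend on
  them.
* Multi-lead ECGs, beat segmentation and physiological realism are out of
  scope; inputs are pre-cut mono-lead 101-sample cycles.
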