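# Methods

## The optimization strategy

Cloud point extraction (CPE) yields are governed by eleven process factors of
mixed type: three categorical (surfactant type, salt type, number of CPE
steps) and eight continuous (surfactant concentration, solid:liquid ratio,
pH, equilibration temperature and time, salt concentration, centrifugation
speed and time). Three responses are maximized jointly: total phenolic
content (TPC, mg GAE/100 g dw), total carotenoids (TC, mg β-carotene/100 g
dw) and antioxidant activity (AA, μmol TE/100 g dw). The pipeline follows the
screen → fit → attribute → optimize → verify pattern:

1. a 12-run Plackett–Burman (PB) design screens all 11 factors at two levels;
2. a multilayer-perceptron surrogate maps the encoded factor settings to the
   three responses;
3. Yoon connection-weight sensitivity attributes response variation to
   factors;
4. an evolutionary multi-objective search over the factor space maximizes the
   three surrogate predictions and reports a Pareto front plus an
   equal-weights compromise optimum;
5. predictions at selected settings are compared with measurements via signed
   relative errors.

## Encoding and scaling

Categorical factors are one-hot encoded (full encoding, one column per
level); continuous factors enter as single columns. For the CPE space this
gives 8 + 2 + 2 + 2 = 14 model inputs, hence the reference network topology
14–7–3. The solid:liquid ratio is modelled as the continuous fraction
solid/liquid (1:50 → 0.02), not as a label. Inputs and responses are min–max
scaled to [0, 1] on the training table; a constant column scales to 0 and
inverts to its constant. Failed phase separations are recorded as exact zero
response triples and kept in the training table (a `drop_failed` escape hatch
exists).

Full one-hot makes each block collinear with the bias. That is harmless for
prediction but means the *split* of weight between a block's levels is not
identified — only level contrasts are. The sensitivity report therefore
offers three block aggregations (signed sum, default; absolute sum; and the
contrast max−min, which is the identified quantity and the one used for
ranking in the recovery experiment).

## Surrogate

A single hidden layer, activations from {identity, logistic, tanh,
exponential} on each of the hidden and output layers, trained by BFGS
(scipy, analytic gradients) on the summed squared error over all three
scaled responses, from uniform(−0.5, 0.5) initial weights. Parameter count is
`n_in·n_h + n_h + n_h·n_out + n_out` — 129 for (14, 7, 3). Convergence:
gradient norm 1e-8 or 500 iterations (both configurable). One failed start is
retried once from a derived sub-seed.

`search` trains `n_restarts` networks per (hidden size, activation pair),
with sub-seeds that are a pure function of (seed, size, pair, restart), so
enlarging the restart budget strictly extends the candidate set. Selection is
by mean training r² across responses (ties: fewer neurons, lower loss, lower
restart index), or by mean r² on a held-out table when one is supplied.
Defaults are 16 hidden sizes (5–20) × 16 activation pairs × 2 restarts; the
original study's 100,000-network search is reachable by raising
`n_restarts`, but a few hundred candidates already saturate the selection on
12-run tables, where every candidate with ≥ 5 hidden neurons has more
parameters than runs and interpolates. The search log flags this regime:
training r² = 1.000 there certifies interpolation, not generalization, which
is why model selection on larger simulated campaigns uses held-out r²
instead.

With identity activations on both layers the network family is exactly the
affine family, so the best achievable training loss equals the
ordinary-least-squares loss — used as a cross-check (normal-equations oracle)
in the tests. r² is computed on original units; with a perfect fit the
normalized/original distinction vanishes.

## Yoon sensitivity

RI(i, j) = Σₖ W[i,k]·V[k,j] / Σᵢ'|Σₖ W[i',k]·V[k,j]| × 100, biases excluded,
computed from the weights as trained on the scaled data (so influences are
unit-free and comparable). By construction |RI| sums to 100% per output. For
identity networks RI equals the normalized coefficients of the equivalent
linear model; for nonlinear networks it is the standard connection-weight
heuristic and is read qualitatively (reference: Yoon, Swales & Margavio,
1993).

## Multi-objective optimization

NSGA-II-style loop, maximizing the three predicted responses: binary
tournament on (non-domination rank, crowding distance), BLX-0.5 blend
crossover and Gaussian mutation (σ = 5% of range, clipped to bounds) on
continuous genes, uniform crossover and uniform resampling on categorical
genes, crossover probability 0.9, per-gene mutation probability 1/n_genes,
elitist (μ+λ) survival. Defaults: 36 generations, population 100 — the
study's reported budget. The final population is reduced to its non-dominated
set (verified by an O(n²) brute-force check in the tests), and the
compromise optimum maximizes the equally weighted sum of front-normalized
objectives (ties → first front member). Continuous search bounds default to
the full explored ranges (e.g. pH 1.5–7.5, 35–75 °C, 2473–9892 g,
10–20 min), which is how interpolated optima between screening levels arise.

On discrete spaces the GA recovers the exact enumerated Pareto front; on
continuous spaces it approximates a continuous front, so individual front
members can sit within numerical slack of the true surface — the oracle
-equivalence test therefore uses a fully discrete space, and front quality on
continuous spaces is asserted via the brute-force non-domination check and
the ground-truth recovery below.

## Response-surface simulator

The noiseless truth is a per-factor product:
`R_j(x) = gate(x) · B_j · Π_f m_{j,f}(x_f)`, with per-response baselines
`B_j`, piecewise-linear multiplier profiles for continuous factors,
per-level multipliers for categorical factors, and declarative gates that
zero all responses (no phase separation). The default configuration mirrors
the qualitative one-factor findings for this system: saturating surfactant
concentration effect, solid:liquid ratio peaked at 1:50, pH optimum low
(pH 3) for phenolics/antioxidant activity but higher (pH 4.5) for
carotenoids, temperature peaked at 45 °C, mildly decreasing equilibration
time, decreasing centrifugation speed and time, a much weaker second CPE
step, and gates for non-clouding surfactants (Span 85, Ceteareth-12),
non-separating salts (KCl, CaCl₂) and salt below 16%. Magnitudes are
order-of-magnitude matches to the printed one-factor tables, not fits;
baselines (352.5, 32.5, 989) put the optimum response triple near the
study's reported optimum. Replicate noise is multiplicative log-normal with
CV 2.5% per response (the printed ± values are roughly 1–3% of their means);
gated runs stay exactly zero. The stated optimum (Tween 80, 10%, 1:50, pH 3,
45 °C, 20 min, NaCl, 16%, 2473 g, 10 min, one step) is the per-factor argmax
of the equal-weights normalized-response sum; because the surface factorizes,
coordinate optimality is verified exhaustively over the scan grids in the
tests.

What the simulator does *not* emulate: factor interactions beyond the
product structure, heteroscedastic or correlated assay errors, drift between
replicate batches, and the discrepancies present in the real screening table
(e.g. KCl runs with non-zero responses). Passing recovery therefore shows
the pipeline recovers a smooth gated multiplicative surface from noisy
designed data — not that a 12-run screen suffices for real systems.

## Recovery experiment

`recovery_experiment` simulates a full campaign over the two-level screening
space: the PB design, OVAT grids around the stated optimum, a 300-point
Latin-hypercube sample over the whole space (which teaches the gates) and a
1200-point sample restricted to the phase-separating region (NaCl, salt
16–18%), each in triplicate. A two-level screening design alone carries no
curvature information, so interior optima (45 °C, 1:50) would be
unidentifiable from it; the space-filling samples supply the curvature. The
surrogate search runs hidden sizes (10, 12, 14) × {tanh/identity,
tanh/exponential} × 3 restarts with selection by held-out r² on a separate
simulated sample (the exponential output matches the multiplicative truth:
exp of a sum of hidden units models a product of per-factor terms). A trust
check rejects candidates whose optimized compromise predicts responses above
1.5× the observed maxima — exponential nets can explode in data-free corners
of the 14-dimensional space, and an optimizer will find such artifacts.

Sensitivity screening is computed, as in the emulated study, on the
PB-stage model (identity activations), where the orthogonal design isolates
the salt-type gate that the pooled campaign confounds with the
salt-concentration gate; factors are ranked by the contrast aggregation.

The report checks: categorical levels of the compromise match the stated
optimum exactly; continuous levels land within 10% of each factor's range;
and the top-ranked factor is among the true largest effects. At the default
seed the experiment passes with worst-factor offsets of 4–8% of range;
across other seeds the surrogate (not the optimizer, which lands within 0.5%
of the optimum when given the noiseless truth) occasionally misses one
interior peak by ~10–25%, an honest picture of surrogate-based optimization
at this noise level and campaign size. One run takes ~45 s on one CPU.

## Verification arithmetic

Relative error is (model − experimental)/experimental × 100, rounded
half-away-from-zero to 2 decimals — the convention that reproduces the
reported −3.54% for sample 6 total phenolics. Under the same convention the
sample 10 carotenoid pair (5.11 vs 5.37) gives −4.84%, not the −4.72%
printed in the source prose; the package reports the value recomputed from
the table. Percentage shares round to the nearest integer; table-sum checks
use the print precision (0.01) as tolerance.

## Numerical and reproducibility choices

- All randomness flows from explicit seeds through `numpy.random.SeedSequence`
  hierarchies; stage sub-seeds are pure functions of the top-level seed.
- Fixed seeds give bit-identical refits, simulations, fronts and pipeline
  artifacts (asserted in tests).
- Exponential/logistic pre-activations are clipped at ±50 to avoid overflow.
- Out-of-range continuous settings warn on encoding and are clipped to bounds
  inside the optimizer.
- Degenerate cases: zero-variance response columns yield NaN r² with a
  warning; all-zero connection-weight products yield NaN influence with a
  warning; constant scaled columns map to 0 and invert exactly.

## Known limitations

- No regularization, cross-validation or uncertainty quantification in the
  surrogate; on 12-run tables the fit is an interpolation by design.
- The PB generator supports exactly the N=12 construction for 11 two-level
  factors; the bundled screening table is loaded as printed rather than
  regenerated (its specific row assignment is honored via fixture).
- Yoon influence on nonlinear networks is a weight-product heuristic; the
  package computes it as specified but ranks recovery results from the
  identity-activation screening fit.
- The GA handles box bounds and level sets only; no general constraints.
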