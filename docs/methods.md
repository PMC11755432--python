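# Methods

## Model

The endpoint (a scalar per molecule; the motivating case is log10
NOEL/NOEC in mg/kg bw/day for long-term avian toxicity) is modelled as
an affine function of the optimal descriptor,

    LTT = C0 + C1 · DCW(T, N),
    DCW(T, N) = Σ CW(Sk) + Σ CW(SSk) + CW(XYX) + CW(XYYX) + CW(XYZYX).

The descriptor is purely string-based. A SMILES line is tokenized into
SMILES atoms — single characters, the two-letter halogens `Cl`/`Br`,
complete bracket expressions `[...]`, and `%nn` ring closures; no
chemical interpretation, canonicalization or sanitization happens
anywhere. Sk are the tokens themselves (weights enter once per
occurrence). SSk are adjacent token pairs; the canonical label puts
the byte-wise greater token first (`O...=` covers both `O=` and `=O`),
padded with dots for display. FLS (fragments of local symmetry) are
palindromic windows of the raw character string — XYX (`s[i]==s[i+2]`),
XYYX (`s[i]==s[i+3] ∧ s[i+1]==s[i+2]`) and XYZYX
(`s[i]==s[i+4] ∧ s[i+1]==s[i+3]`, Z unconstrained) — counted with
overlaps and encoded per molecule as the three count codes `[xyxN]`,
`[xyyxN]`, `[xyzyxN]`, each contributing one weight. FLS scanning
deliberately operates on raw characters, including parentheses,
digits and the letters inside multi-character tokens: the descriptor
treats the SMILES line as a string, and the reference worked examples
count bracket/digit windows as matches. A `use_fls=False` mode drops
the three codes from the vocabulary entirely, which is the ablation
for measuring what local symmetry contributes.

An attribute is *active* if it occurs in at least T active-training
molecules (T = 1 by default: seen once is enough). Inactive and unseen
attributes have weight pinned to zero — at prediction time they
contribute nothing, but they do count toward the applicability-domain
defect. Attribute frequencies NA/NP/NC count molecules containing the
attribute, not occurrences.

## Data protocol

Records are `(id, SMILES, value)`. Curation keeps, for duplicate
SMILES strings (exact string match — all SMILES are assumed to come
from one generator), the lowest endpoint value, i.e. the most toxic
observation; values are then log10-transformed (raw values must be
positive; the transform flag prevents double application). A seeded
shuffle splits the data into active training / passive training /
calibration / validation sets with largest-remainder ~25% sizes
(139 molecules give 35/35/35/34). Each set has one job: tune the
weights; check they transfer; detect overtraining; assess prediction.

## Optimization

The weights of all active attributes are tuned by maximizing

    TF = R²_A + R²_P − 0.1·|R²_A − R²_P| + 0.3·CII + 0.5·IIC,

where R²_A, R²_P are determination coefficients of the descriptor
against the endpoint on the two training sets, and IIC and CII are
computed on the calibration set from the predictions of the final-line
regression refitted on the active set after every accepted move. The
0.1/0.3/0.5 weights are the method's standard coefficients and are
config-exposed.

The search is a seeded stochastic hill-climb. One epoch visits every
active attribute once in seeded-random order; a visit probes, in order,
a reset of the weight to zero, then steps of ±D, ±D/2, ±D/4 (D = 0.1,
three probe scales by default). A change is kept only if TF strictly
increases, so TF is monotone over accepted moves. Design points the
method description leaves open were resolved as follows, for reasons
the planted-signal simulations made concrete:

* **Zero initialization.** Every term of TF is invariant under
  rescaling all weights, so an initial weight scale carries no
  information — it only injects variance the search must undo. With
  all weights starting at zero, the early accepted moves build the
  descriptor up one attribute at a time, the way stagewise regression
  traces a regularized path; this recovered planted signal far better
  than random positive initialization in simulation. The zero-reset
  probe serves the same purpose later in the run: it prunes attributes
  whose weight only adds noise.
* **Paired substitution probes.** Attribute columns of SMILES data are
  strongly collinear (pair counts track atom counts, FLS codes track
  length), and single-weight moves stall in ratio-locked local maxima.
  Each epoch therefore adds `pair_probe_factor × n_attributes` paired
  probes — one weight up, a partner down (all four sign combinations)
  — with the partner sampled in proportion to the absolute
  co-occurrence correlation of the two attributes' multiplicity
  columns on the active training set. The proposal distribution uses
  the design matrix only, never the endpoint.
* **Overtraining snapshot.** The run always completes its N epochs
  (N = 15 default), but the reported weights are the snapshot at the
  accepted move where calibration R² peaked — the start of
  overtraining, tracked move-by-move rather than per epoch.
* **Restarts.** A single stochastic climb commits early to whichever
  improving attribute it visits first, which makes single runs
  high-variance. The optimizer runs `restarts` (default 5) independent
  climbs from sub-seeds derived from the run seed and keeps the
  candidate with the highest target function at its snapshot.

All randomness flows from one integer seed through
`numpy.random.default_rng` (PCG64, recorded in the model file);
identical (dataset, config, seed) triples reproduce the weight table
bit for bit. Multi-run interpretation uses seeds `seed … seed+n−1`.

After optimization, (C0, C1) and their standard errors come from
ordinary least squares of the endpoint on DCW over the active set.

## Statistics panel

All statistics use population (divide-by-n) variances. R² is the
squared Pearson correlation; CCC is Lin's concordance coefficient;
RMSE/MAE are standard; F = r²(n−2)/(1−r²) for the univariate
regression, rounded to an integer in reports. Q² is exact leave-one-out
PRESS of the univariate regression via the hat-matrix closed form
(equal to n explicit refits). IIC is the Pearson r damped by the ratio
of the smaller to the larger of the mean absolute errors of negative
and positive residuals (ratio 1 when either class is empty or the
larger error is zero). CII is 1 − Σ_k max(0, R²₍₋ₖ₎ − R²), computed
from leave-one-out running sums; a removal that leaves a constant
vector contributes zero. Undefined cases (constant inputs, r² = 1 for
F) raise a dedicated error rather than returning NaN. By convention
the validation set reports only R²/RMSE/MAE — it takes no part in
model development — with a flag to unlock the full panel.

One property sometimes claimed for CII — that appending a point
exactly on the regression line can never lower it — is false for the
protest formula (the new point changes every leave-one-out R², not
just its own); simulation finds small decreases. The tests therefore
assert the verified properties (CII ≤ 1, single propping outliers
lower it, exact agreement with explicit LOO refits) instead.

## Interpretation and applicability domain

Promoter analysis classifies every active attribute over several
independent runs: weight > 0 in all runs → increase-promoter;
< 0 in all runs → decrease-promoter; otherwise unstable. Reports sort
by active-training frequency, since conclusions about rare attributes
rest on few molecules.

The statistical defect of attribute A is d(A) = |P − P′| / (P + P′)
with P, P′ the fractions of active-training and calibration molecules
containing A (d = 0 when both are 0; d = 1 for attributes absent from
training). A molecule's defect sums d(A) over its attributes with
multiplicity — multiplicity-inclusive because a rare attribute
occurring five times is five times the extrapolation. A molecule is in
the domain if its defect is below `defect_cutoff_factor` (default 2)
times the mean defect of the active-training molecules; both the
formula and the cutoff are config-exposed.

## Synthetic data generator

Real curated avian-toxicity tables cannot be redistributed, so the
generator emulates one: SMILES-like strings over the token set
{C, c, N, n, O, S, P, Cl, Br, =, (, ), 1, 2, 3} with balanced
parentheses, paired ring digits, and branches/bonds only after atoms
(6–21 atoms per molecule). The endpoint is

    y = c0* + c1* · Σ_a w*(a) · mult(a) + Normal(0, noise_sd),

with planted weights w* ~ N(0,1) on (default) 10 attributes drawn from
those present in ≥ 20% of molecules, and (c0*, c1*) scaling the
noiseless signal to mean −0.5 and SD 0.8 — the range of a logged
mg/kg bw/day endpoint, matching intercepts near −2 in the motivating
models. The default `noise_sd = 0.08` is 10% of the signal SD; the
default 140 molecules mirror the motivating dataset size. The planted
truth is returned so tests can measure recovery.

What the generator does not emulate: real chemical grammar (rings that
close plausibly, valence), the long-tailed frequency distribution of
real substructures, activity cliffs, and measurement error structure
beyond i.i.d. Gaussian noise. Passing recovery tests therefore shows
the search can identify a sparse additive signal under realistic
collinearity and sample sizes — not that real toxicity data meet those
assumptions.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at the
motivating scale (140 molecules, ~130 active attributes, 15 epochs,
5 restarts; about half a minute per fit on one CPU) and use smaller
60–100-molecule fixtures for unit-level checks. Ties in the
hill-climb are rejected (strict improvement) to guarantee
monotonicity; TF evaluation guards division by zero by treating
constant-descriptor candidates as invalid moves; weight tables
serialize weights via `repr` (17 significant digits) for exact
round-trips. Exhaustive FLS validation enumerates all strings to
length 7 over a 5-symbol alphabet (~10⁵ strings) plus seeded longer
samples; window counts are sums of independent per-position
indicators over ≤ 5-character windows, so any disagreement would
already appear on the short strings the sweep covers completely.

## Known limitations

* Single-descriptor models only: no multi-descriptor regression, no
  nonlinearity beyond what attribute counting captures.
* The search optimizes TF greedily; it finds good, not provably
  optimal, weights, and different seeds give different (similarly
  scoring) models — which the promoter analysis turns into a feature.
* Validation R² of ~0.6–0.8 on planted-signal data at n = 140 is the
  realistic ceiling for weight tuning on 35-molecule active sets; the
  information in the three development sets bounds what any method of
  this family can recover.
* The applicability-domain cutoff is a convention (2× mean training
  defect), not a calibrated error bound.
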