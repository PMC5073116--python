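# Methods

## Signal model

The package works with the mono-exponential (cumulant-truncated) kurtosis
model of directionally averaged diffusion-weighted MRI:

    S(b) = S0 · exp(−bD + K·(bD)²/6)

with S0 the signal at b = 0 (arbitrary units), D the apparent diffusion
coefficient (µm²/ms) and K the dimensionless excess kurtosis (K = 0
recovers mono-exponential decay).  The exponent depends on the
acquisition only through the dimensionless product bD, so all design
results are expressed on a bD axis and transfer to any tissue by
b = bD/(D·10⁻³) s/mm².  The unit convention is fixed throughout:
b in s/mm², D in µm²/ms, bD = b·D·10⁻³.

The model is only a valid description of signal decay up to
(bD)max = 3/K, the point where the truncated expansion stops decreasing;
the optimizer never places points beyond it, and the CLI warns when a
user protocol does.

## Covariance (Cramér–Rao style) error analysis

For m acquisitions b₁…b_m the m×3 design matrix A holds the model
sensitivities (∂S/∂S0, ∂S/∂D, ∂S/∂K) at each b, divided by the noise SD
σ₀.  The estimate covariance is approximated by Q = (AᵀA)⁻¹, the
per-parameter coefficient of variation by CoV_i = √Q_ii / a_i
(normalized by the *target* value a_i), and the overall error by
trace(Q).  Column order is fixed as (S0, D, K), so Q₂₂ is var(D) and
Q₃₃ is var(K).

Assumptions: additive Gaussian noise of equal SD at every b (valid for
magnitude MR data when SNR ≳ 4; below that the Rician character
dominates and the analysis is flagged as unreliable), and local
linearity of the model around the true parameters — see "Validity at
clinical SNR" below for where that second assumption bites.

Noise is parametrized by the SNR at b = 0: σ₀ = S0/SNR, with S0
normalized to 1 in all dimensionless computations; the reference SNR is
20 everywhere (hence CoV_S0 = 0.05 in the design tables).  Because A is
proportional to 1/σ₀, every CoV scales exactly as 1/SNR, and echo-time
changes enter through the signal-fading factor exp(TE/T₂); `rescale_cov`
applies both without recomputing Q.

Numerics: Q is obtained by solving AᵀA·Q = I rather than forming an
explicit inverse; designs with cond(AᵀA) > 10¹² (default) raise a
`SingularDesignError` naming the protocol instead of returning absurd
CoVs.  Fewer than three distinct b values is always singular.

## Protocol optimization

Designs are multisets of n grid points on a bD lattice (default step
0.05, which resolves all published optima: 0.75, 0.9, 0.95, 1.05, 1.1
all lie on it) spanning [0, min(3/K, scanner bound)].  If the upper
bound does not fall on the lattice it is appended as a grid point, since
the optimum invariably uses the maximum allowable weighting.  b = 0 is a
grid point but is never forced into a design; it emerges as part of
every optimum, which is a useful end-to-end check of the search.

Two enumeration modes:

- **exhaustive** — all C(g+n−1, n) multisets of g grid points (default
  for n = 3);
- **support_points** — all designs with at most 3 distinct values
  (default for n ≥ 4).  A 3-parameter model needs no more than 3 support
  points in a locally optimal design, repeats acting as averaging; all
  known optima obey this, and it keeps n = 4, 5 searches tractable.  The
  two modes agree wherever both are feasible (tested on coarse grids).

The default objective is CoV_D + CoV_K (optimizing both tissue
parameters jointly); CoV_D, CoV_K and trace(Q) are available.  Candidate
scoring is vectorized: per-grid-point outer products of the sensitivity
rows are pre-computed, candidate information matrices are summed in
chunks, and the needed diagonal elements of the inverse come from the
closed-form cofactor expressions for a symmetric 3×3 matrix; matrices
whose determinant is below 10⁻⁹ of their scale cubed, or with a
non-positive inverse diagonal, are skipped as singular (and counted).
The winner is re-verified with the exact, condition-checked covariance
routine.  Exact objective ties are broken by the lexicographically
smallest sorted design, so results are deterministic bit-for-bit.

The 0.05-grid exhaustive search recovers the full published
3-acquisition design table in about two seconds on one core, and the
support-point search the complete 18-cell table (n = 3–5) in about
fifteen seconds.

`robustness_sweep` evaluates a fixed design over a range of true D or K
values (the design was made for target values; tissue varies), flagging
rather than failing on invalid points.  At the head-and-neck target
(D = 0.86 µm²/ms, K = 1.5) optimized designs beat equally spaced ones
at every n — the package reproduces this as a property, not as digitized
curve values.

## Monte-Carlo verification

For a protocol and target tissue the verifier simulates the clean
signals, adds noise, refits, and repeats:

- **Gaussian noise**: independent N(0, σ₀) at every b.
- **Rician noise**: |S + x + iy| with x, y ~ N(0, σ₀) — exactly the
  magnitude-image noise distribution; at S = 0 it reduces to Rayleigh.

The refitter is a batched, bound-constrained Levenberg–Marquardt solver
written for this package: all repetitions advance in lockstep, each
iteration solving one damped 3×3 normal system per repetition, with
per-problem damping and an active-set treatment of the box bounds
(coordinates pinned at a bound with an outward gradient are frozen for
the step).  This makes 10⁴-repetition runs take ~0.1 s where a
per-repetition call to a generic optimizer takes minutes;
`scipy.optimize.least_squares` serves as the independent cross-check in
the tests, not as the engine.  Convergence requires a small projected
gradient or stalled relative cost improvement (10⁻¹²); non-converged
fits are discarded and counted (default policy), and a run with more
than 50% failures raises.

Defaults, chosen to study estimator noise rather than global-search
behavior: fits start at the true parameters inflated by 10% (a
log-quadratic initialization — the model's exponent is linear in
(log S0, D, KD²/6) — is available instead); box bounds are
S0 ∈ (0, 10·s0], D ∈ (0, 10·d], K ∈ [0, 10].  The K ≥ 0 bound is
physically motivated and *does* bind at SNR 20 for low-kurtosis targets
(for K = 0.3 designs roughly 40% of refits end pinned at K = 0; the
result reports `n_bounded`).  Repetition default is 10⁴ (standard error
of a CoV ≈ CoV/√(2·reps) ≈ 0.7%); larger runs scale linearly.

Empirical CoV is sample SD divided by the true parameter (matching the
covariance analysis' normalization), with SD/mean reported alongside.

## Validity of the covariance prediction at clinical SNR

The covariance matrix is a linearization — a lower bound attained by the
NLS estimator only asymptotically.  The Monte-Carlo verifier shows, and
a fitter-independent check confirms, how far the attainment goes at
SNR 20:

- **CoV_D and CoV_S0 are predicted accurately**: empirical values agree
  with √Q_ii/a_i to within a few percent on every published design.
- **CoV_K is underpredicted.**  K enters the signal only at second order
  in bD, so its estimator is strongly non-linear at clinical noise
  levels.  For three-point designs the NLS fit interpolates the data
  exactly, which makes the estimator available in closed form (a
  log-quadratic through the three points): at SNR 20 even the central
  68% width of the K-estimate distribution exceeds the covariance SD by
  ~13% for the {0, 0.75, 2}, K = 1.5 design, and the full-sample SD by
  far more (heavy left tail).  At SNR 100 the same closed form matches
  the covariance value to ~2%, confirming the analysis is correct in its
  asymptotic regime.  For low-K targets (K ≤ 0.5) the signal at the
  maximum weighting is at or below the noise floor and the empirical
  CoV_K is dominated by the K ≥ 0 bound, falling *below* the covariance
  value.
- **Rician vs Gaussian noise**: at SNR 20 the two give CoVs within a few
  percent of each other for K ≥ 0.8 designs; for low-K designs the
  Rician noise floor at the near-zero high-b signals biases the fit and
  the two noise models diverge (the Gaussian-noise analysis is the
  optimistic one there).

Practical reading: the covariance optimizer still ranks designs
correctly (the Monte-Carlo ordering of optimized vs equally spaced
designs matches), and its CoV_D values can be taken at face value, but
printed CoV_K values at SNR 20 are best-case figures, increasingly so
for small K.  Acceptance tests encode the nominal 10%/15% agreement
claims as stated and are expected to fail on the cells described above;
they are kept failing rather than loosened, as an honest record of where
the linearized analysis leaves its comfort zone.

## What the synthetic conditions do and do not cover

The Monte-Carlo generator emulates a single-voxel (or single-ROI)
measurement: one tissue compartment exactly following the kurtosis
model, equal noise at every b, independent acquisitions.  It does not
emulate multi-compartment or directional diffusion, spatially correlated
noise, motion, eddy currents, or model mismatch from higher cumulant
terms near (bD)max.  Passing tests therefore demonstrate the estimator
statistics under the stated model, not protocol performance on real
scans.

## Known limitations

- The covariance analysis assumes Gaussian noise; no Rician-aware bound
  is computed (SNR < 4 is out of scope and flagged).
- Protocol optimization is discrete; no continuous (gradient-based)
  design refinement is attempted beyond the 0.05 lattice.
- The number of acquisitions n is an input, not optimized against a
  scan-time budget.
- The three flagged entries of the published reference tables (see the
  test fixture) are inconsistent with their own printed designs and are
  treated as typographical; all other ~100 entries reproduce to print
  precision.
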