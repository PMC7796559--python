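# Methods

This note documents the models behind each `depsikin` stage, the defaults
and their rationale, what the synthetic-data generators emulate (and what
they do not), and the numerical choices made where the design was open.

## 1. EXSY exchange kinetics by matrix logarithm (`depsikin.exsy`)

**Model.** For slow chemical exchange among `n` magnetic sites the mixing-time
evolution of longitudinal magnetization is first order,

```
M(tm) = expm(L · tm) · M(0),     L = K − R,
```

where `K` holds the site-to-site rate constants (entry `L[i, j]`, `i ≠ j`,
is the transfer rate from site `j` into site `i`) and `R` the auto-relaxation
rates on the diagonal.  Normalizing the measured EXSY volume matrix column-wise
by the per-site relative 1H intensities ("magnetic fractions", an
approximation of `M(0)`) gives the transfer matrix `A = M · M0⁻¹`, and

```
L = ln(A) / tm
```

recovers the full rate matrix from a single mixing time.  Off-diagonal
entries are the site-to-site exchange rates; diagonals carry minus the
outgoing rates minus `R1`.  Because volumes and magnetic fractions are
typically recorded in different arbitrary units, `A` equals `c · expm(L·tm)`
for an unknown scalar `c`; `ln` turns that into a uniform additive shift of
the diagonal (absorbed into the reported `R1` estimates) and leaves every
off-diagonal rate untouched.  The reported auto-relaxation rates are therefore
estimates *up to a common additive constant* unless volumes and fractions
share one unit.

**Symmetry bookkeeping.**  In a C2-symmetric macrocycle the transition from
the symmetric conformer (site A, one resonance for the equivalent pair) to
the asymmetric conformer (sites B and C) proceeds along two chemically
equivalent pathways, A↔B and A↔C; the B↔C pathway does not exist.  The
extractor averages the two off-diagonal entries of each declared
symmetry-equivalent pathway set, reports the larger average as `k1` and the
smaller as `k2` (matching how the rates are tabulated for these compounds;
the assignment can be overridden via `ExchangeNetwork.k1_group`), and
reports the raw per-pathway entries alongside.  Mechanistic rates correct
for pathway degeneracy: from the symmetric state each nucleus takes either
pathway with equal probability, so the conformational rate is twice the
per-pathway rate, `k1' = 2·k1`, while `k2' = k2`; without C2 symmetry both
are equal to the site rates.  `K_eq` is defined as `k1'/k2'` — the ratio of
the two mechanistic rates *as named here*; the underlying direction
convention of literature `k1`/`k2` labels for these compounds is ambiguous,
so no thermodynamic interpretation is attached.

**Numerics.**
* Matrix log via real eigendecomposition; if the eigenvector condition
  number exceeds `1e8` a Schur-based real logarithm
  (`scipy.linalg.logm`) is used instead.  The matrices are small (3×3) but
  experimentally noisy.
* Eigenvalues must be positive with relative imaginary part below `1e-8`
  (configurable).  Violations are a hard error naming the offending
  eigenvalue: a complex or negative spectrum means the volumes are not
  consistent with first-order exchange, and silently taking real parts
  would fabricate rates.
* Averaged rates in `[−0.005, 0)` s⁻¹ are reported as-is with a warning
  (consistent with the ~20% volume error of cross-peak integrals); larger
  negatives fail validation.
* Missing cross-peaks may be entered as volume 0 (the forbidden B↔C
  entries of the shipped worked example are 0).  Low-intensity conformers
  that cannot be integrated are simply absent from the network.
* Reported rates are rounded to two decimals in s⁻¹ for tables; full
  precision is kept internally and in JSON output.

**Uncertainty.**  With one mixing time there is no analytic error estimate;
`rate_uncertainty` perturbs every volume by an independent multiplicative
factor, uniform on `[1−f, 1+f]` by default (lognormal optional), re-runs
the extraction, and reports medians with central 68%/95% intervals.
Replicates whose matrix log fails are counted and excluded.  At `f = 0.2`
(the assumed volume error) the worked example gives k1 ∈ [0.13, 0.19] s⁻¹
and k2 ∈ [0.08, 0.12] s⁻¹ (95%), computed at run time by
`analysis/01_exsy_rates.py`.

## 2. Coupled conformer/binding equilibria (`depsikin.binding`)

**Model.**  Three coupled equilibria describe a titration of the macrocycle
with a monovalent salt:

```
A ⇌ S           Kc  = [S]/[A]          (salt-independent pre-equilibrium)
S + M ⇌ SM      K1  = [SM]/([S][M])    (1:1 complex)
SM + S ⇌ S2M    K2  = [S2M]/([SM][S])  (2:1 sandwich)
```

Only the symmetric conformer binds; the asymmetric conformer is treated as
non-binding with a salt-independent shift (its small shift changes at high
salt are neglected).  Anion and activity effects are ignored;
concentrations stand in for activities, as is usual when constants are
fitted directly to concentration series.  Whether `K2` carries a
statistical factor is a convention absorbed into the fitted number.
Mixed 2:1 complexes (one symmetric + one asymmetric unit) are excluded from
the default species list.

**Observables.**  All symmetric species are in fast exchange, so the
reporter proton shows one population-weighted line,
`δ = (S·δ_S + SM·δ_SM + 2·S2M·δ_S2M)/(S + SM + 2·S2M)`, with peptide-unit
weights.  The conformer ratio from integration is
`A/(S + SM + 2·S2M)`.

**Speciation solver.**  The free-ion concentration `m` is the single root
variable.  Given `m`, the peptide balance is a quadratic in free `[S]` with
positive coefficients, solved in the numerically stable closed form; the
ion-balance residual is then monotone in `m` and bracketed on
`[0, M_total]`, so `brentq` converges deterministically.  Mass-balance
residuals are recomputed by substitution and kept below `1e-12` relative.

**Two structural facts the model encodes** (both are tested):

* With `K2 = 0` the observed shift is monotone in salt — an interior
  extremum of a titration curve therefore implies a third symmetric
  species.  Note the direction of the signature: the sandwich dominates at
  *low* salt (`S2M/SM = K2·[S]`, and `[S]` falls as salt rises), so a
  drop–minimum–rise curve needs `δ_S2M` below the free-peptide shift with
  `δ_SM` above it (or the mirror image).
* The "lag" — more salt needed to reach a 1:1 conformer ratio than a 50%
  shift change — already follows from the pre-equilibrium plus 1:1 binding
  alone.  With `K2 = 0` the ratio crossing requires `K1·[M] = 1/Kc − 1` and
  the half-shift `K1·[M] = 1`, so the lag is nonnegative exactly when
  `Kc ≤ 1/2`.  All compounds this model targets are strongly
  asymmetric-dominant (`Kc ≤ 1/3`), and the package asserts the property on
  that family.  The lag vanishes only in the joint limit of symmetric
  dominance, strong binding *and* vanishing peptide concentration — at
  finite peptide the half-shift point cannot drop below the stoichiometric
  bound of roughly half the symmetric total.

**Fitting.**  Weighted least squares with residual vector combining shift
residuals (ppm) and `sqrt(λ)`·log-ratio residuals (`λ = 1` by default),
minimized with `lmfit`'s Levenberg–Marquardt from 32 seeded multistarts
(constants perturbed log-uniformly within ±1.5 decades, shifts uniformly
within the observed span).  All local optima within 1% of the best loss and
differing by more than 5% in some free parameter are reported — titration
data of this kind are notoriously under-determining, and surfacing the
degenerate solutions is the package's way of keeping the analysis honest.
Non-identifiable requests (e.g. freeing `δ_S2M` while `K2` is fixed at 0)
are rejected up front.  Two usage modes exist for ratio data: fitted
jointly with shifts (default) or ignored (`ratio_weight = 0`) when the
ratios are instead used upstream to fix the symmetric totals.

**Damped logistic.**  For descriptive curve summaries a five-parameter
empirical form `y0 + L/(1 + exp(−k(c − c0)))·(1 + d·c)⁻¹` is provided; the
baseline `y0` reflects the nonzero symmetric population at zero salt.  It
is a summary device only and feeds no derived quantity.

## 3. Markov-state-model pipeline (`depsikin.msm`)

**Featurization.**  Backbone dihedrals (degrees, in `(−180, 180]`) are
embedded as interleaved `(sin, cos)` pairs, removing the periodic
discontinuity at ±180°.

**TICA.**  The symmetrized generalized eigenproblem `C(τ)v = λC(0)v` is
solved with covariances accumulated over all trajectories (forward and
time-reversed pairs averaged, one global mean) and a small ridge
(`1e-10` × mean variance) on `C(0)`.  The number of retained components
defaults to the smallest set explaining 95% of the kinetic variance
(`Σλᵢ²`), overridable; distances downstream are Euclidean in that space.

**CNN clustering.**  Two retained points are density-connected iff their
distance is ≤ `cutoff` *and* they share ≥ `similarity` common neighbors
within `cutoff`; clusters are connected components of this relation.
Before connecting, the lowest-density fraction of points (default 20%,
ranked by neighbor count with coordinate tie-breaks so the result is
independent of input order) is discarded as noise.  Common-neighbor counts
use a dense boolean adjacency with a BLAS product for ≤ 4000 points and a
sorted-array intersection over the KD-tree pair list above that; the
algorithm is inherently quadratic in dense neighborhoods, so large
trajectory sets should be clustered on a subsample or with a tight cutoff.

**Counting and connectivity.**  Sliding-window counts at lag τ; noise
frames break the chain (no count across a gap) rather than being imputed —
discarded frames must not fabricate dynamics.  No effective-count
correction is applied to the overlapping windows; bootstrap uncertainties
operate at the trajectory level, which sidesteps the window-overlap
correlation.  The model is estimated on the strongly connected state set
carrying the most counts; discarded states are reported with the ids of
the trajectories that visited them, so a state set populated by a single
simulation can be recognised and dismissed as sampling noise.

**Reversible estimation.**  Maximum likelihood under detailed balance via
the classic self-consistent iteration on symmetric fluxes
`x_ij ← (C_ij + C_ji)/(c_i/x_i + c_j/x_j)`, iterated until the largest
change is < 1e-12 (cap 10⁶ sweeps).  Row-stochasticity, `π`-invariance and
detailed balance are asserted as typed invariants on every constructed
model.  For symmetric count matrices the estimator returns row-normalized
counts exactly.

**Validation.**
* *Implied timescales* `tᵢ(τ) = −τ·dt/ln λᵢ(τ)` across lags, with
  2.5–97.5% bands from resampling whole trajectories with replacement.
  Lags are specified in physical units and must be integer multiples of
  the frame spacing (no silent rounding).
* *Chapman–Kolmogorov*: `T(τ)^k` vs a model re-estimated at `kτ`
  (diagonal occupation per state), `k = 1` exact by construction, with the
  same trajectory bootstrap for bands.
* *Symmetry diagnostic*: states that are chemically identical up to the
  C2 rotation of the symmetric conformer must have equal stationary
  populations; the per-pair |πᵢ − πⱼ| and ratio directly measure sampling
  convergence.  This replaces no statistics — it is a free, exact check
  that molecular symmetry donates.  (In practice it is the cheapest way to
  see that simulations started from one crystal structure have not yet
  equilibrated between equivalent basins; `analysis/03_msm.py` reproduces
  that behaviour on synthetic short trajectories.)

Bayesian transition-matrix sampling is deliberately replaced by the
trajectory bootstrap: it plays the same scientific role (error bands for
ITS and CK curves) with far simpler, fully testable machinery.

## 4. T2 relaxation fitting (`depsikin.relaxation`)

Mono-exponential `I(t) = I0·exp(−t/T2)` fitted by nonlinear least squares
(log-linear regression initialization, intensities normalized by their
maximum so the fit is exactly scale-equivariant).  No baseline offset by
default — CPMG-HSQC intensity series of well-resolved peaks decay to zero —
with an optional offset parameter for curves that do not.  The 95%
confidence interval comes from the asymptotic parameter covariance with a
t-distribution at `n − p` degrees of freedom (labelled asymptotic;
profile-likelihood intervals are not implemented).  The canonical delay
grid is ten evenly spaced delays from 15.2 to 456 ms; on that grid, under
5% additive noise, the CI empirically covers the truth in ~95% of
replicates and T2 values across 20–500 ms are recovered with <5% bias
(both computed by the test suite).  Curves from partially overlapping
peaks can be flagged by the user and carry that flag through to the
output.

## 5. Synthetic data (`depsikin.synthetic`)

Each generator draws from the corresponding forward model, so recovery
tests close the loop implementation-independently:

| stage | forward model | default conditions |
|---|---|---|
| `gen_exsy` | `M = expm(L·tm)·diag(M0)` + multiplicative volume noise | pathway rates 0.16/0.09 s⁻¹, R1 = 2 s⁻¹, tm = 0.1 s, fractions (1, 1.5, 1.5), 20% uniform noise |
| `gen_titration` | speciation observables on the experimental schedule | 5 mM peptide; salt 0, 0.25, 0.5, 1, 2, 5, 10, 20, 50, 100, 200 mM; shift noise σ = 0.002 ppm |
| `gen_markov` | discrete chain → per-state Gaussians in a latent space → unit-norm linear mixing into angle features wrapped to (−180, 180] | 2 states, persistence 0.99, emission σ = 10°, states 90° apart on a latent ring |
| `gen_decay` | `I0·exp(−t/T2)` + additive noise | I0 = 100, T2 = 100 ms, ten-delay grid, 5% noise |

The default titration ground truth (`Kc = 1/7`, `K1 = 150 M⁻¹`,
`K2 = 80 M⁻¹`) reproduces the observed 7:1 zero-salt conformer ratio and
binding strong enough to inverted ratios at a 40-fold salt excess; the
0.002 ppm shift noise is the order of the digital resolution of a 1D 1H
spectrum.  A single seed per spec is split into per-stage substreams
(`numpy.random.SeedSequence.spawn`), so regenerating one stage never
perturbs another and identical specs give bit-identical data.

**What the generators do not emulate.**  EXSY volumes carry no
cross-relaxation (ROE) contamination and noise is independent per entry;
titration points have no cation-specific activity effects and no
asymmetric-shift drift; the Markov generator emits isotropic Gaussians with
geometric dwell times (real dihedral basins are anisotropic and the true
dynamics is only approximately Markovian at any lag); decays are strictly
mono-exponential.  Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions — not robustness to every
pathology of real spectra or force-field dynamics.

## 6. Problem sizes used by the shipped analyses and tests

The analysis drivers and the validation suite run on deliberately small
problems chosen to make every claim checkable in seconds on one core: the
worked-example extraction is a 3×3 desk computation with 1000 Monte-Carlo
replicates; titration recovery uses the 11-point experimental schedule with
100 seeded replicates; the MSM stage uses planted chains of 10⁶ frames for
timescale recovery, 20×2000 frames for Chapman–Kolmogorov self-consistency,
and 4×1000-frame feature trajectories for the end-to-end driver; T2
calibration uses 1000 replicates on the ten-delay grid.  These sizes are
the package's validation conditions; nothing in the methodology depends on
them.

## 7. Known limitations

* Single-mixing-time EXSY only; multi-mixing-time build-up fitting and ROE
  contamination handling are out of scope.
* The rate-labelling convention (`k1` = larger averaged set) mirrors the
  published tables for these macrocycles but is a convention; use
  `k1_group` when a different assignment is intended.
* The speciation model is limited to the A/S/SM/S2M species list; adding
  mixed or higher-order complexes requires extending the mass balances.
* CNN clustering is quadratic in dense neighborhoods (see §3).
* Asymptotic (not profile) confidence intervals for T2.
* The damped logistic is an empirical descriptor with no mechanistic
  content.
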