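# Methods

## Signal model and estimator

All information measures assume the windowed EEG is a stationary Gaussian
process, under which Shannon entropy, mutual information and transfer entropy
(TE) reduce to log-determinants of covariance matrices. For a target group
*A* and source group *B* with prediction lag τ samples,

    T(B→A) = H(A⁺, A) − H(A) − H(A⁺, A, B) + H(A, B),

with `A⁺` the target samples τ steps ahead. Embedding dimension and delay are
fixed at 1 (one lagged vector per group); τ is a free parameter stored in
samples, default 2 (7.8125 ms at 256 Hz, conventionally printed as 7.8 ms).
The Gaussian assumption makes the estimator a plug-in of sample covariances:
it is exactly the multivariate Granger-causality log-variance-ratio for
univariate targets (an equivalence the test suite asserts against an
independent regression-based oracle), converges to the population value as
the window grows, and carries a positive O(1/N) small-sample bias — with the
default 60 s windows at 256 Hz (N = 15 360) the bias is ~10⁻⁴ nats, well
below the flows of interest. Non-Gaussian estimators (kernel, k-NN, binned)
are out of scope.

Numerical choices:

- covariances are maximum likelihood (divide by N) on per-window
  mean-removed data; an unbiased (N−1) variant sits behind a flag;
- log-determinants use Cholesky factorization; if it fails, a ridge of
  `1e-10 × mean diagonal` is added and the factorization retried. The ridge
  is *not* applied unconditionally so that population covariances of
  decoupled channels yield TE = 0 to machine precision rather than to ~1e-9;
- TE values in (−1e-12, 0) are clipped to 0; anything more negative is
  clipped with a `RuntimeWarning` (it indicates a conditioning problem, and
  in-sample Gaussian TE is mathematically non-negative).

## Bipartition scan

Two enumeration modes over *n* channels: `disjoint_pairs`, all ordered pairs
of disjoint non-empty subsets (3ⁿ − 2ⁿ⁺¹ + 1 pairs; the union need not cover
the set), and `covering`, ordered two-block partitions (2ⁿ − 2). The default
is `disjoint_pairs` because the three-channel count of such pairs is the
conventional 12; `covering` is the economical choice at 7 channels (126 vs
1932 splits) and is what the synthetic-fixture analyses use. Enumeration
order is canonical (source size, then position; then targets likewise), and
ties in the index extrema resolve to the first entry in that order.

One pooled (2n × 2n) lagged covariance of `[x_{t+τ}, x_t]` is computed per
window; every entropy term of every bipartition is a log-determinant of one
of its sub-blocks, so the full scan costs a single pass over the samples.

T_min's default rule is the plain minimum over the table. The
integrated-information-style reading — per unordered pair of groups take the
weaker direction, then pick the pair whose weak direction is strongest — is
implemented as `rule="maxmin"`. Both readings are defensible for a "minimum
information bipartition"; neither is asserted as canonical, and outputs
record which rule produced them.

## Preprocessing

A 9th-order digital Butterworth low-pass at 50 Hz (bilinear design) is
applied forward–backward (`sosfiltfilt`): zero phase, so window alignment is
undistorted, at the cost of squaring the magnitude response (doubling the
effective order). Filtering precedes segmentation. Windows are half-open
sample ranges `[start, end)`, 0-based, starting at 0 with a fixed step; no
partial windows. The clinical index-selection grid (30 s × 10 min then
1 min × 60 min after infusion start; 30 s/1 min/2 min × 20 min each after
infusion end) is generated with clause boundaries assigned to the later,
coarser grid and duplicates removed.

EDF I/O is a self-contained 16-bit codec; the writer emits one data record
spanning the recording (avoids padding partial records) and round-trips to
within the 16-bit quantization step `(max − min)/65535`. CSV round-trips
exactly (`%.17g` written, round-trip float parsing on read). Annotation
times live in a `time_s,label` CSV; CSV sampling rates come from an `fs`
argument or YAML sidecar.

## VAR validation and the anesthesia fixture

The validation system is a VAR(1), `x_t = F x_{t−1} + e_t`, with stationarity
(spectral radius of F below 1) enforced. Its lag-0 covariance solves the
discrete Lyapunov equation `Σ = F Σ Fᵀ + Q` and the lag-τ cross-covariance is
`F^τ Σ`, giving an *analytic* TE oracle: decoupled channels give exactly 0,
and `y_{t+1} = x_t + e_t` gives exactly ½ ln 2. Simulations discard a
1000-sample burn-in and are reproducible from a single integer seed.

The anesthesia fixture emulates a 7-channel frontoparietal montage (Fp1,
Fp2, F3, F4, P3, P4, Cz at 256 Hz). The base coupling matrix has 0.5
self-couplings, strong frontal→parietal "feedback" couplings (0.3), weaker
return and interhemispheric paths (0.1–0.2), and is deliberately
bidirectional so that *every* bipartition carries non-trivial flow at
baseline — otherwise T_min would sit at zero regardless of drug level and
carry no signal. An infusion schedule drives the 3-compartment PK model, the
plasma curve feeds the effect compartment, and the resulting Ce(t) attenuates
the designated couplings by `g(Ce) = 1/(1 + (Ce/C50_mod)^h)`. Defaults:
20-minute records, infusion of 14 mg/min (12 mg/kg/h at a nominal 70 kg)
over the middle half, ke0 = 0.25 min⁻¹, C50_mod = 1.2 µg/mL, h = 2.5, and
modulation of *all* off-diagonal couplings (anesthetic suppression of
inter-regional connectivity at large, not only the feedback edges). Since
attenuation only shrinks non-negative couplings, stability at the deepest
modulation is verified once per fixture.

What the fixture does *not* emulate: 1/f spectral shape, oscillatory rhythms
and their drug-induced shifts (spindles, frontal alpha), nonstationary
artifacts, volume conduction, or any quantitative Ce→coupling law (none is
established; the attenuation law is a fixture choice). Passing
parameter-recovery tests therefore shows the estimator chain recovers known
directed-connectivity changes of the right kind and size — not that clinical
correlation values are reproduced. The published clinical numbers depend on
undeposited patient data and are intentionally not targets.

## PK/PD

The 3-compartment mammillary model is linear with piecewise-constant
infusion input, so propagation uses the augmented matrix exponential per
segment — exact to floating point. (An adaptive ODE integrator was
considered and rejected: for this system expm is both faster and free of
tolerance knobs.) Units: mg doses, L volumes, L/min clearances, hence
µg/mL ≡ mg/L concentrations. Default parameters are the published
population estimates (V1 = 17.5 L scaled by LBM/48 when a lean body mass is
supplied, V2 = 96.3 L, V3 = 1460 L, Cl = 1.13 L/min, Q1 = 1.03 L/min,
Q2 = 0.894 L/min); LBM itself is accepted as a number, not computed. The
effect compartment `dCe/dt = ke0(Cp − Ce)` is solved by the exact
closed-form update for piecewise-linear Cp.

The sigmoid Emax fit is individual nonlinear least squares (no population
mixed-effects, no bootstrap): parameters (E0, Emax, ln Ce50, ln γ, ln ke0),
the log transform enforcing positivity, 12 multistarts spanning ke0 ∈
{0.05, 0.15, 0.5} min⁻¹, γ ∈ {1.5, 4} and Ce50 at 0.3/0.6 of the observed
Cp range. Standard errors come from the Gauss–Newton Hessian with a delta-
method back-transform; a fit with |Emax − E0| below 10⁻³ of the course scale
is flagged degenerate rather than reported as a drug effect. The
likelihood-ratio helper returns the χ² quantile (3.84 at α = 0.05, df = 1)
used to compare nested models.

## Statistics

Somers' D uses the asymmetric D_yx convention — concordant minus discordant
pairs over pairs untied on the independent variable x — matching its use
with the EEG index as dependent and Ce as independent variable. Its standard
error is the leave-one-observation-out jackknife, computed in O(n²) from
per-observation concordance counts (removing observation i removes exactly
its row of pairs). P_K = 1 − (1 − |D|)/2 with SE(P_K) = SE(D)/2. Pearson and
Spearman delegate to scipy; Spearman equals Pearson on midranks exactly.

## Problem sizes

Defaults throughout are the study conditions: 60 s / 30 s windows, τ = 2 at
256 Hz, 7 channels. Validation suites use sizes chosen for tight oracles at
interactive cost: TE estimator-vs-oracle checks at N = 10⁵ over 20 seeds,
PD recovery at n = 130 course points over 20 noise seeds, fixture analyses
on 20-minute records with covering-mode scans. These sizes are the package's
own verification design, chosen so each check's sampling error is an order
of magnitude below the tolerance it asserts.

## Known limitations

- Gaussian TE sees only second-order structure; genuinely nonlinear
  dependencies are invisible to it.
- The bipartition scan is exhaustive; beyond ~10 channels the disjoint-pairs
  mode grows as 3ⁿ and a heuristic search would be needed.
- The synch-fast-slow comparator follows the open bispectral definition
  (log₁₀ of the 40–47 Hz over 0.5–47 Hz bispectral sums, region membership
  by the sum frequency f1+f2, 2 s Hann segments at 50% overlap); it is not
  the proprietary clinical BIS index.
- The spectral-entropy comparator is normalized to [0, 1] by ln(bin count);
  published monitor scalings differ.
- No artifact rejection, re-referencing or montage conversion is performed.
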