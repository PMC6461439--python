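# Methods

This note documents the models implemented in `chanzyme`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate about real data.

## The coupled ADPRase assay model

ADPRase activity is read out as inorganic phosphate (Pi) liberated by
co-applied alkaline phosphatase from both hydrolysis products (AMP and
ribose-5-phosphate), so the stoichiometry is 2 mol Pi per mol ADPR
hydrolyzed; AMP controls yield 1 Pi each, and the α,β-methylene analog
AMPCPR is resistant and yields none.  The model starts at "Pi released":
the molybdate/ascorbate color chemistry and daily standard curves are
outside its scope, and the Pi detection limit is an input, not a
constant.  Turnover is computed per subunit,

    k_cat = (Pi / stoichiometry) / ([subunit] · t_incubation),

with concentrations in μM (Pi) and nM (protein) and time in seconds.
The smallest quantifiable k_cat follows by inverting this relation at
the detection limit: with 500 nM enzyme and a 5-minute incubation a
12 μM Pi signal corresponds to 0.04 s⁻¹, which is why slow mutants are
assayed at high protein concentration.

Background (spontaneous ADPR hydrolysis at alkaline pH) is subtracted
arithmetically; nets at or below zero are flagged rather than clipped,
because a flag is the honest statement that the signal is
indistinguishable from background.

## Curve models and fitting

Four rate laws are fitted: Michaelis–Menten, Hill, the compound
double-Hill

    k_cat(x) = (k_cat1·K₂^n₂·x^n₁ + k_cat2·x^(n₁+n₂))
               / (K₁^n₁·K₂^n₂ + K₂^n₂·x^n₁ + x^(n₁+n₂)),

which describes a high-affinity pair of Mg²⁺ sites (first plateau
k_cat1) plus further enhancement by a low-affinity third site (second
plateau k_cat2), and the single-group pH titration
k_cat = k_cat,max / (1 + 10^(pKa − pH)).

Fitting is unweighted least squares on untransformed rates
(`scipy.optimize.least_squares`).  All intrinsically positive parameters
(K's, k_cat's, Hill slopes) are optimized as log10 values so they can
never change sign — near-zero turnover mutants otherwise push optimizers
across zero; pKa is fitted on its natural (already logarithmic) scale.
Standard errors come from the Jacobian-based covariance at the optimum,
scaled by the residual variance, with the delta method mapping log-space
errors back to the natural scale.  No bootstrap is run by default.

Initialization: saturation values start at the maximum observed
response; half-saturation constants at the x whose response is closest
to half of it; Hill slopes at 1 (single Hill) or (2, 1) (double Hill,
the shape regime this assay operates in).  Degenerate inputs (constant
response, an x-range that does not bracket K₁ or the titration midpoint)
return explicit `failed`/`warning` statuses, never silently defaulted
parameters.  Whether to fit raw or normalized rates is the caller's
choice; normalization divides by the replicate-mean value at the highest
condition.

## The three-state gating model

Single-channel gating is modeled by the minimal bursting scheme

    C_slow  <--k_so/k_os-->  O  <--k_of/k_fo-->  C_fast ,

with one conducting state (O), long interburst closures in C_slow and
millisecond flickery closures in C_fast.  This is the simplest scheme
consistent with single-exponential open-time and bi-exponential
closed-time distributions.  Derived quantities:

    P_o   = 1 / (1 + k_os/k_so + k_of/k_fo)
    τ_b   = (1/k_os) · (1 + k_of/k_fo)      mean burst duration
    τ_ib  = 1/k_so                          mean interburst duration
    mean open time     = 1/(k_os + k_of)
    openings per burst = 1 + k_of/k_os

An equivalent C_slow↔C_fast↔O ("C-C-O") parameterization is supported;
its rate constants differ but the burst and interburst durations derived
from a fit do not, which the test suite checks by fitting both
topologies to identical data.  For C-C-O, τ_b and τ_ib are obtained by
first-passage arithmetic (geometric number of openings per burst, mean
closed-gap time through the flicker state), and both topologies'
formulas are validated against direct burst segmentation of simulated
truth paths.

### N-channel aggregation

A patch holds N identical independent channels; only the number of
simultaneously open channels (the conductance level) is observable.  The
composite process lives on occupation vectors (n_slow, n_open, n_fast),
(N+1)(N+2)/2 states, with transition rates (count in source state) ×
(single-channel rate).  Channel independence makes the composite
stationary distribution multinomial in the single-channel stationary
probabilities, hence the stationary level distribution is
Binomial(N, P_o) — an exact identity used as a test oracle.

### Dwell-time likelihood

The dwell-time density at level ℓ is

    f_ℓ(t) = φ_ℓ · exp(Q_ℓℓ t) · q_exit ,

where Q_ℓℓ is the within-level block of the composite generator, q_exit
the vector of exit rates, and φ_ℓ the stationary-flux entry vector
(steady-state recordings are assumed, so entries are distributed by
stationary flux).  The matrix exponential is evaluated through the
eigendecomposition of Q_ℓℓ, giving an explicit mixture of N−ℓ+1
exponentials per level; this is both faster and numerically stabler than
repeated `expm` calls when flicker rates exceed interburst rates by
three orders of magnitude.  The top level is a single exponential with
rate N(k_os + k_of).

Dwells are treated as independent draws from their level-conditional
distributions (the histogram-likelihood approximation).  Correlations
between successive dwells are ignored; a full correlated-sequence
likelihood is out of scope.  Rates are estimated by maximizing the
summed log-likelihood over the four log-rates with multi-start
Nelder-Mead (default 5 seeded starts: one moment-based start derived
from the top-level dwell mean and a flicker/interburst split of the
closed dwells at 20 ms, the rest log-uniform over physiologic scales —
interburst and burst rates of order 0.05–5 s⁻¹, flicker exchange of
order 30–3000 s⁻¹).  Standard errors come from the finite-difference
observed information at the optimum.

No missed-event (dead-time) correction is applied inside the
likelihood.  Instead, analyses are run in regimes where the correction
is immaterial: noiseless/unfiltered renderings idealized at full
bandwidth, or event durations much longer than the dead time.  With
200 Hz filtering and the default dead time this approximation biases
flicker rates; the worked example shows the residual bias is small for
~2 ms flickers.

### Channel-count test

The number of active channels is estimated as the maximum simultaneously
open count N′.  The hypothesis of a hidden (N′+1)-th channel is tested
by p = exp(−T_top/τ_ib): the probability that a channel opening at rate
1/τ_ib never opens during the cumulative time T_top spent at level N′.
p < 0.001 excludes N > N′ with high confidence.  The test is
conservative: a real hidden channel also opens from within bursts, so
the simulated frequency of "no top-level excursion" records does not
exceed the analytic bound (checked by Monte Carlo).

## Idealization

Traces are low-pass filtered with a zero-phase Gaussian FIR whose −3 dB
frequency defines the cutoff (σ_t = √(ln 2)/(2π f_c)); the
reciprocal-max-slope rise time of a filtered step is 0.3321/f_c and the
10–90% rise time 2·z₀.₉·σ_t ≈ 0.3396/f_c, both used as filter oracles.
The baseline is re-centered on the histogram mode of the closed level,
identified as the dominant histogram peak within ±1.5 pA of zero;
windowed re-estimation with linear interpolation handles slow drift.  If
no near-zero peak exists the trace is returned unchanged with a warning.

Half-amplitude idealization divides samples by the signed unitary
amplitude so levels count open channels regardless of polarity; level ℓ
covers (ℓ−½, ℓ+½], a sample exactly at a half-amplitude boundary going
to the lower level (a deterministic tie rule).  The default dead time
after filtering at f_c is 0.179/f_c, the event-detection limit of a
Gaussian filter; imposing it removes shorter events, splits their
duration equally between flanking events, merges equal neighbours, and
conserves total duration exactly (the operation is idempotent).  First
and last events are censored by the record edges: they contribute to
occupancy totals but not to dwell-time distributions.

Unitary amplitudes are estimated by fitting sums of Gaussians to the
all-points histogram (initialized from smoothed-histogram peaks) and
averaging adjacent-peak spacings, signed relative to the peak nearest
the baseline.  Fewer than two resolvable peaks is a failure, not a
default.

## Macroscopic analyses

Relaxations are fitted by a single decaying exponential
I(t) = baseline + A·exp(−(t−t₀)/τ) with the baseline free (seal leak is
not assumed zero) and the window start defaulting to the
solution-exchange time plus a margin.  No multi-exponential model
selection is attempted — single exponentials describe both deactivation
(~0.1 s) and inactivation (tens to hundreds of seconds) here, and the
fit flags windows that do not decay or that constrain τ poorly.
Fractional currents are ratios of segment means with an optional edge
margin to exclude exchange artifacts; the ADPR dose–response uses the
same Hill engine as the enzyme fits.

## Motif classification

The Nudix box is located by scoring every hexamer window against the
REUXEE consensus (+1 for identity at positions 1, 2, 5, 6; +1 for a
hydrophobic residue {A,I,L,M,F,V,W,Y} at position 3; position 4 free;
ties to the smallest position).  Classification is rule-based, not
alignment-based: a hexamer is *canonical* iff the three glutamates
(positions 2, 5, 6) are present and position 3 is hydrophobic.  The
position-1 arginine is deliberately not required — domains carrying an
alanine there retain full activity, so requiring R would misclassify
active enzymes.  Pore classification inspects caller-supplied windows:
invertebrate-like = phenylalanine prefix, ≥2 acidic residues in the
post-filter triplet, and a filter glutamate; vertebrate-like = proline
prefix and ≤1 acidic residue; anything else is ambiguous.

## Synthetic data: what it does and does not emulate

Generators produce exact CTMC paths (exponential sojourns,
competing-rate transitions, initial states from the stationary
distribution, since only steady-state records are analyzed), rendered at
10 kHz with optional Gaussian noise and a 2 kHz recording filter — the
standard acquisition setting this kind of data is collected under.
Assay noise is multiplicative with a fixed coefficient of variation,
matching rate data whose scatter grows with signal (an additive mode is
available); noisy rates are clipped at zero because rates are physically
nonnegative.  Recording noise amplitude is not calibrated to any
instrument: the default (≤0.15 × unitary amplitude before filtering) is
chosen so that half-amplitude idealization at a 200 Hz analysis
bandwidth is reliable.

Consequently, passing tests demonstrate correctness of the estimators
under the model's own assumptions — they do not establish robustness to
baseline wander beyond linear drift, 1/f and excess channel noise,
subconductance levels, ligand-concentration-dependent gating, or
correlated dwell sequences, none of which the generators produce.

## Problem sizes and reproducibility

The reference analyses use a single channel simulated for 2000 s
(~6700 events) and twelve channels for 300 s (~12000 events), sizes at
which all four rates are recovered within 15% (single channel) and the
derived P_o, τ_b, τ_ib within 20% (twelve channels); burst-formula
checks segment ≥10⁴ bursts.  Every stochastic routine takes an explicit
integer seed and is bit-reproducible for a fixed seed; the command-line
tools log the seed and parameters they ran with, and config-file values
override flags with a logged notice so a run can be reconstructed from
its artifacts.

## Known limitations

- Dwell correlations and missed-event corrections are not modeled (see
  above); fitted flicker rates are biased at narrow analysis bandwidths.
- The baseline locator assumes the closed level is the dominant
  histogram peak near 0 pA; records dominated by open current need the
  windowed estimator or manual offsets.
- The double-Hill fit requires data spanning both transitions; with
  fewer than ~7 well-placed concentrations the six parameters are
  practically unidentifiable and the fit reports failure.
- Free Mg²⁺ is taken as given; chelator speciation is metadata only.
- The pore rules operate on explicit sequence windows; no alignment is
  performed, so window choice is the caller's responsibility.
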