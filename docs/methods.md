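# Methods

## Scope and model

`megachan` analyzes single-channel current recordings from planar lipid
bilayers and simulates them. The object of study is a Ca²⁺-activated,
multi-conductance channel (the mitochondrial megachannel / permeability
transition pore formed by F-ATP synthase): a closed state at 0 pS, one or
more subconductance states, and a full-open state of order 1 nS, with
heavy flickering. Voltage is referenced to the *cis* chamber with *trans*
grounded; positive current is cation flow *cis*→*trans*, so an open channel
at negative holding potential deflects the current negative.

## Simulator

**Gating.** A continuous-time Markov chain over labelled states with fixed
conductances. Trajectories are sampled by the Gillespie algorithm
(exponential dwells at the state exit rate, categorical jumps). Ca²⁺
dependence enters through a Hill dose–response for the stationary open
probability, p(Ca) = po_max·Caⁿ/(Kⁿ+Caⁿ); the closed-state exit rate is set
to k_close·p/(1−p) against a fixed conducting→closed rate k_close, which
makes the stationary conducting occupancy exactly p for the two-state scheme
(and very nearly so for the packaged multi-state scheme, whose flicker state
contributes < 1% occupancy). Rates are voltage-independent: the mild
experimental increase of open propensity with depolarization has no
published functional form, so it is deliberately not modelled.

**Acquisition chain.** Per-sample ideal current g·V_cis/1000 (pA), plus a
constant instrumental offset, white Gaussian noise (pre-scaled so the
*post-filter* SD equals the user's `sigma_white` — users specify the
observable noise floor), a 50 Hz sinusoid with seeded random phase, and
baseline drift modelled as a first-order Gauss–Markov (Ornstein–Uhlenbeck)
process with corner 0.5 Hz — inside the < 2 Hz exclusion band, as bilayer
drift is in practice. The sum passes a causal 4-pole Butterworth low-pass
at 500 Hz (the analog corner named by the acquisition protocol; the
topology is our choice) and is sampled at 10 kHz. Everything is
bit-reproducible given (scenario, seed); per-trace seeds in batch runs
derive from `SeedSequence(seed, concentration_index, replicate_index)`.

**Inter-experiment variability.** Independent bilayer experiments scatter
substantially (different insertion counts, membrane quality, channel
activity). `SimScenario.experiment_cv` draws one lognormal factor
(mean 1, given CV) per simulated recording and applies it to po_max. The
packaged titration uses CV = 0.3, chosen so per-concentration SEMs and
fitted-parameter SEs have the relative magnitude seen in published bilayer
titrations (~15–25%); without it, 60-s synthetic records are unrealistically
reproducible and any dose–response fit reports near-zero parameter SEs.

**Packaged scenarios** (`megachan.fixtures`):

- `fig3b_scenario` — closed (0) / substate (300 pS) / full-open (1300 pS)
  / flicker (1300 pS, mean dwell 2 ms) at −80 mV, 3 mM Ca²⁺ with Bz-423 and
  PhAsO, 60 s, noise SD 2 pA. Opening splits 60/30/10% among
  substate/full-open/flicker; substate and full-open close at 20 s⁻¹ and
  exchange at 5 s⁻¹.
- `titration_template` — two-state 500 pS channel at −60 mV, 0.15 mM
  Bz-423; K = 0.6 mM and po_max = 0.2 (assumptions — the experimental
  dose–response reports only the Hill coefficient), k_close = 100 s⁻¹ so
  the gating spectrum sits well above the 2 Hz exclusion at every
  concentration; 23 recordings over 0.1–3 mM (replicates 4,4,4,4,4,3).
- `fixed_po_scenario` — two-state channel pinned at a stationary Po
  (≤ 0.5) for conductance-recovery studies.
- `dwell_rule_trace` — deterministic −30 pA / −60 pA two-level trace for
  the 10 ms stability rule.

## PSA

Full-record rectangular-window periodogram of the mean-subtracted signal
(`scipy.signal.periodogram`, density scaling), so that the discrete
integral of the PSD over frequency equals the sample variance (Parseval).
No Welch averaging by default: PSA is an integral statistic whose
expectation is window-invariant, and a single long window matches how the
statistic is used; a Welch mode exists for plotting. Exclusions: the DC bin
always; f < 2 Hz; |f − 50 Hz| ≤ 1 Hz (the mains half-width is our
convention — "near 50 Hz" is not quantified anywhere — and removes < 0.5%
of the retained band); f > 500 Hz, with the 500 Hz bin itself retained.
Whether the 2/500 Hz bounds are inclusive is likewise a convention, not an
experimental fact. Integration is trapezoidal over each contiguous retained
run; on a uniform grid this is exact for flat spectra and loses only the
half-bins at run edges.

## Idealization and conductance metrics

The closed-state baseline is the amplitude-histogram peak nearest the
expected closed level (0 pA, or the documented constant offset); histogram
bin width derives from the sample-to-sample noise scale (robust to rare
gating transitions) so multimodal records resolve their peaks. The noise SD
comes from an iterated Gaussian fit to the peak core (window 3σ, capped at
half the distance to the nearest neighboring peak), floored at 0.02 pA so
noiseless synthetic records still yield a usable quantization-scale band.
If no significant peak lies within max(5·robust SD, 10 pA) of the expected
closed level the record is rejected as never-closed/offset-corrupted; the
10 pA floor keeps legitimate uncorrected offsets of a few pA analyzable.

A sample is open when |I − baseline| > k·σ (k = 3 default: ~0.3% false-open
per tail for Gaussian noise). Maximal open runs form events. Event *level*
is the median of the event's samples after trimming 1 ms at each edge: the
causal 500 Hz filter smears transitions and drags threshold-defined event
boundaries into decay tails, which would bias a mean; the trimmed median
reads the stable level itself. Event amplitudes are referenced to a local
baseline (median of closed samples within ±0.5 s) so slow drift does not
shift levels; drift is effectively constant within one event.

- **Po** = (open samples)·dt / duration. Any conducting level counts as
  open (substate occupancy is not separated out). Known small biases at
  fast kinetics: filter smear at event edges and the false-open floor
  inflate Po by a few percent of its value; both are properties of the
  noise-band method itself.
- **G_mean** averages *all* open samples (not event means) before the
  Ohmic conversion; conductances are magnitudes (|I|/|V|) so negative-
  voltage recordings report positive pS. Events of polarity opposite to
  the holding potential are artifacts: counted in the event tally, logged,
  excluded from conductances.
- **G_max** considers events with duration ≥ 10 ms (inclusive: exactly
  10 ms qualifies) and reports the mean amplitude of the *top cluster*
  (all qualifying events within 3σ of the largest). A single max over many
  noisy event levels is biased upward by extreme-value selection (+2–3% in
  the packaged multistate scenario); the cluster mean is an unbiased
  readout of the top level and reduces exactly to the max on noise-free
  records. Levels closer than 3σ merge under this rule — acceptable, since
  levels inside the noise band are not separable anyway.

Whether the experimental G_mean averaged open samples or event means is
ambiguous in the source protocol; all-open-samples is our documented
convention.

## Dose–response and statistics

**Hill fit.** y = y_max·caⁿ/(Kⁿ+caⁿ), least squares with K and n optimized
in log space (positivity without constraints), up to 20 jittered restarts;
initialization y_max = max(y), K from interpolated half-max, n = 1. Rows at
ca = 0 are excluded (the model forces 0 there). Weighting: per-concentration
SEMs from 3–4 replicates are too noisy to use raw (they produce erratic
weights and inflate the scatter of n̂ beyond its reported SE), and plain
unweighted fitting is fragile under the multiplicative scatter such data
show; the default therefore pools a common coefficient of variation across
concentrations and weights by SEM_i = CV·mean_i/√n_i. Raw-SEM and
unweighted modes remain available, as does pinning n (`fix_n=1` gives the
rectangular-hyperbola fit). SE of n comes from the fit covariance by the
delta method; R² = 1 − SS_res/SS_tot on weighted values. Non-convergence
returns `converged=False` with diagnostics, never a fabricated estimate.
Whether reported coefficient uncertainties are fit-covariance SEs or
between-experiment SEs is unstated in the experimental literature we
emulate; ours are fit-covariance SEs, labelled as such.

**I–V fit.** OLS of current on voltage; the offset is the fitted intercept
(`auto`) or a supplied constant (the 13 pA gradient-shift correction);
slope conductance = 1000·slope.

**Mann–Whitney.** U by midrank summation; exact two-sided p
(2·min tail, capped at 1) by full enumeration of rank assignments when
n₁+n₂ ≤ 12 with no ties, tie-corrected normal approximation otherwise; the
result records which method was used. Pairwise condition comparisons are
reported without multiplicity adjustment (the convention in this
literature), flagged `adjusted=False`.

## Numerical conventions

Units: pA / mV / pS / mM / Hz / s; G[pS] = 1000·|I[pA]|/|V[mV]| defined in
one place. Files: ATF 1.0 (tab-separated, `SyncTimeUnits` in µs,
`Comment=key=value` metadata records) and CSV (`time_s,current_pA` with a
`key=value` sidecar). Currents are written with 4 decimals (0.1 fA
quantum); time as index·dt; a declared rate in the header/sidecar is
authoritative and the time column only corroborates uniformity (relative
jitter tolerance 1e-6). Binary vendor formats are out of scope.

## What the synthetic data does and does not show

The simulator reproduces the acquisition chain and the qualitative channel
phenomenology (substates, flicker, Ca²⁺ activation, line/drift/noise
contamination, inter-experiment scatter). It does not model voltage-
dependent gating, multi-channel stacking, proteoliposome fusion statistics,
or any conformational mechanism; agreement of the pipeline with simulator
ground truth validates the *estimators* under realistic noise, not any
biological claim. Parameter-recovery results quantify estimator bias at the
packaged conditions only (e.g., Po inflation of a few percent at 10 ms
dwell times; G_max cluster-mean bias below 0.5%).

## Problem sizes

Default study sizes were chosen to keep a full validation run on one CPU
short while leaving sampling error well below the tolerances tested:
60-s records (120 s for the near-noise-floor condition) at 10 kHz,
23-recording titrations, and 25 meta-replicates for coverage studies.
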