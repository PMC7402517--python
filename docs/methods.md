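# Methods

This note documents the models and procedures implemented in `roachclock`,
the numerical choices behind them, the design decisions taken where the
underlying science leaves freedom, and — importantly — a quantitative
account of which published behaviours of the dual-network clockwork the
implementation can and cannot reproduce, and why.

## 1. The single-cell oscillator

A pacemaker cell is a switching linear system (SLS) on states
(x₁, x₂, x₃) = (mRNA, repressor protein, coupling substance).  The state
space is partitioned into two closed polyhedral regions separated by the
protein threshold x₂ = 10; each region carries its own linear drift (A₁
below: autonomous mRNA growth; A₂ above: repression, mRNA decay).  Between
boundary crossings the solution is an exact matrix exponential, so the
oscillation is a relaxation cycle produced purely by mode switching, not by
smooth nonlinearity.  From x(0) = (10, 10, 10) the cycle settles to a
constant length of 4.3546 h at τ = 1 (measured; the cycle-length coefficient
of variation over the last five cycles of a 500 h run is < 10⁻¹⁴), with all
three states positive for all time.  The factor τ > 0 rescales time exactly:
period(τ) = 4.3546 / τ, so circadian cells use τ ≈ 0.18.

Boundary semantics: both closed regions contain the threshold plane.  The
active mode persists until the flow points strictly out of its region; the
crossing-direction rule (implemented with exact-propagation probes at
escalating horizons) resolves starts on the boundary and grazing touches
without hysteresis.  The exogenous-input gain B of the SLS definition is
carried in the interface but defaults to zero: all experiments modelled here
are constant-darkness free runs, and light protocols are out of scope.

### Integration scheme

Trajectories are sampled on a uniform grid (default 0.01 h).  Per mode the
one-step propagator e^{Aτ·Δt} is cached; a boundary crossing inside a step is
localized by bisection on the violated region constraint to an event
tolerance of 10⁻⁹ h (configurable).  A chattering guard aborts with a
diagnostic if more than 1000 switches occur within one simulated hour —
surfacing ill-posed configurations instead of hanging.  Fidelity is checked
against a blind dense integration of the same piecewise field (adaptive
library solver at rtol 10⁻¹⁰, re-selecting the mode at every right-hand-side
evaluation, with no event logic and no matrix exponentials): maximum state
deviation 3.5·10⁻⁶ over 500 h.  A naive *fixed-step* oracle is not usable at
this accuracy: quantizing switching times to the step size accumulates
O(0.1 h) of phase drift over 500 h, which is the oracle's error, not the
simulator's.

## 2. The dual-network clockwork

Eight cells share the mode structure: four in the leading network (LeON, all
PER) and four in the lagging network (LaON; a TIM1 pair and a PER/CRY2
pair).  Cell j of network g obeys

    ẋ⁽ʲ⁾ = τⱼ (A_i x⁽ʲ⁾ + E_{g,i} K_g + F_{g,i} K_other),

where i is the cell's own mode (per-cell switching on its own x₂), K_g is
the arithmetic mean of x₃ over the live cells of network g, and the output
is K = 0.5 (K_Le + K_La).  The coupling gains are fixed at their published
values (±0.07 within-network, −0.05 onto LeON, −0.12 onto LaON, with the
LeON gains flipping sign across the threshold and the LaON gains constant).

**τ as an oscillator-local time rescaling.**  τⱼ multiplies the *entire*
state-dependent drift of cell j — its own linear term and the mean-field
input it receives.  The alternative reading (τ on the A-term only) is not
viable: at circadian time scales the constant cross-inhibition −0.12·K_Le
received by a LaON cell then dwarfs the restoring drift τ·x₁ of its slow
dynamics; once x₁ falls below |net coupling|/τ ≈ 2.2 (and the uncoupled
cycle's x₁ minimum is 2.04) the below-threshold mode has no return path and
the trajectory diverges.  We verified this numerically for uniform and
heterogeneous τ across [0.15, 0.5], from the canonical initial state and
from randomized phase configurations (120 random configurations, all
divergent by ≈ 105 h).  Under the time-rescaling reading a uniform τ is an
exact global change of units, and the published gains yield bounded,
synchronizing oscillations — the behaviour the published simulations show.

**Simulation.**  For a fixed assignment of per-cell modes the joint system
is one linear ODE (the mean fields are linear in the third states), so the
network simulator propagates the joint state with cached 24×24 matrix
exponentials per mode combination and localizes threshold crossings by
dyadic bisection built from repeated-squaring sub-step propagators (event
tolerance 10⁻⁹ h, all cached matrix–vector work).  A divergence guard
(|x| > 10⁸) converts the runaway described above into a clean error.
Decoupling (E = F = 0) reproduces the single-cell simulator per cell to
10⁻³, which cross-checks the two independent engines.

**Knockdowns** are simulated by deleting the oscillators whose repressor is
targeted, per the published reduction table: PER keeps one LeON cell (the
lowest-index one by convention, configurable) and the TIM1 pair; TIM1 keeps
LeON and the PER/CRY2 pair; CRY2 keeps LeON and the TIM1 pair.  Mean fields
always average over live cells only.

**A symmetry worth knowing.**  Two cells of the same network with equal τ
and equal initial state have identical trajectories forever (ODE
uniqueness).  Two exact consequences: (i) with τ uniform within each
network, *every* knockdown leaves K(t) unchanged — knockdown period shifts
require within-network heterogeneity (asserted as a test); (ii) under a
"mirrored-pair" parameterization in which both LaON pairs carry the same
(a, b) factors, the TIM1 and CRY2 knockdowns are *exactly* the nominal
clockwork, so that scheme cannot express any LaON-knockdown effect and is
kept only as a degenerate baseline.  Numerically these identical-cell
configurations are transversely unstable on the coupled attractor: roundoff
seeds a symmetry-breaking mode that grows to O(10⁻²) in K(t) by ≈ 200 h.
Exactness tests therefore compare over 150 h; the removal-invariance
property is asserted on the K(t) *period* (equal to < 0.01 h), which is
robust.

## 3. Calibrating the heterogeneity factors

The per-cell τⱼ are the model's only unpublished parameters; the published
anchors are the scenario output periods — nominal 23.60 h, TIM1/CRY2
knockdown 20.50 h, PER knockdown 25.96 h — plus the constraint that LeON
alone runs faster than 24 h.

`calibrate_tau` minimizes a weighted RMS of scenario-period residuals with
Nelder–Mead in log-τ space (the period is a piecewise-smooth function of τ;
log coordinates keep τ positive), after an *anchor step* that exploits the
exact rescaling property to match the nominal target up front.  Three
structural penalties encode what a usable clockwork must satisfy: loss of
synchrony (per-cell period spread beyond 0.05 h in any scenario), TIM1/CRY2
disagreement beyond 0.05 h (the two schemes eliminate equally many
oscillators and the published account treats them as one result), and
scenario misordering (a knockdown shift with the wrong sign).  Scenario
periods during calibration are measured from 500 h simulations (200 h
transient discarded, 0.05 h sampling); the shipped values and all reported
numbers use 800 h / 200 h / 0.02 h.  The shipped calibration
(`DEFAULT_TAU_LE/LA`) is the deterministic outcome of this procedure with
the nominal target weighted 50:1 (it is the one scenario the model can match
exactly) and 200 objective evaluations.

### What the calibration can and cannot reproduce

The nominal period is reproducible exactly (rescaling).  The knockdown
*directions* are reproducible and are reproduced: both LaON knockdowns
shorten the synchronized period (removing either pair makes the lagging
network's mean field more phase-coherent, strengthening its inhibitory
feedback), they agree with each other to 0.03 h, and the PER knockdown
lengthens the period (the surviving LeON cell is calibrated slightly slow).

The knockdown *magnitudes* (−3.10 h and +2.36 h) are not reachable by any
parameter set that keeps the cells synchronized, for a structural reason:
with the published gains the lagging network receives the strong coupling
(0.12) and the leading network the weak one (0.05), so the synchronized
period is set almost entirely by LeON — across the whole LaON entrainment
tongue (natural periods ≈ 21–23 h against a 23.8 h collective rhythm) the
locked output period moves by < 0.1 h.  Meanwhile the within-LeON mutual
locking produced by the sign-flipping 0.07 gain is weak: LeON cells whose
natural periods differ by more than ≈ 0.1 h drift apart, so requiring all
cells to share one period pins LeON nearly uniform and caps the PER-knockdown
shift at ≈ +0.1 h.  A broad randomized search over free τ (periods 18–30 h
per cell) confirms the dichotomy: parameter sets whose scenario "periods"
match the published values are unsynchronized, and their K(t) period is an
estimator artifact that changes with the analysis window.  We therefore ship
the best synchronized fit and report the knockdown residuals (≈ +3.0 h for
TIM1/CRY2, ≈ −2.3 h for PER) rather than an unsynchronized configuration
that would imitate the numbers.  One trade-off inside the feasible set is
also explicit: pushing the PER shift positive requires a survivor ≈ 0.06
natural hours slow, which leaves a 0.06–0.09 h per-cell period spread in the
scenarios that retain that cell — slightly above the 0.05 h sharing
tolerance used elsewhere; weighting synchrony harder shrinks the spread but
flips the CRY2 shift's sign, so the shipped calibration favours the
directional pattern.

## 4. Rhythm analysis

**Period of smooth model output** is measured as the mean spacing of
successive maxima (local quadratic refinement of each peak) after a 200 h
transient; the dispersion of cycle lengths is reported alongside and an
autocorrelation estimator provides an independent cross-check.  The 200 h
default transient is ≈ 8 nominal cycles, after which the calibrated
clockwork's output is periodic to < 0.01 h cycle dispersion.

**Chi-square periodogram.**  For a binned count record and candidate period
P the record is folded into K = round(P / bin width) columns using complete
rows only, and the Sokolove–Bushell statistic Q_P = R·Σ(column mean −
grand mean)² / population variance is referred to a χ² null with K − 1
degrees of freedom; the per-period significance threshold is the 1 − α
quantile (α = 10⁻⁶ by default).  Q_P is invariant under adding a constant to
all counts and under positive scaling (asserted as property tests).  The
candidate grid is 18–30 h in 0.1 h steps (121 points), and the default bin
width 0.1 h (6 min) makes the column count exact on that grid.  These grid
choices are package conventions; the published analysis names only the
period range and α.

**Savitzky–Golay smoothing** is second order, window 11.  Interior points
use the standard convolution weights; the first and last five points are
refit on truncated windows rather than padded — no values are fabricated
beyond the scanned range, where significant peaks may legitimately sit.  The
implementation is tested against a brute-force windowed least-squares oracle
to 10⁻¹⁰ and reproduces exact quadratic sequences.

**Classification.**  Rhythmic = at least one supra-threshold local maximum
of the smoothed statistic (grid endpoints count when they top their single
neighbour); the circadian period τ is the most prominent such peak
(largest statistic / threshold ratio).  Desynchronized = two supra-threshold
peaks ≥ 1 h apart in the full record *and* the same signature in at least
one caller-selected segment periodogram; the segment requirement stands in
for the by-eye actogram inspection used with animal data and is flagged as a
proxy.  Strong vs weak rhythmicity is likewise a proxy convention (dominant
peak ≥ 2× its threshold), configurable and not a published rule.  Δτ =
τ_after − τ_before is defined only when both sides are rhythmic; arrhythmic
records raise instead of returning a value, mirroring the exclusion of
animals without a determinable period.

**Type-I behaviour.**  On pure Poisson noise records the fraction showing
any significant period at α = 10⁻⁶ across the 121-point grid is bounded in
tests by 5·α·121; with 1000 seeded replicates the observed count is zero.

## 5. Relative expression (2^−ΔΔCT)

Technical replicates are averaged on the Ct scale (the published protocol
does not state its convention; averaging before ΔCT is documented here).
ΔCT = Ct(gene) − Ct(reference) within a sample; ΔΔCT subtracts the mean ΔCT
of the same gene in the control group; the ratio is 2^−ΔΔCT with
amplification efficiency fixed at 2 (no efficiency correction — a stated
non-goal).  Exact identities follow and are asserted: one ratio-halving per
ΔΔCT cycle, and control-group ratios with geometric mean exactly 1 (mean
control ΔΔCT is 0 by construction).  Daily profiles summarize per-ZT mean
ratios with dispersion and flag the baseline ZT (lowest mean, ties to the
earliest ZT) as the within-curve comparison point; group testing itself is
out of scope.  Knockdown recovery is evaluated on the geometric mean
(2^−mean ΔΔCT): the arithmetic mean of ratios is biased upward under both Ct
noise and a cosine expression rhythm, the geometric mean is not.

## 6. Synthetic data

The activity generator emulates nocturnal running-wheel records: each
rhythmic component contributes a rectangular night bout (default duty cycle
0.5) carrying a smooth sin² envelope, on a uniform background, with Poisson
counts per 6 min bin.  Defaults: 60 counts/bin peak amplitude for the
strongly rhythmic regime, 25 % of that for weak, zero for arrhythmic, 10
days of recording, baseline 2 counts/bin — values chosen to put the strong
regime far above and the weak regime near the α = 10⁻⁶ detection boundary of
a 10-day record.  A noiseless switch replaces Poisson draws with the rounded
rate for exactness fixtures.  The generator returns its ground truth
(component periods, regime, rate) with the data, so round-trip tests never
re-derive truth from the data.  It does not emulate injection-induced
inactivity, mortality, bout microstructure or entrainment transients, so
passing round trips demonstrate estimator correctness on idealized records,
not robustness to all real-data pathologies.

The Ct generator produces a control + knockdown experiment for one gene of
interest and a flat reference gene: ZTs (0, 4, ..., 20), three pools per ZT,
technical triplicates, Gaussian Ct noise (default SD 0.15 cycles, halved for
technical replicates around their pool value), a cosine expression rhythm
(default amplitude 1 Ct ≈ 2-fold peak-to-trough) dipping the Ct at the peak
ZT, and a knockdown that adds log₂(1/factor) cycles in the treated group.

`generate_clockwork_targets` simulates scenario periods from a *known* τ
set, providing the self-consistency oracle for calibration round trips.

## 7. Problem sizes and runtimes

Default analyses simulate 500–800 h of network time at 0.02–0.05 h sampling
(a few hundred mode-switch events; well under a second per scenario on one
core).  Calibration uses 500 h scenario simulations and ≈ 200 objective
evaluations (≈ 3 minutes); reported periods always come from 800 h runs with
a 200 h transient at 0.02 h sampling.  The full reproduction script
(`scripts/acceptance.py`) runs in about 4 minutes and is deterministic.

## 8. Known limitations

- The model's knockdown period shifts are an order of magnitude smaller than
  the published ones for any synchronized parameter set (Section 3); the
  package reproduces the directional pattern, the nominal period, and all
  pipeline-level results, and reports the discrepancy rather than masking it.
- Identical-cell configurations decohere numerically after ≈ 200 h
  (transverse instability); exact-symmetry statements hold on shorter
  horizons or at the period level.
- The nominal clockwork with a slowed survivor is weakly quasi-periodic
  (cell-period spread ≈ 0.08 h over 600 h); reported periods are therefore
  protocol-defined (duration, transient, sampling) and the protocol is fixed
  and documented.
- Light input, graded (non-eliminating) knockdowns, and inferential group
  statistics are out of scope by design.
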