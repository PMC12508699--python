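# Methods

This note records the models behind `sptkin`, the estimator and parameter
choices, and what the simulation-based validation does and does not
demonstrate about real data.

## Kinetic model

A particle near a cell surface is modelled as a four-state continuous-time
process observed at the frame interval Δt:

- **FREE** — Brownian diffusion with coefficient D_free (µm²/s);
  per-axis displacement variance 2·D_free·Δt per frame.
- **BOUND_SPECIFIC** — receptor-bound, residual mobility D_bound;
  entered from FREE at rate λ_on (only inside the cell region), left at
  rate k_off = 1/τ_B. Dwell times are therefore exponential with mean τ_B.
- **BOUND_NONSPECIFIC** — short-lived sticking, entered at rate λ_ns
  anywhere, mean dwell τ_ns < 1 s. This is what the 100-step specificity
  filter exists to reject.
- **BLEACHED** — absorbing; photobleaching and focal-plane exit are not
  distinguishable from the track record, so both are collapsed into a
  single termination hazard λ_bleach. The analysis never uses z, so a 2D
  simulation suffices.

Event counting connects to kinetics through 1/τ_D = k_on·c·n (events per
unit time, with ligand concentration c and receptor number n): holding c and
n fixed within a comparison, specific-event-count ratios equal k_on ratios.
Only *relative* rates are identifiable without absolute calibration, so the
package reports fold changes, and defines the relative dissociation constant
as K_D_rel = k_off / (relative k_on), the standard orientation.

## Simulator

Discrete-time state machine at Δt with transition probabilities
1 − e^(−rate·Δt) and at most one transition per frame. With Δt = 10 ms and
dwell times ≥ 1 s, the discretization bias on a mean dwell is ≈ Δt/2 = 5 ms
(< 1%), far below the statistical resolution of any analysis here.
Boundaries reflect (preserving particle number without drift); positions are
observed with independent Gaussian localization noise of std σ_loc per axis;
detection dropout (keep probability p_detect per frame) is applied when
identities are stripped to produce localization tables, so the linking
problem — fragmentation and gap closing — originates entirely there.

Defaults encode the acquisition the analysis targets: 2000 frames at
10 ms/frame, 50×50 µm field, 10 µm cell region, D_free = 2.5 µm²/s,
D_bound = 0.05 µm²/s, σ_loc = 30 nm, p_detect = 0.95, τ_ns = 0.3 s,
λ_bleach = 0.05 s⁻¹. The bound-state residual mobility is not measurable
from the track record the pipeline sees; 0.05 µm²/s is a simulator choice
placed well below the 1 µm²/s classification threshold, consistent with the
observed 0–1 µm²/s bound population. λ_on = 0.5 s⁻¹ and τ_B = 2 s give
binding occupancies of a few tens of percent inside the cell region, the
regime the classification stages are exercised in.

What the simulator does **not** emulate: anisotropic or rotational motion of
rod-shaped particles, motion blur within an exposure, fluorophore blinking,
cell-membrane topography, spatially varying receptor density, and particle
influx from bulk solution (the particle number is fixed). Passing recovery
tests therefore validate the estimators under the model's assumptions; they
do not certify tracker behaviour under, e.g., heavy blinking or strong
background gradients.

## Linking

Per frame, active track ends and current localizations are matched by exact
minimum-cost bipartite assignment on squared distance. A pair is admissible
only within a distance budget of max_link_distance × (gap + 1); the linear
growth with gap length is deliberately conservative relative to the √t
growth of diffusive displacement. Track ends unmatched for more than
max_frame_gap frames close; leftover localizations seed tracks. Two
localizations within the exclusion radius of each other are both removed
from that frame — ambiguity is resolved by refusing to guess, at the cost of
an extra gap. Defaults (0.8 µm, gap 3, 1.2 µm exclusion, ≥ 30 steps) mirror
common tracker filter settings for this acquisition. The commercial trackers
these settings come from do not document their exact semantics; here
"minimum distance between frames" is implemented as the *maximum* allowed
link displacement, since a literal minimum would discard slow (bound)
particles — at D = 2.5 µm²/s and 10 ms the 99th-percentile frame step is
≈ 0.43 µm, so 0.8 µm acts as a generous cap.

## Diffusion estimation

Time-averaged MSD with overlapping pairs; lags bridged by a gap simply have
fewer pairs. D = slope/4 of a least-squares line through the first 4 lags
(weights = pair counts, free intercept), clipped at 0 — few-lag fitting with
an offset is the standard compromise between bias (long-lag curvature) and
variance for short noisy tracks, and the intercept absorbs the localization
noise floor 4σ²_loc, which the recovery tests confirm. The anomalous
exponent α is the unweighted log–log slope over the same lags; class cutoffs
(confined < 0.8 ≤ Brownian ≤ 1.3 < directed) are pipeline conventions, as
the motion classes themselves have no universal thresholds.

Free-diffusion recovery experiments use a 200×200 µm field: the diffusion
length over a 20 s track is √(4DT) ≈ 14 µm, and in a 50 µm field reflection
introduces a small downward MSD curvature that shows up as a spurious
positive intercept component (~7×10⁻⁴ µm²). The large field realizes the
unbounded-diffusion regime the 4σ²_loc oracle assumes.

## Classification and kinetics

Bound iff D ≤ 1 µm²/s (inclusive); specific iff a bound track exceeds 100
steps (strict), i.e. 1 s at 100 fps. A bound track's dwell time is its full
duration. Dwells below the 1 s specificity threshold are excluded before
fitting, so both estimators see a left-truncated exponential — harmless for
the least-squares fit (memorylessness preserves the decay constant) and
handled exactly by the MLE oracle τ̂ = mean(dwell) − truncation point.

The histogram fit uses 0.1 s bins (10 frames; ≥ 10 bins across the ≥ 1 s
specific range), unweighted nonlinear least squares on counts initialized at
y0 = min count, A = max − min, τ_B = sample mean, tolerance 1e−8, 500
iteration budget. Unweighted count fitting matches what a generic
curve-fitting tool applied to a histogram does; the MLE oracle is the guard
against binning artifacts. At ~1000 events the fit's sampling sd is ≈ 6% of
τ_B (the MLE's is τ_B/√n ≈ 3%).

Two biases are inherent to this procedure and are quantified by the test
suite rather than corrected:

- **Right-censoring.** Track termination (bleaching, defocus) competes with
  unbinding, so the apparent rate estimates 1/τ_B + λ_bleach, an upper bound
  on k_off. Termination hazards shared across conditions cancel in
  comparisons.
- **Finite observation window.** A completed event must end before the
  movie does, length-biasing completed dwells low by a factor
  ≈ (T − 2τ_B)/(T − τ_B) for observation span T (≈ 5% for τ_B = 2 s,
  T = 40 s).

Group comparisons use one-way ANOVA plus Dunnett's test against a declared
reference (per-replicate values, SciPy implementations), with significance
stars at 0.05/0.01/0.001. SEM over biological replicates is reported as
undefined — not zero — for a single replicate; technical replicates are
pooled into their biological replicate before percentages are computed.

## Problem sizes

Validation simulations use 150–600 particles × 1000–4000 frames per
scenario and ≥ 1000 dwell events per τ_B value (5000 where the comparison
of two estimators at 2 joint SE needs the resolution); these sizes put
sampling error well inside the tolerances asserted while keeping the whole
suite and the acceptance script in the tens of seconds.

## Degenerate inputs and numerical choices

Duplicate (track, frame) rows, non-numeric coordinates and missing columns
are rejected with row-level messages. Single-point tracks are legal output
of the linker (the min-steps filter removes them) but contribute no links to
fidelity, which is *undefined* (None), not 1.0, over an empty link set.
All-zero MSDs yield D = 0 with undefined α, classed confined. A dwell sample
entirely at the truncation point yields τ̂ = 0 with a degeneracy warning.
Coordinates serialize with 10 significant digits, making write/read round
trips stable at analysis precision. Every stochastic component takes an
explicit integer seed, and equal seeds give bit-identical outputs.
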