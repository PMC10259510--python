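# Methods

## The instrument model

The twin reduces the instrument to a 1-D measurement axis (positive in the
direction the tissue pushes the tip) with four coupled parts.

**Piezo and chip.** Commanded voltage maps linearly to chip position,
`X_C = g·V + d(t)`, with gain `g` (default 0.4 µm/V over 0–150 V, i.e.
60 µm of travel) and a drift term `d(t)` performing a Gaussian random walk
with increments of s.d. `drift_rate·√dt` (default 0.01 µm/√s — about 0.6 µm
r.m.s. per hour, the scale a bench-top stage drifts). Voltage outside the
driver range saturates and is flagged, never raised. Piezo hysteresis and
creep beyond this drift are not modeled.

**Capacitive sensing.** Two plate capacitors flank the piezo:
`C1 = c0/(g0 − x)`, `C2 = c0/(g0 + x)` with `c0 = 900 pF·µm` and gap
`g0 = 100 µm` (a ~9 pF pair, ΔC sensitivity ≈ 0.18 pF/µm at center).
Each reading carries independent Gaussian noise (0.002 pF s.d. ≈ 11 nm of
position). ΔC = C1 − C2 is strictly monotone on (−g0, g0) and has the
closed inverse `x = ΔC g0²/(c0 + √(c0² + ΔC²g0²))`, used for
sensor-consistency checks; the *software* path never uses it and relies on
the swept lookup table, as the real system must.

**Cantilever.** A single linear spring: `F = k·(X_T − X_C)`, k in N/m
(0.01–0.2 for commercial probes), F in nN (`1 N/m · 1 µm = 1000 nN`), and
`σ = F/A` with `1 nN/µm² = 1000 Pa`. No beam PDE and no large-deflection
correction; a deflection beyond half the probe length raises a
"beam-theory regime exceeded" flag on the state.

**Active tissue.** The field provides no constitutive equation for an
elongating embryonic axis pressing on a probe, so the twin adopts the
minimal law that reproduces the observed phenomenology (fast initial
displacement, slowing, stall; and, for the lateral paraxial tissue,
dissipation over hours): a degree-1 Hill-like force–velocity relation

    v = v0 · (1 − σ_r/σ_a),        σ_r = k(X_T − X_C)/A,

with free velocity `v0` and active-stress capacity `σ_a`, the tip pinned to
the tissue front (no slip — a probe inserted *through* tissue cannot
plausibly slide along it at these scales). With the chip held, deflection
converges to the fixed point `δ∞ = σ_a·A/k` and the approach is monotone
with decaying increments. Dissipation multiplies σ_a by `e^(−dt/τ_d)`.
Overload behavior is configurable: by default the front stops when
`σ_r ≥ σ_a`; with `yield_when_overloaded` (used for the dissipating
scenario) the same law continues into negative velocity, capped at −v0, so
a decaying σ_a unloads the probe quasi-statically and the measured force
trace follows `σ_a(t)` — without this the trace would freeze at its peak
and no dissipation would ever be measurable.

**Cell density.** An optional 1-D linear density advects with the tissue
velocity through a flux-conservative upwind scheme whose interface at the
foil carries zero flux: cells pile up against the moving foil, none leak
through, and total number is conserved to machine precision (the
conservation test allows 10⁻⁶ relative).

**Integration.** Fixed-step explicit Euler. Dynamics are hours-slow
(mechanical response time δ∞/v0 is minutes to hours), so stability is not a
concern; control loops integrate at their inner-loop period (0.05–0.5 s in
the presets) and long scenarios record at the imaging cadence.

## Imaging and localization

Frames are rendered with analytically anti-aliased profiles (foil: a
rectangle of the foil thickness × width; sharp/triangular tip: a filled
triangle of the tip width; fluorescent label: a Gaussian spot), positioned
so the profile's intensity centroid sits exactly at the ground-truth tip
position — the renderer is therefore its own localization oracle. Imaging
through tissue is modeled as Gaussian blur with s.d. proportional to the
imaging depth D_I (default 1.5 px per 100 µm; no measurement quantifies
this, so it is a fixture parameter), plus a static textured background
(the dish/tissue scene), Poisson-scaled shot noise and Gaussian read noise,
quantized to 16-bit. The pixel size defaults to 0.5 µm and the frame rate
is bounded at 200 fps, the stated hardware limits.

The centroid localizer thresholds the background-subtracted signal (Otsu),
keeps the connected component nearest the prior, and takes an
intensity-weighted centroid over a dilated window with a column-wise
background estimate from profile-free rows. Two details matter for
sub-pixel accuracy: the window must cover the profile's dim skirt
(truncating an asymmetric profile at the threshold biases the centroid by
several hundredths of a pixel), and the static texture must be subtracted
column-wise (it does not average out over frames that share a scene). At
high SNR the estimator is unbiased to ≤ 0.02 px with RMSE ≈ 0.02 px; at the
default texture and depth the RMSE is ≈ 0.04 px (0.02 µm). The template
alternative (normalized cross-correlation with parabolic peak refinement)
is shift-equivariant but carries the reference patch's sub-pixel offset as
a constant; it is provided because the real instrument's segmentation
algorithm is unspecified and either method serves.

Movie tracking bridges gaps of up to 3 lost frames by constant-velocity
interpolation (dropouts of a frame or two must not unseat a feedback loop);
longer gaps are marked lost, and a trace with more than half its frames
lost is flagged as a quality failure.

## Calibration, stability, alignment

Calibration sweeps the voltage grid (≥ 5 points; presets use 16 across the
full range), averages 10 simultaneous (ΔC, imaged-position) samples per
point, and fits a monotone PCHIP interpolant in both directions. A held-out
validation (fit on even points plus the endpoints, score the interior odd
points) estimates the round-trip error, recorded on the table; queries
outside the swept range are refused in the public API and clamped (with a
logged saturation event) inside control loops. With default noise the
round trip agrees with the exact capacitor inverse to well under 0.1 µm.

The stability suite mirrors the three bench tests: (1) piezo unpowered —
scaffold only, voltage identically zero; (2) energized open loop — drift
accumulates; (3) capacitance feedback closed. Movement is reported from a
1 Hz timelapse of the imaged chip (so localization noise sets the floor of
the reported figures) alongside the twin's ground-truth s.d. for
controller benchmarking; the suite passes when feedback corrects the
open-loop drift and the unpowered scaffold stays within 0.25 µm.

Insertion-angle alignment images the probe at tip-focus and base-focus
planes; the on-camera displacement between the two equals `L·sin θ_I`.
Each iteration rotates by the measured tilt (a Newton step with exact unit
gradient) until the displacement falls below the localization noise floor
(0.15 µm ≈ 0.3 px): for L = 200 µm this terminates around sin θ_I ~ 10⁻³,
far inside the 0.05 practical bound. Insertion depth is the difference of
recorded objective z positions and carries the stated ±20 µm practical
uncertainty into the contact-area budget.

## Feedback control

Both protocols share an incremental PI law on the position error acting on
voltage, with clamping at the driver limits doubling as anti-windup. PI is
the minimal law that rejects constant drift; no derivative term is needed
for dynamics this slow. Gains default to kp = 0.3 and ki = 0.5·(inner
rate), making the per-step integral action rate-independent: the error
recursion then has spectral radius ≈ 0.66, settling in under ten inner
ticks at any configured rate.

*Stall measurement* pins ΔC at its value on entry; the imaging loop watches
the tip and each imaging tick appends a synchronized record row
(F = k·deflection and σ = F/A hold exactly by construction). A stall event
requires both that the tip has displaced by more than the criterion bound
(0.5 µm default) since insertion *and* that its excursion over the sliding
window (10 min default) is below that bound — arrested motion, not absence
of motion.

*Constant force* runs a two-rate architecture: the imaging-rate outer loop
measures the tip, extrapolates its short-term motion with a
constant-velocity fit over the recent window, and re-targets the chip to
`X_T_predicted − δ*` with `δ* = F*/k` (signed: assisting loads place the
chip ahead of the tip). The velocity feedforward removes the lag bias that
a pure tracking loop would leave (≈ tip speed × outer period, several nN at
stiff k); residual force error after settling is set by the zero-mean
tracking noise and averages out in the time-averaged force, which is the
quantity the accuracy figures quote.

Long Monte-Carlo runs use a synthetic tip sensor (ground truth plus
Gaussian noise at 0.05 µm, the RMSE measured from the full
render-and-localize path on equivalent frames); a short run with the
imaging sensor is tested to agree with it at the noise level. This keeps
20–50-seed experiments to seconds while the imaging path remains exercised
and validated.

## Uncertainty budget

Relative components of σ: insertion angle `1 − cos θ_I` (projected-area
effect; the off-axis force fraction `sin θ_I` is reported alongside but not
folded into σ, as no correction is applied); depth `ΔA/A` from D ± 20 µm
(zero for a fully inserted foil, whose area no longer depends on D; for a
triangular tip A ∝ D², so D = 30 ± 20 µm spans a factor of 25 and raises an
order-of-magnitude flag instead of a meaningless percentage); fabrication
(default 0.15 for cut foils, within the 0.10–0.20 fabrication spread);
tracking `k·RMSE/F` against a caller-supplied working force (unbounded and
flagged at F = 0). Components combine by worst-case sum by default — the
quoted bound for a good foil configuration reads as a maximum, not a 1-σ
quadrature — with quadrature available and the rule recorded on the result.
At the reference working point (100 µm foil fully inserted, θ_I = 15°,
high-SNR tracking of a ~100 nN force on a 0.01 N/m probe) the worst-case
total is ≈ 19 %.

## Scenario presets and the synthetic generator

* `axial_stall` — k = 0.2 N/m, 200 µm square foil (A = 4×10⁴ µm²),
  σ_a0 = 100 Pa, v0 = 150 µm/h, no dissipation: δ∞ = 20 µm, stall force
  4000 nN, stall stress 100 Pa, mechanical rise time δ∞/v0 = 8 min.
* `ppsm_compression` — k = 0.01 N/m, triangular tip, A = 10³ µm² (within
  the order-of-magnitude contact estimate for a ~30 µm insertion),
  v0 = 15 µm/h (lateral convergence is ten times slower than axial
  elongation), τ_d = 2 h, yielding on overload. σ_a0 = 200 Pa was
  calibrated once against the deterministic ODE so that the *peak* force —
  rise racing against dissipation — lands near 100 nN; the observed stall
  stress is then ~100 Pa, at the top of the 10–100 Pa band this
  configuration is meant to emulate.
* `constant_load` — k = 0.2 N/m sharp tip, F* = 175 nN (the 150–200 nN
  loading band), A = 1750 µm² and σ_a0 = 100 Pa so that the full target
  load exactly doubles the free elongation speed (v0 = 100 µm/h, the
  slowed on-microscope rate), 600 s runs inside the 60 µm piezo travel.

The cell-track generator emulates labelled clusters leaving the posterior
progenitor pool: axial velocity decays with a 1 h turn timescale (the
U-shaped path), lateral velocity is `5 µm/h + 0.04 (µm/h)/nN × load`, and
each 5-min interval adds independent 6 µm/h velocity noise per component.
At 175 nN the lateral mean rises to 12 µm/h, a shift the interval-speed +
Welch-test pipeline detects with power > 0.9 at 30 tracks per cohort.

**What the generator does not emulate.** Real embryos bring tissue
heterogeneity (scattering far more complex than a depth-proportional
Gaussian blur), probe–tissue slip and contact-angle drift at large
deflections, wound response at the insertion site, biological variability
between embryos, and 2-D/3-D mechanics (the twin is strictly 1-D along the
measurement axis). Passing tests therefore validate the *instrument
software* — sensing, calibration, control, localization, unit handling,
uncertainty accounting, statistics — under realistic noise, not any
biological claim about real tissues.

## Numerical choices and problem sizes

Default test/demo problem sizes: stall runs 3 h (axial) and 6 h (pPSM) of
simulated time at a 2 Hz inner loop and 30 s imaging cadence; loading runs
600 s at 10 Hz / 2 Hz; calibration 16 voltage points × 10 frames; 200
frames for localization statistics; 20–50 seeds for Monte-Carlo claims;
1000 replicates for the type-I-error check. The whole suite runs in well
under a minute on one core.

Ties and degenerate inputs: Otsu on a blank frame is rejected by requiring
the winning component to rise 6× above the robust noise floor; equal-mean
zero-variance cohorts return t = 0, p = 1 by convention; a stress trace
still ramping at its end reports "no plateau" rather than a number; decay
fitting starts where the trace has fallen to 80 % of peak (the immediate
post-peak shoulder still carries the probe's mechanical relaxation and
biases the timescale upward); the plateau slope test uses a regression over
the trailing 30 min window rather than pointwise derivatives, which noise
would dominate.

## Known limitations

Single-spring cantilever (no beam bending profile); linear piezo (no
hysteresis/creep); 1-D tissue with a phenomenological two-parameter law;
Gaussian blur as the entire optical transfer model; the template localizer
inherits its reference patch's sub-pixel phase; constant-force control
assumes the tissue front is differentiable on the outer-loop timescale
(a jump discontinuity would transiently break the ±5 % band until the
predictor re-locks).
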