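# Methods

## The measurement model

A head-mounted RTK GNSS antenna tracks a point rigidly linked to the trunk
at 100 Hz. In the spring-mass abstraction of running the centre of mass
(CoM) oscillates vertically once per step: it is lowest near mid-stance,
and during the aerial phase it falls until the leg begins absorbing load at
initial contact (IC), so the vertical velocity reaches its per-cycle
minimum at IC. These two facts give two single-signal event detectors:
minima of the filtered vertical position (Method 1, mid-stance) and minima
of its derivative (Method 2, IC). Consecutive events define the step time,
SF = 1/step time, SL = planar displacement between the event positions, and
velocity = SF x SL (an identity, exact by construction in every record).

## Processing chain

1. **Frame.** Geodetic samples are converted to a local East-North-Up
   frame on the WGS-84 ellipsoid tangent plane at the first epoch
   (closed-form ECEF rotation; the vertical channel carries the ellipsoidal
   height difference exactly). Over a 400 m track the tangent-plane error
   is sub-millimetre; a guard rejects spans over 10 km. Note the frame is a
   *plane at antenna height*: horizontal coordinates scale with (1 + h/R)
   relative to geodesics on the ellipsoid surface — irrelevant at the
   centimetre level over 400 m but visible in millimetre-level comparisons.
2. **Filtering.** A zero-phase (forward-backward) Butterworth low-pass,
   4th order with 5 Hz cutoff by default, is applied identically to the
   vertical and both horizontal coordinates. The two passes square the
   magnitude response and cancel phase lag; edges use odd reflection with
   3x(order+1) samples of padding. The cutoff sits above sprint step
   frequencies (~3-4.5 Hz, and `dominant_frequency` reports the
   periodogram argmax for checking it) and below the noise band.
3. **Differentiation.** Central differences (one-sided at the ends). At
   gait frequencies the attenuation sin(w dt)/(w dt) is below 0.3%.
4. **Detection.** `find_peaks`-based minima with a topographic prominence
   floor and a minimum separation; among conflicting candidates the deeper
   wins, ties go to the earlier, flat minima resolve to their first sample.
   Defaults: separation 0.167 s (caps SF at 6 Hz, above any human sprint),
   prominence 0.005 m for position and 0.05 m/s for velocity — above
   Fix-level filtered noise, far below the 3-7 cm spring-mass oscillation.
   Event times are refined to sub-sample precision by a parabolic fit
   through the three samples around each minimum; without this the 10 ms
   grid aliases into per-step SF at the 0.1 Hz level. Event positions (for
   SL) are interpolated at the refined times.
5. **Per-step records.** Record k spans events k -> k+1 and is attributed
   to the *end* event: its leg label, its cumulative distance (used to
   classify curve 5-115/205-315 m, straight 125-195/325-400 m, transition
   elsewhere), and a FLOAT_TOUCHED flag if any epoch in the interval ran on
   a Float solution. Step indexing is 1-based. The first five steps are
   excluded from temporal analyses (block-start transients); flagged steps
   are retained but excludable.
6. **Totals.** Cumulative distance is accumulated on the *filtered*
   horizontal track so noise does not inflate path length; the total sprint
   time interpolates the time at which it reaches the target distance
   (400 m default). The step count is the number of footstrike events
   (= records + 1).

## IMU reference and synchronization

Ankle accelerometers provide reference ICs: the resultant
sqrt(ax^2+ay^2+az^2) is orientation-free (gravity deliberately retained),
low-passed at 70 Hz (2nd order, zero phase), and an IC fires at the onset
of the impact transient — the first sample exceeding a rolling-median
baseline by max(3 x rolling MAD, 0.5 g), with a 0.25 s refractory period
(under half the slowest stride). The absolute floor matters: on a quiet
sensor 3 x MAD approaches the noise quantiles, while genuine footstrike
transients are several g. Onset (not peak) is the IC convention here.

Clock offset between the GNSS and IMU streams comes from the pre-run
vertical jump: the magnitude of the GNSS vertical acceleration is
cross-correlated with the head-IMU resultant deviation from rest over a
user-chosen window (both resampled to 200 Hz), with parabolic sub-sample
refinement of the correlation peak. Correlating the *acceleration*
magnitude (not the velocity) against the accelerometer makes the two
signals trace the same physical quantity and sharpens the peak. The offset
convention is `offset = t_B - t_A`; a peak correlation below 0.5 flags the
estimate unreliable. Event pairing for statistics is greedy
nearest-neighbour within a tolerance (default 40% of the median reference
step time), each event used at most once.

## Agreement statistics

For paired per-step series: bias (mean difference) with a t-based 95% CI,
SD of differences (n-1), RMSE (satisfying rmse^2 = bias^2 + sd^2 (n-1)/n),
Bland-Altman limits bias +/- 1.96 sd, Pearson r with a two-sided p-value
(undefined and reported as such when either series is constant), and
ICC(2,1) — two-way random effects, absolute agreement, single measurement
(Shrout-Fleiss) — with the exact F-based CI; ICC(3,1) is available for
sensitivity. Because ICC(2,1) penalises absolute disagreement, a constant
bias lowers it below Pearson r, which is exactly why a biased detector
scores lower ICC at equal correlation. Interpretation bins: |r| >= 0.90
excellent / 0.70 strong / 0.50 moderate / 0.30 weak / below negligible;
ICC > 0.90 excellent / >= 0.75 good / >= 0.50 moderate / below poor.
Percent match of total time is 100 x (1 - |derived - ref|/ref), reported to
two decimals. Stratified comparisons (overall, left, right, curve,
straight) skip strata with fewer than three pairs.

## The sprint simulator

The generator produces exactly the structure the detectors exploit, with
ground truth for every estimated quantity.

**Schedules.** Per-step SL and step time follow a linear ramp to a peak
(default over ~25 steps) then a linear decay whose endpoint is solved so
the totals hit the scenario's distance and time exactly. Presets:
`subjectA_like` (200 steps, peak SL 2.10 m / SF 4.00 Hz, 400 m in 55.06 s,
Float spans covering ~half the run), `subjectB_like` (242 steps, 1.86 m /
3.57 Hz, 73.07 s, all Fix), `clean_unit_test` (20 steps, zero noise).

**Vertical model.** One IC and one stance per step. Stance is a half-sine
dip of depth `osc_amp` (default 0.05 m, a literature-typical vertical
oscillation; the source data report none); flight is a ballistic parabola
anchored at the IC height with apex at mid-flight. Position is continuous
everywhere. Velocity is *not* continuous at touchdown: simultaneous
position and velocity continuity with a free dip depth is over-determined
(a half-sine of depth A exits stance at A*pi/ts, a 0->0 parabola of
duration tf must launch at g*tf/2, and the two agree at one amplitude
only), and the physical event at touchdown is an impact. The velocity step
at IC is what pins the per-cycle velocity minimum exactly at IC. The run
begins with a drive phase (gun to first strike) ending in a small hop so
the first IC is approached in flight like every other, and ends with a full
final stance followed by a half-cosine velocity settle to rest —
acceleration-continuous throughout, so the zero-phase filter has no
discontinuity to ring on and no spurious events appear after the line.

**Asymmetry.** `asym` scales the dip depth *and* the stance duration
together, per leg (the more compliant leg compresses deeper and stays
grounded longer). The coupling is essential: a pure amplitude scale leaves
the clean position waveform exactly mirror-symmetric about every mid-stance
(both flanking flight arcs are identical and both neighbouring dips belong
to the other leg), so Method 1's filtered minima would not move at all.
With the coupling, mid-stance events stay *individually* accurate but drift
within the gait cycle by ~duty x T x asym alternating sign — so Method 1's
*step-time* (hence SF) error grows with asymmetry while Method 2's
IC-pinned events are unaffected. That per-step time error is the quantity
the asymmetry analyses report.

**Horizontal model.** The runner advances along a lane-one-like 400 m path
(counter-clockwise: curve, straight, curve, straight; radius 36.80 m,
straights solved from the radius so the lap closes at exactly 400 m) by the
scheduled SL per step, with smoothstep within-step progression (speed
continuous across step boundaries). Truth SL is the planar chord between
consecutive IC positions; on these curves the chord-arc gap at 2 m steps is
<0.1 mm.

**Noise.** AR(1) Gaussian noise per ENU axis. Fix spans: SD 1 cm
horizontal / 2 cm vertical, lag-1 correlation 0.9 at 100 Hz (RTK jitter is
temporally correlated; white noise would understate minima jitter). Float
spans: 10x the SDs ("decimetre-level") with correlation 0.999 (~10 s time
constant) — real Float-mode error is a slowly drifting bias, not fast
jitter; a fast decimetre noise would wipe out step detection, which
contradicts the observed behaviour of Float spans in practice (steps remain
detectable, per-step SL degrades, totals stay accurate). Geodetic samples
come from inverting the ENU mapping at the origin (default 35 N, so
meridian/parallel scaling is non-trivial).

**IMU streams.** 1000 Hz; ankles carry 1 g plus a decaying-exponential
transient (8 g, tau 20 ms) at each IC of the matching leg plus 0.02 g
noise; the head unit carries gravity plus the analytic CoM vertical
acceleration, and the optional pre-run jump (sin^2 bump, 20 cm) appears in
both the trajectory and the head IMU. A configurable clock offset shifts
all IMU timestamps for synchronization tests.

**What the simulator does not emulate:** multipath and satellite-geometry
excursions, antenna-to-CoM lever-arm motion (head sway), soft-tissue and
footwear variation in the impact shape, wind, and physiological variability
beyond the deterministic schedules. Passing tests therefore demonstrate
correctness of the *pipeline* under the stated signal model, not field
accuracy of the hardware.

## Numerical choices and limitations

* Validation problem sizes: 20-step noise-free runs for exact recovery,
  20 seeds x 100 steps for the noise study, 10 seeds x 80 steps per
  asymmetry level — sizes at which the studied effects are stable and the
  whole suite runs in seconds.
* Digital filter gains are compared against the exact bilinear-design
  response 1/(1+(tan(pi f/fs)/tan(pi fc/fs))^(2n)); the analog formula
  1/(1+(f/fc)^(2n)) is off by ~20% already at fs/10.
* GNSS gaps up to 5 consecutive missing epochs are tolerated and logged;
  longer gaps abort detection rather than silently interpolating data.
* rtklib `.pos` epochs are rebased difference-first ((dweek) x 604800 +
  dsow) to preserve sub-millisecond precision.
* ICC values are clamped at 1 against floating-point fuzz on near-identical
  series; zero-variance series yield an explicitly undefined Pearson r.
* Detection on a full recording also fires on movement before the gun and
  after the finish; whole-run analyses therefore either trim to the sprint
  window or match events to a reference rather than comparing raw counts.
* The stance-phase dip is symmetric, so "mid-stance" coincides with the
  stance midpoint by construction; real runners' lowest CoM point can lead
  or lag the temporal midpoint of contact.
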