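# Methods

This note documents the models, conventions, and numerical choices behind
`focidyn`, and what the synthetic-data tests do and do not establish about
real microscopy data.

## Motion model

Damage-focus mobility is simulated as *tethered* (confined) diffusion: each
focus diffuses with coefficient D (µm²/s) under an Ornstein–Uhlenbeck
restoring force toward a fixed anchor. We parameterize the tether by the
**confinement radius R**, defined as the stationary root-mean-square radial
distance from the anchor, so that

- per-axis stationary variance σ² = R²/2,
- relaxation time τ = R²/(2D),
- long-lag MSD plateau (about the anchor) = 4σ² = 2R².

Frame-to-frame propagation uses the exact OU transition
x' = a + (x − a)·e^(−Δt/τ) + N(0, σ²(1 − e^(−2Δt/τ))), so the short-lag
step variance is 2·D·Δt per axis regardless of the frame interval, and the
long-run statistics match the closed forms above — those closed forms are
the oracles for the confinement-recovery tests. Free diffusion is the
R = ∞ (or `confinement_radius=None`) special case; an infinite
`nucleus_radius` additionally disables boundary reflection, giving truly
free motion for diffusion-recovery tests (a finite boundary measurably
suppresses the MSD of foci that start near it).

This model was chosen because measured focus MSD curves are sublinear and
saturate; it makes no claim about mechanism (chromatin polymer dynamics,
cytoskeletal coupling, and motor activity are all outside scope). Whether
reduced mobility in a perturbed condition reflects lower D, tighter R, or
both is left open: the simulator exposes both knobs independently.

Other simulator conventions:

- **Boundary**: radial reflection at the nuclear radius (keeps the focus
  count stable; absorption would confound disappearance statistics).
- **Drift**: a rigid per-frame offset shared by all foci, either a constant
  velocity vector or an arbitrary per-frame series; recorded positions
  include it, and the true offsets are kept in the ground truth.
- **Fusion**: two foci closer than `fusion_radius` merge; both parent
  tracks end the frame before, one child starts at the intensity-weighted
  mean position with summed intensity. Total track count never increases.
- **Disappearance**: exponential lifetime per focus (rate λ), equivalent to
  per-frame loss probability 1 − e^(−λΔt). Event times are recorded at the
  first absent frame, i.e. ceiling-discretized to the frame grid; tests and
  consumers must allow for the ≤ one-frame (+Δt/2 median) bias.
- **Seeding**: one master seed; every focus draws from its own
  counter-derived substream, so adding focus n+1 leaves the paths of foci
  0..n bit-identical. Rendering and stripe noise use separate substreams.

Default parameters emulate the standard acquisition conditions: mobility
movies at one frame per 30 s for 10 min (21 frames), event movies at one
frame per 3 min for 1 h; ~20 foci in an 8 µm-radius nuclear disk (an
etoposide-induced focus load); D = 0.005 µm²/s with R = 0.5 µm, placing
the MSD plateau at 0.5 µm² and per-step motion in the few-hundred-nm
range typical of damage foci; 0.1 µm pixels, a 1.5 px PSF, 100-photon
background, SNR 10. The event protocol adds a 0.35 µm fusion radius and a
disappearance rate of ln2/20 min. Where the underlying publications report
only cadences and qualitative behaviour, these values are this package's
own choice of realistic study conditions and are fixed, not tuned.

## Rendering

Each live focus becomes an isotropic 2D Gaussian at its subpixel position
with width `psf_sigma` (px). The Gaussian is evaluated over the whole frame
rather than a truncated window: a hard cutoff leaves C⁰ kinks that a
band-pass detector amplifies into rings of spurious maxima. Peak amplitude
is `snr` × the background noise standard deviation, with noise modelled as
Poisson shot noise on signal + background plus additive Gaussian read noise
(2 photons RMS). `noise=False` returns the expected-photon image — the
noiseless oracle used for exactness tests. Rendering is 2D; z-stacks exist
only as metadata because all quantification uses projected positions.

A deterministic *scheduled-event* generator (`simulate_scheduled_events`)
places foci on concentric rings with a guaranteed minimum spacing;
designated pairs converge linearly and merge at exact frames, designated
foci vanish at exact frames, and everything else wiggles in place with
~60 nm RMS. Converging pairs hold ≥ 0.8 µm separation until the frame
before their merge so they remain optically resolvable and the event is
scored at the scheduled frame, not earlier. This is the oracle movie for
end-to-end event-scoring tests.

## Detection

Spots are strict local maxima of the scale-normalized
Laplacian-of-Gaussian response (−σ²·LoG), median-centred to remove the DC
leakage of the truncated filter kernel. The threshold is expressed in
robust noise units — `threshold` × 1.4826 × MAD of the response, default 5
— making it scale-free across SNRs; an absolute floor of 10⁻⁶ × the
response maximum (independent of the user threshold, so threshold
monotonicity holds) rejects float-level ripple on exactly noiseless
images. Maxima closer than the merge radius (default 2σ, the resolution
limit) are merged strongest-first. Subpixel refinement is an
intensity-weighted centroid in a (2·⌈2σ⌉+1)² window after subtracting the
window-perimeter median; centroiding was chosen over iterative Gaussian
fitting because it is deterministic with no convergence failure modes (the
Gaussian fit exists in the test suite as the localization oracle; at
SNR 10 both land within ~0.15 px RMS of truth). Coordinates are 0-based
pixels, (x, y) = (column, row); micrometre positions are
origin + pixel × pixel size, stated in every CSV header.

## Tracking

Greedy nearest-neighbour linking, shortest distance first (ties broken by
lower track id), each spot used once; unmatched spots seed new tracks;
tracks silent for more than `max_gap` frames (default 1) are closed.
`max_disp` defaults to 1.5 µm per link — a generous bound on per-step focus
motion at the 30 s cadence. Spots are canonically ordered within each frame
before assignment, so the output is invariant to input row order. Greedy
linking is deterministic and, at damage-focus densities (inter-focus
spacing ≫ per-step motion), agrees with the globally optimal assignment;
the exhaustive minimum-total-displacement matcher is kept in the tests as
an oracle, not as a production path. Gap-closed frames are not
interpolated — MSD pair counting simply skips missing frames. No Kalman
prediction and no split/merge resolution inside the linker; events are
scored downstream.

**Known limitation**: when two real foci approach within the optical merge
radius, detection returns one spot at their joint centroid and the linker
may swap identities when they separate. Displacements spanning a swap
reference the wrong focus, so the MSD of detected tracks inflates at long
lags in dense fields (visible as a plateau overshoot). Ground-truth
trajectories do not have this artifact; exactness tests therefore use
separated-foci layouts, and MSD reporting defaults to lags up to half the
movie length, where pair counts are high and swap contamination is
smallest. Real analyses should treat long-lag values with the same caution.

## MSD, drift correction, distance travelled

The global centre (GC) is the unweighted per-frame centroid of all tracked
focus positions — computable from tracking output alone, and cancelling
rigid translation exactly (the drift-injection tests verify invariance to
<10⁻⁹ µm²). A frame with no tracked focus has no GC; such frames are
skipped, never zero-filled. An optional nucleus-mask centroid mode is not
provided in this release. MSD averages over both foci and time origins;
lag 0 is reported as 0, lags with no valid pair are omitted, and the
per-lag pair count and standard error accompany every value. For n
independent walkers the GC reference deflates the expected MSD by
(1 − 1/n); the diffusion-recovery test targets D·(1 − 1/n) accordingly.

Distance travelled sums Euclidean step lengths between consecutive
*observed* frames of the drift-corrected trajectory within the requested
window (default raw mode available for sensitivity checks); by the triangle
inequality it bounds the net displacement from above. Pooling foci across
cells (rather than averaging per cell first) is the default reduction.

Model fits: the free model is a closed-form least-squares line through the
origin; the confined model uses bounded Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with data-derived starts (plateau ≈ max MSD,
τ ≈ an early lag) and reports per-parameter standard errors;
non-convergence raises with diagnostics rather than returning defaults.

## Event scoring

A **fusion** requires a track to terminate within `fuse_radius` of another
track that exists in the next frame and persists ≥ `persist` frames
(default 2) — the persistence requirement distinguishes coalescence from
crossing at a 3-min cadence, a convention of this package since the
distinction is not observable in a single frame. Terminating parents
matched to the same survivor at the same frame are grouped into one event,
so the scorer handles both ground-truth bookkeeping (both parents end, a
child starts) and tracker output (one parent continues through the merge).
The default `fuse_radius` is 2·psf_sigma·pixel_size (resolution-limited
coalescence).

A **disappearance** requires the track to end more than `confirm` frames
(default 2) before the movie end with no spot of any track within the
linking radius during the confirmation window, and the track must not be a
fusion parent (no double counting). Tracks ending at or near the final
frame are censored. Time-to-disappearance is measured from recording start
to the first absent frame; when acquisition began a fixed delay after
treatment, that offset is experiment metadata and is not added to the
times. A partition check (`partition_terminations`) classifies every track
termination into exactly one of {fusion parent, disappearance, censored,
unresolved}; on clean synthetic data the unresolved class is empty.

## Stripe enrichment and recruitment kinetics

Relative enrichment is the mean in-stripe intensity divided by the mean
out-of-stripe intensity, frame by frame (ratio within each image, so the
measure is invariant to global intensity scaling; an optional t₀-normalized
mode exists for movies with a pre-damage frame). The background region
excludes a 3 px guard band around the stripe so PSF bleed-through cannot
inflate the denominator, and is restricted to the cell mask when one is
supplied. Near-zero denominators flag the frame rather than emitting a
number. Whether the out-of-stripe reference should be the whole nucleus or
a matched contralateral band is not standardized; this package uses all
non-guarded pixels of the (masked) frame.

The recruitment model is
R(t) = 1 + A_fast·(1−e^(−k_fast·t))·e^(−γ·t) + A_slow·(1−e^(−k_slow·t)):
a fast component that rises within ~1 min and decays as its recruiting
mark is removed (γ), and a slow, persistent component. The fast-component
peak time has the closed form ln(1 + k_fast/γ)/k_fast, used as a test
oracle. Defaults (A_fast = 2, k_fast = 0.05 s⁻¹, γ = 0.006 s⁻¹,
A_slow = 1, k_slow = 0.004 s⁻¹) put the fast peak at ~45 s with decay
largely complete by ~10 min. Setting A_fast = 0 reproduces a
PARP-inhibited profile, A_slow = 0 an ATM-inhibited one, and the fitter
reports both amplitudes so the regimes are distinguishable.

Fitting is bounded nonlinear least squares with multi-start over a small
grid of rate constants (36 starts), because the five-parameter family has
rate/decay trade-off local minima; the best residual wins, and
single-component fallbacks are attempted and flagged if the full fit fails
everywhere. The synthetic stripe movie used for round-trip validation
records 15 min at 10 s intervals over a 12 px-wide stripe in a 128×160
field: five parameters are only well identified when the slow component
approaches saturation within the record, and this geometry keeps all
parameter errors within a few percent at SNR 10.

## Statistics

Condition comparisons use the classical pooled-variance two-sample
Student's t-test with two-sided p (Welch's variant by flag), matching the
test conventionally reported alongside focus measurements; stars map
p < 0.05/0.01/0.001 to */**/***. Zero variance in both groups with equal
means returns t = 0, p = 1; with unequal means the case is raised as
degenerate rather than silently returning infinity. No multiple-testing
correction is applied; `compare_all` reports the number of comparisons so
users can apply their own. Per-cell nesting is not modelled (no
mixed-effects layer) — measurements are pooled at the focus level, a known
simplification.

## Problem sizes and tolerances

The verification suite uses: brute-force MSD agreement on fixtures up to
10 foci × 20 frames at 10⁻¹² µm²; drift invariance at 10⁻⁹ µm²; diffusion
recovery with 50 foci × 21 frames × 50 seeds against a 99% CI;
confinement recovery with 100 foci × 25 seeds within 20% of 2R²;
event scoring on a 30-focus noiseless movie with 5 + 5 scheduled events at
exact precision/recall; disappearance statistics with 350 tracks × 121
frames against a bootstrap 95% CI of ln2/λ; recruitment round trips within
5% (noiseless) and 15% (SNR 10); and t-test agreement at 10⁻¹⁰. These
sizes give stable statistics at interactive runtimes; all are the
package's own choices.

## What passing tests do not show

The simulator emulates the *statistical* structure the analysis assumes —
it does not reproduce chromatin polymer mechanics, heterogeneous nuclear
backgrounds, photobleaching, focus splitting, z-drift, or non-Gaussian
PSFs. Passing the suite demonstrates that the pipeline measures correctly
*when its assumptions hold*; on real movies, background structure and
density-dependent identity switches (see Tracking) remain the dominant
failure modes and deserve visual spot checks.
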