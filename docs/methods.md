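# Methods

This note records the models, conventions and design choices behind
`tiltpipe`, in the order data flows through the system.

## Scope and stance

The package reproduces the *orchestration contracts* of a facility cryoET
live-processing deployment — queue semantics, DAG recipes, tilt-series
aggregation, autoscaling, transfer safety — at a scale where everything is
testable on one CPU in minutes. The numeric stages are real algorithms
(not mocks), but deliberately minimal ones: they stand where a production
deployment runs dedicated GPU tools, and those tools remain reachable
through command templates (`stages.external`) that are built and validated
but never executed here.

## Queue model

Queues are FIFO per queue; consuming moves a message to an un-acknowledged
set with deadline `now + ack_timeout`; a sweep returns expired messages to
the *front* of their queue (transient failures should retry promptly, and
live feedback favours low latency over strict global ordering). The
delivery limit (default 3) bounds retries: a message whose next delivery
would exceed it is dead-lettered instead, so a poison input cannot occupy
consumers indefinitely, and dead messages are only ever reinjected by an
explicit operator action, which resets their delivery budget. Payloads are
round-tripped through JSON at publish time so the in-process backend stays
interchangeable with a wire protocol. The backend is in-memory and
process-local by design; durability across host loss is explicitly out of
scope.

Failure classification is one rule applied everywhere: missing or
unreadable files are *transient* (the filesystem may be recovering —
requeue), validation failures (blank movie, too few tilts, malformed
record) are *permanent* (dead-letter). The classification is carried in
the stage result; the worker only translates it into ack/nack.

## Recipes and idempotency

Recipes are YAML data, not code: vertices name services, edges carry
results. Two recipes ship, one per data domain — `preprocess` (per movie)
and `reconstruct` (per tilt series). The movie → tilt-series transition is
deliberately *not* an edge: a DAG edge cannot express "N inputs, once
complete", so that aggregation lives in the coordination server's
registry.

Every unit of work carries an idempotency key
`session:recipe:vertex:input`. Dispatch, downstream routing and outcome
insertion all deduplicate on it, which is what makes at-least-once
delivery safe: a worker that dies after routing but before acking causes a
redelivery whose re-routing and re-recording are no-ops. Fan-out payloads
carry value copies, never references, so retries are self-contained.

Every service with a `record_kind` publishes an outcome-record request on
success. Besides the four analysis kinds (motioncorr, ctf, tomogram,
denoised_tomogram) the images service records its panels under kind
`images`, so terminal vertices always leave a queryable trace.

## Motion correction

Per-frame translational shifts are estimated by FFT cross-correlation of
each frame against the running aligned average, integer peak within
±`max_shift` (default 16 px — it must cover the worst *cumulative* drift
over a movie, not the per-frame step), refined by separable parabolic
interpolation of the correlation peak. Two numerical guards matter: the
parabola is skipped when the peak is too flat for the offset to be
meaningful (smooth noiseless images otherwise amplify float noise), and
estimates within 5·10⁻³ px of an integer are snapped — genuine subpixel
offsets under realistic noise are an order of magnitude larger. Boundary
conditions are periodic (`grid-wrap`), matching the generator's cyclic
drift; note that scipy's `wrap` mode is *not* periodic. With integer
ground-truth drift and no noise, recovery is bit-exact and the corrected
average equals the clean projection; an exhaustive ±window integer search
is kept alongside as an independent oracle.

## CTF estimation

The estimator fits only defocus (astigmatism and phase plates are out of
scope). Conventions: defocus in µm, underfocus positive; χ(k) = πλΔz k² −
½πC_s λ³k⁴ + arcsin(A); CTF = −sin χ; λ from the relativistic electron
wavelength (0.0197 Å at 300 kV). The radially averaged power spectrum is
high-passed by subtracting its own heavily smoothed profile, and the same
filter is applied to each candidate CTF² model; the fitted defocus is the
grid argmax of the Pearson correlation over the configured search range
(default 0.5–5 µm in 0.05 µm steps), restricted to 12–88 % of Nyquist
(below: background dominates; above: ring spacing approaches the bin
width). The fit score is that correlation; scores below 0.1 flag low
confidence. A constant image scores 0. When the true defocus lies outside
the search range the argmax is an essentially arbitrary in-range value
with a low, flagged score — the flag, not the value, is the contract.

On the default 64 px frames the radial spectrum has too few bins to
resolve Thon rings, so quantitative recovery is demonstrated on 256 px
synthetic micrographs (white noise × CTF, whose expected power spectrum is
exactly the fitted model family); in the end-to-end session the CTF
service exercises plumbing and record-keeping, not metrology.

## Alignment and reconstruction

Geometry: volumes are (Z, Y, X), z along the beam at zero tilt, tilt axis
along y, angles in degrees, rotation about y only; a projection at angle θ
maps centred volume coordinates to the detector coordinate
u = x·cosθ − z·sinθ. The projector (shared by the synthetic generator and
the aligner) integrates along the beam by linear interpolation.

Alignment is translational and uses *projection matching*: each raw tilt
is cross-correlated against the reprojection of the current
reconstruction, and the reconstruction is repeated with the refined shifts
(2 iterations by default, converging earlier when shifts stabilise).
Correlating adjacent tilts directly — the more obvious scheme — conflates
genuine stage shifts with the parallax of off-plane content, which moves
by z·Δ(sinθ) between tilts even in a perfectly aligned series; matching
against the model's own reprojection cancels that term, and an aligned
series is a fixed point (shifts below 0.25 px snap to zero, so the
all-zero trace is exact). This is also how production fiducial-less
aligners work. Translational alignment cannot, by construction, recover
the x–z degeneracy of a single dominant off-plane feature; the tests
inject global shifts of a few pixels, which it recovers well enough to
preserve reconstruction quality.

Reconstruction is weighted back-projection: ramp filter |f| along x, then
accumulation with linear interpolation, scaled by π/2N. A 64³ sphere
phantom projected over 11 tilts (−50°…+50°) reconstructs with Pearson
r ≈ 0.70–0.74 against ground truth — the missing wedge and ramp ringing
bound this well below 1 — and the frozen acceptance threshold is r ≥ 0.5.
A point source reconstructs with its maximum at exactly the true voxel. A
series needs ≥ 3 strictly monotone tilt angles; anything less is a
permanent validation failure.

Denoising is an isotropic Gaussian (σ = 1 voxel by default), the
desk-scale stand-in for a trained denoising model: variance never
increases, σ = 0 is the identity, and on the noiseless phantom
reconstruction it slightly *raises* ground-truth correlation by smoothing
back-projection streaks (the frozen regression bound allows at most a 0.05
drop).

## Coordination, transfer, completion

The transfer client polls rather than subscribing to filesystem events: a
file is acted on only when its size is unchanged across two scans
(write-completion heuristic). Metadata sidecars grow in place while a
series is acquired, so they bypass the stability gate and are mirrored
every poll, *before* any movie registration — membership and completion
information always leads the data. Movie copies are verified by MD5 (a
content-identity check, not a security boundary; size is compared first);
the source is deleted only after verification, an interrupted or
mismatched copy deletes the partial destination and retries, and the
source is never touched until a verified destination exists.

Series membership comes from the sidecar (`SeriesID`, `TiltAngle`,
`SubFramePath`), falling back to the `<series>_<index>_<angle>.mrc`
filename convention; a movie with neither is quarantined with an alert and
never blocks its neighbours. Completion requires an explicit acquired
event carrying the expected tilt count (the generator writes it as the
sidecar's `ExpectedTilts` line); an inactivity timeout would mask
acquisition stalls and is deliberately not the default. If more movies
are observed than declared, the declared count is raised and an alert
recorded.

The registry is embedded SQLite behind a single server-side lock; the
reconstruction trigger is an atomic compare-and-set on the series row, so
any number of concurrent or reordered completion checks dispatch exactly
once. Event-order independence holds for every *causally consistent*
arrival order (a movie's correction mark follows its registration — marks
for unknown movies are, by contract, logged no-ops); the acquired event
may arrive anywhere. The client and server share a process here; the same
three operations are also exposed as JSON over HTTP for a genuinely
remote client.

## Runtime, scaling, spillover

Replicas are concurrent workers inside one runtime — individually
killable, which is the property the tests need; the orchestrator steps
them deterministically on a simulated clock (1 tick = 1 s), so every fault
schedule reproduces the same event log. Service time is modelled in ticks
(reconstruction 5, denoising 2, others 1); dispatch and record insertion
are sub-tick services allowed to absorb many messages per tick (32), since
in reality they are orders of magnitude cheaper than the imaging stages —
without that contrast the dispatcher queue would absorb any acquisition
burst and no reconstruction spike could form.

Desired replicas = ceil(depth / messages_per_instance), clamped to the
per-service bounds (motion correction 8, CTF 4, reconstruction 4,
denoising 2, LIMS connector 4, images 4, dispatcher 2), re-evaluated under
a 5 s cooldown. Scale-down removes idle workers only — never one holding a
message. GPU-class services additionally compete for a local GPU capacity
(default 8 slots, allocated in catalogue order); when every local GPU slot
is busy and a GPU service's queue still has depth, remote-pool submitters
spin up and consume from the same queue. Spin-up is saturation-gated; an
already-running remote worker may finish its message after saturation
ends. The remote pool is a second local pool wearing a label — actual
cluster submission is out of scope.

## Synthetic data

Defaults are the desk-scale study conditions: 64×64 px frames at 4 Å/px, 8
frames per movie, 11 tilts from −50° to +50°, 3 series, sphere phantoms of
64³ voxels with 5 non-overlapping spheres (rejection-sampled; impossible
packings warn and place fewer), per-movie integer drift uniform in ±2
px/frame applied cyclically, Gaussian noise σ = 1 on projection values of
order 10 (generous SNR — these tests probe mechanism, not detection
limits). CTF blur is off by default so drift and reconstruction recovery
are not confounded; when enabled, per-series defocus is uniform in 1–3 µm.
Schedules are `sequential` (series contiguous, completion marker
immediately after the last tilt) or `beam_shift` (angle-major across
groups of `burst_size` series, so a whole group completes within
`burst_size` gaps — the burst the autoscaler must absorb). Every replay
writes a manifest with all seeds and parameters; each movie is exactly
regenerable from it.

What the generator does **not** emulate: electron-optical image formation
(dose, detective quantum efficiency, radiation damage), stage-jitter
inter-tilt shifts, fiducials, astigmatism, sample-dependent contrast.
Passing tests therefore demonstrate that the pipeline's *mechanisms* —
recovery, ordering, conservation, scaling — are correct, and that the toy
stages invert their own generative model; they say nothing about
biological image quality on real data.

## Reporting

Outcomes are unique on (session, kind, series, movie, idempotency key) —
absent movie ids are stored as empty strings because SQL NULLs defeat
uniqueness. The report is static HTML plus `summary.json` (the
machine-testable surface): per-series pages with micrograph thumbnails and
power spectra in tilt order, tomogram central slice and projections,
denoised beside raw; missing artifacts render as placeholders with a
warning rather than failing the report.

## Known limitations

Single-process, single-host: the broker and registry are in-memory/
embedded, and "remote" execution is a labelled second pool. No dose
weighting, no astigmatism, no iterative (SART/SIRT) reconstruction, no
trained denoiser. Alignment is translation-only and cannot resolve the
parallax degeneracy of dominant off-plane features. The CTF fit is 1-D.
Timings are simulated ticks, not wall-clock benchmarks.
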