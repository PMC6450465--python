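# Methods

## Alternans statistic and mapping pipeline

The per-pixel statistic is the normalized alternans magnitude
NAM = |A − B| / (A + B), with *A* the mean calcium-transient amplitude of
even-indexed beats and *B* of odd-indexed beats; the signed variant
(A − B)/(A + B) carries phase. Beat parity is anchored to the first
recorded stimulus — the anchor is arbitrary, so phase is meaningful only up
to a global sign, and shifting the anchor by one beat negates every signed
value while leaving NAM unchanged. With an odd beat count the final beat is
dropped so both parity series have equal length (unbiased means). APD
alternans is the same statistic on per-beat action-potential durations.

Per beat, the amplitude is the window peak minus a baseline taken as the
minimum over the 10 ms preceding the stimulus (robust to slow drift; the
first beat, which has no earlier context, uses its onset sample). Beat
windows are aligned to the known stimulus onsets; the final partial beat is
dropped. CaTD90 runs from stimulus onset to the linearly interpolated
recovery of 90 % of the peak-to-baseline excursion; beats that never
recover in-window are right-censored and excluded from averaging.

Preprocessing defaults: per-pixel linear detrend, 3×3 spatial mean filter,
3-frame temporal mean filter — all configurable through
`AnalysisSettings`. A pixel is valid when its mean beat amplitude exceeds
`snr_k` (default 5) times a robust per-pixel noise estimate (1.4826·MAD of
the second difference, scaled by √6); weak-signal scar pixels fail this
test. Nodal lines are marching-squares zero contours of the signed map,
kept only where a 3×3 neighborhood reaches NAM ≥ 0.05, so regions without
alternans produce no spurious contours.

Two accuracy regimes are deliberately distinguished. With preprocessing
disabled (`AnalysisSettings.raw()`), the pipeline must reproduce the
generator's programmed NAM to machine precision — spatial filtering mixes
pixels with different alternans and detrending perturbs amplitudes at the
~10⁻³ level, so exactness checks bypass them. With the defaults and 5 %
noise, the claims are statistical: median per-pixel |error| ≤ 0.02, nodal
lines within 2 px, zone ratio within 10 %.

Recording-level numbers are means over valid pixels per zone (the BZ/NZ
ratio is the ratio of those means); three repeat recordings of a condition
are averaged element-wise, and fewer repeats are averaged with a warning.
The CaTD90→alternans relationship is an ordinary least-squares regression
with the standard t-test on the slope and R² as squared correlation.

## Synthetic movies

The generator writes 32×32-pixel, 1 kHz, 1 s recordings per pacing rate
(default ladder 140…80 ms), mirroring typical panoramic-mapping geometry
(7×7 mm field). Each pixel's calcium trace is a train of single-beat
transients: a half-cosine rise to the peak (`time_to_peak`, default 15 ms)
followed by exponential decay (`decay_tau`, default 25 ms; border-zone
pixels 1.3× slower, giving the BZ its prolonged CaTD90). The decay is
tapered smoothly to baseline ending 10 ms before the next stimulus, so
beats have compact support: the pre-stimulus baseline window is exactly
flat and measured amplitudes are exactly proportional to programmed ones —
that is what makes the machine-precision round trip meaningful. The taper
does not disturb CaTD90 at the slow rates where transient duration is
analyzed (the 90 %-recovery point falls well before it).

Even/odd beats have amplitudes a(1+s) and a(1−s), where s is the pixel's
signed field, so the true NAM is exactly |s|. Fields are either uniform per
zone or discordant: s = peak·tanh(d/w) with d the signed distance from a
programmed nodal line (w = 4 px). Noise is zero-mean Gaussian per frame and
pixel with SD expressed as a fraction of the mean beat amplitude (default
5 %) — the simplest model that exercises the SNR mask. A voltage channel
with square-ish APs whose APD alternates in phase with calcium is generated
alongside. Perfusion-condition labels scale the generator: norepinephrine
multiplies alternans by 0.4 (the experimentally reported median ~60 %
attenuation) and shortens the transient 10 %; adding metoprolol restores
control values.

What the generator does *not* emulate: optics (dye spectra, photobleaching,
motion), spatially correlated noise, and any reaction–diffusion origin of
the patterns (alternans fields are prescribed, not emergent). Passing tests
therefore validate the *measurement* pipeline, not biological inference
from real recordings.

## Cell model

The shipped model (`"ca-ms"`, a registered plugin; other equation sets can
be registered by name) is phenomenological:

* **Membrane** — a two-variable excitable system: normalized potential *v*
  (mapped to mV as Vm = −85 + 110·v) with a cubic ingoing current gated by
  a recovery variable *h* (τ_in = 0.3 ms, τ_out = 6 ms, v_gate = 0.13);
  *h* drains during the AP with the per-beat repolarization constant
  τ_close and recovers with τ_open = 30 ms. APD is ∝ τ_close.
* **Calcium cycling** — cytosolic calcium decays exponentially (τ_ca: NZ
  45 ms, BZ 60 ms); the SR load *s* refills toward 1 (τ_refill: NZ 140 ms,
  BZ 250 ms); at each upstroke a sigmoidal fraction
  r_max/(1 + (K/s)^γ) of the load is released (γ = 24; r_max/K: NZ
  0.6/0.85, BZ 0.7/0.90). Steep release against slow refill is the classic
  period-doubling instability of calcium cycling: with these values the BZ
  map alternates at a 300 ms cycle length but not at 400 ms, and the NZ map
  is stable above ≈180 ms. These regimes were fixed once by map-level
  analysis and define the phenotypes.
* **Calcium→APD coupling** — each beat's τ_close is the baseline times
  (release/reference)^0.4, clipped to [0.35, 1.30]; the reference is the
  phenotype's own steady-state release at the 300 ms reference rate
  (computed from the beat map at construction). A large-release beat is
  long, and a premature beat with a depleted SR is strongly abbreviated —
  calcium-driven APD alternans and calcium-driven APD restitution in one
  mechanism.
* **Post-repolarization refractoriness of the BZ** — in border-zone cells
  the recovery gate recovers only once the membrane is repolarized below a
  deep level (v < 0.03 at full deficit, vs. the excitation gate 0.13 for
  NZ), a documented electrophysiological hallmark of the infarct border
  zone. The per-beat deficit scales with the square of the normalized SR
  release, so the long (large-release) alternans beat leaves the deepest
  refractoriness. Functionally this is what blocks a premature wave inside
  the BZ: tissue held semi-depolarized by a stalled wavefront's foot or a
  neighboring plateau cannot restore excitability, so a waiting front dies
  instead of creeping through.
* **β-adrenergic stimulation** (`bar_level` ∈ [0, 1], steady-state — no
  PKA kinetics) — accelerates SR refill (−55 % τ_refill at full level) and
  cytosolic decay (−30 % τ_ca), removing the alternans instability and
  shortening the calcium transient; shortens the baseline APD by 2 %; and
  reverses the BZ remodeling of repolarization and of the recovery deficit,
  so a fully stimulated BZ cell behaves like NZ ("faster recovery of
  excitability").

Integration is explicit fixed-step (default dt = 0.02 ms); halving or
doubling dt moves APD90 by < 0.1 ms. Trajectories are bit-deterministic.
APD90 is measured from the −40 mV activation crossing to the interpolated
downward crossing of peak − 0.9·(peak − takeoff), with the takeoff
potential the diastolic minimum of the 10 ms before the upstroke (a
last-sample definition lands mid-upstroke and jitters the level). ERP is a
single-cell S1–S2 scan at 1 ms resolution: the shortest interval whose S2
elicits a *new* upstroke with ≥ 80 % of the steady S1 amplitude.

One caveat worth knowing: for an alternating BZ cell the single-cell ERP
probe lands after whichever beat ends the pre-pacing train; after the short
beat the measured ERP is short. β-adrenergic ERP comparisons are therefore
made on the non-alternating NZ phenotype.

## Fiber

The cable is monodomain with no-flux ends: 240 cells, dx = 0.01 cm, BZ at
cells 80–159, S1 to the five leftmost cells, 500 pre-pacing beats by
default. The diffusion coefficient default (1.2×10⁻³ cm²/ms, CV ≈
0.036 cm/ms — within the physiological ventricular range) was chosen
together with the geometry: a larger value lengthens the electrotonic space
constant and smears BZ alternans into the adjacent NZ. Even so, monodomain
electrotonics unavoidably produce intermediate alternans within ~0.2 cm of
the BZ boundary; "confinement" is therefore assessed at the representative
cells of the standard geometry (BZ center cell 128, distal NZ cell 220) and
as a BZ/NZ mean contrast, not cell-by-cell at the boundary.

`run_prepace` snapshots the full state immediately before each of the last
two S1 stimuli and records which snapshot precedes the long-APD BZ beat, so
S2 protocols restart with pinned beat parity. Coupling intervals are
measured from the S1 stimulus of the preceding beat. Activation is the
−40 mV upcrossing; conduction velocity is a linear fit of activation time
against position.

Problem sizes: tests and the acceptance script pre-pace for 60 beats — the
alternans pattern, its amplitude (to ~1 ms) and the snapshot parity are
converged by ~40 beats (checked against 100-, 200- and 500-beat runs) — and
scan coupling intervals on the 1 ms grid with an early stop after a run of
full-propagation outcomes.

## Vulnerability protocols

S2 outcomes are classified from post-S2 activations: FULL_PROPAGATION iff
the five-cell sentinel groups at both fiber ends activate; NO_PROPAGATION
iff no cell outside the stimulated segment activates; BZ_BLOCK otherwise
(the wave enters but fails to traverse the BZ). Two operationalizations are
documented: cells within 3 cells of the segment count as part of it,
because a stimulus into relatively refractory tissue excites its immediate
neighbors electrotonically without launching a wave (a graded local
response, not propagation); and a sentinel group swallowed by an
end-located segment is vacuously satisfied.

The conduction-block S2 is delivered to proximal NZ, by default 50 cells
(0.5 cm) before the BZ edge: far enough that the segment's repolarization
is genuinely that of non-infarcted tissue (segments within the plateau
space constant of the BZ inherit its prolonged repolarization and leave no
differential recovery to scan), yet on the S1 side so the premature wave
must traverse the BZ. It follows the long-APD BZ beat. The PVC S2 is a
five-cell segment centered in the BZ (fiber middle for NZ-only fibers),
after the short-APD beat; "propagating" requires both fiber ends. Scans are
strictly linear on a 1 ms grid over 150–320 ms (PVC: 140–340 ms);
monotonicity of the outcome sequence is verified and flagged, never
assumed.

The five-fiber table (A: 300 ms NZ-BZ-NZ; B: 300 ms NZ; C/D: the same at
400 ms; E: as A at full β-adrenergic level) reports the shortest
propagating coupling interval per fiber; fibers that fail to pre-pace
appear as partial rows carrying the error.

## Known limitations

* The cell model is phenomenological: absolute milliseconds (APDs, ERPs,
  window edges, table values) are not comparable to ionic-model or
  experimental values — only the orderings and window structure are claims.
  A published ionic equation set can be dropped in through the model
  registry, and all protocols run unchanged.
* Two-variable membranes exhibit a band of very slow, supernormal
  conduction just above ERP; the BZ recovery deficit is what converts the
  resulting "creeping" premature waves into honest block within the border
  zone. Without it (e.g. for NZ-only fibers) near-ERP S2 waves propagate
  with long latency rather than blocking.
* The mapping generator prescribes alternans patterns; it cannot test
  hypotheses about how nodal lines form.
* No 2D/3D tissue, no re-entry induction, no gap-junction or sodium-current
  remodeling in the BZ, no receptor-subtype pharmacology.
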