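# cardalt

Cardiac alternans — the beat-to-beat alternation of calcium-transient
amplitude and action-potential duration (APD) at a constant pacing rate — is
a precursor of ventricular arrhythmia, and the infarct **border zone** (BZ),
the remodeled-but-viable tissue surrounding a healed scar, is especially
prone to it. `cardalt` is a toolkit for studying this in two connected
settings:

1. **Optical-mapping analysis.** Dual-channel (voltage + calcium)
   fluorescence movies recorded during rapid pacing are analyzed per pixel.
   With *A* the mean calcium-transient amplitude of even beats and *B* of
   odd beats, the **normalized alternans magnitude** of a pixel is

   NAM = |A − B| / (A + B),

   independent of absolute fluorescence; its signed variant carries the
   alternans phase, and zero crossings of the signed map are the **nodal
   lines** separating discordant regions. The package ships a synthetic
   movie generator with programmed per-pixel alternans, BZ geometry,
   calcium-transient shape (time-to-peak, CaTD90) and noise, so every stage
   of the pipeline is testable against known truth.

2. **Fiber simulation.** A 1D monodomain cable of phenomenological
   ventricular myocytes — a two-variable excitable membrane driven by a
   two-variable calcium-cycling subsystem whose SR-release steepness
   controls alternans — with an NZ–BZ–NZ composition, S1 pre-pacing, and
   S1–S2 vulnerable-window protocols: conduction block of an extrastimulus
   delivered after the long-APD alternans beat, and premature-ventricular-
   complex (PVC) propagation after the short-APD beat, with β-adrenergic
   stimulation as a continuous condition level that accelerates calcium
   reuptake, shortens the APD and reverses BZ remodeling.

## Worked example

Analyze a synthetic recording whose border zone was programmed with
alternans 0.3 and the non-infarcted zone with 0.1, at 5 % noise:

```python
import numpy as np
import cardalt as ca

cfg   = ca.SyntheticProtocolConfig(noise_sd=0.05, seed=21)
field = ca.make_uniform_field(cfg.grid, s_bz=0.3, s_nz=0.1)
movie, truth = ca.synthesize_movie(cfg, field, bcl=100.0)

amap = ca.alternans_map(movie)
summ = ca.summarize_recording(amap, ca.catd_map(movie), movie.bz_mask)
print(f"mean NAM BZ={summ.mean_nam_bz:.3f} NZ={summ.mean_nam_nz:.3f} "
      f"ratio={summ.bz_nz_ratio:.2f}")
print(f"median |NAM error| = {np.nanmedian(np.abs(amap.nam - truth['nam'])):.4f}")
print(f"CaTD90 BZ={summ.catd90_bz:.1f} ms  NZ={summ.catd90_nz:.1f} ms")
```

prints

```
mean NAM BZ=0.287 NZ=0.101 ratio=2.85
median |NAM error| = 0.0056
CaTD90 BZ=84.1 ms  NZ=77.1 ms
```

— the pipeline recovers the programmed alternans of both zones (ratio
2.85 vs the true 3.0), with a median per-pixel error of 0.006, and sees the
prolonged calcium-transient duration of the border zone.

On the simulation side, the five-fiber PVC comparison (fiber A: alternating
BZ at 300 ms cycle length; B: non-infarcted only; C/D: the same at 400 ms,
no alternans; E: as A under full β-adrenergic stimulation):

```bash
cardalt table2 --prepace-beats 60 --out-dir out/
```

```
fiber_id  bcl_ms composition  bar_level  min_propagating_ci_ms error
       A   300.0    NZ-BZ-NZ        0.0                  225.0
       B   300.0          NZ        0.0                  234.0
       C   400.0    NZ-BZ-NZ        0.0                  288.0
       D   400.0          NZ        0.0                  240.0
       E   300.0    NZ-BZ-NZ        1.0                  231.0
```

The column is the shortest S2 coupling interval from which a premature
stimulus in the (central) border zone propagates to both fiber ends. The
orderings carry the physiology: A < B — the alternans-shortened beat makes
the border zone *more* vulnerable to premature activation than uniform
tissue; C > D — without alternans the border zone's refractory period is
*longer*, so the A/B difference is an alternans effect; E > A —
β-adrenergic suppression of alternans removes that extra vulnerability.
`cardalt scan-block --fiber A` likewise finds a window of S2 intervals
(209–252 ms here) where the premature wave enters the border zone after its
long-APD beat and dies inside it, while the β-stimulated fiber (`--fiber E`)
shows no conduction block at any interval.

Other subcommands: `cardalt synthesize` (movie sets + ground-truth
sidecars), `cardalt analyze` (per-pixel CSV, zone summaries, optional heat
maps), `cardalt scan-pvc`. Every command writes a `manifest.json` with the
full configuration and seed.

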