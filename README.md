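# ccfdq — choriocapillaris flow-deficit quantification for en-face OCTA

The choriocapillaris (CC) is the capillary bed directly under Bruch's
membrane.  OCT angiography cannot resolve its individual capillaries, so CC
perfusion is quantified inversely, through **flow deficits (FD)**: regions
of an en-face CC slab without detectable flow signal, summarized as **FD%**,
the percentage of analyzable pixels classified as deficit.  A known
confounder of this measurement are **large choroidal vessels (LCV)** of the
deeper Sattler/Haller layers: when the choroid is thin they project into
the CC slab as dark elongated structures that *replace* the granular flow
texture, hide the deficits beneath them, and bias FD% toward seemingly
healthier values.

`ccfdq` implements the full quantification pipeline and its statistical
layer for studies of this effect in intermediate age-related macular
degeneration (iAMD) versus healthy eyes, together with a seeded synthetic
scene generator so that every stage is testable without patient data.

## Pipeline

For each eye (6×6 mm scan, angiographic + co-registered structural slab):

1. **Signal compensation** — the angio slab is divided by its smoothed,
   max-normalized, floored structural counterpart, correcting attenuation
   by the overlying RPE/drusen;
2. **Exclusion masks** — pixels under superficial-plexus projection
   artifacts are flagged invalid and never enter any count;
3. **Phansalkar binarization** — the local adaptive threshold
   `t = μ·(1 + p·e^(−q·μ) + k·(σ/r − 1))` (k = 0.25, r = 0.5, p = 2,
   q = 10) over a digital-disk window, at the conventional 15 px radius and
   at a radius adjusted to the scan geometry (4 px for 1024 px / 6 mm, i.e.
   slightly larger than the ~24 µm intercapillary distance, ICD);
4. **Particle analysis** — 8-connected components of sub-threshold pixels;
   components smaller than a circle with the ICD as diameter
   (⌈π·12²/pitch²⌉ = 14 px at native pitch) are discarded as noise;
5. **Sector FD%** — four 1×1 mm squares flush to the scan corners
   (two nasal, two temporal, by laterality), FD% = 100 × valid FD pixels /
   valid pixels; squares containing drusen are flagged and excluded from
   the FD% model;
6. **Statistics** —
   * linear mixed model (REML, random intercept per eye) for FD% with
     LCV, group, orientation and LCV×group, and four planned contrasts with
     Bonferroni ×4 adjustment,
   * random-intercept logistic models of per-sector LCV visibility
     (Gauss–Hermite quadrature ML; odds ratio per µm of choroidal
     thickness, nasal vs temporal shift),
   * eye-level logistic model of "LCV in ≥1 sector" vs sub-foveal
     choroidal thickness,
   * Youden-optimal CT cutoff for expecting visible LCV, with
     sensitivity/specificity intervals from a cluster ratio-estimator
     variance that respects within-eye correlation.

## Worked example

```python
from ccfdq import SimulationConfig, simulate_eye, quantify_eye

cfg = SimulationConfig(seed=42, n_iamd=2, n_control=2, image_size_px=256)
scene = simulate_eye(cfg, 0, "iamd")
res = quantify_eye(scene.angio, scene.structural, scene.truth.vessel_mask,
                   compensate=True, radius=15)
print(f"radius {res['radius_px']} px, min FD area {res['min_area_px']} px")
for s in res["sectors"]:
    print(f"sector {s.index} ({s.orientation:8s}): FD% = {res['fd_percent'][s.index]:6.2f}  "
          f"true = {100*scene.truth.sector_fd_fraction[s.index]:5.2f}  "
          f"CT = {scene.truth.ct_um[s.index]:5.1f} um  LCV = {scene.truth.lcv_flags[s.index]}")
```

prints

```
radius 15 px, min FD area 1 px
sector 1 (temporal): FD% =  10.76  true = 10.76  CT = 175.8 um  LCV = False
sector 2 (nasal   ): FD% =  10.55  true = 10.56  CT = 189.2 um  LCV = False
sector 3 (nasal   ): FD% =   9.14  true =  9.13  CT = 168.5 um  LCV = False
sector 4 (temporal): FD% =  11.25  true = 11.25  CT = 108.6 um  LCV = False
```

i.e. on an LCV-free synthetic eye the measured FD% recovers the simulated
deficit fraction almost exactly (the 1 px minimum area reflects the coarse
23.4 µm pitch of the 256 px demo raster; at the native 1024 px pitch the
filter is 14 px).  Rendering LCV into a sector lowers its measured FD% —
the masking effect the statistical layer quantifies.

The same pipeline is scriptable from the shell:

```bash
ccfdq run-all --config config.yaml     # simulate -> quantify -> fit, with manifest
ccfdq quantify --angio eye/angio.tif --structural eye/structural.tif \
               --vessel-mask eye/vessel.png --radius adjusted --out sectors.csv
```

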