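# fecgel

Automated densitometric analysis of fluorescent enzyme-cascade (fEC)
SDS-PAGE gels.

Fluorescent enzyme cascades turn small structural or chemical differences
between protein samples — stress-induced unfolding, deglycosylation,
partial proteolysis — into differential fluorescent labelling that is read
out on an SDS-PAGE gel. Because the readout is direct fluorescence rather
than enzymatic chemiluminescence, the signal is absolutely quantifiable
and comparable across gels. `fecgel` provides the computational half of
that workflow for analysts running such assays:

1. **Gel geometry** — locate the gel cassette in a two-channel scan
   (e.g. 700 nm sample / 800 nm molecular-weight ladder), find the
   stacking/resolving border, and correct small global rotations so lanes
   run vertically.
2. **Densitometry** — partition the gel into equal-width lanes, extract
   intensity-vs-migration-distance profiles, subtract background, and
   detect bands by topographic prominence.
3. **Mass calibration** — pair detected ladder bands with the declared
   marker masses and interpolate migration distance against log₁₀ mass
   (the standard SDS-PAGE relation *d* = *a* − *b*·log₁₀ *M*), assigning
   a molecular mass to every migration distance by inter- and
   extrapolation.
4. **Absolute quantification** — convert a lane's fluorescence into moles
   of coupled fluorophore via a dilution-series standard curve, giving
   the degree of labelling (DoL): the percentage of protein molecules
   carrying a label (legitimately > 100 % for multiply-labelled
   molecules) and the percentage of lysine residues labelled.
5. **Digital reference libraries** — resample every lane onto a shared
   log-spaced mass grid and classify unknown samples against stored
   reference profiles by squared Pearson correlation (R²), which is
   invariant to exposure and loading and therefore works across
   independently run gels.

A fully ground-truthed gel simulator (`fecgel.sim`) renders synthetic
two-channel scans — log-linear band migration, Gaussian band shapes,
rotation, background plateaus, emission-shoulder channel bleed, exposure
scaling and noise — so every stage of the pipeline is testable without
laboratory data.

## Worked example

Simulate a realistic gel (tilted 1.5°, noisy, with 8 % channel bleed) in
which lane 1 carries a 120 kDa and a 45 kDa band, then run the full
pipeline:

```python
from fecgel import RunConfig, run_analysis
from fecgel.sim import BandSpec, LaneSpec, SimConfig, simulate_gel

lanes = [LaneSpec()]                       # lane 0: marker ladder
lanes.append(LaneSpec(bands=[BandSpec(mass_kda=120.0, amount_pmol=1.0),
                             BandSpec(mass_kda=45.0,  amount_pmol=0.6)],
                      label="stressed"))
lanes += [LaneSpec() for _ in range(8)]    # empty lanes

cfg = SimConfig(lanes=lanes, rotation_deg=1.5, noise_sigma=10.0,
                bleed_k=0.08, seed=7)
img, truth = simulate_gel(cfg)

bundle = run_analysis(RunConfig(out_dir="out", min_prominence=0.1), img=img)
print(f"rotation correction: {bundle.rotation_deg:+.1f} deg")
print(f"bleed coefficient k: {bundle.bleed_k:.3f}")
g = bundle.geometry
print(f"gel region: cols [{g.left_col}, {g.right_col}), "
      f"resolving border row {g.resolving_top_row}, bottom {g.bottom_row}")
for band in bundle.bands[(1, "700nm")]:
    mass = bundle.curve.mass(band.apex_distance)
    print(f"lane 1 band at {band.apex_distance:6.1f} px "
          f"-> {mass:6.1f} kDa (prominence {band.prominence:,.0f})")
```

prints

```
rotation correction: -1.5 deg
bleed coefficient k: 0.080
gel region: cols [40, 440), resolving border row 60, bottom 340
lane 1 band at   83.0 px ->  120.1 kDa (prominence 13,129)
lane 1 band at  152.7 px ->   45.1 kDa (prominence 7,849)
```

The applied 1.5° tilt and the 0.08 bleed coefficient are recovered, the
detected gel region matches the simulated cassette, and both band masses
come back within 0.3 % — the ladder in lane 0 was detected, paired with
its declared masses and interpolated automatically. `run_analysis`
persists every intermediate (geometry JSON, profile/band CSVs,
calibration, mass profiles) into `out/`. Raising `min_prominence` from
its 0.05 default to 0.1 suppresses noise-level peaks in this noisy
example.

The same pipeline is scriptable from the shell:

```sh
fecgel simulate gel --seed 7 --out gel.tiff --truth truth.json
fecgel analyze --image gel.tiff --channels 700nm,800nm \
       --n-lanes 10 --ladder 250,150,100,75,50,37,25 --out analysis/
fecgel quantify --standards std.csv --intensity 2.82e5 \
       --protein-pmol 2.0 --n-lysine 98
fecgel library build --profile native.csv --profile uv.csv --out lib.json
fecgel library classify --query unknown.csv --lib lib.json
```

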