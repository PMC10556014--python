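# pedobar

Standardized processing, analysis and visualization of biomechanical
pressure-distribution data — most commonly plantar (foot) pressure measured
on platform or in-shoe sensor arrays.

Pressure hardware families (emed, pedar, pliance, Tekscan, footscan) export
mutually incompatible formats and their proprietary software disagrees even
on the definitions of basic variables: there are at least two quantities
called the "pressure–time integral", and "mean peak pressure" can mean a
spatial or a temporal mean. `pedobar` gives researchers and clinicians one
open, scriptable path from raw export to reported variable: every recording
becomes the same standardized object, every metric has exactly one
documented definition, and every processing step that is interactive in
vendor GUIs (step selection, mask drawing, mask editing) is a pure function
with explicit arguments.

## What it computes

For a recording with pressure frames `x` (kPa), sensor areas `a` (cm²) and
sampling interval Δt, per regional mask:

- vertical force `F_t = 0.1 · Σ_cells x_t a` (N), contact area, contact time;
- peak pressure `PP = max_{i,j} x_{i,j}` over the region's sensors and frames;
- force–time integral `FTI = ∫ F dt` (trapezoidal, N·s);
- **two** pressure–time integrals, under distinct names:
  `pti_melai = FTI / A` (A = peak regional contact area) and
  `pti_peak = ∫ max_cells x dt` (kPa·s);
- `press_peak_mean`, explicitly the temporal mean of the spatial peak.

Whole-recording operations: step detection from a force threshold,
interpolation to 101 frames (percent of stance), center of pressure,
automatic left/right detection, the center-of-pressure excursion index
(CPEI: deviation of the COP path from a medial-border construction line at
the anterior trisection, as % of forefoot width) and the dynamic plantar
loading index (DPLI: 1 − R² of a Gaussian fit to the peak-pressure-vs-time
curve). A 10-region barefoot automask (heel, midfoot, MTH1–5, hallux,
toe2, toes3–5) partitions the footprint geometrically; manual polygon and
sensor-set masks, mask editing and template insole schemes are included.

A synthetic gait generator produces platform steps and multi-step in-shoe
trials with known ground truth (site cell sets, side, contact windows,
noise-free COP), so the entire pipeline is testable without proprietary
data. See `docs/methods.md` for model details and conventions.

## Worked example

```python
import pedobar as pb

# a synthetic barefoot step stands in for load_emed("trial.lst")
rec, _ = pb.generate_footprint(pb.FootModel(), seed=1)

rec = pb.pressure_interp(rec, 101)                # normalize to % stance
rec = pb.create_mask_auto(rec, "automask_novel",  # 10 anatomical regions
                          foot_side="auto")
table = pb.mask_analysis(rec, "press_peak_sensor")
print(table.to_string(index=False))
res = pb.cpei(rec, force_threshold=10.0)
print(f"CPEI = {res.cpei:.2f} % ({res.side.value})")
```

prints

```
 region            metric      value units
   heel press_peak_sensor 384.393344   kPa
midfoot press_peak_sensor  79.648731   kPa
   MTH1 press_peak_sensor 406.167543   kPa
   MTH2 press_peak_sensor 304.557895   kPa
   MTH3 press_peak_sensor 282.831874   kPa
   MTH4 press_peak_sensor 235.660754   kPa
   MTH5 press_peak_sensor 202.230788   kPa
 hallux press_peak_sensor 282.374154   kPa
   toe2 press_peak_sensor 137.394099   kPa
toes3_5 press_peak_sensor  99.349839   kPa
CPEI = 22.65 % (right)
```

— the regional peak pressures (kPa, highest single-sensor reading in each
anatomical region across stance) of the simulated right foot, with the
heaviest loading under the first metatarsal head and heel, and the COP
excursion index of the step.

The same pipeline from a shell:

```sh
pedobar simulate --preset barefoot --seed 1 -o sim/
pedobar run sim/barefoot.emed.lst -o out/     # steps→interp→mask→metrics→plot
pedobar plot out/processed.canonical.txt --cop --outline -o footprint.png
pedobar animate out/processed.canonical.txt --fps 25 -o step.gif
```

Vendor exports are read through one documented, strictly parsed dialect per
system (`pedobar convert <file> --system auto -o out.txt`); the canonical
output format is versioned plain text with bit-faithful pressures, suitable
for archiving and diffing.

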