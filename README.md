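# gradsafe

Desk-scale toolkit for MRI gradient-coil cardiac magnetostimulation
dosimetry: synthetic voxel torso phantoms, wire-loop gradient-coil models
with exact finite-segment Biot-Savart fields, a magneto-quasistatic
scalar-potential solver for induced E-fields, percentile-based myocardial
field metrics, landmark-sweep dB/dt-over-E ratio studies, and a log-normal
population stimulation-threshold risk model with strength-duration limit
curves.

## Modules

| module | purpose |
| --- | --- |
| `gradsafe.phantoms` | homogeneous validation cylinders and reduced five-tissue torso phantoms (torso bulk 0.23, lung 0.101, myocardium 0.385, blood 0.662 S/m) on uniform voxel grids; seeded synthetic populations |
| `gradsafe.coils` | Maxwell-pair (Z) and Golay-saddle (X/Y) coil generators, optional shields; B and vector potential A via finite straight-segment closed forms; gradient efficiency; peak dB/dt over the 20 cm compliance cylinder |
| `gradsafe.em_solver` | cell-centered finite-volume solve of div(sigma(grad phi + dA/dt)) = 0 with harmonic-mean face conductivities and insulating boundaries; E = -dA/dt - grad phi; conservation diagnostics |
| `gradsafe.field_metrics` | nearest-rank percentile metrics (Emax/E99.9/E99/E95), strictly-above threshold masking, single-layer mask erosion, histograms |
| `gradsafe.sweep` | z-landmark sweeps (body translated, coil fixed), worst-case selection per metric, Cartesian ratio studies, aggregation |
| `gradsafe.risk` | log-normal threshold distribution (median 12 V/m, 1st percentile 6 V/m), product convolution with ratio distributions, adverse-event probability, rheobase/chronaxie limit curves, effective stimulus duration |

## CLI

```bash
gradsafe phantom make --preset torso --resolution 2 --heart-scale 1.22 --out model/
gradsafe phantom population --n 8 --seed 1 --resolution 4 --out pop/
gradsafe coil make --axis z --id 0.70 --length 1.40 --shielded --out coil.json
gradsafe coil dbdt --coil coil.json --slew 100 --cv-radius 0.20
gradsafe solve --model model/ --coil coil.json --slew 100 --landmark-z 0.0 --out efield.nii
gradsafe metrics --efield efield.nii --mask model/mask_myocardium.nii --percentiles 95,99,99.9
gradsafe sweep run --models pop/ --coils coils/ --axes z --step 0.05 --n 9 --out study/
gradsafe sweep aggregate --table study/ratios.csv --metric E99
gradsafe risk prob --eval-ratio 13
gradsafe risk limit --tau-ms 0.45
gradsafe risk tau --waveform waveform.csv
```

## Conventions

- Right-handed coordinates, z along the bore, isocenter at the origin;
  positions in meters, voxel spacing in mm, fields in T, V/m, T/s.
- Real arithmetic at the peak of the sinusoidal drive (quasi-static,
  conductivities real at 1 kHz): dA/dt = A x slew/G_eff per axis.
- Percentiles are nearest-rank; threshold masking removes strictly-above
  values, so an all-distinct map loses exactly N - ceil(0.99 N) voxels.
- Axis combinations drive each axis in phase at slew/sqrt(n)
  (root-sum-square convention; configurable strategy).
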