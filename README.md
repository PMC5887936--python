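# hp13c

Analysis tools for hyperpolarized ¹³C magnetic resonance spectroscopy of
inflamed tissue: voxelwise **lactate/pyruvate ratio mapping** from
[1-¹³C]pyruvate MRSI, and **extracellular pH estimation** from dynamic
H¹³CO₃⁻/¹³CO₂ spectra via the Henderson–Hasselbalch relation. The package
is aimed at preclinical MR groups studying tissue metabolism and acid–base
status — for example, whether the elevated glycolysis of an inflamed joint
is accompanied by tissue acidosis — and ships seeded synthetic-data
generators so every stage of the pipeline is testable without scanner data.

## What it computes

**Lactate/pyruvate mapping.** Each voxel of a 32×32 chemical-shift image
holds a free induction decay modelled as four Lorentzian lines,

    s(t) = Σⱼ Aⱼ · exp(iφ) · exp(i·2π·fⱼ·t − π·Δνⱼ·t),

with [1-¹³C]pyruvate at 173 ppm, [1-¹³C]lactate at 185 ppm and two small
auxiliary lines. A time-domain least-squares fit (variable projection with
non-negative amplitudes) yields the amplitude ratio A_lac/A_pyr per voxel.
Voxels pass quality control when the pyruvate amplitude, expressed as the
peak height of a 50 Hz-linewidth absorption line, exceeds 11× the RMS
spectral noise; region-of-interest selection keeps voxels whose centres
fall inside a polygon drawn on the proton reference image. Groups of voxel
ratios are compared with an uncorrected Welch t-test.

**pH estimation.** With carbonic anhydrase keeping the ¹³C label
equilibrated between bicarbonate and CO₂,

    pH = pKa − log₁₀( S(CO₂) / S(HCO₃⁻) ),   pKa = 6.17,

where the signals are window integrals (123–127 ppm for CO₂, 156–163 ppm
for HCO₃⁻) of the spectrum obtained by summing the serial spectra acquired
every second from 12 to 39 s after injection (28 spectra), zero-order
phasing, and quadratic baseline correction. An equilibration check on the
per-spectrum ratio series guards the constant-ratio assumption.

Morphometry utilities round out the study statistics: foot volumes from
outlined 2 mm image slices, one-sided Welch t-tests (also from printed
summary statistics), and a two-way treatment × day ANOVA with
Sidak-adjusted per-day comparisons.

## Worked example

```python
from hp13c import BicarbonatePHModel
from hp13c.simulate import BicarbSeriesConfig, simulate_bicarbonate_series

series = simulate_bicarbonate_series(BicarbSeriesConfig(ph_true=7.23, seed=1))
print(BicarbonatePHModel(series).fit().summary())
```

```
Bicarbonate/CO2 pH estimate
---------------------------
summed spectra        : 28
CO2 integral          : 0.0063355 (noise 6.56e-05)
HCO3- integral        : 0.072393
CO2/HCO3- ratio       : 0.087515
pKa                   : 6.17
pH                    : 7.228
zero-order phase (rad): 0.0027
equilibrated          : True (slope -0.000203/s, 95% CI -0.000442..3.5e-05)
```

The simulated paw had a true extracellular pH of 7.23; the full pipeline
reads back 7.228 from the 28 summed spectra, and the equilibration check
confirms the CO₂/HCO₃⁻ ratio was stable over the acquisition. The MRSI
side works the same way:

```python
from hp13c import LactatePyruvateModel, ROIPolygon
from hp13c.simulate import (MRSIPhantomConfig, PawRegion, disk_polygon,
                            simulate_mrsi_phantom)

poly = tuple(disk_polygon((20.0, 20.0), 6.0))
phantom = simulate_mrsi_phantom(
    MRSIPhantomConfig(regions=(PawRegion(poly, ratio_mean=0.74),), seed=12))
results = LactatePyruvateModel(phantom.grid, roi=ROIPolygon(poly)).fit()
print(results.summary())
```

```
Lactate/pyruvate MRSI fit
-------------------------
grid                : 32x32
voxels fitted       : 76
voxels in ROI       : 76
QC-passing in ROI   : 76 (SNR > 11.0)
noise RMS           : 0.0003177
mean ratio (all ROI): 0.7342
mean ratio (QC)     : 0.7342
```

Here an inflamed-paw phantom with a regional mean ratio of 0.74 is
recovered as 0.734 over the 76 quality-passing voxels — the elevated value
typical of inflamed tissue, against ~0.30 in a non-inflamed paw.

A `hp13c` command-line interface exposes the same pipeline
(`simulate-mrsi`, `simulate-bicarb`, `simulate-paws`, `fit-mrsi`,
`estimate-ph`, `stats`); every run writes a `provenance.json` sufficient to
reproduce deterministic stages bit-identically.

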