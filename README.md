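# epirepair

Agent-based simulation and morphometry of collective epithelial
migration during segmental kidney repair.

After a band of tubule epithelium dies (as in laser-ablation models of
acute kidney injury in the larval zebrafish pronephros), the surviving
epithelium closes the gap by collective migration within hours, and —
only after long injuries, and only after a delay — proliferates in two
bands flanking the injury site. The working hypothesis this package
implements is mechanical: migration stretches the flanking epithelium,
and sustained stretch, not a diffusible wound factor, triggers the
divisions. A short ablation (~3 cell diameters, ~20 µm) distributed over
a stretch zone of ~434 µm produces < 5 % average linear stretch and no
proliferative response; a long ablation (~80–100 µm) produces ~20 % and
two proliferation bands.

The package is aimed at quantitative/computational biologists who want a
tested, reproducible implementation of:

* **`epirepair.abm`** — a 2-D agent-based model of the repairing sheet:
  cells on a cut-open tubule (periodic circumference, anchored axial
  ends) with short-range repulsion/attraction between junctional
  neighbours, an active crawling response of free-edge cells with
  follower activation, plastic substrate adhesion, and stochastic
  division gated by sustained over-threshold mean neighbour distance
  with a delay.
* **`epirepair.morphometry`** — the track-based analyses: edge
  migration-rate series, peak-rate vs ablation-length regression
  (`Y = A·X + B`), symmetric cell-pair stretch profiling with the
  stretch-zone x-intercept (−B/A), the stretch-fraction arithmetic,
  proliferation-band detection (fixed-width Gaussian kernel density,
  one peak per side of the injury), and Welch / paired t-tests.
* **`epirepair.synthetic`** — generators for edge traces with
  exponentially declining closure speed, symmetric pair tracks sampling
  a linear stretch-decay field, banded proliferation-event positions,
  and paired count tables — each returning its ground truth for
  parameter-recovery testing.
* **`epirepair` (CLI)** — `simulate`, `analyze-tracks`, `analyze-bands`
  and `synth` subcommands over tidy CSV files with JSON metadata
  sidecars.

## Worked example

Simulate a long (90 µm) ablation with the packaged calibrated profile
and analyse the outcome:

```python
import numpy as np
from epirepair import abm
from epirepair.morphometry import proliferation_bands, stretch_fraction

params = abm.ModelParams(seed=4)
result = abm.run_simulation(params, rows=10, cols=80, gap_length=90.0)
rates = abm.migration_rate_series(result, "left", bin_steps=25)
gw = result.gap_width_series()
print(f"initial closure rate : {rates[0, 1]:.1f} um/h")
print(f"gap width            : {gw[0]:.0f} -> {gw[-1]:.0f} um")
print(f"divisions            : {result.n_divisions}, first at t = "
      f"{result.division_events[0, 0] * params.step_hours:.1f} h")
bands = proliferation_bands(result.division_positions(), result.gap)
print(f"band peak separation : {bands.separation:.0f} um "
      f"(peaks {bands.peaks[0] - result.gap_center:+.0f} / "
      f"{bands.peaks[1] - result.gap_center:+.0f} um from centre)")
print(f"avg stretch, 90/434  : {stretch_fraction(90, 434):.1f} %")
```

prints

```
initial closure rate : 7.4 um/h
gap width            : 101 -> 3 um
divisions            : 10, first at t = 7.7 h
band peak separation : 281 um (peaks -132 / +148 um from centre)
avg stretch, 90/434  : 20.7 %
```

The edges start closing at ~7.4 µm/h (the calibration anchor — the rate
observed in vivo over the first two hours of migration) and slow as
flank tension builds; the gap closes essentially completely; divisions
begin hours later and sit in two bands ~130–150 µm either side of the
injury centre, the zone of maximal migration-induced stretch. Running
the same simulation with `gap_length=20.1` (a short, three-cell-diameter
ablation) closes the gap just as completely but produces **zero**
divisions — the short/long dichotomy that distinguishes stretch-gated
proliferation from a secreted-factor response.

The same pipeline from the shell:

```sh
epirepair simulate --profile calibrated --gap-um 90 --seed 4 -o out/
epirepair analyze-bands out/events.csv --injury-lo 219.65 --injury-hi 309.65
epirepair synth pairs --l-tot 434 -n 60 --seed 8 -o pairs/
epirepair analyze-tracks pairs/tracks.csv --injury-lo -27.5 --injury-hi 27.5
```

`analyze-tracks` writes the per-pair stretch profile and its regression
fit (`A`, `B`, x-intercept ≈ the 434 µm zone extent used to generate the
data); `analyze-bands` writes the band peaks, their separation and the
per-side counts.

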