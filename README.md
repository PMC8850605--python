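# entosense

Signal-analysis pipeline for dual-wavelength near-infrared insect
monitoring sensors.

Automated, trap-free insect monitoring can be done optically: an emitter
illuminates an air volume at two near-infrared bands (808 nm and 980 nm)
and a quadrant photodiode records the light backscattered by each insect
that crosses the measurement volume, as an 8-channel stream
(4 quadrants x 2 bands) at 20 kHz.  Each ~100 ms transit carries a
harmonic wingbeat modulation on top of a slowly varying body glint.
`entosense` implements the complete computation downstream of the
demodulated stream, for researchers in optical entomology and
agricultural monitoring:

* **`entosense.synthgen`** — synthetic recordings, single transits and
  paired sensor/trap field studies with full ground truth, so every stage
  is testable without field data;
* **`entosense.extract`** — automated event extraction: block-mean
  downsampling to 2 kHz, rolling-median baseline (2 s boxcar, 50 %
  overlap) with a below-median noise SD, a 10 x SD one-sided threshold,
  500 µs erosion / 30 ms dilation of the boolean mask, and an OR across
  all channels;
* **`entosense.features`** — per-event features: fundamental wingbeat
  frequency f₀ from a Welch spectrum via harmonic-sum peak picking,
  minimum-envelope body/wing decomposition and body-to-wing ratio,
  808/980 melanisation indices, quadrant cross-correlation lags and
  crossing direction, and a validity flag (rain / no distinguishable
  wingbeat);
* **`entosense.activity`** — daily activity series normalised by sensor
  uptime, trap-schedule alignment (Sunday catches pool into the next
  collection and divide by trapping days), Spearman rank correlation with
  exact small-n p-values, least-squares fit, and study summaries;
* **`entosense.io` / `entosense.cli`** — HDF5/CSV recording formats,
  JSON-Lines events, YAML configuration with the deployed constants as
  defaults, and an `entosense` command with `simulate`, `extract`,
  `features`, `aggregate`, `compare` and `run` subcommands.

## The core statistics

For a transit signal s(t), the wingbeat spectrum is the Welch density of
the quadrant- and band-summed snippet; f₀ maximises the harmonic sum
Σₖ P(k·f) over spectral peaks in 30–1000 Hz.  The body track is the
minimum envelope (rolling minimum over one period 1/f₀, smoothed), the
wing track the remainder, and

    body-to-wing ratio = mean(body) / mean(upper envelope of wing)

over the central half of the event.  Field validation compares daily
means: sensor counts / uptime versus trap catches / trapping days, paired
on common days, with Spearman's ρ = 1 − 6 Σd²/(n(n²−1)) (average ranks
under ties) and a two-sided exact permutation p-value for n ≤ 9.

## Worked example

The package ships a preset transit modelled on a representative event: a
160 Hz fundamental with five geometrically decaying harmonics and a
designed body-to-wing ratio of 0.4.

```python
import entosense as es

scene = es.SceneConfig(duration=4.0, noise_sd=1.0,
                       insects=[es.demo_preset(t0=2.0)], seed=1)
recording, truth = es.synth_recording(scene)
events, model = es.extract_events(recording)
feats = es.extract_features(events[0])
print(len(events), round(feats.f0, 2), round(feats.body_to_wing_ratio, 3))
```

prints

```
1 159.98 0.38
```

one event was extracted from the 4 s recording; its estimated wingbeat
frequency is 159.98 Hz (the preset's fundamental, recovered to well within
the ~5 Hz spectral resolution of a 200 ms snippet) and its body-to-wing
ratio 0.38, within the envelope estimator's tolerance of the designed
0.4.  The same chain runs from the shell:

```bash
entosense simulate recording --config scene.yaml --out rec.h5
entosense extract --in rec.h5 --out events.jsonl
entosense features --in events.jsonl --out features.csv
```

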