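# buzzpam

Passive acoustic monitoring of flying insects. The package detects
wingbeat "buzz" events in mono WAV audio by verifying a harmonic
spectral pattern (a fundamental in 50–1000 Hz plus peaks at its integer
multiples), merges candidate frames into events, and counts them. A
duty-cycled recording schedule (by default 12 min on / 48 min off during
06:00–21:00 and 4 min on / 56 min off overnight, 216 recorded minutes
per day) maps counts to buzz/h — events per hour of equivalent
continuous recording — which is then aggregated into hourly, weekly and
temperature-binned activity metrics and correlated against standardized
trap-survey counts.

Because no field recordings are available, the `synth` module generates
complete scenarios with known ground truth: harmonic-stack buzzes over
white noise, event times from a temperature-driven inhomogeneous
Poisson process, rendered through the recording schedule.

## Layout

| module | purpose |
|---|---|
| `buzzpam.audio_io` | WAV read/write (16-bit PCM mono), manifest CSV, window slicing |
| `buzzpam.spectral` | Hann-tapered power spectra at 5 Hz bins, band-limited 4 Hz–3 kHz |
| `buzzpam.detector` | harmonic-comb frame classification, event segmentation, counting |
| `buzzpam.schedule` | duty-cycle model: on-windows, recorded minutes, instant queries |
| `buzzpam.metrics` | buzz/h, hourly/weekly means, temperature bins, Pearson correlation |
| `buzzpam.synth` | synthetic buzzes, scenarios, survey designs with ground truth |
| `buzzpam.cli` | `buzz` command line and the end-to-end pipeline |

## CLI

```sh
# render a synthetic scenario (WAVs + manifest + ground truth)
buzz simulate scenario.yaml --out sim/

# detect buzzes in one file or a whole manifest
buzz detect sim/site-A-dev00_20230422T060000.wav --out-summary s.csv
buzz batch sim/manifest.csv --out-events events.csv --out-summary summary.csv

# hourly activity table, then correlate with survey counts
buzz aggregate summary.csv -o activity.csv
buzz correlate activity.csv surveys.csv --periods periods.csv \
    --window 10:00-16:00 -o correlation.csv

# full simulate -> detect -> aggregate -> correlate run from one config
buzz report pipeline.yaml --out run/
```

Outputs are plain CSV with a one-line `#` provenance header (version,
seed, config hash); reruns with identical inputs are byte-identical.
Exit codes: 0 success, 2 configuration error, 3 data error.

A minimal scenario file:

```yaml
start_day: 2023-04-22
days: 1
site_id: site-A
n_devices: 2
base_rate: 30        # events/h at the thermal optimum
t_opt: 22.5          # degC
t_width: 5.0
diurnal_factor: 1.2  # day/night rate ratio
seed: 1
```

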