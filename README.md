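# axoasym

Quantitative analysis pipelines for **proximal–distal asymmetry of the
axoneme and flagellar beat control in trypanosomatids** (*Leishmania
mexicana*, *Trypanosoma brucei*).

The eukaryotic flagellum is built around the axoneme — nine doublet
microtubules and a central pair — whose composition is not uniform along
its length: some proteins (outer-dynein-arm docking-complex variants among
them) occupy only the proximal or only the distal part of the flagellum.
This package implements the measurements needed to map such asymmetries
and their consequences for motility:

* **Fluorescence profiles** (`axoasym.profiles`) — intensity of a tagged
  protein sampled along a manually traced flagellum, background-subtracted,
  per-cell max-normalized, resampled onto a common 0–1 arclength grid,
  group-averaged and hierarchically clustered (UPGMA, Euclidean distance).
* **Signal-onset distance** (`axoasym.onset`) — the distance from the
  kinetoplast to the start of flagellar signal, measured as the midpoint
  r₅₀ of a four-parameter logistic
  v(r) = b + (M − b) / (1 + e^(−κ(r − r₅₀)))
  fitted to the maximum pixel value within discs of increasing radius r
  around the kinetoplast centroid, with strict quality gates
  (r₅₀ within range, κ > 0.7 px⁻¹, M > 1000 AU, R² > 0.95).
* **Beat waveform metrics** (`axoasym.waveform`) — the planar flagellum
  shape as a tangent-angle field θ(s, t); angular amplitude (maximal
  tangent-angle range over a beat cycle along the flagellum), dominant
  frequency (argmax of the arclength-aggregated power spectrum of θ),
  waves per flagellum (spatial phase progression of the dominant Fourier
  component / 2π), digitisation and sinusoidality screens, proximal/distal
  segment metrics, beat-type tallies, and the kinematic requirement on a
  base-to-tip initiation signal (period 1000/f ms, speed f·L μm/s).
* **Ninefold EM averaging** (`axoasym.emavg`) — axoneme cross-sections are
  perspective-corrected (the ellipse through the nine doublet centres is
  mapped to a circle of radius √(ab)), averaged over the nine 40°
  rotations, mutually aligned, group-averaged, and compared between cell
  lines with per-pixel two-sided Mann–Whitney U tests corrected for the
  number of pixels in the axoneme cross-section (Bonferroni by default).
* **Swimming-track statistics** (`axoasym.motility`) — mean speed (path
  length / duration), mean velocity (displacement / duration) and
  directionality (displacement / path length).
* **Synthetic ground truth** (`axoasym.synthetic`) — generators for all
  four input kinds (fluorescence cells with a logistic signal onset,
  travelling-wave beats, 9-fold axoneme densities with controllable ODA
  occupancy and tilt projection, correlated-random-walk tracks), so every
  pipeline stage is testable against known truth.

The package is aimed at flagellum/cilium labs analysing widefield
fluorescence micrographs, high-speed beat videos, EM cross-sections and
darkfield swimming tracks of uniflagellate cells.

## Worked example

Recover the beat parameters of a synthetic 28 Hz tip-to-base travelling
wave (half-amplitude a = 0.5 rad, 1.5 waves per flagellum, 200 fps,
0.5 s, angle noise 0.02 rad):

```python
from axoasym import synthetic as syn, waveform as wf

spec = syn.SyntheticBeatSpec(frequency=28.0, half_amplitude=0.5,
                             waves_per_flagellum=1.5, fps=200.0,
                             duration=0.5, noise_sd=0.02, seed=42)
series, truth = syn.generate_beat_series(spec)
m = wf.analyze_series(series, with_segments=True)
print(f"dominant frequency: {m.dominant_frequency:.1f} Hz")
print(f"angular amplitude:  {m.angular_amplitude:.3f} rad")
print(f"waves/flagellum:    {m.waves_per_flagellum:.2f}")

period_ms, speed = wf.required_signal_speed(40.0, 25.0)
print(f"40 Hz beat period: {period_ms:.0f} ms -> required signal speed "
      f"{speed:.0f} um/s over 25 um")
```

prints

```
dominant frequency: 28.0 Hz
angular amplitude:  1.000 rad
waves/flagellum:    1.47
40 Hz beat period: 25 ms -> required signal speed 1000 um/s over 25 um
```

The dominant frequency lands on the exact 28 Hz spectral bin, the
amplitude equals the full tangent-angle range 2a = 1 rad, and the spatial
phase progression recovers the 1.5 waves on the flagellum to within the
finite-difference bias of the tangent estimate.  The last two numbers are
the kinematic argument for beat coordination: waveforms initiated at the
flagellar tip at 40 Hz leave only a 25 ms period, so any base-to-tip
signal triggering them must travel ≈1000 μm/s over a 25 μm flagellum —
faster than diffusion or intraflagellar transport, consistent with a
mechanical (shear) signal.

A command-line interface wraps each pipeline
(`axoasym {simulate,profile,onset,beat,beat-tally,emavg,motility}`);
every run writes a JSON manifest with input checksums and the exact
thresholds used.

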