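# alcmv — accelerated LCMV beamforming for streaming EEG source reconstruction

`alcmv` reconstructs brain-source time series from multichannel EEG with a
linearly constrained minimum variance (LCMV) beamformer, built for the
streaming setting: the channel covariance and its inverse are maintained
recursively as samples arrive, and dipole orientations are obtained in
closed form instead of with an iterative eigensolver.  It is aimed at
people prototyping real-time source-space pipelines (BCI, neurofeedback,
online localization) who want every numerical step testable against ground
truth, so the package also ships a synthetic dipole forward simulator and
the evaluation metrics — no recordings or MRI-derived head models are
required to exercise the full method.

## The method

For a source at location *r* with lead field *L(r)* (channels × 3) and unit
orientation *η*, the scalar beamformer is

```
g = L(r) η,    w(r) = R⁻¹ g / (gᵀ R⁻¹ g),    ŝ(r, t) = w(r)ᵀ y(t),
```

where *R* is the channel covariance of the recording *y*.  The filter
passes the source with unit gain (*wᵀg = 1*) while minimizing output
variance.  Three accelerations are implemented:

1. **Sliding-window covariance recursion.**  The uncentered scatter
   *C = X Xᵀ* of a window of `ns` samples is updated exactly when the
   window advances by `cy` samples: `C ← C − D Dᵀ + D′ D′ᵀ` with *D*, *D′*
   the departing and arriving blocks.  `ns ≥ k` (channel count) keeps the
   window full rank; `cy ≤ ns/2`.
2. **Recursive inverse via Miller rank-one updates.**  The update
   *H = −DDᵀ + D′D′ᵀ* is split into *k* column-masked rank-one terms
   *E₁ + … + E_k*, and the inverse is chained through
   `(C+E)⁻¹ = C⁻¹ − C⁻¹EC⁻¹ / (1 + tr(C⁻¹E))`.  Degenerate denominators
   and accumulated drift trigger a logged dense rebuild, never a silent
   error.
3. **Closed-form orientation detection.**  The optimal orientation is the
   eigenvector of the smallest eigenvalue of the symmetric 3 × 3 matrix
   *A = Lᵀ R⁻¹ L*, computed analytically (trigonometric cubic roots, then a
   structure-dispatched null vector of *A − λI*).  Collapsing *L* to the
   single column *g = Lη* reduces the reconstruction stage from `3·k·N` to
   `k·N` multiply–accumulates — a 66.7% cut, for any problem size.

## Worked example

Write a run configuration (a 24-channel, 8-second simulated recording with
one planted burst dipole, then streaming + batch reconstruction and the
comparison metrics):

```json
{
  "output_dir": "demo-run",
  "ns": 24,
  "cy": 1,
  "seed": 7,
  "simulate": {
    "k": 24, "N": 2000, "fs": 250.0, "noise_sigma": 0.05,
    "sources": [
      {"location_index": 0, "orientation": [0.6, 0.0, 0.8], "waveform": "burst"}
    ]
  }
}
```

```bash
alcmv run demo.json
```

prints (abbreviated):

```
{
  "k": 24, "N": 2000, "ns": 24, "cy": 1,
  "signal_reconstruction_error_pct": 16.33,
  "signal_reconstruction_error_rel_pct": 15.88,
  "orientation_error_pct": {"mean": 80.37},
  "orientation_cosine": [0.9999996212912854],
  "fallback_events": 110,
  ...
}
```

How to read this:

* `orientation_cosine` ≈ 1.0000: the closed-form detector, applied to the
  full-recording covariance, recovered the planted orientation (0.6, 0, 0.8)
  essentially exactly.
* `orientation_error_pct` is the sign-invariant max-normalized component
  error.  Because it divides by the largest component *difference*, it is a
  shape statistic of the error vector, not a size statistic — any nonzero
  error lands between 33% and 100% no matter how small the components are
  (here the components differ by ~1e−4, cosine 0.9999996).  Use the cosine
  to judge accuracy and this metric to compare error profiles.
* `signal_reconstruction_error_pct` compares the streaming reconstruction
  (weights from a sliding 24-sample window) with the batch reconstruction
  (weights from all 2000 samples).  A 24-sample covariance is a very noisy
  estimate, so the two genuinely differ; the companion
  `_rel_pct` value normalizes by the signal maximum instead of the
  difference maximum.  Longer windows (`ns`) shrink the true discrepancy.
* `fallback_events` counts the dense inverse rebuilds triggered when the
  strong burst drives the short window near rank deficiency — logged
  fidelity safeguards, not failures.

The analytic cost of the collapsed filter:

```bash
$ alcmv benchmark -k 24 -n 2000
collapsed (k x 1) filter : 48000 MACs
vector (k x 3) filter    : 144000 MACs
computational-load reduction: 66.7%
```

The library API mirrors the CLI: `simulate_recording`, `alcmv_stream`,
`lcmv_batch`, `aori_orientation`, `smallest_eigenvector`,
`reconstruction_error`, `active_source_ranking`, … (see the module
docstrings under `src/alcmv/`).

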