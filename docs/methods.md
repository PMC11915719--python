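# Methods

## Signal model and the beamformer

The forward model is linear and quasi-static: a dipolar source at grid
location *r* with unit orientation η ∈ ℝ³ and activity *s(t)* contributes
*L(r) η s(t)* to the k sensors, where *L(r)* is the k × 3 lead field
(sensor gain per Cartesian dipole component).  A recording is

y(t) = Σₘ L(rₘ) ηₘ sₘ(t) + ε(t),   ε ~ 𝒩(0, σ² I), i.i.d. per channel/sample.

The scalar LCMV beamformer for location *r* minimizes output power subject
to unit gain at the collapsed gain column g = L(r) η:

w = R⁻¹g / (gᵀR⁻¹g),  ŝ(t) = wᵀ y(t).

Weights are invariant to positive scaling of R, which licenses two
simplifications used throughout: the covariance may be kept as an
*unnormalized* scatter (no 1/(N−1)), and the streaming path may use the
*uncentered* second moment.  Sources are reconstructed independently, one
scalar filter per candidate location; simultaneous multi-source
constraints are out of scope by design (the method does not support them).

## Orientation detection (3 × 3 closed form)

The power-maximizing orientation is the eigenvector of the smallest
eigenvalue of A = LᵀR⁻¹L, a symmetric 3 × 3 matrix.  `alcmv.eigen3` solves
this without iteration:

* **Eigenvalues** by the trigonometric solution of the characteristic
  cubic (shift by the mean eigenvalue, scale, arccos of the scaled
  determinant).  Exactly diagonal input short-circuits to its sorted
  diagonal so multiplicities are preserved bit-exactly.  For simple
  eigenvalues the accuracy is ~machine epsilon relative to ‖A‖; a *double*
  root is determined only to ~√ε ≈ 1.5e−8 relative — an intrinsic property
  of the cubic, handled below.
* **Eigenvectors** as null vectors of B = A − λI, dispatched on the
  structure of B with every branch labelled (`case_label`), so tests can
  verify branch coverage:
  - `diagonal`: all off-diagonal entries below 1e−12·‖A‖_max — canonical
    axis with the smallest index among (near-)zero shifted diagonals.
  - `block-jk`: one coordinate decouples; the eigenvector is either the
    free axis or the null vector of the remaining symmetric 2 × 2 block,
    taken from its larger row.
  - general `pq-ij` / `pr-ij` / `qr-ij`: cross product of two rows of B.
    For a symmetric rank-2 B every row pair's cross product is parallel to
    the null vector (rows of adj(B) are μ·vᵢ·v), and the pair with the
    largest cross norm is the complement of the null vector's dominant
    component — so exactly three general labels are reachable in practice
    (`pq-12`, `pr-13`, `qr-23`, i.e. unit pivot on the third, second, or
    first component).  The pair choice maximizes the cross norm, which is
    the numerically best-conditioned 2 × 2 minor.
  - `degenerate`: if a second eigenvalue lies within 3e−8·(1 + scale) of λ
    (an unresolvable double root) or all cross products vanish, B is
    treated as rank ≤ 1 and the canonical basis-aligned null-space vector
    with the smallest index is returned.  Residuals in this branch are
    bounded by the double-root accuracy (~√ε·‖A‖), not machine epsilon.

Signs are canonicalized (first component of magnitude > 1e−12 made
positive); η and −η are physically equivalent, so all downstream metrics
are sign-invariant.  An independent LAPACK eigendecomposition serves as
the oracle in the test suite, never as the implementation.

## Streaming covariance and recursive inverse

The window scatter C = X Xᵀ over [start, start+ns) is advanced by
C ← C − DDᵀ + D′D′ᵀ.  This identity is *exact* only for uncentered
scatter — the window mean changes as the window slides — so the engine
assumes approximately zero-mean (high-pass-filtered) signals and offers
the centered 1/(N−1) covariance separately for reporting.  Constraints:
ns ≥ k (full-rank initial window, enforced with a condition-number check
at 1e12) and 1 ≤ cy ≤ ⌊ns/2⌋.

The inverse is carried by the Miller rank-one identity chained over the k
column-masked terms of H = −DDᵀ + D′D′ᵀ: term i keeps column i of H and
zeroes the rest, giving an O(k²) update per term (the trace reduces to a
single entry of C⁻¹h).  Two failure modes are handled explicitly:

* **Degenerate denominator**: |1 + tr(C⁻¹E)| ≤ 1e−10·(1 + |tr|) aborts the
  chain and rebuilds (C+H)⁻¹ densely; the event is logged.
* **Drift on ill-conditioned windows**: when a strong coherent source
  dominates a short window the condition number can exceed 1e8, and the
  chained inverse loses accuracy multiplicatively.  The engine supports a
  periodic residual check (‖C·C⁻¹ − I‖_max > 1e−4 → dense rebuild); the
  streaming driver `alcmv_stream` enables it every update by default
  (`check_every=1`), because at ns = k this regime occurs routinely.  The
  check costs one k × k product, the same order as the Miller chain
  itself, and keeps the advertised invariant (inverse residual ≤ 1e−6)
  over arbitrarily long streams.

`alcmv_stream` seeds the window with the first ns samples, reconstructs
those samples retroactively with the initial weights (so output length
equals input length), then per stride updates scatter + inverse, refreshes
orientations and weights every `reorient_every` strides (default 1 — the
covariance and the filter move together; larger values decouple
orientation churn from the covariance recursion), and filters the newly
arrived samples with the current weights.  With ns = N the path reduces
exactly to the batch path under the uncentered-scatter convention, which
the tests assert.

## Evaluation metrics

Both headline errors are sign-invariant, max-normalized mean absolute
differences expressed as percentages:

* orientation: Σ_d ||η̂_d| − |η_d|| / (3 · max_d ||η̂_d| − |η_d||) × 100,
* reconstruction: Σ ||Ŝ_a| − |Ŝ_b|| / (r·c · max ||Ŝ_a| − |Ŝ_b||) × 100.

Because the normalizer is the maximum *difference*, these metrics are
scale-free in the differences: they quantify how evenly the error is
distributed (100% = uniform, →33% for a 3-vector with one dominant
component, →0 only as the profile becomes a single spike), not how large
it is.  Two consequences shape the implementation:

* **Agreement tolerance.**  Two eigensolvers that agree to rounding would
  still score O(50%) on pure noise, so `orientation_error` treats a
  maximum component difference ≤ `atol` (default 1e−6, the resolution
  below which two double-precision eigensolvers are not meaningfully
  distinct on moderately conditioned 3 × 3 problems) as agreement → 0%.
  This extends the 0/0 convention (numerator and denominator vanish
  together) continuously.  `reconstruction_error` defaults to exact
  (`atol=0`): the pairs it compares differ by genuine algorithmic
  discrepancies, not rounding.
* **Alternative normalizer.**  `reconstruction_error(..., 
  normalizer="max_signal")` divides by the largest absolute signal value
  instead, yielding an error *relative to the signals* that does tend to 0
  as two reconstructions converge.  The pipeline report carries both.
  Reports also include the plain orientation cosine |⟨η̂, η⟩|, the most
  interpretable single accuracy number.

Active sources are ranked by Σ_t |ŝ(t)|; ties break to the lower index.
The active/inactive call uses a threshold at a fraction (default 0.1) of
the top score — the fraction is a free parameter with no canonical value,
chosen to separate planted sources from beamformer leakage by an order of
magnitude at the simulator's default SNR.  Localization error is the
Euclidean distance between grid positions in millimetres.

## Synthetic data generator

`alcmv.synthetic` emulates multichannel EEG with fully known ground truth:

* **Lead fields**: seeded standard-normal k × 3 matrices (full column
  rank almost surely, verified), preserving exactly the structure the
  inverse methods use; optionally an analytic dipole-in-a-homogeneous-
  sphere model (electrodes on a 10 cm sphere, sources inside 7 cm,
  σ = 0.33 S/m, average reference) when source *positions* are needed.
* **Waveforms**: sine (default 10 Hz, phase π/2 so the peak amplitude is
  attained exactly), Gaussian-windowed burst (default: centered,
  envelope SD = duration/8), seeded Poisson spike trains (3 Hz, 20 ms
  Gaussian pulses), or caller-supplied samples.
* **Noise**: i.i.d. Gaussian per channel and sample.  Study conditions
  quote amplitude-ratio SNR: σ_noise = (peak noiseless sensor
  amplitude)/SNR.

Defaults reflect a modest clinical montage: k = 24 channels, fs = 250 Hz,
N = 2000 samples (8 s), SNR 10.  The generator does **not** model
spatially correlated or 1/f background activity, artifacts, electrode
geometry errors, head-model mismatch, or nonstationary source coupling —
so passing tests demonstrate algorithmic correctness (recursions exact,
inverses accurate, orientations recovered, planted sources ranked first),
not clinical-grade localization on real EEG.

## Problem sizes and numerical choices

The bundled study uses desk-scale sizes: 1000 simulated beamformer
matrices (k = 24, 200-sample covariances) for the orientation comparison,
and one 24-channel, 2000-sample recording (ns = 24, cy = 1, re-orientation
every stride) for the streaming-vs-batch comparison; the whole acceptance
run completes in seconds.

Known limitations worth restating:

* An ns = k covariance window is the *minimum* that is invertible, and its
  estimation variance is large: streaming weights from a 24-sample window
  differ materially from batch weights, the more so the stronger and the
  less stationary the source.  The pipeline reports this discrepancy
  rather than hiding it; longer windows reduce it at the cost of
  adaptation speed.
* For cy = 1 the Miller chain costs O(k³) per stride (k rank-one updates
  of O(k²)), the same order as a dense re-inversion; the saving over a
  naive implementation is in never recomputing the O(k²N) full covariance.
  The chain's advantage grows when cy > 1 amortizes orientation/weight
  refreshes.
* Repeated eigenvalues of A (isotropic source configurations) make the
  orientation ill-defined; the solver returns a canonical null-space
  vector and labels it `degenerate` rather than guessing.
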