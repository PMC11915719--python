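"""Evaluation metrics: sign-invariant normalized errors, ranking, localization.

Both error metrics compare magnitudes (a spatial filter determines the
source time series and orientation only up to a global sign), take the
element-wise absolute difference, and normalize by the number of elements
times the maximum absolute difference, expressed as a percentage::

    err = 100 * sum(| |a| - |b| |) / (n_elements * max(| |a| - |b| |))

For orientations (3-vectors) n_elements is 3; for reconstructed signal
matrices it is rows x columns.  The metric lies in [0, 100] by construction
and is 0 when the arguments agree up to sign.

Because the normalizer is the maximum *difference*, the metric is scale
free in the differences: it measures the shape of the error distribution,
not its size, and would amplify pure floating-point noise between two
otherwise identical results to an O(1) percentage.  Each metric therefore
takes an ``atol`` — when the largest absolute difference is below it the
arguments are declared in agreement and the error is 0 (the continuous
extension of the 0/0 case).  ``orientation_error`` defaults to
``atol=1e-6`` on unit vectors, the resolution below which two
double-precision eigensolvers are not meaningfully distinct;
``reconstruction_error`` defaults to exact (``atol=0``) because the methods
it compares differ by genuine algorithmic discrepancies, not rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationErrorReport",
    "ReconstructionErrorReport",
    "orientation_error",
    "orientation_error_report",
    "reconstruction_error",
    "active_source_ranking",
    "localization_error",
    "active_classification_accuracy",
]


@dataclass(frozen=True)
class OrientationErrorReport:
    per_source: np.ndarray  # percentages
    mean: float
    max: float


@dataclass(frozen=True)
class ReconstructionErrorReport:
    error: float  # percentage
    n_elements: int


def _max_normalized_error(a, b, atol, normalizer="max_difference"):
    d = np.abs(np.abs(a) - np.abs(b))
    if normalizer == "max_difference":
        m = d.max()
    elif normalizer == "max_signal":
        m = max(np.abs(a).max(), np.abs(b).max())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if d.max() <= atol or m == 0.0:
        return 0.0
    return float(d.sum() / (d.size * m) * 100.0)


def orientation_error(est, ref, atol=1e-6):
    """Sign-invariant normalized orientation error between two unit 3-vectors (%)."""
    est = np.asarray(est, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if est.shape != (3,) or ref.shape != (3,):
        raise ValueError("orientation_error expects two 3-vectors")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise ValueError("orientations must be finite")
    return _max_normalized_error(est, ref, atol)


def orientation_error_report(estimates, references, atol=1e-6):
    """Per-source orientation errors with mean and max summaries."""
    errs = np.array(
        [orientation_error(e, r, atol=atol) for e, r in zip(estimates, references)]
    )
    return OrientationErrorReport(per_source=errs, mean=float(errs.mean()),
                                  max=float(errs.max()))


def reconstruction_error(S_a, S_b, atol=0.0, normalizer="max_difference"):
    """Sign-invariant normalized discrepancy between two signal matrices (%).

    Typically compares the streaming and batch reconstructions of the same
    recording; 0 means agreement up to sign.  ``normalizer`` selects the
    denominator scale: ``"max_difference"`` (default) divides by the largest
    absolute difference, measuring the shape of the error profile;
    ``"max_signal"`` divides by the largest absolute signal value, measuring
    the error *relative to the signals* — the quantity to reach for when
    asking how close two reconstructions are (the default cannot fall toward
    0 as the methods converge, since mean/max of any residual profile stays
    O(0.1)).
    """
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    if S_a.shape != S_b.shape:
        raise ValueError(f"shape mismatch: {S_a.shape} vs {S_b.shape}")
    return _max_normalized_error(S_a, S_b, atol, normalizer)


def reconstruction_error_report(S_a, S_b, atol=0.0, normalizer="max_difference"):
    return ReconstructionErrorReport(
        error=reconstruction_error(S_a, S_b, atol=atol, normalizer=normalizer),
        n_elements=int(np.asarray(S_a).size),
    )


def _scores(estimate):
    s_hat = getattr(estimate, "s_hat", estimate)
    s_hat = np.atleast_2d(np.asarray(s_hat, dtype=float))
    return np.abs(s_hat).sum(axis=1)


def active_source_ranking(estimate):
    """Rank candidate sources by summed absolute reconstructed amplitude.

    Accepts a :class:`~alcmv.beamformer.SourceEstimate` or a raw M x N
    array.  Returns ``(indices, scores)`` in descending score order; ties
    break toward the lower source index.
    """
    scores = _scores(estimate)
    if scores.size < 1:
        raise ValueError("need at least one source")
    order = np.lexsort((np.arange(scores.size), -scores))
    return order, scores[order]


def localization_error(est_index, true_index, positions):
    """Euclidean distance (mm) between two grid positions (M x 3, mm)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an M x 3 array")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    M = positions.shape[0]
    for name, idx in (("est_index", est_index), ("true_index", true_index)):
        if not 0 <= idx < M:
            raise ValueError(f"{name}={idx} outside the {M}-point grid")
    return float(np.linalg.norm(positions[est_index] - positions[true_index]))


def active_classification_accuracy(scores, truth, threshold_fraction=0.1):
    """Accuracy (%) of active/inactive calls from ranking scores.

    A source is called active when its score exceeds ``threshold_fraction``
    times the top score; the call is compared against the ground-truth
    activity flags.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth flags must align")
    top = scores.max() if scores.size else 0.0
    predicted = scores > threshold_fraction * top
    return float(np.mean(predicted == truth) * 100.0)
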