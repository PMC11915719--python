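"""Synthetic EEG forward simulation with known ground truth.

Dipolar sources with fixed unit orientations drive a linear forward model

    y(t) = sum_m  L_m  eta_m  s_m(t)  +  noise,

where each ``L_m`` is a k x 3 lead field (sensors x Cartesian dipole
components), ``eta_m`` a unit orientation, ``s_m(t)`` the source waveform,
and the sensor noise is i.i.d. zero-mean Gaussian with configurable
standard deviation.  Lead fields are either seeded random full-column-rank
matrices (the default, preserving only the k x 3 structure the inverse
methods rely on) or an analytic dipole-in-a-homogeneous-sphere model with
scalp electrodes and interior source positions, which additionally yields
the source coordinates needed for localization-error metrics.

Everything is deterministic for a fixed seed.  Channels are rows and
samples are columns throughout (k x N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = [
    "SourceSpec",
    "SimulationConfig",
    "make_lead_field",
    "make_spherical_montage",
    "simulate_sources",
    "forward_project",
    "simulate_recording",
    "write_ground_truth",
    "read_ground_truth",
]

_WAVEFORMS = ("sine", "burst", "spikes", "samples")


@dataclass
class SourceSpec:
    """One candidate dipole: grid location, orientation, waveform, activity flag.

    Waveform families (amplitudes in arbitrary source units, frequencies Hz):

    - ``sine``  : ``a * sin(2*pi*f*t + phase)``; default phase pi/2, so the
      waveform starts at its peak and attains ``a`` exactly on sample 0.
    - ``burst`` : the sine multiplied by a Gaussian envelope centered at
      ``burst_center`` seconds (default: mid-record) with standard deviation
      ``burst_width`` seconds (default: an eighth of the record).
    - ``spikes``: seeded Poisson train (``spike_rate`` Hz) of Gaussian-shaped
      pulses of width ``spike_width`` seconds and height ``a``.
    - ``samples``: caller-supplied waveform in ``samples`` (length N).
    """

    location_index: int
    orientation: np.ndarray
    waveform: str = "sine"
    amplitude: float = 1.0
    frequency: float = 10.0
    phase: float = np.pi / 2
    burst_center: Optional[float] = None
    burst_width: Optional[float] = None
    spike_rate: float = 3.0
    spike_width: float = 0.02
    samples: Optional[np.ndarray] = None
    active: bool = True

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3,):
            raise ValueError("orientation must be a 3-vector")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-12:
            raise ValueError("orientation must have unit Euclidean norm (to 1e-12)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.location_index < 0:
            raise ValueError("location_index must be nonnegative")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(
                f"unknown waveform family {self.waveform!r}; choose from {_WAVEFORMS}"
            )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording."""

    k: int = 24
    N: int = 2000
    fs: float = 250.0
    noise_sigma: float = 0.0
    seed: int = 0
    sources: List[SourceSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 channels")
        if self.N < self.k:
            raise ValueError("need N >= k samples so a full-rank window exists")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def make_lead_field(k, M, seed, geometry="random"):
    """M candidate lead fields of shape k x 3, deterministic for a seed.

    ``geometry="random"`` draws standard-normal entries (full column rank
    with probability one; verified and redrawn if necessary).
    ``geometry="sphere"`` uses the analytic spherical model of
    :func:`make_spherical_montage` and returns only the lead fields.
    """
    if k < 2:
        raise ValueError("need at least 2 channels")
    if M < 1:
        raise ValueError("need at least 1 source location")
    if geometry == "sphere":
        return make_spherical_montage(k, M, seed)[0]
    if geometry != "random":
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    fields = []
    target_rank = min(k, 3)
    for _ in range(M):
        L = rng.standard_normal((k, 3))
        while np.linalg.matrix_rank(L) < target_rank:  # pragma: no cover
            L = rng.standard_normal((k, 3))
        fields.append(L)
    return fields


def _fibonacci_hemisphere(n, radius):
    """Roughly uniform points on the upper hemisphere of the given radius."""
    i = np.arange(n)
    z = 0.05 + 0.95 * (i + 0.5) / n  # keep off the equator and the pole
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_spherical_montage(k, M, seed, head_radius=0.10, source_radius=0.07,
                           sigma=0.33):
    """Analytic dipole model: electrodes on a sphere, sources inside it.

    The scalp potential of a unit dipole ``q`` at ``r0`` in an (infinite)
    homogeneous conductor of conductivity ``sigma`` S/m is
    ``V(r) = q . (r - r0) / (4 pi sigma |r - r0|^3)``; potentials are
    average-referenced across the montage.  Radii in metres.

    Returns ``(lead_fields, electrode_positions, source_positions)`` with
    source positions in millimetres (the unit localization errors use).
    """
    if k < 2 or M < 1:
        raise ValueError("need k >= 2 electrodes and M >= 1 sources")
    rng = np.random.default_rng(seed)
    electrodes = _fibonacci_hemisphere(k, head_radius)
    # sources: random directions at radii in [0.3, 1.0] * source_radius
    dirs = rng.standard_normal((M, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = source_radius * (0.3 + 0.7 * rng.random(M))
    sources = dirs * radii[:, None]
    fields = []
    for r0 in sources:
        d = electrodes - r0  # k x 3
        L = d / (4.0 * np.pi * sigma * np.linalg.norm(d, axis=1, keepdims=True) ** 3)
        L = L - L.mean(axis=0, keepdims=True)  # average reference
        fields.append(L)
    return fields, electrodes, sources * 1000.0


def simulate_sources(specs, N, fs, seed):
    """Source activity matrix, one row per spec (M x N); inactive rows are zero."""
    if N < 1:
        raise ValueError("need at least one sample")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(N) / fs
    duration = N / fs
    activity = np.zeros((len(specs), N))
    for m, spec in enumerate(specs):
        # one independent stream per source so activity is order-stable
        row_rng = np.random.default_rng(rng.integers(0, 2**63))
        if not spec.active:
            continue
        if spec.waveform == "sine":
            activity[m] = spec.amplitude * np.sin(
                2.0 * np.pi * spec.frequency * t + spec.phase
            )
        elif spec.waveform == "burst":
            center = duration / 2.0 if spec.burst_center is None else spec.burst_center
            width = duration / 8.0 if spec.burst_width is None else spec.burst_width
            carrier = np.sin(2.0 * np.pi * spec.frequency * t + spec.phase)
            envelope = np.exp(-0.5 * ((t - center) / width) ** 2)
            activity[m] = spec.amplitude * carrier * envelope
        elif spec.waveform == "spikes":
            n_spikes = row_rng.poisson(spec.spike_rate * duration)
            times = row_rng.uniform(0.0, duration, size=n_spikes)
            row = np.zeros(N)
            for t0 in times:
                row += np.exp(-0.5 * ((t - t0) / spec.spike_width) ** 2)
            peak = np.abs(row).max()
            if peak > 0:
                row *= spec.amplitude / peak
            activity[m] = row
        else:  # samples
            if spec.samples is None:
                raise ValueError("waveform 'samples' requires the samples field")
            samples = np.asarray(spec.samples, dtype=float)
            if samples.shape != (N,):
                raise ValueError(
                    f"supplied samples have shape {samples.shape}, expected ({N},)"
                )
            activity[m] = spec.amplitude * samples
    return activity


def forward_project(lead_fields, specs, activity, noise_sigma, seed):
    """Mix source activity to the sensors and add Gaussian noise.

    ``y = sum_m L[spec_m.location_index] @ eta_m * s_m(t) + eps``, with
    ``eps ~ N(0, noise_sigma^2)`` i.i.d. per channel and sample
    (``noise_sigma=0`` gives the exact linear mixture).
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    if activity.shape[0] != len(specs):
        raise ValueError(
            f"activity has {activity.shape[0]} rows for {len(specs)} source specs"
        )
    k = np.asarray(lead_fields[0]).shape[0]
    N = activity.shape[1]
    y = np.zeros((k, N))
    for spec, row in zip(specs, activity):
        if spec.location_index >= len(lead_fields):
            raise ValueError(
                f"location_index {spec.location_index} outside the "
                f"{len(lead_fields)}-point grid"
            )
        L = np.asarray(lead_fields[spec.location_index], dtype=float)
        if L.shape != (k, 3):
            raise ValueError(f"lead field has shape {L.shape}, expected ({k}, 3)")
        y += np.outer(L @ spec.orientation, row)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sigma * rng.standard_normal(y.shape)
    return y


def simulate_recording(config, lead_fields=None):
    """End-to-end simulation: lead fields, activity, sensors.

    Returns ``(y, lead_fields, activity)``.  Sub-seeds for the lead fields,
    waveforms and noise are derived from ``config.seed`` so the three stages
    are independently reproducible.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31, size=3)
    M = max((s.location_index for s in config.sources), default=-1) + 1
    if lead_fields is None:
        lead_fields = make_lead_field(config.k, max(M, 1), seed=int(seeds[0]))
    activity = simulate_sources(config.sources, config.N, config.fs, seed=int(seeds[1]))
    y = forward_project(
        lead_fields, config.sources, activity, config.noise_sigma, seed=int(seeds[2])
    )
    return y, lead_fields, activity


def write_ground_truth(path, specs, config=None):
    """Plain-text JSON sidecar with the planted source parameters."""
    payload = {
        "sources": [
            {
                "location_index": int(s.location_index),
                "orientation": [float(x) for x in s.orientation],
                "waveform": s.waveform,
                "amplitude": float(s.amplitude),
                "frequency": float(s.frequency),
                "active": bool(s.active),
            }
            for s in specs
        ]
    }
    if config is not None:
        payload["config"] = {
            "k": config.k,
            "N": config.N,
            "fs": config.fs,
            "noise_sigma": config.noise_sigma,
            "seed": config.seed,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_ground_truth(path):
    with open(path) as fh:
        return json.load(fh)
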