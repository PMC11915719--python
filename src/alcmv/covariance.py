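"""Windowed channel covariance with recursive scatter and inverse updates.

For streaming EEG the k x k second-moment matrix of a sliding window of ns
samples is maintained without recomputation: when the window advances by cy
samples, the scatter of the departing block is subtracted and the scatter of
the arriving block added::

    C_{n+1} = C_n - R_n + R'_n

The update ``H = -R_n + R'_n`` is decomposed column-by-column into k
rank-one terms (term i keeps column i of H and zeroes the rest), and the
inverse is carried along with the Miller rank-one identity

    (C + E)^{-1} = C^{-1} - v * C^{-1} E C^{-1},   v = 1 / (1 + tr(C^{-1} E)),

chained over the k terms.  The recursion is exact for *uncentered* scatter
matrices ``X X^T`` only (the window mean changes as the window slides), so
the engine stores uncentered scatter and assumes approximately zero-mean
(high-pass filtered) signals; :func:`batch_covariance` provides the
mean-removed 1/(N-1) sample covariance for reporting.  Beamformer weights
are invariant to positive scaling of the covariance, so deferring the
1/(N-1) factor is harmless downstream.

When a Miller denominator falls within tolerance of zero the update is
degenerate and the engine rebuilds the inverse by dense inversion, logging
the event; an optional periodic residual check (``check_every``) bounds
drift over long streams the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

__all__ = [
    "DegenerateUpdate",
    "SingularCovariance",
    "RankOneTerm",
    "CovarianceState",
    "batch_covariance",
    "init_state",
    "window_update",
    "rank_one_decompose",
    "miller_inverse_update",
    "recursive_inverse_update",
    "save_state",
    "load_state",
]

# relative tolerance on the Miller denominator 1 + tr(Cinv E)
_MILLER_RTOL = 1e-10
# inverse-residual threshold that triggers a dense rebuild in the periodic check
_RESIDUAL_LIMIT = 1e-4
# condition number beyond which the initial window is treated as singular
_COND_LIMIT = 1e12


class DegenerateUpdate(Exception):
    """A Miller denominator is numerically zero; rebuild the inverse densely."""


class SingularCovariance(Exception):
    """The (windowed) covariance is rank deficient or numerically singular."""


@dataclass(frozen=True)
class RankOneTerm:
    """One column-masked term of the rank-one decomposition of a square H.

    Represents the k x k matrix with ``column`` in position ``index`` and
    zeros elsewhere; rank <= 1 by construction.
    """

    column: np.ndarray
    index: int

    def to_matrix(self):
        k = self.column.shape[0]
        E = np.zeros((k, k))
        E[:, self.index] = self.column
        return E


@dataclass
class CovarianceState:
    """Scatter matrix and inverse of the current sliding window.

    ``C`` is the uncentered scatter ``X X^T`` of the samples in
    ``[window_start, window_end)`` (plus any diagonal loading applied at
    initialization); ``Cinv`` its inverse, valid when ``cinv_valid`` is set.
    """

    C: np.ndarray
    Cinv: np.ndarray
    window_start: int
    window_end: int
    ns: int
    cy: int
    cinv_valid: bool = True
    check_every: int = 0
    update_count: int = 0
    fallback_log: List[str] = field(default_factory=list)

    @property
    def k(self):
        return self.C.shape[0]

    def normalized_covariance(self):
        """C scaled by 1/(ns - 1): the covariance view of the scatter."""
        return self.C / (self.ns - 1)

    def copy(self):
        return CovarianceState(
            C=self.C.copy(),
            Cinv=self.Cinv.copy(),
            window_start=self.window_start,
            window_end=self.window_end,
            ns=self.ns,
            cy=self.cy,
            cinv_valid=self.cinv_valid,
            check_every=self.check_every,
            update_count=self.update_count,
            fallback_log=list(self.fallback_log),
        )


def batch_covariance(block, center=True):
    """k x k covariance of a k x n block (channels are rows).

    With ``center=True`` this is the sample covariance with 1/(n-1)
    normalization; with ``center=False`` the raw uncentered scatter
    ``block @ block.T`` used inside the sliding-window recursion.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    n = block.shape[1]
    if center:
        if n < 2:
            raise ValueError("centered covariance needs at least 2 samples")
        x = block - block.mean(axis=1, keepdims=True)
        return (x @ x.T) / (n - 1)
    if n < 1:
        raise ValueError("empty block")
    return block @ block.T


def _validate_window_params(k, ns, cy):
    if ns < k:
        raise ValueError(
            f"initial window length ns={ns} must be >= the channel count k={k} "
            "so the window scatter has full rank"
        )
    if not 1 <= cy <= ns // 2:
        raise ValueError(f"update stride cy={cy} must satisfy 1 <= cy <= floor(ns/2)={ns // 2}")


def init_state(first_block, ns, cy, diagonal_loading=0.0, check_every=0):
    """Initialize the sliding-window state from the first ns samples.

    ``diagonal_loading`` adds ``lambda * mean(diag(C)) * I`` before the
    initial dense inversion (default 0: the window is assumed full rank).
    """
    first_block = np.atleast_2d(np.asarray(first_block, dtype=float))
    k, n = first_block.shape
    if n != ns:
        raise ValueError(f"first block has {n} samples, expected ns={ns}")
    _validate_window_params(k, ns, cy)
    C = batch_covariance(first_block, center=False)
    if diagonal_loading > 0:
        C = C + diagonal_loading * np.mean(np.diag(C)) * np.eye(k)
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularCovariance(
            f"initial window scatter is numerically singular "
            f"(condition number {cond:.3e}); the first {ns} samples must span "
            f"all {k} channels — consider diagonal loading"
        )
    Cinv = np.linalg.inv(C)
    return CovarianceState(
        C=C, Cinv=Cinv, window_start=0, window_end=ns, ns=ns, cy=cy,
        check_every=check_every,
    )


def window_update(state, departing_block, arriving_block):
    """Advance the window by cy samples, updating the scatter only.

    ``C_new = C - D D^T + D' D'^T`` where D / D' are the departing and
    arriving k x cy blocks.  Returns a new state with ``Cinv`` marked stale;
    use :func:`recursive_inverse_update` to carry the inverse along instead.
    """
    D = np.atleast_2d(np.asarray(departing_block, dtype=float))
    Dp = np.atleast_2d(np.asarray(arriving_block, dtype=float))
    for name, blk in (("departing", D), ("arriving", Dp)):
        if blk.shape != (state.k, state.cy):
            raise ValueError(
                f"{name} block has shape {blk.shape}, expected ({state.k}, {state.cy})"
            )
    new = state.copy()
    new.C = state.C - D @ D.T + Dp @ Dp.T
    new.window_start += state.cy
    new.window_end += state.cy
    new.cinv_valid = False
    return new


def rank_one_decompose(H):
    """Decompose square H into k column-masked rank-one terms summing to H."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError(f"H must be square, got shape {H.shape}")
    return [RankOneTerm(column=H[:, i].copy(), index=i) for i in range(H.shape[0])]


def miller_inverse_update(Cinv, E):
    """Rank-one inverse update: (C + E)^{-1} from C^{-1}.

    ``E`` may be a :class:`RankOneTerm` (O(k^2) path) or a dense rank-one
    matrix.  Raises :class:`DegenerateUpdate` when the denominator
    ``1 + tr(Cinv E)`` is within relative tolerance of zero, in which case
    the caller must rebuild the inverse directly.
    """
    Cinv = np.asarray(Cinv, dtype=float)
    if isinstance(E, RankOneTerm):
        u = Cinv @ E.column  # column index of Cinv E
        t = u[E.index]  # tr(Cinv E): only diagonal entry of Cinv E
        denom = 1.0 + t
        if abs(denom) <= _MILLER_RTOL * (1.0 + abs(t)):
            raise DegenerateUpdate(
                f"Miller denominator 1 + tr(Cinv E) = {denom:.3e} is numerically zero"
            )
        return Cinv - np.outer(u / denom, Cinv[E.index, :])
    E = np.asarray(E, dtype=float)
    t = float(np.trace(Cinv @ E))
    denom = 1.0 + t
    if abs(denom) <= _MILLER_RTOL * (1.0 + abs(t)):
        raise DegenerateUpdate(
            f"Miller denominator 1 + tr(Cinv E) = {denom:.3e} is numerically zero"
        )
    return Cinv - (Cinv @ E @ Cinv) / denom


def recursive_inverse_update(state, H):
    """Apply a full window transition ``C -> C + H`` with a recursive inverse.

    ``H`` must be the scatter difference ``-R + R'`` of the departing and
    arriving blocks for the current window.  The inverse is chained through
    the k column terms of :func:`rank_one_decompose`; if any step is
    degenerate, the whole update falls back to dense inversion of ``C + H``
    and the event is recorded in ``fallback_log``.  The window indices
    advance by cy.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != state.C.shape:
        raise ValueError(f"H has shape {H.shape}, expected {state.C.shape}")
    if not state.cinv_valid:
        raise ValueError("state.Cinv is stale; rebuild it before recursive updates")
    new = state.copy()
    new.C = state.C + H
    new.window_start += state.cy
    new.window_end += state.cy
    new.update_count += 1
    try:
        Cinv = state.Cinv
        for term in rank_one_decompose(H):
            Cinv = miller_inverse_update(Cinv, term)
        new.Cinv = Cinv
    except DegenerateUpdate as exc:
        new.Cinv = np.linalg.inv(new.C)
        new.fallback_log.append(
            f"update {new.update_count} (window start {new.window_start}): "
            f"dense rebuild after degenerate Miller step: {exc}"
        )
        return new
    if new.check_every > 0 and new.update_count % new.check_every == 0:
        resid = np.abs(new.C @ new.Cinv - np.eye(new.k)).max()
        if resid > _RESIDUAL_LIMIT:
            new.Cinv = np.linalg.inv(new.C)
            new.fallback_log.append(
                f"update {new.update_count}: dense rebuild after residual "
                f"{resid:.3e} exceeded {_RESIDUAL_LIMIT:g}"
            )
    return new


def save_state(path, state):
    """Checkpoint the state to an .npz container with a JSON header."""
    import json

    header = json.dumps(
        {
            "k": state.k,
            "ns": state.ns,
            "cy": state.cy,
            "window_start": state.window_start,
            "window_end": state.window_end,
            "cinv_valid": state.cinv_valid,
            "check_every": state.check_every,
            "update_count": state.update_count,
            "fallback_log": state.fallback_log,
        }
    )
    np.savez(path, C=state.C, Cinv=state.Cinv, header=np.array(header))


def load_state(path):
    """Restore a checkpointed state written by :func:`save_state`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        return CovarianceState(
            C=data["C"],
            Cinv=data["Cinv"],
            window_start=header["window_start"],
            window_end=header["window_end"],
            ns=header["ns"],
            cy=header["cy"],
            cinv_valid=header["cinv_valid"],
            check_every=header["check_every"],
            update_count=header["update_count"],
            fallback_log=list(header["fallback_log"]),
        )
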