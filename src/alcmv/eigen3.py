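"""Closed-form eigendecomposition of real symmetric 3x3 matrices.

The matrix ``A = L^T R^{-1} L`` formed from a k x 3 lead field ``L`` and an
inverse channel covariance ``R^{-1}`` is always symmetric 3x3, so the dipole
orientation (the eigenvector of its smallest eigenvalue) can be obtained
without an iterative eigensolver:

* eigenvalues come from the trigonometric solution of the characteristic
  cubic, which is exact (up to rounding) for symmetric input;
* the eigenvector for an eigenvalue ``lam`` is a null vector of
  ``B = A - lam*I``.  ``B`` has rank 2 for a simple eigenvalue, so the null
  vector is read off in closed form from the structure of ``B``: a canonical
  axis when ``B`` is diagonal, a 2x2 null vector when one coordinate
  decouples, and a cross product of two rows of ``B`` in the general case.

Every returned eigenvector carries a ``case_label`` naming the structural
branch that produced it, so that test suites can verify that each branch of
the dispatch is exercised.  Branch selection uses a relative tolerance: an
entry or minor counts as nonzero when its magnitude exceeds
``1e-12 * ||A||_max`` (squared for minors, which scale quadratically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenPair3",
    "sym3",
    "eigenvalues_sym3",
    "eigenvector_sym3",
    "eig_sym3",
    "smallest_eigenvector",
]

# relative threshold below which an entry of A - lam*I counts as zero
_DISPATCH_RTOL = 1e-12
# tolerance for accepting ``lam`` as an eigenvalue of A
_EIGENVALUE_RTOL = 1e-6
# two eigenvalues closer than this (relative) are an unresolvable double root
_DEGENERATE_GAP = 3e-8


@dataclass(frozen=True)
class EigenPair3:
    """Full decomposition of a symmetric 3x3 matrix.

    Attributes
    ----------
    eigenvalues : ndarray, shape (3,)
        Real eigenvalues in descending order.
    eigenvectors : ndarray, shape (3, 3)
        Unit eigenvectors as *columns*, matching ``eigenvalues`` order,
        sign-canonicalized (first component of magnitude > 1e-12 positive).
    case_labels : tuple of str
        Structural branch used for each eigenvector.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    case_labels: tuple


def sym3(a11, a12, a13, a22, a23, a33):
    """Build a symmetric 3x3 matrix from its upper triangle."""
    return np.array(
        [[a11, a12, a13], [a12, a22, a23], [a13, a23, a33]], dtype=float
    )


def _check_sym3(A):
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    if not np.allclose(A, A.T, rtol=1e-10, atol=1e-10 * max(1.0, np.abs(A).max())):
        raise ValueError("matrix is not symmetric")
    # work on the exactly symmetrized matrix
    return 0.5 * (A + A.T)


def eigenvalues_sym3(A):
    """Eigenvalues of a symmetric 3x3 matrix, descending, in closed form.

    Uses the trigonometric solution of the characteristic cubic.  Diagonal
    input returns its diagonal exactly (sorted), preserving multiplicities.
    """
    A = _check_sym3(A)
    off = np.array([A[0, 1], A[0, 2], A[1, 2]])
    if np.all(off == 0.0):
        return np.sort(np.diag(A))[::-1]

    p1 = np.dot(off, off)
    q = A.trace() / 3.0
    dq = np.diag(A) - q
    p2 = np.dot(dq, dq) + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    if p == 0.0:  # scalar matrix (cannot happen with off != 0, kept for safety)
        return np.full(3, q)
    B = (A - q * np.eye(3)) / p
    r = np.clip(np.linalg.det(B) / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    lam1 = q + 2.0 * p * np.cos(phi)
    lam3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam2 = 3.0 * q - lam1 - lam3  # trace identity, exact to rounding
    return np.array([lam1, lam2, lam3])


def _canonical_sign(v):
    for comp in v:
        if abs(comp) > 1e-12:
            return v if comp > 0 else -v
    return v


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _null_vector_2x2(b_aa, b_ab, b_bb):
    """Null vector (x, y) of the singular symmetric block [[b_aa, b_ab], [b_ab, b_bb]]."""
    if np.hypot(b_aa, b_ab) >= np.hypot(b_ab, b_bb):
        return np.array([-b_ab, b_aa])
    return np.array([-b_bb, b_ab])


def _degenerate_null_vector(B, tol):
    """Canonical unit null vector when rank(B) <= 1 (repeated eigenvalue)."""
    row_norms = np.linalg.norm(B, axis=1)
    if row_norms.max() <= tol:
        return np.array([1.0, 0.0, 0.0])
    u = B[np.argmax(row_norms)]
    u = u / np.linalg.norm(u)
    # basis-aligned null-space vector with smallest index
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        v = e - np.dot(e, u) * u
        if np.linalg.norm(v) > 1e-6:
            return _unit(v)
    return np.array([1.0, 0.0, 0.0])  # unreachable


# axis of the unit-pivot component of the cross-product null vector, by the
# tabulated closed forms: 'pq' ~ (P, Q, 1), 'pr' ~ (P, 1, R), 'qr' ~ (1, Q, R)
_AXIS_FORM = {0: "qr", 1: "pr", 2: "pq"}


def eigenvector_sym3(A, lam):
    """Closed-form unit eigenvector of symmetric 3x3 ``A`` for eigenvalue ``lam``.

    Returns ``(v, case_label)`` where ``v`` is a sign-canonicalized unit
    vector satisfying ``A @ v ~= lam * v`` and ``case_label`` names the
    structural branch of ``B = A - lam*I`` used:

    - ``"diagonal"``      : all off-diagonal entries of B vanish;
    - ``"block-12"``, ``"block-13"``, ``"block-23"`` : one coordinate
      decouples and the named 2x2 block carries the null vector (the label
      ``block-jk`` means rows/columns j,k form the coupled block);
    - ``"pq-ij"``, ``"pr-ij"``, ``"qr-ij"`` : general case, null vector from
      the cross product of rows i and j of B, with the unit pivot on the
      third / second / first component respectively;
    - ``"degenerate"``    : rank(B) <= 1 (repeated eigenvalue); any canonical
      null-space vector is returned.

    Raises ``ValueError`` when ``lam`` is not an eigenvalue of ``A`` within
    tolerance.
    """
    A = _check_sym3(A)
    lam = float(lam)
    scale = max(np.abs(A).max(), abs(lam), 1e-300)

    evs = eigenvalues_sym3(A)
    if np.min(np.abs(evs - lam)) > _EIGENVALUE_RTOL * (1.0 + scale):
        raise ValueError(
            f"{lam!r} is not an eigenvalue of the matrix (spectrum {evs})"
        )

    B = A - lam * np.eye(3)
    tol = _DISPATCH_RTOL * scale
    b11, b22, b33 = B[0, 0], B[1, 1], B[2, 2]
    b12, b13, b23 = B[0, 1], B[0, 2], B[1, 2]

    # --- diagonal branch -------------------------------------------------
    if abs(b12) <= tol and abs(b13) <= tol and abs(b23) <= tol:
        pass  # handled below; checked first so exact structure keeps its label
    elif np.sum(np.abs(evs - lam) <= _DEGENERATE_GAP * (1.0 + scale)) >= 2:
        # repeated eigenvalue: the cubic resolves a double root only to
        # ~sqrt(eps), so B cannot be trusted beyond rank 1 — return a
        # canonical null-space vector
        return _degenerate_null_vector(B, max(tol, _DEGENERATE_GAP * scale)), "degenerate"

    if abs(b12) <= tol and abs(b13) <= tol and abs(b23) <= tol:
        diag = np.abs([b11, b22, b33])
        hits = np.flatnonzero(diag <= tol)
        i = int(hits[0]) if hits.size else int(np.argmin(diag))
        v = np.zeros(3)
        v[i] = 1.0
        return v, "diagonal"

    # --- one decoupled coordinate: 2x2 block branches ---------------------
    det_tol = _DISPATCH_RTOL * scale * scale
    for free, (a, b), label in (
        (0, (1, 2), "block-23"),
        (1, (0, 2), "block-13"),
        (2, (0, 1), "block-12"),
    ):
        i, j = (free, a), (free, b)
        if abs(B[i]) <= tol and abs(B[j]) <= tol:
            baa, bab, bbb = B[a, a], B[a, b], B[b, b]
            det2 = baa * bbb - bab * bab
            free_diag = B[free, free]
            if abs(free_diag) <= tol and abs(det2) > det_tol:
                v = np.zeros(3)
                v[free] = 1.0
                return v, label
            if abs(det2) <= det_tol and abs(free_diag) > tol:
                v = np.zeros(3)
                v[[a, b]] = _null_vector_2x2(baa, bab, bbb)
                return _canonical_sign(_unit(v)), label
            # both the axis and the block are null: repeated eigenvalue
            return _degenerate_null_vector(B, tol), "degenerate"

    # --- general branch: cross product of two rows of B -------------------
    crosses = {
        "12": np.cross(B[0], B[1]),
        "13": np.cross(B[0], B[2]),
        "23": np.cross(B[1], B[2]),
    }
    pair = max(crosses, key=lambda key: np.linalg.norm(crosses[key]))
    c = crosses[pair]
    if np.linalg.norm(c) <= det_tol:
        return _degenerate_null_vector(B, tol), "degenerate"
    form = _AXIS_FORM[int(np.argmax(np.abs(c)))]
    return _canonical_sign(_unit(c)), f"{form}-{pair}"


def eig_sym3(A):
    """Full closed-form decomposition of a symmetric 3x3 matrix."""
    A = _check_sym3(A)
    evs = eigenvalues_sym3(A)
    vecs = np.empty((3, 3))
    labels = []
    for i, lam in enumerate(evs):
        v, label = eigenvector_sym3(A, lam)
        vecs[:, i] = v
        labels.append(label)
    return EigenPair3(eigenvalues=evs, eigenvectors=vecs, case_labels=tuple(labels))


def smallest_eigenvector(A):
    """Unit eigenvector of the smallest eigenvalue of symmetric 3x3 ``A``.

    This is the optimal dipole orientation when ``A = L^T R^{-1} L``: the
    direction minimizing the beamformer output-power denominator.  The sign
    is canonical but physically arbitrary (``v`` and ``-v`` are equally
    valid orientations).
    """
    A = _check_sym3(A)
    evs = eigenvalues_sym3(A)
    v, _ = eigenvector_sym3(A, evs[2])
    return v
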