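"""Head-system inversion and lead-field (gain matrix) computation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .assembly import HeadMatrix, SourceMatrix, TransferMatrix

__all__ = [
    "BoundarySolution",
    "GainMatrix",
    "invert_head_matrix",
    "solve_head_system",
    "gain_eeg",
    "gain_meg",
    "gain_eit",
    "gain_ip",
]

SOLVER_TOL = 1e-10
COND_THRESHOLD = 1e12


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


@dataclass
class BoundarySolution:
    """Boundary unknowns X (one column per source) with residual check."""

    X: np.ndarray
    residual: float

    def __post_init__(self):
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite boundary solution")


@dataclass
class GainMatrix:
    matrix: np.ndarray
    modality: str
    provenance: str = ""
    # diagnostics for MEG: the two contributions kept separately
    ohmic: np.ndarray | None = None
    primary: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite gain matrix")

    @property
    def shape(self):
        return self.matrix.shape


def invert_head_matrix(head: HeadMatrix) -> np.ndarray:
    """Explicit symmetric inverse of the (deflated) head matrix.

    Errors out with a diagnosis when the matrix is numerically singular
    (most likely a missing deflation or a degenerate mesh).
    """
    h = head.matrix
    lu, piv = scipy.linalg.lu_factor(h)
    # cheap 1-norm reciprocal condition estimate from the factorization
    rcond = scipy.linalg.lapack.dgecon(lu, np.linalg.norm(h, 1))[0]
    if not np.isfinite(rcond) or rcond < 1.0 / COND_THRESHOLD:
        raise np.linalg.LinAlgError(
            f"head matrix numerically singular (cond ~ {1.0 / max(rcond, 1e-300):.2e}); "
            "likely cause: missing deflation or a degenerate mesh")
    hinv = scipy.linalg.lu_solve((lu, piv), np.eye(head.n))
    hinv = 0.5 * (hinv + hinv.T)  # symmetrize (H is symmetric)
    return hinv


def solve_head_system(head: HeadMatrix, source: SourceMatrix,
                      hinv: np.ndarray | None = None) -> BoundarySolution:
    """X with H X = SourceMatrix, via the explicit inverse when provided
    (mirroring the reusable-inverse workflow) or a direct solve."""
    b = source.matrix
    if hinv is not None:
        x = hinv @ b
    else:
        x = scipy.linalg.solve(head.matrix, b, assume_a="sym")
    nb = np.linalg.norm(b)
    res = float(np.linalg.norm(head.matrix @ x - b) / nb) if nb > 0 else 0.0
    if res > 1e-6:
        raise np.linalg.LinAlgError(f"head solve residual {res:.2e}")
    return BoundarySolution(x, res)


def _zero_mean(rows: np.ndarray) -> np.ndarray:
    return rows - rows.mean(axis=0, keepdims=True)


def gain_eeg(hinv_or_head, source: SourceMatrix,
             h2eeg: TransferMatrix) -> GainMatrix:
    """L_EEG = Head2EEG . H^-1 . SourceMatrix, re-referenced to zero mean
    over the electrodes."""
    x = _solve(hinv_or_head, source)
    if h2eeg.matrix.shape[1] != x.shape[0]:
        raise ValueError(
            f"Head2EEG maps {h2eeg.matrix.shape[1]} boundary unknowns, "
            f"solution has {x.shape[0]}")
    g = _zero_mean(h2eeg.matrix @ x)
    return GainMatrix(g, "EEG", provenance=_hash(h2eeg.matrix, x))


def _solve(hinv_or_head, source: SourceMatrix) -> np.ndarray:
    if isinstance(hinv_or_head, HeadMatrix):
        return solve_head_system(hinv_or_head, source).X
    hinv = np.asarray(hinv_or_head)
    if hinv.shape[1] != source.matrix.shape[0]:
        raise ValueError(
            f"inverse is {hinv.shape}, source matrix {source.matrix.shape}")
    return hinv @ source.matrix


def gain_meg(hinv_or_head, source: SourceMatrix, h2meg: TransferMatrix,
             s2meg: TransferMatrix) -> GainMatrix:
    """L_MEG = Head2MEG . X + Source2MEG; both parts kept for diagnostics."""
    x = _solve(hinv_or_head, source)
    ohmic = h2meg.matrix @ x
    primary = s2meg.matrix
    if ohmic.shape != primary.shape:
        raise ValueError(f"MEG parts mismatch: {ohmic.shape} vs "
                         f"{primary.shape}")
    return GainMatrix(ohmic + primary, "MEG",
                      provenance=_hash(ohmic, primary),
                      ohmic=ohmic, primary=primary)


def gain_eit(hinv_or_head, eit_source: SourceMatrix,
             h2eeg: TransferMatrix) -> GainMatrix:
    """EIT lead field: scalp potential per injection pattern (EEG pipeline
    with the EIT right-hand side)."""
    g = gain_eeg(hinv_or_head, eit_source, h2eeg)
    return GainMatrix(g.matrix, "EIT", provenance=g.provenance)


def gain_ip(hinv_or_head, source: SourceMatrix, h2ip: TransferMatrix,
            s2ip: TransferMatrix) -> GainMatrix:
    """L_IP = Head2IP . X + Source2IP (no re-referencing: gauge fixed by the
    scalp zero-mean deflation)."""
    x = _solve(hinv_or_head, source)
    rep = h2ip.matrix @ x
    if rep.shape != s2ip.matrix.shape:
        raise ValueError(f"IP parts mismatch: {rep.shape} vs "
                         f"{s2ip.matrix.shape}")
    return GainMatrix(rep + s2ip.matrix, "IP",
                      provenance=_hash(rep, s2ip.matrix))
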