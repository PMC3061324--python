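"""Accuracy metrics comparing numerical and analytical forward fields."""

from __future__ import annotations

import numpy as np

__all__ = ["rdm", "mag"]


def rdm(g_n, g_a) -> float:
    """Relative difference measure between two forward fields.

    ``|| g_n/||g_n|| - g_a/||g_a|| ||_2`` with the Euclidean norm over the
    sensor measurements; ranges over [0, 2] and is invariant to positive
    rescaling of either argument.
    """
    g_n = np.asarray(g_n, dtype=float).ravel()
    g_a = np.asarray(g_a, dtype=float).ravel()
    if g_n.shape != g_a.shape:
        raise ValueError("field vectors must have the same length")
    nn, na = np.linalg.norm(g_n), np.linalg.norm(g_a)
    if nn == 0 or na == 0:
        raise ValueError("rdm is undefined for zero-norm fields")
    return float(np.linalg.norm(g_n / nn - g_a / na))


def mag(g_n, g_a) -> float:
    """Magnitude ratio ``||g_n|| / ||g_a||`` (Euclidean norms)."""
    g_n = np.asarray(g_n, dtype=float).ravel()
    g_a = np.asarray(g_a, dtype=float).ravel()
    if g_n.shape != g_a.shape:
        raise ValueError("field vectors must have the same length")
    na = np.linalg.norm(g_a)
    if na == 0:
        raise ValueError("mag is undefined for a zero-norm reference")
    return float(np.linalg.norm(g_n) / na)
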