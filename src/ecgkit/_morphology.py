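"""Flat-structuring-element grayscale morphology with two backends.

Both backends replicate edge samples by half the element width and compute
identical min/max windows, so their outputs are bitwise equal; the naive
backend is a straightforward per-sample loop, the vectorized one uses
stride tricks.  The pipeline exposes the pair as interchangeable execution
backends whose end-to-end annotations must agree exactly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["erode", "dilate", "opening", "closing", "BACKENDS"]

BACKENDS = ("naive", "vectorized")


def _check(k: int, backend: str) -> None:
    if k < 1 or k % 2 == 0:
        raise ValueError(f"structuring element length must be odd and >= 1, got {k}")
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def _pad_edge(x: np.ndarray, half: int) -> np.ndarray:
    return np.pad(x, half, mode="edge")


def erode(x: np.ndarray, k: int, backend: str = "vectorized") -> np.ndarray:
    _check(k, backend)
    half = k // 2
    p = _pad_edge(x, half)
    if backend == "vectorized":
        return sliding_window_view(p, k).min(axis=1)
    out = np.empty_like(x)
    for i in range(x.size):
        lo = p[i]
        for j in range(1, k):
            v = p[i + j]
            if v < lo:
                lo = v
        out[i] = lo
    return out


def dilate(x: np.ndarray, k: int, backend: str = "vectorized") -> np.ndarray:
    _check(k, backend)
    half = k // 2
    p = _pad_edge(x, half)
    if backend == "vectorized":
        return sliding_window_view(p, k).max(axis=1)
    out = np.empty_like(x)
    for i in range(x.size):
        hi = p[i]
        for j in range(1, k):
            v = p[i + j]
            if v > hi:
                hi = v
        out[i] = hi
    return out


def opening(x: np.ndarray, k: int, backend: str = "vectorized") -> np.ndarray:
    return dilate(erode(x, k, backend), k, backend)


def closing(x: np.ndarray, k: int, backend: str = "vectorized") -> np.ndarray:
    return erode(dilate(x, k, backend), k, backend)
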