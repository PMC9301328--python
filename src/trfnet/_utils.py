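"""Shared helpers: seed derivation and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng", "pearson"]


def child_seed(seed: int | None, label: str) -> int:
    """Derive a stable 31-bit child seed from a root seed and a stage label.

    The same (seed, label) pair always yields the same child, and distinct
    labels decorrelate the streams, so every stochastic stage of a run can be
    reseeded independently and reproducibly.
    """
    if seed is None:
        seed = 0
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def child_rng(seed: int | None, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-D arrays; NaN if either is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("arrays must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))
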