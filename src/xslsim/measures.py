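"""Convergence measures: child error, chi-squared, Pearson correlation.

All three compare the child's probabilistic lexicon ``C`` with the group
lexicon ``G`` row by row and then average over referents.  They accept
stacked inputs: any leading batch dimensions (e.g. an ensemble of runs)
are preserved, with the last two axes read as (referent, word).

* ``child_error`` — mean child mass on the words the group never uses
  for a referent (the spurious associations); a probability in [0, 1].
* ``chi_squared`` — mean over referents of sum_w (C - G)^2 / G, taken
  over the words with G > 0 only (the G = 0 cells are exactly what the
  error measure covers).
* ``pearson`` — mean per-referent linear correlation between the child
  and group rows; rows with zero variance contribute 0 ("no linear
  relationship").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import ZERO_TOL

__all__ = ["MeasureRecord", "child_error", "chi_squared", "pearson", "evaluate"]


@dataclass(frozen=True)
class MeasureRecord:
    """Snapshot of the three measures at iteration ``t``."""

    t: int
    E: float
    chi2: float
    pearson: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.E <= 1.0):
            raise ValueError(f"child error must lie in [0, 1], got {self.E}")
        if self.chi2 < 0.0:
            raise ValueError(f"chi-squared must be non-negative, got {self.chi2}")
        if not (-1.0 - 1e-12 <= self.pearson <= 1.0 + 1e-12):
            raise ValueError(f"pearson must lie in [-1, 1], got {self.pearson}")


def _check_shapes(C: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = np.asarray(C, dtype=float)
    G = np.asarray(G, dtype=float)
    if C.ndim < 2 or G.ndim < 2 or C.shape[-2:] != G.shape[-2:]:
        raise ValueError(
            f"child and group lexicons must share the (referent, word) shape; "
            f"got {C.shape} vs {G.shape}"
        )
    return C, G


def child_error(C, G) -> np.ndarray | float:
    """Mean child probability mass on the group's zero-support words.

    For each referent the child's probabilities are averaged over the
    words with ``G(r, w) = 0`` (referents with full group support
    contribute 0), then averaged over referents.
    """
    C, G = _check_shapes(C, G)
    zero = G <= ZERO_TOL
    w0 = zero.sum(axis=-1)
    mass = (C * zero).sum(axis=-1)
    e_r = np.divide(mass, w0, out=np.zeros(np.broadcast(mass, w0).shape),
                    where=w0 > 0)
    out = e_r.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def chi_squared(C, G) -> np.ndarray | float:
    """Mean per-referent chi-squared statistic over the group's support."""
    C, G = _check_shapes(C, G)
    pos = G > ZERO_TOL
    dev = np.where(pos, (C - G) ** 2, 0.0)
    denom = np.where(pos, G, 1.0)
    chi_r = (dev / denom).sum(axis=-1)
    out = chi_r.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def pearson(C, G) -> np.ndarray | float:
    """Mean per-referent Pearson correlation between child and group rows."""
    C, G = _check_shapes(C, G)
    if C.shape[-1] < 2:
        raise ValueError("Pearson correlation needs at least 2 words")
    Cc = C - C.mean(axis=-1, keepdims=True)
    Gc = G - G.mean(axis=-1, keepdims=True)
    num = (Cc * Gc).sum(axis=-1)
    den = np.sqrt((Cc ** 2).sum(axis=-1) * (Gc ** 2).sum(axis=-1))
    num, den = np.broadcast_arrays(num, den)
    p_r = np.divide(num, den, out=np.zeros(num.shape), where=den > 0)
    out = p_r.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def evaluate(C, G, t: int = 0) -> MeasureRecord:
    """All three measures of a single child lexicon as a record."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("evaluate() scores a single (R, W) child lexicon")
    return MeasureRecord(
        t=t,
        E=float(child_error(C, G)),
        chi2=float(chi_squared(C, G)),
        pearson=float(pearson(C, G)),
    )
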