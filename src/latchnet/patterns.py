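"""Sparse random item codes and the cosine overlap used for recall
detection.

Each list item (a "word") is coded by a pattern with exactly one active
unit per hypercolumn — an H-of-(H*M) binary vector of norm ``sqrt(H)``.
Recall of item ``k`` is detected from the normalized dot product between
the network output and the stored pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = ["PatternList", "generate_list", "overlap", "overlap_all"]


@dataclass(frozen=True)
class PatternList:
    """A list of item patterns.

    ``active`` has shape ``(n_items, H)``: ``active[k, h]`` is the index
    (in ``0..M-1``) of the active unit of item ``k`` in hypercolumn ``h``.
    """

    active: np.ndarray
    H: int
    M: int

    @property
    def n_items(self) -> int:
        return self.active.shape[0]

    def dense(self) -> np.ndarray:
        """Patterns as 0/1 vectors of length ``H*M``, shape
        ``(n_items, H*M)``."""
        n = self.n_items
        x = np.zeros((n, self.H * self.M))
        rows = np.repeat(np.arange(n), self.H)
        cols = (np.arange(self.H) * self.M)[None, :] + self.active
        x[rows, cols.ravel()] = 1.0
        return x

    def to_frame(self) -> pd.DataFrame:
        """Tidy (item, hypercolumn, active_unit) table for CSV export."""
        n = self.n_items
        return pd.DataFrame({
            "item": np.repeat(np.arange(n), self.H),
            "hypercolumn": np.tile(np.arange(self.H), n),
            "active_unit": self.active.ravel(),
        })


def generate_list(n_items: int, params: ModelParams,
                  rng: np.random.Generator) -> PatternList:
    """Draw ``n_items`` distinct sparse random patterns.

    Each hypercolumn's active unit is drawn uniformly and independently;
    whole-pattern duplicates are redrawn so all items in a list are
    distinct (two random patterns still share ``H/M`` active units on
    average, which is the chance overlap the recall detector must reject).
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if np.log(n_items) > params.H * np.log(params.M):
        raise ValueError(
            f"cannot draw {n_items} distinct patterns from M**H = "
            f"{params.M}**{params.H} possibilities")
    seen: set[tuple[int, ...]] = set()
    rows = []
    while len(rows) < n_items:
        cand = rng.integers(0, params.M, size=params.H)
        key = tuple(int(v) for v in cand)
        if key in seen:
            continue
        seen.add(key)
        rows.append(cand)
    return PatternList(active=np.array(rows, dtype=np.int64),
                       H=params.H, M=params.M)


def overlap(pattern: np.ndarray, o: np.ndarray) -> float:
    """Cosine overlap ``m = (x . o) / (||x|| ||o||)`` of one dense 0/1
    pattern with the network output.  Always in ``[0, 1]`` for
    non-negative ``o`` and invariant to positive rescaling of ``o``."""
    no = float(np.linalg.norm(o))
    if no == 0.0:
        raise ValueError("network output has zero norm")
    return float(pattern @ o) / (float(np.linalg.norm(pattern)) * no)


def overlap_all(patterns: PatternList, o: np.ndarray) -> np.ndarray:
    """Overlap of every stored pattern with the output, shape
    ``(n_items,)``.  Uses the sparse index form: ``x_k . o`` is the sum of
    ``o`` at item ``k``'s active units and ``||x_k|| = sqrt(H)``."""
    no = float(np.linalg.norm(o))
    if no == 0.0:
        raise ValueError("network output has zero norm")
    cols = (np.arange(patterns.H) * patterns.M)[None, :] + patterns.active
    dots = o[cols].sum(axis=1)
    return dots / (np.sqrt(patterns.H) * no)
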