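"""Behavioral statistics over batches of free-recall trials.

Implements the standard analyses of the free-recall literature on the
simulated event logs: the serial position curve (primacy/recency), the
recall-length (memory span) distribution, the lag conditional-response
probability curve (contiguity and forward asymmetry), the encoding-phase
reactivation analyses, and a mean-squared-error comparison against
externally supplied target curves.

Trials flagged as excluded (two items registered at the identical time
step) are omitted from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import RecallEventLog

__all__ = [
    "BehavioralSummary",
    "serial_position_curve",
    "lag_crp",
    "span_distribution",
    "reactivation_analysis",
    "mse_compare",
    "summarize",
    "curves_frame",
]


@dataclass
class BehavioralSummary:
    """Bundle of the behavioral curves computed from one batch."""

    n_items: int
    n_trials_included: int
    n_trials_excluded: int
    spc: np.ndarray                 # recall prob per input position
    span_pmf: np.ndarray            # P(exactly r items), r = 0..n
    span_cum: np.ndarray            # P(at least r items), r = 0..n
    crp_lags: np.ndarray            # -(n-1)..-1, +1..(n-1)
    crp: np.ndarray                 # opportunity-normalized CRP per lag
    reactivation_counts: np.ndarray  # mean encoding reactivations per pos
    reactivation_grouped: dict      # positions 1-4 single, 5-8, 9-12
    p_recall_by_reactivations: np.ndarray  # bins 0, 1, 2+
    recall_counts_by_reactivations: np.ndarray  # items per bin


def _included(logs: list[RecallEventLog]) -> list[RecallEventLog]:
    return [lg for lg in logs if not lg.excluded]


def serial_position_curve(logs: list[RecallEventLog],
                          n_items: int) -> np.ndarray:
    """Fraction of included trials whose first-recall set contains the
    item presented at each input position."""
    inc = _included(logs)
    if not inc:
        raise ValueError("no included trials")
    spc = np.zeros(n_items)
    for lg in inc:
        for pos in set(lg.recalled_positions):
            spc[pos] += 1
    return spc / len(inc)


def lag_crp(logs: list[RecallEventLog], n_items: int,
            normalize: str = "opportunity",
            ) -> tuple[np.ndarray, np.ndarray]:
    """Lag conditional-response probability curve.

    For each successive pair in a trial's first-recall order the
    transition lag is the difference of input positions.  With
    ``normalize="opportunity"`` (the standard analysis) each realized lag
    is divided by the number of transitions in which that lag was still
    available given the not-yet-recalled items; ``normalize="raw"``
    divides by the total number of transitions instead.

    Returns ``(lags, crp)`` where lags run ``-(n-1)..(n-1)`` excluding 0.
    Lags with zero opportunities get probability 0.
    """
    if normalize not in ("opportunity", "raw"):
        raise ValueError(f"unknown normalize={normalize!r}")
    span = np.arange(-(n_items - 1), n_items)
    lags = span[span != 0]
    actual = np.zeros(lags.size)
    possible = np.zeros(lags.size)
    idx = {int(lag): i for i, lag in enumerate(lags)}
    n_transitions = 0
    for lg in _included(logs):
        order = lg.recalled_positions
        recalled: set[int] = set()
        for t in range(len(order) - 1):
            cur, nxt = order[t], order[t + 1]
            recalled.add(cur)
            actual[idx[nxt - cur]] += 1
            n_transitions += 1
            for pos in range(n_items):
                if pos != cur and pos not in recalled:
                    possible[idx[pos - cur]] += 1
    if normalize == "opportunity":
        with np.errstate(invalid="ignore"):
            crp = np.where(possible > 0,
                           actual / np.maximum(possible, 1), 0.0)
    else:
        crp = actual / max(n_transitions, 1)
    return lags, crp


def span_distribution(logs: list[RecallEventLog],
                      n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the number of items recalled per trial.

    Returns ``(pmf, cum)`` over ``r = 0..n_items`` where ``cum[r]`` is the
    probability of recalling at least ``r`` items (non-increasing in r).
    """
    inc = _included(logs)
    if not inc:
        raise ValueError("no included trials")
    counts = np.array([len(lg.first_recalls) for lg in inc])
    pmf = np.bincount(counts, minlength=n_items + 1)[:n_items + 1]
    pmf = pmf / len(inc)
    cum = 1.0 - np.concatenate([[0.0], np.cumsum(pmf)[:-1]])
    return pmf, cum


def reactivation_analysis(
    logs: list[RecallEventLog], n_items: int,
) -> tuple[np.ndarray, dict, np.ndarray, np.ndarray]:
    """Encoding-phase reactivation statistics.

    Returns per-position mean reactivation counts, the grouped summary
    (positions 1-4 individually, 5-8 and 9-12 pooled), the recall
    probability conditioned on the item's reactivation count (bins 0, 1,
    2+), and the number of item observations per bin.
    """
    inc = _included(logs)
    if not inc:
        raise ValueError("no included trials")
    totals = np.zeros(n_items)
    bin_hits = np.zeros(3)
    bin_n = np.zeros(3)
    for lg in inc:
        counts = lg.reactivation_counts()
        totals += counts
        recalled = set(lg.recalled_positions)
        for pos in range(n_items):
            b = min(int(counts[pos]), 2)
            bin_n[b] += 1
            if pos in recalled:
                bin_hits[b] += 1
    mean_counts = totals / len(inc)
    grouped = {str(p + 1): float(mean_counts[p])
               for p in range(min(4, n_items))}
    if n_items >= 8:
        grouped["5-8"] = float(mean_counts[4:8].mean())
    if n_items >= 12:
        grouped["9-12"] = float(mean_counts[8:12].mean())
    with np.errstate(invalid="ignore"):
        p_recall = np.where(bin_n > 0, bin_hits / np.maximum(bin_n, 1), 0.0)
    return mean_counts, grouped, p_recall, bin_n


def mse_compare(sim: "BehavioralSummary", targets: dict) -> float:
    """Mean squared error between simulated and target curves.

    ``targets`` maps any of ``"spc"``, ``"span_cum"``, ``"crp"`` to an
    array of matching length; the result is the sum of the per-curve mean
    squared errors (equal weights).
    """
    total = 0.0
    curve_map = {"spc": sim.spc, "span_cum": sim.span_cum, "crp": sim.crp}
    for name, target in targets.items():
        if name not in curve_map:
            raise KeyError(f"unknown target curve {name!r}")
        simc = curve_map[name]
        target = np.asarray(target, dtype=float)
        if target.shape != simc.shape:
            raise ValueError(
                f"length mismatch for {name}: target {target.shape} vs "
                f"simulated {simc.shape}")
        total += float(np.mean((simc - target) ** 2))
    return total


def summarize(logs: list[RecallEventLog],
              n_items: int | None = None) -> BehavioralSummary:
    """Compute every behavioral curve for a batch of trial logs."""
    if not logs:
        raise ValueError("empty batch")
    if n_items is None:
        n_items = logs[0].n_items
    inc = _included(logs)
    spc = serial_position_curve(logs, n_items)
    pmf, cum = span_distribution(logs, n_items)
    lags, crp = lag_crp(logs, n_items)
    counts, grouped, p_recall, bin_n = reactivation_analysis(logs, n_items)
    return BehavioralSummary(
        n_items=n_items,
        n_trials_included=len(inc),
        n_trials_excluded=len(logs) - len(inc),
        spc=spc, span_pmf=pmf, span_cum=cum,
        crp_lags=lags, crp=crp,
        reactivation_counts=counts, reactivation_grouped=grouped,
        p_recall_by_reactivations=p_recall,
        recall_counts_by_reactivations=bin_n)


def curves_frame(summary: BehavioralSummary) -> pd.DataFrame:
    """Tidy (curve, x, value) table of all behavioral curves, for the CSV
    interface."""
    rows = []
    for p in range(summary.n_items):
        rows.append(("spc", p + 1, summary.spc[p]))
    for r in range(summary.n_items + 1):
        rows.append(("span_pmf", r, summary.span_pmf[r]))
        rows.append(("span_cum", r, summary.span_cum[r]))
    for lag, v in zip(summary.crp_lags, summary.crp):
        rows.append(("crp", int(lag), v))
    for p in range(summary.n_items):
        rows.append(("reactivations", p + 1, summary.reactivation_counts[p]))
    for b, v in enumerate(summary.p_recall_by_reactivations):
        rows.append(("p_recall_by_reactivations", b, v))
    return pd.DataFrame(rows, columns=["curve", "x", "value"])
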