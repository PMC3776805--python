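"""Cq calling and single-curve amplification-efficiency estimation.

A quantification cycle (Cq) is the fractional cycle at which
baseline-subtracted fluorescence first crosses a fixed threshold (default
30 RFU), linearly interpolated between the flanking cycles.

Efficiency is estimated per reaction by the window-of-linearity approach:
ordinary least squares of log10(fluorescence) on cycle over a short window
(5, then 4, then 3 consecutive points) inside the exponential phase,
accepting the largest window with R² at or above a stringency cutoff
(default 0.998).  The amplification factor follows from the slope as
``1 + E = 10**slope``; no dilution series is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AmplificationCurve",
    "EfficiencyFit",
    "estimate_baseline",
    "call_cq",
    "fit_efficiency",
    "summarize_efficiencies",
]

#: Accepted efficiency span of validated assays; fits outside it warn.
EFFICIENCY_WARN_RANGE = (0.85, 1.10)


@dataclass(frozen=True)
class AmplificationCurve:
    """One reaction's fluorescence trace."""

    reaction_id: str
    gene: str
    sample: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cycles)
        f = np.asarray(self.fluorescence, dtype=float)
        if c.ndim != 1 or f.ndim != 1 or len(c) != len(f):
            raise ValueError("cycles and fluorescence must be 1-D and aligned")
        if len(c) and not np.all(np.diff(c) > 0):
            raise ValueError("cycles must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence must be finite")
        object.__setattr__(self, "cycles", np.asarray(c))
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class EfficiencyFit:
    """A window-of-linearity fit for one reaction.

    ``amplification_factor == 10**slope`` exactly, and ``E`` is that minus 1.
    """

    gene: str
    reaction_id: str
    E: float
    amplification_factor: float
    window: tuple[int, int]
    n_points: int
    r2: float
    slope: float


def estimate_baseline(
    curve: AmplificationCurve, early_window: tuple[int, int] = (3, 10)
) -> float:
    """Mean fluorescence over the early, pre-exponential cycles."""
    return _baseline_stats(curve, early_window)[0]


def _baseline_stats(
    curve: AmplificationCurve, early_window: tuple[int, int]
) -> tuple[float, float]:
    lo, hi = early_window
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    if not mask.any():
        raise ValueError(f"baseline window {early_window} outside curve cycles")
    vals = curve.fluorescence[mask]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def call_cq(
    curve: AmplificationCurve,
    threshold: float = 30.0,
    baseline: float | None = None,
    early_window: tuple[int, int] = (3, 10),
) -> float | None:
    """Fractional cycle at which the curve crosses ``threshold``.

    Fluorescence is baseline-subtracted first (``baseline=None`` estimates it
    from ``early_window``; pass ``0.0`` for already-corrected curves).  The
    crossing is linearly interpolated between the flanking cycles.  Returns
    ``None``, with a logged reason, if the curve never crosses — such
    reactions are excluded downstream.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if baseline is None:
        baseline = estimate_baseline(curve, early_window)
    f = curve.fluorescence - baseline
    above = f >= threshold
    if not above.any():
        logger.warning(
            "reaction %s (%s/%s): no threshold crossing at %.3g RFU",
            curve.reaction_id, curve.gene, curve.sample, threshold,
        )
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.cycles[0])
    c0, c1 = curve.cycles[i - 1], curve.cycles[i]
    f0, f1 = f[i - 1], f[i]
    return float(c0 + (threshold - f0) / (f1 - f0) * (c1 - c0))


def _exponential_phase_mask(
    f: np.ndarray, baseline_sd: float, plateau_frac: float = 0.8
) -> np.ndarray:
    """Cycles usable for the log-linear fit: above baseline noise, below
    plateau onset, strictly positive."""
    fmax = f.max()
    lower = max(3.0 * baseline_sd, 0.0)
    return (f > lower) & (f > 0) & (f < plateau_frac * fmax)


def fit_efficiency(
    curve: AmplificationCurve,
    r2_min: float = 0.998,
    window_sizes: tuple[int, ...] = (5, 4, 3),
    baseline: float | None = None,
    early_window: tuple[int, int] = (3, 10),
) -> EfficiencyFit | None:
    """Window-of-linearity efficiency estimate for a single reaction.

    Slides windows of 5, then 4, then 3 consecutive cycles over the
    exponential phase; the first (largest) window size with any fit reaching
    ``r2 >= r2_min`` wins, ties broken by highest R².  Returns ``None`` when
    no window qualifies; the reaction is then excluded from its gene's mean.
    """
    if baseline is None:
        baseline, base_sd = _baseline_stats(curve, early_window)
    else:
        try:
            _, base_sd = _baseline_stats(curve, early_window)
        except ValueError:
            base_sd = 0.0
    f = curve.fluorescence - baseline
    mask = _exponential_phase_mask(f, base_sd)
    idx = np.flatnonzero(mask)
    if idx.size < min(window_sizes):
        return None

    cycles = curve.cycles
    best: tuple[float, int, int, float] | None = None  # (r2, start_idx, size, slope)
    for size in window_sizes:
        for s in range(len(idx) - size + 1):
            win = idx[s : s + size]
            # consecutive cycles only
            if cycles[win[-1]] - cycles[win[0]] != size - 1:
                continue
            y = np.log10(f[win])
            res = stats.linregress(cycles[win].astype(float), y)
            r2 = res.rvalue**2
            if r2 >= r2_min and (best is None or r2 > best[0]):
                best = (r2, int(win[0]), size, float(res.slope))
        if best is not None:
            break
    if best is None:
        return None
    r2, start, size, slope = best
    factor = 10.0**slope
    return EfficiencyFit(
        gene=curve.gene,
        reaction_id=curve.reaction_id,
        E=factor - 1.0,
        amplification_factor=factor,
        window=(int(cycles[start]), int(cycles[start + size - 1])),
        n_points=size,
        r2=float(r2),
        slope=slope,
    )


def summarize_efficiencies(
    fits: list[EfficiencyFit | None],
    genes: list[str] | None = None,
    warn_range: tuple[float, float] = EFFICIENCY_WARN_RANGE,
) -> pd.DataFrame:
    """Per-gene mean E ± SEM over accepted reaction fits.

    ``None`` entries (failed fits) are dropped.  ``genes`` forces a row for
    every expected gene; genes without a single accepted fit are reported
    with missing efficiency.  A mean outside ``warn_range`` (the span of
    acceptable assays) logs a warning but does not fail.
    """
    accepted = [f for f in fits if f is not None]
    by_gene: dict[str, list[float]] = {}
    for f in accepted:
        by_gene.setdefault(f.gene, []).append(f.E)
    if genes is None:
        genes = list(by_gene)
    rows = {}
    for g in genes:
        es = by_gene.get(g, [])
        if not es:
            logger.warning("gene %s: no accepted efficiency fits", g)
            rows[g] = {
                "E": math.nan,
                "sem": math.nan,
                "amplification_factor": math.nan,
                "n_reactions": 0,
            }
            continue
        mean = float(np.mean(es))
        sem = (
            float(np.std(es, ddof=1) / math.sqrt(len(es))) if len(es) > 1 else 0.0
        )
        if not warn_range[0] <= mean <= warn_range[1]:
            logger.warning(
                "gene %s: mean efficiency %.4f outside accepted span %s",
                g, mean, warn_range,
            )
        rows[g] = {
            "E": mean,
            "sem": sem,
            "amplification_factor": 1.0 + mean,
            "n_reactions": len(es),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out
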