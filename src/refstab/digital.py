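"""Digital (in-silico) expression-stability screen over read-count libraries.

Given a unigene × library matrix of read counts with whole-library totals,
the screen (i) filters unigenes by presence across libraries, (ii) computes
relative virtual expression folds ``m / (n · (M / N))`` against a reference
library, (iii) scores each unigene by the coefficient of variation (SD/MV)
of its normalized expression across libraries, and (iv) asks how each CV
changes when a library subset (e.g. the fruit series) is omitted — a
predominance of decreases indicates that the omitted tissue's transcriptome
differs enough that panels should be screened separately.

CVs are computed on per-library proportions (count/total); this equals the
CV of fold values, since folds are a common rescaling of the proportions,
but avoids any dependence on which library is the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountPanel",
    "present_filter",
    "virtual_expression",
    "digital_profile",
    "unigene_cv",
    "omission_analysis",
]


@dataclass(frozen=True)
class CountPanel:
    """Unigene × library read counts with whole-library totals.

    ``totals`` are whole-library read totals (not column sums of the
    retained unigenes) and must therefore be at least the column sums.
    ``panels`` annotates each library with a tissue panel label.
    """

    counts: pd.DataFrame
    totals: pd.Series
    panels: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValueError("counts must be integers")
        if list(self.totals.index) != list(c.columns):
            raise ValueError("totals must be indexed by the count columns")
        colsums = c.sum(axis=0)
        bad = self.totals.index[self.totals < colsums]
        if len(bad):
            raise ValueError(f"library totals below column sums: {list(bad)}")
        if list(self.panels.index) != list(c.columns):
            raise ValueError("panels must be indexed by the count columns")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_in_panel(self, panel: str) -> list[str]:
        return list(self.panels.index[self.panels == panel])

    def proportions(self) -> pd.DataFrame:
        """Per-library read proportions count/total."""
        return self.counts.div(self.totals, axis=1)


def present_filter(
    panel: CountPanel, mode: str = "min_calls", k: int = 7, r: int = 7
) -> pd.Index:
    """Unigenes retained by a presence criterion.

    ``min_calls``: detected (count >= 1) in at least ``k`` libraries.
    ``min_reads_all``: at least ``r`` reads in *every* library.
    Both phrasings of the screen are exposed; neither is privileged.
    """
    n_lib = len(panel.libraries)
    if mode == "min_calls":
        if not 1 <= k <= n_lib:
            raise ValueError(f"k={k} infeasible for {n_lib} libraries")
        keep = (panel.counts >= 1).sum(axis=1) >= k
    elif mode == "min_reads_all":
        if r < 1:
            raise ValueError("r must be >= 1")
        keep = (panel.counts >= r).all(axis=1)
    else:
        raise ValueError(f"unknown present-filter mode {mode!r}")
    return panel.counts.index[keep]


def virtual_expression(m: float, n: float, M: float, N: float) -> float:
    """Fold expression ``m / (n · (M / N))`` of a unigene between two
    libraries: m, n reads in the unigene; M, N total library reads."""
    if M <= 0 or N <= 0:
        raise ValueError("library totals must be > 0")
    if n <= 0:
        raise ValueError("reference count n must be > 0 (undefined fold)")
    return float(m / (n * (M / N)))


def digital_profile(
    panel: CountPanel,
    unigenes: Iterable[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-unigene fold profile relative to a reference library, plus
    MV/SD/CV of the normalized expression across all libraries.

    A zero count in the reference library leaves the unigene's folds
    undefined; it is flagged (NaN folds and CV) and logged.  Zeros in
    non-reference libraries simply give fold 0.
    """
    if reference is None:
        reference = panel.libraries[0]
    if reference not in panel.libraries:
        raise KeyError(f"unknown reference library {reference!r}")
    sub = panel.counts if unigenes is None else panel.counts.loc[list(unigenes)]
    props = sub.div(panel.totals, axis=1)
    ref_p = props[reference]
    undefined = ref_p == 0
    if undefined.any():
        logger.warning(
            "zero reads in reference library %s: folds undefined for %s",
            reference, list(sub.index[undefined]),
        )
    folds = props.div(ref_p.where(~undefined), axis=0)
    mv = props.mean(axis=1)
    sd = props.std(axis=1, ddof=1)
    out = folds.add_prefix("fold_")
    out["mv"] = mv
    out["sd"] = sd
    out["cv"] = (sd / mv).where(mv > 0)
    out.loc[undefined, "cv"] = np.nan
    out.index.name = "unigene"
    return out


def unigene_cv(
    panel: CountPanel, unigene: str, libraries: Sequence[str] | None = None
) -> float:
    """CV (SD/mean, SD with n−1) of one unigene's read proportions over the
    chosen libraries.  NaN, with a log entry, when the mean is zero."""
    libs = list(libraries) if libraries is not None else panel.libraries
    if len(libs) < 2:
        raise ValueError("CV needs at least 2 libraries")
    p = panel.counts.loc[unigene, libs] / panel.totals[libs]
    mv = p.mean()
    if mv == 0:
        logger.warning("unigene %s: zero mean over %s, CV undefined", unigene, libs)
        return float("nan")
    return float(p.std(ddof=1) / mv)


def omission_analysis(
    panel: CountPanel,
    retained: Iterable[str],
    omit: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """How each unigene's CV changes when ``omit`` libraries are dropped.

    ``delta_cv = CV(remaining libraries) − CV(all libraries)``, so a
    negative value means the unigene looks *more* stable without the
    omitted series.  The summary counts decreases/increases (exact zeros
    reported separately) and gives mean ± SEM of the change within each
    direction.

    ``omit`` may be library labels or a single panel label (e.g.
    ``["fruit"]`` expands to the fruit libraries).
    """
    omit_libs: list[str] = []
    for o in omit:
        if o in panel.libraries:
            omit_libs.append(o)
        elif o in set(panel.panels):
            omit_libs.extend(panel.libraries_in_panel(o))
        else:
            raise KeyError(f"{o!r} is neither a library nor a panel label")
    remaining = [l for l in panel.libraries if l not in omit_libs]
    if len(remaining) < 2:
        raise ValueError("omission must leave at least 2 libraries")

    rows = {}
    for u in retained:
        full = unigene_cv(panel, u)
        part = unigene_cv(panel, u, remaining)
        rows[u] = {"cv_all": full, "cv_omitted": part, "delta_cv": part - full}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "unigene"

    d = table["delta_cv"].dropna()
    dec, inc = d[d < 0], d[d > 0]

    def _mean_sem(x: pd.Series) -> tuple[float, float]:
        if len(x) == 0:
            return float("nan"), float("nan")
        sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(x.mean()), sem

    dec_mean, dec_sem = _mean_sem(dec)
    inc_mean, inc_sem = _mean_sem(inc)
    summary = {
        "n_unigenes": int(len(d)),
        "n_decrease": int(len(dec)),
        "n_increase": int(len(inc)),
        "n_unchanged": int((d == 0).sum()),
        "frac_decrease": float(len(dec) / len(d)) if len(d) else float("nan"),
        "decrease_mean": dec_mean,
        "decrease_sem": dec_sem,
        "increase_mean": inc_mean,
        "increase_sem": inc_sem,
        "omitted_libraries": omit_libs,
    }
    return table, summary
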