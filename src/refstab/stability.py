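"""Reference-gene expression stability: geNorm M values and qBase CVs.

The geNorm stability measure of gene *j* within a candidate panel is the
average pairwise variation

    M_j = mean_{k != j} SD_s[ log2( RQ_js / RQ_ks ) ]

where the standard deviation (n−1 denominator) is taken over samples.  A
lower M means more stable expression.  Because only log-*ratios* enter, M is
invariant both to rescaling a gene's RQ by a constant and to rescaling all
genes within one sample (sample loading), which is exactly why it isolates
biological instability.  Genes are ranked by iteratively recomputing M on
the retained panel and eliminating the least stable gene until two remain;
those two cannot be resolved further and jointly take the best rank.

The complementary qBase statistic is the coefficient of variation of each
reference gene's *normalized* relative quantities (its RQ divided by the
panel's geometric-mean normalization factor) across samples; the panel-level
figure is the arithmetic mean of the per-gene CVs.  Heterogeneous-panel
practice accepts references with M < 0.5 and CV < 0.25.

:class:`GeNormRanker` exposes the ranking as a scikit-learn estimator
(``fit`` on a samples × genes matrix of relative quantities); the
module-level functions are thin wrappers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantify import normalization_factor

logger = logging.getLogger(__name__)

__all__ = [
    "GeNormRanker",
    "genorm_m",
    "genorm_rank",
    "qbase_cv",
    "classify_acceptability",
    "compare_reference_sets",
    "ReferenceSetComparison",
]

#: geNorm's default stability cutoff; any retained-set M above it is flagged.
GENORM_DEFAULT_CUTOFF = 1.5


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.astype(float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples × genes matrix")
        df = pd.DataFrame(arr, columns=[f"g{i}" for i in range(arr.shape[1])])
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(df.values)):
        raise ValueError("RQ matrix must be finite")
    if (df.values <= 0).any():
        raise ValueError("RQ values must be strictly positive")
    return df


def genorm_m(rq: pd.DataFrame, genes: Iterable[str] | None = None) -> pd.Series:
    """Per-gene geNorm M over the given panel (default: all columns)."""
    df = _as_frame(rq)
    if genes is not None:
        df = df[list(genes)]
    if df.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 genes")
    logx = np.log2(df.values)
    G = logx.shape[1]
    V = np.zeros((G, G))
    for j, k in itertools.combinations(range(G), 2):
        sd = np.std(logx[:, j] - logx[:, k], ddof=1)
        V[j, k] = V[k, j] = sd
    m = V.sum(axis=1) / (G - 1)
    return pd.Series(m, index=df.columns, name="M")


class GeNormRanker(BaseEstimator):
    """geNorm stability ranking of candidate reference genes.

    Parameters
    ----------
    cutoff : float, default 1.5
        Flag threshold: any M computed on a retained set above this is
        logged (the algorithm's default heterogeneity alarm).

    Attributes
    ----------
    genes_ : list of str
    m_values_ : Series
        Full-panel M per gene (before any elimination).
    stepwise_m_ : Series
        Each gene's M at the point it was eliminated; the final pair shares
        the two-gene M.
    elimination_order_ : list of str
        Least stable first.
    final_pair_ : tuple of two gene labels (the most stable pair).
    final_m_ : float, the shared M of the final pair.
    ranking_ : DataFrame with columns ``m, rank, final_pair``
        Competition ranking: the final pair both take rank 1, the next gene
        rank 3, and so on.
    """

    def __init__(self, cutoff: float = GENORM_DEFAULT_CUTOFF):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        df = _as_frame(X)
        genes = list(df.columns)
        if len(genes) < 2:
            raise ValueError("geNorm needs at least 2 genes")
        self.genes_ = genes
        self.m_values_ = genorm_m(df)

        stepwise: dict[str, float] = {}
        order: list[str] = []
        retained = list(genes)
        if len(retained) == 2:
            logger.warning("only 2 genes: degenerate ranking, no elimination")
        while len(retained) > 2:
            m = genorm_m(df, retained)
            self._flag_cutoff(m)
            worst_m = m.max()
            # exact ties broken by gene-label order: later label goes first
            tied = sorted(m.index[m == worst_m])
            victim = tied[-1]
            if len(tied) > 1:
                logger.info(
                    "M tie at %.6g between %s; eliminating %s (label order)",
                    worst_m, tied, victim,
                )
            stepwise[victim] = float(worst_m)
            order.append(victim)
            retained.remove(victim)
        m_final = genorm_m(df, retained)
        self._flag_cutoff(m_final)
        final_pair = tuple(sorted(retained))
        final_m = float(m_final.iloc[0])
        for g in final_pair:
            stepwise[g] = final_m

        self.stepwise_m_ = pd.Series(stepwise).loc[genes].rename("M")
        self.elimination_order_ = order
        self.final_pair_ = final_pair
        self.final_m_ = final_m

        rank = {}
        for g in final_pair:
            rank[g] = 1
        for pos, g in enumerate(reversed(order)):
            rank[g] = 3 + pos
        self.ranking_ = pd.DataFrame(
            {
                "m": self.stepwise_m_,
                "rank": pd.Series(rank).loc[genes],
                "final_pair": [g in final_pair for g in genes],
            }
        ).sort_values("rank", kind="stable")
        self.ranking_.index.name = "gene"
        return self

    def _flag_cutoff(self, m: pd.Series) -> None:
        over = m[m > self.cutoff]
        if len(over):
            logger.warning(
                "M above geNorm cutoff %.3g: %s",
                self.cutoff,
                {g: round(v, 4) for g, v in over.items()},
            )


def genorm_rank(rq: pd.DataFrame, cutoff: float = GENORM_DEFAULT_CUTOFF) -> pd.DataFrame:
    """Elimination ranking; see :class:`GeNormRanker`.

    With exactly two genes the report is degenerate: both share rank 1.
    """
    return GeNormRanker(cutoff=cutoff).fit(rq).ranking_


def qbase_cv(
    rq: pd.DataFrame, ref_genes: Iterable[str] | None = None
) -> tuple[pd.Series, float]:
    """qBase coefficients of variation for a candidate reference set.

    The NF is the geometric mean over the *full* candidate set (each gene
    included in its own NF); per gene, CV = SD/mean of RQ/NF across samples
    (SD with n−1).  Returns the per-gene CVs and their arithmetic mean.
    A single-gene set self-normalizes to CV = 0.
    """
    df = _as_frame(rq)
    refs = list(ref_genes) if ref_genes is not None else list(df.columns)
    if not refs:
        raise ValueError("reference-gene set must be non-empty")
    nf = normalization_factor(df, refs).nf
    nrq = df[refs].div(nf, axis=0)
    cv = nrq.std(ddof=1) / nrq.mean()
    cv.name = "cv"
    return cv, float(cv.mean())


def classify_acceptability(
    stability: pd.DataFrame, m_max: float = 0.5, cv_max: float = 0.25
) -> pd.DataFrame:
    """Accept/reject calls at the heterogeneous-panel thresholds.

    A gene is accepted iff its M is strictly below ``m_max``; the attributes
    ``attrs['set_accepted']``, ``attrs['mean_m']`` and ``attrs['mean_cv']``
    summarize the whole set (accepted iff mean M < m_max and mean CV <
    cv_max).  Boundary values are rejected (strict inequality), which is
    logged once.
    """
    if "m" not in stability.columns:
        raise ValueError("stability frame needs an 'm' column")
    out = stability.copy()
    out["accepted"] = out["m"] < m_max
    if "cv" in out.columns:
        out["accepted"] &= out["cv"] < cv_max
    boundary = out.index[(out["m"] == m_max)]
    if len(boundary):
        logger.info("M exactly at threshold %.3g rejected (strict <): %s",
                    m_max, list(boundary))
    mean_m = float(out["m"].mean())
    mean_cv = float(out["cv"].mean()) if "cv" in out.columns else float("nan")
    out.attrs["mean_m"] = mean_m
    out.attrs["mean_cv"] = mean_cv
    out.attrs["set_accepted"] = bool(
        mean_m < m_max and (np.isnan(mean_cv) or mean_cv < cv_max)
    )
    out.attrs["m_max"] = m_max
    out.attrs["cv_max"] = cv_max
    return out


@dataclass(frozen=True)
class ReferenceSetComparison:
    """Per-sample agreement between two normalization factors.

    ``folds`` are NF_A/NF_B rescaled to geometric mean 1, so systematic
    scale (which normalization cancels anyway) is ignored and only
    sample-to-sample disagreement remains.
    """

    folds: pd.Series
    mean_fold: float
    sem_fold: float
    max_abs_log2: float
    target_nrq_a: pd.DataFrame | None = None
    target_nrq_b: pd.DataFrame | None = None
    target_peak_a: pd.Series | None = None
    target_peak_b: pd.Series | None = None
    peak_shifted: pd.Series | None = None


def compare_reference_sets(
    rq: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    targets: Sequence[str] | None = None,
    groups: pd.Series | None = None,
) -> ReferenceSetComparison:
    """Compare two reference-gene sets through their normalization factors.

    For each sample the fold NF_A/NF_B is computed and rescaled so the panel
    geometric mean is 1; the summary reports mean ± SEM and the maximum
    absolute log2 fold.  When ``targets`` (and ``groups``) are given, each
    target's NRQ profile under both sets is returned together with the
    group at which it peaks — a peak that moves between the two
    normalizations is the classic single-bad-reference artifact.
    """
    df = _as_frame(rq)
    nf_a = normalization_factor(df, set_a).nf
    nf_b = normalization_factor(df, set_b).nf
    folds = nf_a / nf_b
    folds = folds / np.exp(np.log(folds).mean())
    mean = float(folds.mean())
    sem = (
        float(folds.std(ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else 0.0
    )
    max_l2 = float(np.abs(np.log2(folds)).max())

    t_a = t_b = peak_a = peak_b = shifted = None
    if targets:
        nrq_a = df[list(targets)].div(nf_a, axis=0)
        nrq_b = df[list(targets)].div(nf_b, axis=0)
        t_a, t_b = nrq_a, nrq_b
        if groups is not None:
            ga = nrq_a.groupby(groups.loc[nrq_a.index]).mean()
            gb = nrq_b.groupby(groups.loc[nrq_b.index]).mean()
            peak_a = ga.idxmax()
            peak_b = gb.idxmax()
            shifted = peak_a != peak_b
    return ReferenceSetComparison(
        folds=folds,
        mean_fold=mean,
        sem_fold=sem,
        max_abs_log2=max_l2,
        target_nrq_a=t_a,
        target_nrq_b=t_b,
        target_peak_a=peak_a,
        target_peak_b=peak_b,
        peak_shifted=shifted,
    )
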