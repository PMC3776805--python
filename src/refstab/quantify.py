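"""Efficiency-corrected relative quantification.

Implements the qBase-style quantification chain:

1. collapse technical replicates to a mean Cq (± SD/SE) per (sample, gene);
2. transform Cq to relative quantities ``RQ = (1 + E)**(Cq_cal - Cq)`` using
   each gene's amplification efficiency and the lowest-Cq sample as
   calibrator (so 0 < RQ <= 1, with RQ = 1 at the calibrator);
3. build sample-specific normalization factors as the geometric mean of the
   reference genes' RQs, with delta-method error propagation;
4. divide a target gene's RQs by the NF and rescale so a chosen group
   averages 1 (normalized relative quantities, NRQ);
5. single-reference, efficiency-corrected fold ratios between two sample
   groups (the Pfaffl model).

Standard errors propagate in quadrature on the relative (log) scale
throughout: SE(RQ) = RQ·ln(1+E)·SE(Cq); SE(NF)/NF = (1/f)·sqrt(Σ(SE/RQ)²);
SE(NRQ)/NRQ = sqrt((SE(RQ)/RQ)² + (SE(NF)/NF)²).

`RelativeQuantifier` wraps steps 1–2 as a scikit-learn style transformer:
``fit`` learns per-gene calibrator Cqs from a tidy replicate table and
``transform`` maps Cq data to the samples × genes RQ matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_replicates",
    "cq_to_rq",
    "normalization_factor",
    "normalized_rq",
    "pfaffl_ratio",
    "RQResult",
    "NFResult",
    "NRQResult",
    "RelativeQuantifier",
]


def _efficiency_series(efficiencies) -> pd.Series:
    if isinstance(efficiencies, pd.DataFrame):
        return efficiencies["E"].astype(float)
    return pd.Series(dict(efficiencies), dtype=float)


def collapse_replicates(data: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (sample, gene) with SD and SE over technical replicates.

    SD uses the n−1 denominator.  A singleton replicate yields SD = SE = 0
    with a logged warning.  Rows with missing Cq are dropped; a (sample,
    gene) pair left with no valid replicate is recorded as missing and
    logged — downstream matrix operations require completeness.
    """
    required = {"sample", "gene", "cq"}
    if not required.issubset(data.columns):
        raise ValueError(f"need columns {sorted(required)}")
    d = data.copy()
    if "group" not in d.columns:
        d["group"] = "all"
    n_missing = d["cq"].isna().sum()
    if n_missing:
        logger.warning("dropping %d replicate rows with missing Cq", n_missing)
        d = d.dropna(subset=["cq"])

    grouped = d.groupby(["sample", "group", "gene"], sort=True)["cq"]
    out = grouped.agg(cq_mean="mean", cq_sd="std", n="count").reset_index()
    singletons = out["n"] == 1
    if singletons.any():
        pairs = out.loc[singletons, ["sample", "gene"]].itertuples(index=False)
        logger.warning(
            "singleton replicates (SE set to 0): %s",
            [f"{s}/{g}" for s, g in pairs],
        )
    out["cq_sd"] = out["cq_sd"].fillna(0.0)
    out["cq_se"] = out["cq_sd"] / np.sqrt(out["n"])
    return out


@dataclass(frozen=True)
class RQResult:
    """Efficiency-corrected relative quantities, samples × genes."""

    rq: pd.DataFrame
    se: pd.DataFrame
    calibrators: pd.Series      # gene -> calibrator sample
    groups: pd.Series           # sample -> group label


def cq_to_rq(mean_cq: pd.DataFrame, efficiencies) -> RQResult:
    """Transform collapsed Cq values into relative quantities.

    Parameters
    ----------
    mean_cq : DataFrame
        Output of :func:`collapse_replicates` (columns ``sample, group,
        gene, cq_mean, cq_se``).
    efficiencies : mapping or DataFrame
        Per-gene efficiency E (DataFrame must carry an ``E`` column, as
        written by :func:`refstab.amplification.summarize_efficiencies`).

    The calibrator per gene is the sample with the lowest mean Cq, ties
    broken by lexicographic sample order.  Samples missing any gene are
    dropped with a logged list (stability statistics need a complete grid).
    """
    eff = _efficiency_series(efficiencies)
    cq = mean_cq.pivot(index="sample", columns="gene", values="cq_mean").sort_index()
    cq = cq.sort_index(axis=1)
    se = (
        mean_cq.pivot(index="sample", columns="gene", values="cq_se")
        .reindex(index=cq.index, columns=cq.columns)
        .fillna(0.0)
    )
    missing_eff = [g for g in cq.columns if g not in eff.index or pd.isna(eff[g])]
    if missing_eff:
        raise ValueError(f"missing efficiency for genes: {missing_eff}")
    bad_eff = eff[cq.columns][eff[cq.columns] <= 0]
    if len(bad_eff):
        raise ValueError(f"non-positive efficiency for genes: {list(bad_eff.index)}")

    incomplete = cq.index[cq.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping samples with missing genes: %s", list(incomplete)
        )
        cq = cq.drop(index=incomplete)
        se = se.drop(index=incomplete)
    if cq.empty:
        raise ValueError("no complete samples left")

    groups = (
        mean_cq.drop_duplicates("sample").set_index("sample")["group"].loc[cq.index]
    )
    cal = cq.idxmin(axis=0)  # index sorted lexicographically -> ties by label
    factors = 1.0 + eff[cq.columns]
    delta = cq.min(axis=0) - cq  # Cq_cal - Cq_s, per gene column
    rq = pd.DataFrame(
        np.power(factors.values[None, :], delta.values),
        index=cq.index,
        columns=cq.columns,
    )
    rq_se = rq * np.log(factors.values)[None, :] * se.values
    return RQResult(rq=rq, se=rq_se, calibrators=cal, groups=groups)


@dataclass(frozen=True)
class NFResult:
    """Per-sample normalization factor (geometric mean of reference RQs)."""

    nf: pd.Series
    se: pd.Series
    ref_genes: tuple[str, ...]


def normalization_factor(
    rq: pd.DataFrame | RQResult,
    ref_genes: Iterable[str],
    rq_se: pd.DataFrame | None = None,
) -> NFResult:
    """Geometric-mean normalization factor over a reference-gene set.

    ``NF_s = (prod RQ_gs)**(1/f)``;
    ``SE(NF) = NF · (1/f) · sqrt(Σ (SE(RQ)/RQ)²)``.
    With a single reference gene this is the identity on that gene's RQ.
    """
    if isinstance(rq, RQResult):
        rq_se = rq.se if rq_se is None else rq_se
        rq = rq.rq
    refs = list(ref_genes)
    if not refs:
        raise ValueError("reference-gene set must be non-empty")
    missing = [g for g in refs if g not in rq.columns]
    if missing:
        raise KeyError(f"reference genes absent from RQ matrix: {missing}")
    sub = rq[refs]
    if (sub <= 0).any().any():
        raise ValueError("RQ values must be > 0")
    f = len(refs)
    nf = np.exp(np.log(sub).mean(axis=1))
    if rq_se is not None:
        rel = (rq_se[refs] / sub) ** 2
        se = nf * np.sqrt(rel.sum(axis=1)) / f
    else:
        se = pd.Series(0.0, index=nf.index)
    nf.name, se.name = "nf", "nf_se"
    return NFResult(nf=nf, se=se, ref_genes=tuple(refs))


@dataclass(frozen=True)
class NRQResult:
    """Normalized relative quantities of one target gene."""

    nrq: pd.Series
    se: pd.Series
    target: str
    rescale_group: str


def normalized_rq(
    rq: pd.DataFrame | RQResult,
    target: str,
    nf: NFResult,
    groups: pd.Series | None = None,
    rescale_group: str | None = None,
    rq_se: pd.DataFrame | None = None,
) -> NRQResult:
    """Target RQ divided by NF, rescaled so ``rescale_group`` averages 1.

    The rescaling constant (the group's mean NRQ) is treated as exact, so
    relative errors are unchanged by the rescale step.
    """
    if isinstance(rq, RQResult):
        rq_se = rq.se if rq_se is None else rq_se
        groups = rq.groups if groups is None else groups
        rq = rq.rq
    if target not in rq.columns:
        raise KeyError(f"target gene {target!r} absent from RQ matrix")
    t = rq[target]
    t, nfv = t.align(nf.nf, join="inner")
    if len(t) != len(rq.index):
        raise ValueError("samples of target RQ and NF do not align")
    raw = t / nfv
    if rescale_group is not None:
        if groups is None:
            raise ValueError("rescale_group given but no group labels")
        in_group = groups.loc[raw.index] == rescale_group
        if not in_group.any():
            raise ValueError(f"rescale group {rescale_group!r} has no samples")
        raw = raw / raw[in_group].mean()
    else:
        rescale_group = ""
    rel = pd.Series(0.0, index=raw.index)
    if rq_se is not None:
        rel = rel.add((rq_se[target].loc[raw.index] / t) ** 2, fill_value=0.0)
    rel = rel.add((nf.se.loc[raw.index] / nfv) ** 2, fill_value=0.0)
    se = raw * np.sqrt(rel)
    raw.name, se.name = "nrq", "nrq_se"
    return NRQResult(nrq=raw, se=se, target=target, rescale_group=rescale_group)


def pfaffl_ratio(
    mean_cq: pd.DataFrame,
    target: str,
    reference: str,
    sample_group: str,
    calibrator_group: str,
    efficiencies,
) -> float:
    """Single-reference, efficiency-corrected fold change between groups.

    ``ratio = (1+E_t)**(Cq_t,cal − Cq_t,sample) / (1+E_r)**(Cq_r,cal −
    Cq_r,sample)`` on group-mean Cq values.  At E = 1 for both assays this
    reduces to the classical 2^ΔΔCq.
    """
    eff = _efficiency_series(efficiencies)
    for g in (target, reference):
        if g not in eff.index:
            raise KeyError(f"no efficiency for gene {g!r}")

    def group_mean(gene: str, group: str) -> float:
        sel = mean_cq[(mean_cq["gene"] == gene) & (mean_cq["group"] == group)]
        if sel.empty:
            raise ValueError(f"no Cq data for gene {gene!r} in group {group!r}")
        return float(sel["cq_mean"].mean())

    d_t = group_mean(target, calibrator_group) - group_mean(target, sample_group)
    d_r = group_mean(reference, calibrator_group) - group_mean(reference, sample_group)
    return float(
        (1.0 + eff[target]) ** d_t / (1.0 + eff[reference]) ** d_r
    )


class RelativeQuantifier(TransformerMixin, BaseEstimator):
    """Tidy Cq table → efficiency-corrected RQ matrix (samples × genes).

    scikit-learn style transformer.  ``fit`` collapses technical replicates
    and learns, per gene, the calibrator sample and its mean Cq;
    ``transform`` converts (the same or new) Cq data into relative
    quantities against those fitted calibrators.

    Parameters
    ----------
    efficiencies : mapping or DataFrame
        Per-gene amplification efficiency E.

    Attributes
    ----------
    calibrators_ : Series, gene -> calibrator sample label
    calibrator_cq_ : Series, gene -> calibrator mean Cq
    rq_ : DataFrame, the fitted data's RQ matrix
    rq_se_ : DataFrame, delta-method standard errors of ``rq_``
    groups_ : Series, sample -> group label
    """

    def __init__(self, efficiencies=None):
        self.efficiencies = efficiencies

    def fit(self, X: pd.DataFrame, y=None):
        if self.efficiencies is None:
            raise ValueError("efficiencies must be provided")
        mean_cq = collapse_replicates(X)
        res = cq_to_rq(mean_cq, self.efficiencies)
        self.calibrators_ = res.calibrators
        cq = mean_cq.pivot(index="sample", columns="gene", values="cq_mean")
        self.calibrator_cq_ = pd.Series(
            {g: cq.loc[res.calibrators[g], g] for g in res.calibrators.index}
        )
        self.rq_ = res.rq
        self.rq_se_ = res.se
        self.groups_ = res.groups
        self.result_ = res
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "calibrator_cq_"):
            raise ValueError("RelativeQuantifier is not fitted")
        eff = _efficiency_series(self.efficiencies)
        mean_cq = collapse_replicates(X)
        cq = mean_cq.pivot(index="sample", columns="gene", values="cq_mean")
        genes = [g for g in cq.columns if g in self.calibrator_cq_.index]
        cq = cq[genes].sort_index().sort_index(axis=1)
        delta = self.calibrator_cq_[cq.columns] - cq
        factors = 1.0 + eff[cq.columns]
        return pd.DataFrame(
            np.power(factors.values[None, :], delta.values),
            index=cq.index,
            columns=cq.columns,
        )
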