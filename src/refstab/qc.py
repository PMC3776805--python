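"""Sample-level RNA/cDNA quality gates.

Two groups of checks run on data the quantification pipeline already sees:

* **3′:5′ amplification ratio** — two amplicons from the 3′ and 5′ ends of a
  long transcript are quantified by qPCR; with oligo-dT-primed cDNA,
  incomplete reverse transcription depletes the 5′ amplicon, so
  ``ratio = factor**(Cq_5 − Cq_3)`` (comparative-Cq, factor 2 by default)
  rises above 1 as integrity degrades.  Ratios above 4.43 fail the gate.
* **Spectrophotometric purity** — A260/A280 within a panel-specific band
  (1.9–2.1 for floral buds and leaves, 1.75–2.1 for fruits, inclusive) and
  A260/A230 strictly above 2.0.

All gates are pure functions; a missing Cq fails closed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["three_five_ratio", "integrity_gate", "purity_gate", "evaluate_qc"]

#: 3':5' ratio above which RNA quality is deemed inadequate.
INTEGRITY_MAX_RATIO = 4.43

#: Inclusive A260/A280 bounds per tissue panel; leaves use the bud band.
A260_280_BOUNDS = {
    "bud": (1.9, 2.1),
    "fruit": (1.75, 2.1),
    "leaf": (1.9, 2.1),
}

A260_230_MIN = 2.0  # strict >


def three_five_ratio(
    cq_5: float, cq_3: float, amplification_factor: float = 2.0
) -> float:
    """Comparative-Cq 3′:5′ abundance ratio, ``factor**(cq_5 − cq_3)``.

    Ratio > 1 means the 3′ amplicon is more abundant (oligo-dT priming bias
    toward the 3′ end).  ``amplification_factor`` defaults to the classical
    perfect doubling; pass ``1 + E`` to use a measured efficiency.
    """
    if not (math.isfinite(cq_5) and math.isfinite(cq_3)):
        raise ValueError("both Cq values must be finite")
    if amplification_factor <= 1.0:
        raise ValueError("amplification_factor must be > 1")
    return float(amplification_factor ** (cq_5 - cq_3))


def integrity_gate(ratio: float, max_ratio: float = INTEGRITY_MAX_RATIO) -> bool:
    """True (pass) unless the 3′:5′ ratio strictly exceeds ``max_ratio``."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return False  # fail closed
    return not ratio > max_ratio


def purity_gate(
    a260_280: float, a260_230: float, panel: str
) -> tuple[bool, bool]:
    """(pass_260_280, pass_260_230) for one sample.

    A260/A280 bounds are inclusive and panel specific; A260/A230 must be
    strictly greater than 2.0.
    """
    if panel not in A260_280_BOUNDS:
        raise ValueError(f"unknown panel {panel!r}; expected {sorted(A260_280_BOUNDS)}")
    if a260_280 < 0 or a260_230 < 0:
        raise ValueError("absorbance ratios must be >= 0")
    lo, hi = A260_280_BOUNDS[panel]
    return (lo <= a260_280 <= hi, a260_230 > A260_230_MIN)


def evaluate_qc(records: pd.DataFrame, amplification_factor: float = 2.0,
                max_ratio: float = INTEGRITY_MAX_RATIO) -> pd.DataFrame:
    """Run all gates over a QC table.

    Expects columns ``sample, cq_5prime, cq_3prime, a260_280, a260_230,
    panel``; returns the table with ``ratio_3to5`` and per-gate pass flags
    plus an overall ``pass_all``.
    """
    req = {"sample", "cq_5prime", "cq_3prime", "a260_280", "a260_230", "panel"}
    if not req.issubset(records.columns):
        raise ValueError(f"need columns {sorted(req)}")
    out = records.copy()
    ratios = []
    for _, row in out.iterrows():
        c5, c3 = row["cq_5prime"], row["cq_3prime"]
        if pd.isna(c5) or pd.isna(c3):
            logger.warning("sample %s: missing Cq, integrity gate fails closed",
                           row["sample"])
            ratios.append(float("nan"))
        else:
            ratios.append(three_five_ratio(c5, c3, amplification_factor))
    out["ratio_3to5"] = ratios
    out["pass_integrity"] = [integrity_gate(r, max_ratio) for r in out["ratio_3to5"]]
    flags = [
        purity_gate(r["a260_280"], r["a260_230"], r["panel"])
        for _, r in out.iterrows()
    ]
    out["pass_260_280"] = [f[0] for f in flags]
    out["pass_260_230"] = [f[1] for f in flags]
    out["pass_all"] = (
        out["pass_integrity"] & out["pass_260_280"] & out["pass_260_230"]
    )
    return out
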