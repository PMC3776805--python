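"""Table readers/writers and run configuration.

All on-disk formats are plain text: long-format CSV for Cq data
(``sample,group,gene,replicate,cq``), CSV for curves
(``reaction,gene,sample,cycle,fluorescence``), TSV for count matrices plus a
library-metadata TSV (``library,panel,total_reads``).  Decimal output uses
12 significant digits so a write/read round trip is lossless well below
1e-9.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .amplification import AmplificationCurve
from .digital import CountPanel

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_cq_table",
    "write_cq_table",
    "read_efficiency_table",
    "read_count_table",
    "write_count_table",
    "read_curves",
    "write_curves",
    "write_table",
]

FLOAT_FMT = "%.12g"
CQ_RANGE = (0.0, 45.0)


@dataclass
class RunConfig:
    """Every named analysis constant in one place.

    Defaults are the validated-workflow values: 30 RFU threshold for Cq
    calling, R² ≥ 0.998 for the efficiency window, M < 0.5 / CV < 0.25
    acceptability, geNorm alarm cutoff 1.5, 3′:5′ integrity limit 4.43,
    present-filter k = r = 7.
    """

    rfu_threshold: float = 30.0
    r2_min: float = 0.998
    m_max: float = 0.5
    cv_max: float = 0.25
    genorm_cutoff: float = 1.5
    integrity_max: float = 4.43
    present_mode: str = "min_calls"
    present_k: int = 7
    present_r: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rfu_threshold", "r2_min", "m_max", "cv_max",
                     "genorm_cutoff", "integrity_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def log(self) -> None:
        logger.info("run configuration: %s", asdict(self))


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Cq CSV.

    Duplicate (sample, gene, replicate) rows are an error naming the
    offending line numbers.  Non-numeric Cq entries (e.g. ``ND``) are
    flagged missing (NaN) rather than parsed as zero; out-of-range Cq
    values warn.
    """
    df = pd.read_csv(path, dtype={"sample": str, "group": str, "gene": str})
    required = ["sample", "group", "gene", "replicate", "cq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    bad = df.index[cq.isna() & df["cq"].notna()]
    if len(bad):
        logger.warning(
            "%s: non-numeric Cq flagged missing at lines %s",
            path, [int(i) + 2 for i in bad],  # +2: header + 1-based
        )
    df["cq"] = cq
    dup = df.duplicated(subset=["sample", "gene", "replicate"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ValueError(
            f"{path}: duplicate (sample, gene, replicate) rows at lines {lines}"
        )
    out_of_range = df["cq"].notna() & (
        (df["cq"] <= CQ_RANGE[0]) | (df["cq"] >= CQ_RANGE[1])
    )
    if out_of_range.any():
        logger.warning(
            "%s: %d Cq values outside (0, 45)", path, int(out_of_range.sum())
        )
    return df[required]


def write_cq_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_efficiency_table(path: str | Path) -> pd.DataFrame:
    """Per-gene efficiency CSV with columns ``gene,E`` (extras kept)."""
    df = pd.read_csv(path)
    if "gene" not in df.columns or "E" not in df.columns:
        raise ValueError(f"{path}: need columns gene,E")
    df = df.set_index("gene")
    if (df["E"] <= 0).any():
        raise ValueError(f"{path}: efficiencies must be > 0")
    return df


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def write_curves(curves: list[AmplificationCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for cyc, f in zip(c.cycles, c.fluorescence):
            rows.append(
                {"reaction": c.reaction_id, "gene": c.gene, "sample": c.sample,
                 "cycle": int(cyc), "fluorescence": f}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_curves(path: str | Path) -> list[AmplificationCurve]:
    df = pd.read_csv(path, dtype={"reaction": str, "gene": str, "sample": str})
    required = {"reaction", "cycle", "fluorescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    for col in ("gene", "sample"):
        if col not in df.columns:
            df[col] = ""
    curves = []
    for (rid, gene, sample), grp in df.groupby(
        ["reaction", "gene", "sample"], sort=True
    ):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                reaction_id=str(rid), gene=str(gene), sample=str(sample),
                cycles=grp["cycle"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Count panels
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, meta_path: str | Path) -> CountPanel:
    """Unigene × library TSV plus library metadata TSV.

    Totals come from the metadata (whole-library totals, not column sums);
    a matrix library absent from the metadata, a negative count, or a total
    below the matrix column sum is an error.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    req = {"library", "panel", "total_reads"}
    if not req.issubset(meta.columns):
        raise ValueError(f"{meta_path}: need columns {sorted(req)}")
    meta = meta.set_index("library")
    unknown = [l for l in counts.columns if l not in meta.index]
    if unknown:
        raise ValueError(f"libraries missing from metadata: {unknown}")
    if (counts.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    meta = meta.loc[counts.columns]
    return CountPanel(
        counts=counts,
        totals=meta["total_reads"].astype(int),
        panels=meta["panel"],
    )


def write_count_table(panel: CountPanel, path: str | Path,
                      meta_path: str | Path) -> None:
    panel.counts.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"library": panel.libraries,
         "panel": panel.panels.values,
         "total_reads": panel.totals.values}
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True,
                sep: str = ",") -> None:
    """Generic result writer at the package's fixed float precision."""
    df.to_csv(path, index=index, sep=sep, float_format=FLOAT_FMT)
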