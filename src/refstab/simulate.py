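"""Synthetic qPCR and sequencing data with known ground truth.

Three generators mirror the three data streams of a reference-gene
validation study:

* :func:`simulate_cq` — replicate-level quantification cycles for a panel of
  candidate reference genes over grouped samples (developmental stages ×
  genotypes), with per-sample loading variation, per-gene biological noise,
  optional regulation trends, and technical replicate noise.
* :func:`simulate_curves` — sigmoidal real-time amplification curves with a
  known per-cycle efficiency, baseline and plateau.
* :func:`simulate_counts` — read-count libraries (e.g. 454 sequencing) with
  stable and regulated unigenes, for the digital expression screen.

Every generator is deterministic under a fixed seed and returns the ground
truth (loading factors, true stabilities, fold profiles, multipliers)
alongside the data, so downstream estimators can be tested for recovery.

Noise model for Cq data
-----------------------
Biological and loading variation are drawn on the log2-expression scale and
converted to cycles through ``log2(1 + E)``, so that at perfect efficiency
(E = 1) one expression doubling corresponds to exactly one cycle.  Replicate
(technical) noise is additive Gaussian directly on the Cq scale::

    x_ig   = log2(trend_g at group of i) + N(0, bio_sd_g) + loading_i
    Cq_igr = base_cq_g - x_ig / log2(1 + E_g) + N(0, tech_sd)

with ``loading_i ~ N(0, loading_sd)`` shared by every gene in sample ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSimSpec",
    "CqSimSpec",
    "CurveSimSpec",
    "UnigeneSimSpec",
    "CountSimSpec",
    "CqGroundTruth",
    "simulate_cq",
    "simulate_curves",
    "simulate_counts",
    "example_cq_spec",
    "example_count_spec",
]


# ---------------------------------------------------------------------------
# Cq panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSimSpec:
    """One gene of a simulated qPCR panel.

    Parameters
    ----------
    gene_id : str
        Gene label.
    base_cq : float
        Expression level at the calibrator, expressed as the noise-free Cq a
        sample with zero log2 expression would show.  Must lie in (5, 40).
    efficiency : float
        Amplification efficiency E in (0, 1.2]; the amplification factor per
        cycle is ``1 + E``.
    bio_sd : float
        Per-sample biological log2-expression noise SD.  This is the gene's
        *true instability*: a perfectly stable reference has ``bio_sd = 0``.
    trend_fold : float
        Total multiplicative fold change across the ordered groups; the
        profile is geometric, ``fold ** (k / (G - 1))`` for group ``k`` of
        ``G``.  ``1`` means unregulated.
    group_profile : tuple of float, optional
        Explicit per-group fold vector (overrides ``trend_fold``); lets a
        gene peak mid-series instead of following a monotone trend.
    """

    gene_id: str
    base_cq: float = 25.0
    efficiency: float = 0.95
    bio_sd: float = 0.1
    trend_fold: float = 1.0
    group_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 5.0 < self.base_cq < 40.0:
            raise ValueError(f"{self.gene_id}: base_cq must lie in (5, 40)")
        if not 0.0 < self.efficiency <= 1.2:
            raise ValueError(f"{self.gene_id}: efficiency must lie in (0, 1.2]")
        if self.bio_sd < 0:
            raise ValueError(f"{self.gene_id}: bio_sd must be >= 0")
        if self.trend_fold <= 0:
            raise ValueError(f"{self.gene_id}: trend_fold must be > 0")
        if self.group_profile is not None and any(f <= 0 for f in self.group_profile):
            raise ValueError(f"{self.gene_id}: group_profile folds must be > 0")

    def trend_log2(self, n_groups: int) -> np.ndarray:
        """Noise-free log2 expression per ordered group."""
        if self.group_profile is not None:
            if len(self.group_profile) != n_groups:
                raise ValueError(
                    f"{self.gene_id}: group_profile has {len(self.group_profile)} "
                    f"entries for {n_groups} groups"
                )
            return np.log2(np.asarray(self.group_profile, dtype=float))
        if n_groups == 1:
            return np.zeros(1)
        k = np.arange(n_groups, dtype=float)
        return k / (n_groups - 1) * np.log2(self.trend_fold)

    @property
    def is_unregulated(self) -> bool:
        if self.group_profile is not None:
            return len(set(self.group_profile)) == 1
        return self.trend_fold == 1.0


@dataclass(frozen=True)
class CqSimSpec:
    """A simulated Cq experiment: grouped samples × a gene panel.

    ``groups`` gives one group label per sample, in sample order; group
    *levels* are ordered by first appearance (they are the developmental
    axis along which regulated genes trend).
    """

    groups: tuple[str, ...]
    genes: tuple[GeneSimSpec, ...]
    loading_sd: float = 0.25
    tech_sd: float = 0.15
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not self.genes:
            raise ValueError("need at least 1 gene")
        if self.loading_sd < 0 or self.tech_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.groups)

    @property
    def group_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)


@dataclass(frozen=True)
class CqGroundTruth:
    """Everything the Cq generator knew: the recovery oracle."""

    loadings: pd.Series                # per sample, log2 units
    log2_signal: pd.DataFrame          # samples × genes: trend + biological noise
    trend_log2: pd.DataFrame           # group levels × genes, noise free
    bio_sd: pd.Series                  # per gene true instability
    efficiency: pd.Series              # per gene E
    base_cq: pd.Series
    unregulated: pd.Series             # per gene bool (flat trend)

    @property
    def stable_genes(self) -> list[str]:
        return list(self.unregulated.index[self.unregulated])


def simulate_cq(spec: CqSimSpec) -> tuple[pd.DataFrame, CqGroundTruth]:
    """Draw a replicate-level Cq dataset plus its ground truth.

    Returns
    -------
    data : DataFrame
        Tidy table with columns ``sample, group, gene, replicate, cq``.
    truth : CqGroundTruth
    """
    rng = np.random.default_rng(spec.seed)
    n, reps = spec.n_samples, spec.n_replicates
    levels = spec.group_levels
    group_idx = np.array([levels.index(g) for g in spec.groups])
    samples = [f"S{i + 1:02d}" for i in range(n)]

    loadings = rng.normal(0.0, spec.loading_sd, size=n)

    rows: list[dict] = []
    signal = {}
    trends = {}
    for gene in spec.genes:
        trend = gene.trend_log2(len(levels))
        bio = rng.normal(0.0, gene.bio_sd, size=n)
        x_sig = trend[group_idx] + bio
        x = x_sig + loadings
        scale = np.log2(1.0 + gene.efficiency)
        cq0 = gene.base_cq - x / scale
        tech = rng.normal(0.0, spec.tech_sd, size=(n, reps))
        for i, s in enumerate(samples):
            for r in range(reps):
                rows.append(
                    {
                        "sample": s,
                        "group": spec.groups[i],
                        "gene": gene.gene_id,
                        "replicate": r + 1,
                        "cq": cq0[i] + tech[i, r],
                    }
                )
        signal[gene.gene_id] = x_sig
        trends[gene.gene_id] = trend

    data = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cq"])
    gene_ids = [g.gene_id for g in spec.genes]
    truth = CqGroundTruth(
        loadings=pd.Series(loadings, index=samples, name="loading"),
        log2_signal=pd.DataFrame(signal, index=samples),
        trend_log2=pd.DataFrame(trends, index=levels),
        bio_sd=pd.Series({g.gene_id: g.bio_sd for g in spec.genes}, name="bio_sd"),
        efficiency=pd.Series(
            {g.gene_id: g.efficiency for g in spec.genes}, name="efficiency"
        ),
        base_cq=pd.Series({g.gene_id: g.base_cq for g in spec.genes}, name="base_cq"),
        unregulated=pd.Series(
            {g.gene_id: g.is_unregulated for g in spec.genes}, name="unregulated"
        ).loc[gene_ids],
    )
    return data, truth


def example_cq_spec(
    seed: int = 0,
    stages: Sequence[str] = ("green", "white", "pink", "blue"),
    n_bio_reps: int = 4,
) -> CqSimSpec:
    """A 13-gene demonstration panel over four developmental stages.

    Eleven genes of graded stability (bio_sd 0.05–0.4) plus two regulated
    genes: one trending 4-fold across the series and one with a mid-series
    peak, mimicking the behaviour of classical housekeeping genes that turn
    out to be regulated during fruit ripening.
    """
    groups = tuple(s for s in stages for _ in range(n_bio_reps))
    genes = []
    sds = np.linspace(0.05, 0.4, 11)
    for i, sd in enumerate(sds):
        genes.append(
            GeneSimSpec(
                gene_id=f"REF{i + 1:02d}",
                base_cq=22.0 + i * 0.8,
                efficiency=0.88 + 0.02 * (i % 6),
                bio_sd=round(float(sd), 3),
            )
        )
    genes.append(
        GeneSimSpec("TREND4", base_cq=24.0, efficiency=0.95, bio_sd=0.05, trend_fold=4.0)
    )
    genes.append(
        GeneSimSpec(
            "PEAKMID",
            base_cq=23.0,
            efficiency=1.0,
            bio_sd=0.05,
            group_profile=tuple([1.0, 1.0, 4.0, 1.0][: len(stages)])
            if len(stages) == 4
            else None,
            trend_fold=1.0,
        )
    )
    return CqSimSpec(groups=groups, genes=tuple(genes), seed=seed)


# ---------------------------------------------------------------------------
# Amplification curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSimSpec:
    """Sigmoidal amplification-curve generator settings.

    ``start_fluorescence`` is the fluorescence-equivalent template amount at
    cycle 0; the noise-free curve is::

        F_c = baseline + min(start * (1 + E)**c, plateau - baseline)

    with Gaussian read noise added and a hard clip at ``plateau``.
    """

    efficiency: float = 0.95
    start_fluorescence: float = 0.001
    baseline: float = 50.0
    plateau: float = 1200.0
    noise_sd: float = 1.5
    n_cycles: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.2:
            raise ValueError("efficiency must lie in (0, 1.2]")
        if self.baseline >= self.plateau:
            raise ValueError("baseline must be < plateau")
        if self.start_fluorescence <= 0:
            raise ValueError("start_fluorescence must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")


def simulate_curves(
    spec: CurveSimSpec,
    n_reactions: int = 1,
    gene: str = "gene",
    sample: str = "sample",
    cq_threshold: float | None = 30.0,
):
    """Draw ``n_reactions`` noisy amplification curves.

    Returns a list of :class:`refstab.amplification.AmplificationCurve`.
    Warns when the curve's dynamic range cannot cross ``cq_threshold`` (no
    Cq call would be possible).
    """
    from .amplification import AmplificationCurve  # local import: avoid cycle

    if cq_threshold is not None and spec.plateau - spec.baseline <= cq_threshold:
        logger.warning(
            "plateau - baseline = %.3g <= Cq threshold %.3g: curves cannot cross",
            spec.plateau - spec.baseline,
            cq_threshold,
        )
    rng = np.random.default_rng(spec.seed)
    cycles = np.arange(1, spec.n_cycles + 1)
    signal = np.minimum(
        spec.start_fluorescence * (1.0 + spec.efficiency) ** cycles,
        spec.plateau - spec.baseline,
    )
    curves = []
    for r in range(n_reactions):
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_cycles)
        f = np.minimum(spec.baseline + signal + noise, spec.plateau)
        curves.append(
            AmplificationCurve(
                reaction_id=f"r{r:03d}",
                gene=gene,
                sample=sample,
                cycles=cycles.copy(),
                fluorescence=f,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Read-count libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnigeneSimSpec:
    """One unigene: base proportion of library reads plus per-library fold
    multipliers (all 1 = stably expressed)."""

    unigene_id: str
    base_proportion: float
    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.base_proportion < 0:
            raise ValueError("base_proportion must be >= 0")
        if any(m < 0 for m in self.multipliers):
            raise ValueError("multipliers must be >= 0")

    @property
    def is_stable(self) -> bool:
        return all(m == 1.0 for m in self.multipliers)


_DEFAULT_LIBRARIES = (
    ("bud_0cu", "bud"),
    ("bud_397cu", "bud"),
    ("bud_789cu", "bud"),
    ("bud_1333cu", "bud"),
    ("fruit_green", "fruit"),
    ("fruit_white", "fruit"),
    ("fruit_pink", "fruit"),
    ("fruit_blue", "fruit"),
)


@dataclass(frozen=True)
class CountSimSpec:
    """Read-count library generator: Poisson sampling of unigene reads.

    ``reads_ul ~ Poisson(library_size_l * base_proportion_u * multiplier_ul)``.
    Default layout is 8 libraries: four flower-bud chill-unit stages and four
    fruit ripening stages.
    """

    unigenes: tuple[UnigeneSimSpec, ...]
    library_sizes: tuple[int, ...] = (100_000,) * 8
    library_labels: tuple[str, ...] | None = None
    library_panels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.library_sizes):
            raise ValueError("library_sizes must be >= 1")
        if not self.unigenes:
            raise ValueError("need at least one unigene")
        n = self.n_libraries
        for u in self.unigenes:
            if len(u.multipliers) != n:
                raise ValueError(
                    f"{u.unigene_id}: {len(u.multipliers)} multipliers for "
                    f"{n} libraries"
                )
        if self.library_labels is not None and len(self.library_labels) != n:
            raise ValueError("library_labels length mismatch")
        if self.library_panels is not None and len(self.library_panels) != n:
            raise ValueError("library_panels length mismatch")

    @property
    def n_libraries(self) -> int:
        return len(self.library_sizes)

    def labels_panels(self) -> tuple[list[str], list[str]]:
        if self.library_labels is not None:
            labels = list(self.library_labels)
            panels = list(self.library_panels or ["all"] * self.n_libraries)
        elif self.n_libraries == 8:
            labels = [l for l, _ in _DEFAULT_LIBRARIES]
            panels = [p for _, p in _DEFAULT_LIBRARIES]
        else:
            labels = [f"lib{i + 1}" for i in range(self.n_libraries)]
            panels = ["all"] * self.n_libraries
        return labels, panels


def simulate_counts(spec: CountSimSpec):
    """Draw a read-count panel and its ground truth.

    Returns
    -------
    panel : refstab.digital.CountPanel
    truth : DataFrame
        Per unigene: ``base_proportion``, ``multiplier_variance`` (population
        variance of the per-library multipliers) and ``stable``.
    """
    from .digital import CountPanel  # local import: avoid cycle

    rng = np.random.default_rng(spec.seed)
    labels, panels = spec.labels_panels()
    sizes = np.asarray(spec.library_sizes, dtype=float)

    counts = {}
    truth_rows = {}
    for u in spec.unigenes:
        mult = np.asarray(u.multipliers, dtype=float)
        lam = sizes * u.base_proportion * mult
        counts[u.unigene_id] = rng.poisson(lam)
        truth_rows[u.unigene_id] = {
            "base_proportion": u.base_proportion,
            "multiplier_variance": float(np.var(mult)),
            "stable": u.is_stable,
        }

    matrix = pd.DataFrame(counts, index=labels).T
    panel = CountPanel(
        counts=matrix,
        totals=pd.Series(spec.library_sizes, index=labels, dtype=int),
        panels=pd.Series(panels, index=labels),
    )
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "unigene"
    return panel, truth


def example_count_spec(
    seed: int = 0,
    n_stable: int = 40,
    n_regulated: int = 40,
    depth: int = 100_000,
) -> CountSimSpec:
    """8-library panel: stable unigenes plus unigenes up-regulated only in
    the fruit libraries, with graded fold changes (1.5–6×)."""
    unigenes = []
    for i in range(n_stable):
        unigenes.append(
            UnigeneSimSpec(f"stable{i + 1:03d}", 1e-3, (1.0,) * 8)
        )
    folds = np.linspace(1.5, 6.0, n_regulated)
    for i, f in enumerate(folds):
        unigenes.append(
            UnigeneSimSpec(
                f"fruitreg{i + 1:03d}",
                1e-3,
                (1.0, 1.0, 1.0, 1.0, float(f), float(f), float(f), float(f)),
            )
        )
    return CountSimSpec(
        unigenes=tuple(unigenes), library_sizes=(depth,) * 8, seed=seed
    )
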