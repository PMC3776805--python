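import numpy as np
import pandas as pd
import pytest

from refstab.simulate import CqSimSpec, GeneSimSpec, simulate_cq


def random_rq_matrix(rng: np.random.Generator, n_genes: int, n_samples: int) -> pd.DataFrame:
    """A strictly positive RQ-like matrix with log-normal variation."""
    logx = rng.normal(0.0, 1.0, size=(n_samples, n_genes))
    df = pd.DataFrame(2.0**logx, columns=[f"g{i}" for i in range(n_genes)])
    df.index = [f"s{i}" for i in range(n_samples)]
    return df


def brute_force_genorm_m(rq: pd.DataFrame) -> dict:
    """Independent geNorm oracle: explicit double loop, manual SD.

    For each ordered pair (j, k) the sample SD (n-1) of log2(RQ_j/RQ_k) is
    accumulated; M_j is the average over partners.  No shared code with the
    package implementation.
    """
    import math

    genes = list(rq.columns)
    n = len(rq.index)
    m = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                math.log(rq.loc[s, j] / rq.loc[s, k], 2) for s in rq.index
            ]
            mean = sum(ratios) / n
            var = sum((r - mean) ** 2 for r in ratios) / (n - 1)
            sds.append(math.sqrt(var))
        m[j] = sum(sds) / len(sds)
    return m


def brute_force_elimination(rq: pd.DataFrame) -> list:
    """Oracle elimination order: repeated argmax of the brute-force M."""
    retained = list(rq.columns)
    order = []
    while len(retained) > 2:
        m = brute_force_genorm_m(rq[retained])
        worst = max(m.values())
        tied = sorted(g for g, v in m.items() if v == worst)
        victim = tied[-1]
        order.append(victim)
        retained.remove(victim)
    return order


@pytest.fixture
def stable_panel_spec():
    """6 stable + 4 regulated genes over 16 samples (4 groups x 4)."""

    def make(seed: int) -> CqSimSpec:
        genes = [
            GeneSimSpec(f"stab{i}", base_cq=22.0 + i, efficiency=0.9 + 0.02 * i,
                        bio_sd=0.05)
            for i in range(6)
        ]
        genes += [
            GeneSimSpec(f"reg{i}", base_cq=24.0 + i, efficiency=0.95,
                        bio_sd=0.05, trend_fold=4.0)
            for i in range(4)
        ]
        groups = tuple(g for g in ("A", "B", "C", "D") for _ in range(4))
        return CqSimSpec(groups=groups, genes=tuple(genes), loading_sd=0.5,
                         tech_sd=0.1, n_replicates=2, seed=seed)

    return make


@pytest.fixture
def toy_cq_data():
    """Small noiseless dataset with a known fold profile 1:2:8:4."""
    genes = (
        GeneSimSpec("ref1", base_cq=22.0, efficiency=1.0, bio_sd=0.0),
        GeneSimSpec("ref2", base_cq=25.0, efficiency=0.9, bio_sd=0.0),
        GeneSimSpec("tgt", base_cq=27.0, efficiency=1.0, bio_sd=0.0,
                    group_profile=(1.0, 2.0, 8.0, 4.0)),
    )
    spec = CqSimSpec(
        groups=("G1",) * 2 + ("G2",) * 2 + ("G3",) * 2 + ("G4",) * 2,
        genes=genes, loading_sd=0.0, tech_sd=0.0, n_replicates=2, seed=0,
    )
    return simulate_cq(spec)
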