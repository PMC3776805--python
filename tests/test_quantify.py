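"""Efficiency-corrected quantification: RQ, NF, NRQ, Pfaffl ratios."""

import numpy as np
import pandas as pd
import pytest

from refstab.quantify import (
    RelativeQuantifier,
    collapse_replicates,
    cq_to_rq,
    normalization_factor,
    normalized_rq,
    pfaffl_ratio,
)


def tidy(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cq"])


def simple_mean_cq(cq: dict, groups: dict, eff: dict):
    """Build (mean_cq frame, efficiency frame) from {gene: {sample: cq}}."""
    rows = []
    for gene, per_sample in cq.items():
        for sample, val in per_sample.items():
            rows.append({"sample": sample, "group": groups[sample], "gene": gene,
                         "cq_mean": val, "cq_sd": 0.0, "cq_se": 0.0, "n": 2})
    eff_df = pd.DataFrame({"E": pd.Series(eff)})
    return pd.DataFrame(rows), eff_df


class TestCollapseReplicates:
    def test_mean_and_sd(self):
        data = tidy([("s1", "A", "g", 1, 19.0), ("s1", "A", "g", 2, 21.0)])
        out = collapse_replicates(data)
        assert out.loc[0, "cq_mean"] == 20.0
        assert out.loc[0, "cq_sd"] == pytest.approx(np.sqrt(2))
        assert out.loc[0, "cq_se"] == pytest.approx(1.0)

    def test_constant_replicates(self):
        data = tidy([("s1", "A", "g", r, 20.0) for r in range(3)])
        out = collapse_replicates(data)
        assert out.loc[0, "cq_mean"] == 20.0
        assert out.loc[0, "cq_sd"] == 0.0

    def test_singleton_replicate_warns_and_gets_zero_se(self, caplog):
        with caplog.at_level("WARNING"):
            out = collapse_replicates(tidy([("s1", "A", "g", 1, 25.0)]))
        assert out.loc[0, "cq_se"] == 0.0
        assert "singleton" in caplog.text

    def test_missing_cq_rows_dropped(self, caplog):
        data = tidy([("s1", "A", "g", 1, 20.0), ("s1", "A", "g", 2, np.nan)])
        with caplog.at_level("WARNING"):
            out = collapse_replicates(data)
        assert out.loc[0, "n"] == 1


class TestCqToRq:
    def test_two_doublings_at_perfect_efficiency(self):
        mean_cq, eff = simple_mean_cq(
            {"g": {"s1": 20.0, "s2": 22.0}}, {"s1": "A", "s2": "B"}, {"g": 1.0}
        )
        res = cq_to_rq(mean_cq, eff)
        assert res.rq.loc["s1", "g"] == pytest.approx(1.0)
        assert res.rq.loc["s2", "g"] == pytest.approx(0.25)
        assert res.calibrators["g"] == "s1"

    def test_rq_is_one_at_calibrator_and_bounded_by_one(self):
        rng = np.random.default_rng(2)
        cq = {f"g{i}": {f"s{j}": 20 + rng.uniform(0, 8) for j in range(5)}
              for i in range(4)}
        groups = {f"s{j}": "A" for j in range(5)}
        eff = {f"g{i}": 0.9 + 0.05 * i for i in range(4)}
        res = cq_to_rq(*simple_mean_cq(cq, groups, eff))
        assert (res.rq.values <= 1.0 + 1e-12).all()
        for g in res.rq.columns:
            assert res.rq.loc[res.calibrators[g], g] == pytest.approx(1.0)

    def test_efficiency_correction_closed_form(self):
        mean_cq, eff = simple_mean_cq(
            {"g": {"s1": 20.0, "s2": 23.0}}, {"s1": "A", "s2": "A"}, {"g": 0.9}
        )
        res = cq_to_rq(mean_cq, eff)
        assert res.rq.loc["s2", "g"] == pytest.approx(1.9**-3)

    def test_calibrator_tie_broken_by_sample_label(self):
        mean_cq, eff = simple_mean_cq(
            {"g": {"s2": 20.0, "s1": 20.0}}, {"s1": "A", "s2": "A"}, {"g": 1.0}
        )
        assert cq_to_rq(mean_cq, eff).calibrators["g"] == "s1"

    def test_missing_efficiency_rejected(self):
        mean_cq, eff = simple_mean_cq(
            {"g": {"s1": 20.0, "s2": 21.0}}, {"s1": "A", "s2": "A"}, {"other": 1.0}
        )
        with pytest.raises(ValueError, match="efficiency"):
            cq_to_rq(mean_cq, eff)

    def test_incomplete_samples_dropped_with_warning(self, caplog):
        mean_cq, eff = simple_mean_cq(
            {"g1": {"s1": 20.0, "s2": 21.0}, "g2": {"s1": 22.0}},
            {"s1": "A", "s2": "A"}, {"g1": 1.0, "g2": 1.0},
        )
        with caplog.at_level("WARNING"):
            res = cq_to_rq(mean_cq, eff)
        assert list(res.rq.index) == ["s1"]
        assert "s2" in caplog.text

    def test_se_propagation_delta_method(self):
        mean_cq, eff = simple_mean_cq(
            {"g": {"s1": 20.0, "s2": 22.0}}, {"s1": "A", "s2": "A"}, {"g": 1.0}
        )
        mean_cq["cq_se"] = 0.1
        res = cq_to_rq(mean_cq, eff)
        rq = res.rq.loc["s2", "g"]
        assert res.se.loc["s2", "g"] == pytest.approx(rq * np.log(2.0) * 0.1)


class TestNormalizationFactor:
    def test_single_gene_is_identity(self):
        rq = pd.DataFrame({"g": [1.0, 0.5, 0.25]}, index=["a", "b", "c"])
        nf = normalization_factor(rq, ["g"])
        assert np.allclose(nf.nf, rq["g"])

    @pytest.mark.parametrize("vals,expected", [([1.0, 4.0], 2.0),
                                               ([0.5, 0.5, 0.5], 0.5)])
    def test_geometric_mean(self, vals, expected):
        rq = pd.DataFrame([vals], index=["s"],
                          columns=[f"g{i}" for i in range(len(vals))])
        nf = normalization_factor(rq, list(rq.columns))
        assert nf.nf["s"] == pytest.approx(expected)

    def test_empty_set_rejected(self):
        rq = pd.DataFrame({"g": [1.0, 1.0]})
        with pytest.raises(ValueError):
            normalization_factor(rq, [])

    def test_se_propagation(self):
        rq = pd.DataFrame({"g1": [1.0], "g2": [4.0]}, index=["s"])
        se = pd.DataFrame({"g1": [0.1], "g2": [0.8]}, index=["s"])
        nf = normalization_factor(rq, ["g1", "g2"], rq_se=se)
        expected = 2.0 * 0.5 * np.sqrt(0.1**2 + 0.2**2)
        assert nf.se["s"] == pytest.approx(expected)


class TestNormalizedRq:
    def test_target_equal_to_nf_is_flat_one(self):
        rq = pd.DataFrame({"t": [1.0, 0.5, 2.0], "r": [1.0, 0.5, 2.0]},
                          index=["a", "b", "c"])
        nf = normalization_factor(rq, ["r"])
        nrq = normalized_rq(rq, "t", nf)
        assert np.allclose(nrq.nrq, 1.0)

    def test_rescaling_to_first_group(self):
        rq = pd.DataFrame({"t": [1.0, 2.0, 4.0, 8.0],
                           "r": [1.0, 1.0, 1.0, 1.0]},
                          index=["a", "b", "c", "d"])
        groups = pd.Series(["G1", "G2", "G3", "G4"], index=rq.index)
        nf = normalization_factor(rq, ["r"])
        nrq = normalized_rq(rq, "t", nf, groups=groups, rescale_group="G1")
        assert np.allclose(nrq.nrq, [1.0, 2.0, 4.0, 8.0])

    def test_absent_rescale_group_rejected(self):
        rq = pd.DataFrame({"t": [1.0, 2.0], "r": [1.0, 1.0]}, index=["a", "b"])
        groups = pd.Series(["G1", "G1"], index=rq.index)
        nf = normalization_factor(rq, ["r"])
        with pytest.raises(ValueError):
            normalized_rq(rq, "t", nf, groups=groups, rescale_group="G9")

    def test_true_loadings_recover_simulated_fold_profile(self, toy_cq_data):
        # normalizing by the generator's own loading factors must return the
        # generating 1:2:8:4 profile exactly on noise-free data
        data, truth = toy_cq_data
        from refstab.quantify import NFResult

        res = cq_to_rq(collapse_replicates(data),
                       truth.efficiency.rename("E").to_frame())
        loading_nf = NFResult(
            nf=(2.0**truth.loadings).loc[res.rq.index] ,
            se=pd.Series(0.0, index=res.rq.index),
            ref_genes=("truth",),
        )
        nrq = normalized_rq(res, "tgt", loading_nf, rescale_group="G1")
        by_group = nrq.nrq.groupby(res.groups).mean()
        assert np.allclose(by_group[["G1", "G2", "G3", "G4"]], [1, 2, 8, 4],
                           rtol=1e-9)


class TestPfafflRatio:
    def _frame(self, cq_t, cq_r):
        rows = []
        for (gene, per) in (("t", cq_t), ("r", cq_r)):
            for group, val in per.items():
                rows.append({"sample": f"s_{group}", "group": group,
                             "gene": gene, "cq_mean": val, "cq_se": 0.0})
        return pd.DataFrame(rows)

    def test_identical_shifts_cancel(self):
        mc = self._frame({"cal": 20.0, "exp": 18.0}, {"cal": 25.0, "exp": 23.0})
        r = pfaffl_ratio(mc, "t", "r", "exp", "cal", {"t": 1.0, "r": 1.0})
        assert r == pytest.approx(1.0)

    def test_three_cycle_shift_is_eightfold(self):
        mc = self._frame({"cal": 20.0, "exp": 17.0}, {"cal": 25.0, "exp": 25.0})
        r = pfaffl_ratio(mc, "t", "r", "exp", "cal", {"t": 1.0, "r": 1.0})
        assert r == pytest.approx(8.0)

    def test_efficiency_corrected_closed_form(self):
        mc = self._frame({"cal": 20.0, "exp": 16.8}, {"cal": 25.0, "exp": 23.9})
        r = pfaffl_ratio(mc, "t", "r", "exp", "cal", {"t": 0.95, "r": 0.90})
        assert r == pytest.approx(1.95**3.2 / 1.90**1.1)

    def test_missing_group_rejected(self):
        mc = self._frame({"cal": 20.0}, {"cal": 25.0})
        with pytest.raises(ValueError):
            pfaffl_ratio(mc, "t", "r", "exp", "cal", {"t": 1.0, "r": 1.0})


class TestInvariances:
    def _simulated(self):
        from refstab.simulate import CqSimSpec, GeneSimSpec, simulate_cq

        genes = tuple(GeneSimSpec(f"g{i}", base_cq=22 + i, efficiency=0.95,
                                  bio_sd=0.2) for i in range(4))
        spec = CqSimSpec(groups=("A",) * 3 + ("B",) * 3, genes=genes,
                         loading_sd=0.3, tech_sd=0.1, seed=5)
        return simulate_cq(spec)[0]

    def test_gene_wise_cq_shift_leaves_pfaffl_and_nrq_unchanged(self):
        data = self._simulated()
        eff = {f"g{i}": 0.95 for i in range(4)}
        shifted = data.copy()
        shifted.loc[shifted["gene"] == "g0", "cq"] += 2.5

        def run(d):
            mc = collapse_replicates(d)
            res = cq_to_rq(mc, eff)
            nf = normalization_factor(res, ["g1", "g2"])
            nrq = normalized_rq(res, "g0", nf, rescale_group="A")
            pf = pfaffl_ratio(mc, "g0", "g1", "B", "A", eff)
            return nrq.nrq, pf

        nrq0, pf0 = run(data)
        nrq1, pf1 = run(shifted)
        assert np.allclose(nrq0, nrq1, rtol=1e-10)
        assert pf0 == pytest.approx(pf1, rel=1e-10)

    def test_sample_wise_cq_shift_at_common_efficiency(self):
        # +c cycles on every gene of one sample divides that sample's RQ and
        # NF by the same factor, leaving NRQ untouched
        data = self._simulated()
        eff = {f"g{i}": 0.95 for i in range(4)}
        shifted = data.copy()
        shifted.loc[shifted["sample"] == "S03", "cq"] += 1.7

        def run(d):
            res = cq_to_rq(collapse_replicates(d), eff)
            nf = normalization_factor(res, ["g1", "g2", "g3"])
            return normalized_rq(res, "g0", nf, rescale_group="A").nrq

        assert np.allclose(run(data), run(shifted), rtol=1e-10)


class TestRelativeQuantifier:
    def test_fit_transform_matches_cq_to_rq(self):
        from refstab.simulate import simulate_cq, CqSimSpec, GeneSimSpec

        spec = CqSimSpec(groups=("A", "A", "B", "B"),
                         genes=(GeneSimSpec("g1"), GeneSimSpec("g2")), seed=1)
        data, truth = simulate_cq(spec)
        eff = truth.efficiency.rename("E").to_frame()
        est = RelativeQuantifier(efficiencies=eff).fit(data)
        direct = cq_to_rq(collapse_replicates(data), eff)
        pd.testing.assert_frame_equal(est.rq_, direct.rq)
        pd.testing.assert_frame_equal(est.transform(data), direct.rq)

    def test_sklearn_params_round_trip(self):
        est = RelativeQuantifier(efficiencies={"g": 1.0})
        assert est.get_params()["efficiencies"] == {"g": 1.0}
        est.set_params(efficiencies={"g": 0.9})
        assert est.efficiencies == {"g": 0.9}
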