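"""qPCR quantification, geNorm stability and ddPCR Poisson inversion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from painmark import presets, synth
from painmark.pcr import (
    collapse_replicates,
    genorm,
    group_stats,
    normalize,
    normalize_copies,
    poisson_copies,
    relative_quantities,
)
from painmark.synth import QpcrGene


def _cq_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "is_reference", "cq"])


class TestRelativeQuantities:
    def test_sample_at_gene_mean_has_rq_one(self):
        cq = _cq_frame([("g", "s1", "a", False, 20.0), ("g", "s2", "a", False, 22.0)])
        rq = relative_quantities(cq, efficiency=2.0)
        # gene mean Cq = 21; s1 is one cycle below the mean
        assert rq.set_index("sample").rq["s1"] == pytest.approx(2.0)
        assert rq.set_index("sample").rq["s2"] == pytest.approx(0.5)

    def test_nondefault_efficiency(self):
        cq = _cq_frame(
            [("g", "s1", "a", False, 20.0), ("g", "s2", "a", False, 20.0),
             ("g", "s3", "a", False, 26.0)])
        # gene mean = 22; s3 sits 4 cycles above; check E = 1.9 to the formula
        rq = relative_quantities(cq, efficiency=1.9)
        assert rq.set_index("sample").rq["s3"] == pytest.approx(1.9 ** (-4), rel=1e-12)

    def test_two_cycles_above_mean_example(self):
        # direct evaluation: E = 1.9, Cq two cycles above the gene mean
        assert 1.9 ** (-2) == pytest.approx(0.2770083102493075, rel=1e-12)

    def test_bad_efficiency_rejected(self):
        cq = _cq_frame([("g", "s1", "a", False, 20.0)])
        with pytest.raises(ValueError):
            relative_quantities(cq, efficiency=1.0)

    def test_replicates_collapsed_with_qc_flag(self):
        cq = _cq_frame(
            [("g", "s1", "a", False, 20.0), ("g", "s1", "a", False, 20.8),
             ("g", "s2", "a", False, 21.0), ("g", "s2", "a", False, 21.1)])
        out = collapse_replicates(cq)
        flags = out.set_index("sample").noisy
        assert bool(flags["s1"]) and not bool(flags["s2"])


def brute_force_genorm_m(wide: pd.DataFrame) -> dict[str, float]:
    """Independent geNorm M: mean over partners of SD of pairwise log2 ratios."""
    out = {}
    for j in wide.columns:
        vs = []
        for k in wide.columns:
            if k == j:
                continue
            ratios = np.log2(wide[j] / wide[k])
            vs.append(ratios.std(ddof=1))
        out[j] = float(np.mean(vs))
    return out


class TestGenorm:
    TOY = pd.DataFrame(
        {
            "r1": [1.00, 0.52, 1.90, 0.75, 1.42, 1.05],
            "r2": [0.98, 0.55, 2.10, 0.70, 1.30, 1.15],
            "r3": [1.20, 0.40, 1.60, 0.95, 1.55, 0.85],
            "r4": [0.66, 0.80, 2.60, 0.50, 1.05, 1.60],
        },
        index=[f"s{i}" for i in range(6)],
    )

    def _toy_rq(self):
        long = self.TOY.stack().reset_index()
        long.columns = ["sample", "gene", "rq"]
        long["group"] = "a"
        long["is_reference"] = True
        return long

    def test_toy_matches_brute_force_oracle(self):
        report = genorm(self._toy_rq(), candidates=list(self.TOY.columns))
        expected = brute_force_genorm_m(self.TOY)
        for row in report.table.itertuples():
            assert row.M == pytest.approx(expected[row.gene], rel=1e-13)

    def test_proportional_candidates_have_zero_pairwise_v(self):
        wide = self.TOY.copy()
        wide["r2"] = 3.0 * wide["r1"]  # perfectly proportional pair
        long = wide.stack().reset_index()
        long.columns = ["sample", "gene", "rq"]
        long["group"] = "a"
        long["is_reference"] = True
        report = genorm(long, candidates=list(wide.columns))
        assert report.pairwise_v.at["r1", "r2"] == pytest.approx(0.0, abs=1e-12)

    def test_m_invariant_to_scaling_one_candidate(self):
        base = genorm(self._toy_rq(), candidates=list(self.TOY.columns))
        scaled_rq = self._toy_rq()
        scaled_rq.loc[scaled_rq.gene == "r3", "rq"] *= 17.0
        scaled = genorm(scaled_rq, candidates=list(self.TOY.columns))
        pd.testing.assert_series_equal(
            base.table.set_index("gene").M, scaled.table.set_index("gene").M,
            rtol=1e-12)

    def test_exclusion_order_ends_with_most_stable_pair(self):
        report = genorm(self._toy_rq(), candidates=list(self.TOY.columns))
        assert len(report.exclusion_order) == 2
        assert set(report.final_pair) | set(report.exclusion_order) == set(
            self.TOY.columns)

    def test_needs_three_candidates(self):
        with pytest.raises(ValueError):
            genorm(self._toy_rq(), candidates=["r1", "r2"])

    def test_calibrated_preset_recovers_published_stability(self):
        # the 12-gene preset is calibrated so the two most stable genes
        # have expected M = 0.419
        vals = []
        for s in range(30):
            spec = presets.refgene_panel_preset(seed=3000 + s)
            cq, _ = synth.gen_cq_experiment(spec)
            report = genorm(relative_quantities(cq), list(spec.reference_noise_sd))
            vals.append(report.table.M.iloc[:2].mean())
        assert np.mean(vals) == pytest.approx(presets.GENORM_M_TARGET, rel=0.10)


class TestNormalize:
    def _rq(self, frame: pd.DataFrame, refs: set[str]):
        long = frame.stack().reset_index()
        long.columns = ["sample", "gene", "rq"]
        long["group"] = "a"
        long["is_reference"] = long.gene.isin(refs)
        return long

    def test_constant_unit_references_are_identity(self):
        frame = pd.DataFrame(
            {"t": [2.0, 0.5, 1.5], "ref": [1.0, 1.0, 1.0]},
            index=["s1", "s2", "s3"])
        nrq = normalize(self._rq(frame, {"ref"}), references=["ref"])
        target = nrq[nrq.gene == "t"].set_index("sample").nrq
        assert target.tolist() == pytest.approx([2.0, 0.5, 1.5])

    def test_reference_geomean_is_one_per_sample(self):
        cq, _ = synth.gen_cq_experiment(presets.timp1_qpcr_preset(seed=5))
        nrq = normalize(relative_quantities(cq), references=["Atp5b", "Ubc"])
        refs = nrq[nrq.is_reference].pivot(index="sample", columns="gene",
                                           values="nrq")
        geo = np.exp(np.log(refs).mean(axis=1))
        np.testing.assert_allclose(geo.values, 1.0, rtol=1e-12)

    def test_per_sample_scaling_cancels(self):
        frame = pd.DataFrame(
            {"t": [2.0, 0.5], "r1": [1.1, 0.9], "r2": [0.8, 1.3]},
            index=["s1", "s2"])
        base = normalize(self._rq(frame, {"r1", "r2"}), references=["r1", "r2"])
        scaled_frame = frame.copy()
        scaled_frame.loc["s1"] *= 10.0
        scaled = normalize(self._rq(scaled_frame, {"r1", "r2"}),
                           references=["r1", "r2"])
        pd.testing.assert_series_equal(base.nrq, scaled.nrq, rtol=1e-12)

    def test_missing_reference_names_sample(self):
        frame = pd.DataFrame({"t": [2.0, 0.5], "ref": [1.0, np.nan]},
                             index=["s1", "s2"])
        long = self._rq(frame, {"ref"}).dropna(subset=["rq"])
        with pytest.raises(ValueError, match="s2"):
            normalize(long, references=["ref"])


class TestGroupStats:
    def test_identical_groups_null(self):
        rows = [("g", f"a{i}", "snl", False, v)
                for i, v in enumerate([1.0, 2.0, 3.0])]
        rows += [("g", f"b{i}", "sham", False, v)
                 for i, v in enumerate([1.0, 2.0, 3.0])]
        nrq = pd.DataFrame(rows, columns=["gene", "sample", "group",
                                          "is_reference", "nrq"])
        res = group_stats(nrq, case="snl", control="sham")
        assert res.fc.iloc[0] == pytest.approx(1.0)
        assert res.direction.iloc[0] == "up"
        assert res.p.iloc[0] == pytest.approx(1.0)

    def test_label_permutation_within_group_is_irrelevant(self, rng):
        cq, _ = synth.gen_cq_experiment(presets.timp1_qpcr_preset(seed=6))
        nrq = normalize(relative_quantities(cq), ["Atp5b", "Ubc"])
        targets = nrq[~nrq.is_reference].copy()
        res_a = group_stats(targets, "snl", "sham")
        snl_ids = targets.loc[targets.group == "snl", "sample"].unique()
        perm = dict(zip(snl_ids, rng.permutation(snl_ids)))
        shuffled = targets.assign(
            sample=[perm.get(s, s) for s in targets["sample"]])
        res_b = group_stats(shuffled, "snl", "sham")
        assert res_a.p.iloc[0] == pytest.approx(res_b.p.iloc[0], rel=1e-12)
        assert res_a.fc.iloc[0] == pytest.approx(res_b.fc.iloc[0], rel=1e-12)

    def test_noiseless_pipeline_recovers_planted_ratio_exactly(self):
        spec = presets.timp1_qpcr_preset(seed=7, noise_sd=0.0).model_copy(
            update={"size_factor_sd": 0.0,
                    "reference_noise_sd": {"Atp5b": 0.0, "Ubc": 0.0}})
        cq, _ = synth.gen_cq_experiment(spec)
        nrq = normalize(relative_quantities(cq), ["Atp5b", "Ubc"])
        res = group_stats(nrq[~nrq.is_reference], "snl", "sham")
        assert res.fc.iloc[0] == pytest.approx(2.19, rel=1e-12)
        assert res.direction.iloc[0] == "up"

    def test_underpowered_gene_marked_not_analysable(self):
        rows = [("g", "a1", "snl", False, 1.0), ("g", "b1", "sham", False, 1.2),
                ("g", "b2", "sham", False, 0.8)]
        nrq = pd.DataFrame(rows, columns=["gene", "sample", "group",
                                          "is_reference", "nrq"])
        res = group_stats(nrq, case="snl", control="sham")
        assert res.method.iloc[0] == "not_analysable"
        assert np.isnan(res.p.iloc[0])


def _droplet_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "well",
                                       "positives", "total"])


class TestPoissonCopies:
    def test_zero_positives_is_zero_copies(self):
        d = _droplet_frame([("g", "s", "a", "W0", 0, 15000)])
        out = poisson_copies(d)
        assert out.copies_per_reaction.iloc[0] == 0.0

    def test_closed_form_example(self):
        # 5000/15000 positive, droplet 0.85 nl, reaction 20 ul
        d = _droplet_frame([("g", "s", "a", "W0", 5000, 15000)])
        out = poisson_copies(d, droplet_volume_nl=0.85, reaction_volume_ul=20.0)
        lam = -math.log(2.0 / 3.0)
        assert out["lambda"].iloc[0] == pytest.approx(lam, rel=1e-13)
        assert out.copies_per_reaction.iloc[0] == pytest.approx(
            lam * 20000.0 / 0.85, rel=1e-13)

    def test_wells_pooled_before_inversion(self):
        pooled = poisson_copies(_droplet_frame(
            [("g", "s", "a", "W0", 3000, 15000), ("g", "s", "a", "W1", 2000, 15000)]))
        direct = poisson_copies(_droplet_frame([("g", "s", "a", "W0", 5000, 30000)]))
        assert pooled.copies_per_reaction.iloc[0] == pytest.approx(
            direct.copies_per_reaction.iloc[0], rel=1e-13)

    def test_strictly_increasing_in_positives(self):
        vals = [
            poisson_copies(_droplet_frame([("g", "s", "a", "W0", k, 1000)]))
            .copies_per_reaction.iloc[0]
            for k in range(0, 1000, 50)
        ]
        assert all(b > a for a, b in itertools.pairwise(vals))

    def test_halving_droplet_volume_doubles_copies(self):
        d = _droplet_frame([("g", "s", "a", "W0", 4000, 15000)])
        c1 = poisson_copies(d, droplet_volume_nl=0.85).copies_per_reaction.iloc[0]
        c2 = poisson_copies(d, droplet_volume_nl=0.425).copies_per_reaction.iloc[0]
        assert c2 == pytest.approx(2.0 * c1, rel=1e-13)

    def test_saturated_well_flagged_undefined(self):
        d = _droplet_frame([("g", "s", "a", "W0", 15000, 15000)])
        out = poisson_copies(d)
        assert bool(out.saturated.iloc[0])
        assert np.isnan(out.copies_per_reaction.iloc[0])


class TestNormalizeCopies:
    def _copies(self, mapping):
        rows = [(g, s, "a", v) for (g, s), v in mapping.items()]
        return pd.DataFrame(rows, columns=["gene", "sample", "group",
                                           "copies_per_reaction"])

    def test_unit_references_are_identity(self):
        c = self._copies({("t", "s1"): 123.0, ("r1", "s1"): 1.0, ("r2", "s1"): 1.0})
        out = normalize_copies(c, ["r1", "r2"])
        assert out.set_index("gene").normalized["t"] == pytest.approx(123.0)

    def test_geometric_mean_divisor(self):
        c = self._copies({("t", "s1"): 12.0, ("r1", "s1"): 4.0, ("r2", "s1"): 9.0})
        out = normalize_copies(c, ["r1", "r2"])
        assert out.set_index("gene").normalized["t"] == pytest.approx(2.0, rel=1e-13)

    def test_per_sample_scaling_cancels(self):
        c = self._copies({("t", "s1"): 12.0, ("r1", "s1"): 4.0, ("r2", "s1"): 9.0})
        scaled = c.assign(copies_per_reaction=c.copies_per_reaction * 7.5)
        a = normalize_copies(c, ["r1", "r2"]).set_index("gene").normalized["t"]
        b = normalize_copies(scaled, ["r1", "r2"]).set_index("gene").normalized["t"]
        assert a == pytest.approx(b, rel=1e-13)

    def test_zero_reference_names_sample(self):
        c = self._copies({("t", "s9"): 12.0, ("r1", "s9"): 0.0, ("r2", "s9"): 9.0})
        with pytest.raises(ValueError, match="s9"):
            normalize_copies(c, ["r1", "r2"])


def test_ddpcr_generator_recovery_within_five_percent():
    # planted 2000 copies/reaction at 15000 droplets: the Poisson inversion
    # recovers the truth to better than 5% averaged over replicates
    est = []
    for s in range(100):
        spec = synth.DdpcrSpec(
            copies={"g": {"s1": 2000.0}}, groups={"s1": "a"}, seed=s)
        counts, _ = synth.gen_droplet_counts(spec)
        est.append(poisson_copies(counts).copies_per_reaction.iloc[0])
    assert abs(np.mean(est) - 2000.0) < 0.05 * 2000.0
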