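"""CT aggregation, relative quantification, group comparison, simulation."""

import numpy as np
import pandas as pd
import pytest

from ephysq import (
    CtPanel,
    GeneSpec,
    PanelDesign,
    aggregate_triplicates,
    compare_groups,
    default_panel_design,
    relative_expression,
    simulate_ct_panel,
)


def make_panel(rows, refs=("Ref1",), efficiency=2.0):
    df = pd.DataFrame(rows, columns=["sample_id", "group", "zt", "hemisphere",
                                     "gene", "well", "ct"])
    return CtPanel(data=df, reference_genes=frozenset(refs),
                   efficiency=efficiency)


def triplicate_rows(sample, group, gene, cts, zt=None, hemi=None):
    return [(sample, group, zt, hemi, gene, f"w{i+1}", ct)
            for i, ct in enumerate(cts)]


class TestAggregate:
    def test_triplicate_mean(self):
        panel = make_panel(
            triplicate_rows("s1", "control", "Ref1", [24.1, 24.3, 24.2])
        )
        agg = aggregate_triplicates(panel)
        assert agg["ct_mean"].iloc[0] == pytest.approx(24.2)
        assert agg["n_replicates"].iloc[0] == 3

    def test_single_replicate_passthrough(self):
        panel = make_panel(triplicate_rows("s1", "control", "Ref1", [30.0]))
        agg = aggregate_triplicates(panel)
        assert agg["ct_mean"].iloc[0] == 30.0
        assert not agg["high_variance"].iloc[0]

    def test_high_variance_flag_count(self):
        # two noisy records programmed in; flag count found by enumeration
        rows = (triplicate_rows("s1", "control", "Ref1", [24.0, 24.1, 24.2])
                + triplicate_rows("s1", "control", "G1", [30.0, 31.5, 30.1])
                + triplicate_rows("s2", "control", "Ref1", [24.0, 24.0, 24.1])
                + triplicate_rows("s2", "control", "G1", [28.0, 29.9, 28.2]))
        panel = make_panel(rows)
        agg = aggregate_triplicates(panel, sd_flag_cycles=0.5)
        expected = sum(
            np.std(c, ddof=1) > 0.5
            for c in ([24.0, 24.1, 24.2], [30.0, 31.5, 30.1],
                      [24.0, 24.0, 24.1], [28.0, 29.9, 28.2])
        )
        assert int(agg["high_variance"].sum()) == expected == 2


class TestRelativeExpression:
    def test_identical_cts_give_unity(self):
        rows = []
        for s in ["a", "b", "c", "d"]:
            grp = "control" if s in "ab" else "treated"
            rows += triplicate_rows(s, grp, "Ref1", [24.0] * 3)
            rows += triplicate_rows(s, grp, "G1", [30.0] * 3)
        expr = relative_expression(make_panel(rows))
        np.testing.assert_allclose(expr.data["normalized_rel_expr"], 1.0)

    def test_one_cycle_shift_doubles_expression(self):
        rows = []
        for s, grp, ct in [("c1", "control", 30.0), ("c2", "control", 30.0),
                           ("t1", "treated", 29.0), ("t2", "treated", 29.0)]:
            rows += triplicate_rows(s, grp, "Ref1", [24.0] * 3)
            rows += triplicate_rows(s, grp, "G1", [ct] * 3)
        expr = relative_expression(make_panel(rows))
        g = expr.data[expr.data.gene == "G1"]
        ratio = (g[g.group == "treated"].normalized_rel_expr.mean()
                 / g[g.group == "control"].normalized_rel_expr.mean())
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_hand_computed_panel_with_two_references(self):
        # 4 samples x 3 genes, worked through by hand:
        # RQ = 2^(ctbar - ct); NF = gmean(RQ_Ref1, RQ_Ref2); norm = RQ/NF,
        # then anchored to control mean 1
        cts = {
            "s1": {"Ref1": 24.0, "Ref2": 20.0, "G1": 30.0},
            "s2": {"Ref1": 25.0, "Ref2": 21.0, "G1": 30.0},
            "s3": {"Ref1": 24.0, "Ref2": 20.0, "G1": 28.0},
            "s4": {"Ref1": 25.0, "Ref2": 21.0, "G1": 29.0},
        }
        groups = {"s1": "control", "s2": "control",
                  "s3": "treated", "s4": "treated"}
        rows = []
        for s, gd in cts.items():
            for g, ct in gd.items():
                rows += triplicate_rows(s, groups[s], g, [ct] * 3)
        expr = relative_expression(make_panel(rows, refs=("Ref1", "Ref2")))

        ctbar = {g: np.mean([cts[s][g] for s in cts]) for g in ["Ref1", "Ref2", "G1"]}
        norm = {}
        for s in cts:
            rq = {g: 2.0 ** (ctbar[g] - cts[s][g]) for g in ctbar}
            nf = np.sqrt(rq["Ref1"] * rq["Ref2"])
            norm[s] = rq["G1"] / nf
        ctrl_mean = np.mean([norm["s1"], norm["s2"]])
        for s in cts:
            got = expr.data.query("sample_id == @s and gene == 'G1'")
            assert got["normalized_rel_expr"].iloc[0] == pytest.approx(
                norm[s] / ctrl_mean, rel=1e-12
            )

    def test_control_mean_is_exactly_one_per_stratum(self):
        panel = simulate_ct_panel(default_panel_design(), seed=9)
        expr = relative_expression(panel)
        ctrl = expr.data[expr.data.group == "control"]
        for (_, _), sub in ctrl.groupby(["gene", "zt"]):
            assert sub["normalized_rel_expr"].mean() == pytest.approx(1.0,
                                                                      abs=1e-9)

    def test_missing_reference_gene_names_sample(self):
        rows = (triplicate_rows("s1", "control", "Ref1", [24.0] * 3)
                + triplicate_rows("s1", "control", "G1", [30.0] * 3)
                + triplicate_rows("s2", "treated", "G1", [30.0] * 3))
        with pytest.raises(ValueError, match="s2"):
            relative_expression(make_panel(rows))

    def test_bad_efficiency_rejected(self):
        rows = triplicate_rows("s1", "control", "Ref1", [24.0] * 3)
        with pytest.raises(ValueError, match="efficiency"):
            make_panel(rows, efficiency=2.5)

    def test_sample_loading_offset_cancels(self):
        # adding a constant to every CT of one sample leaves its normalized
        # expression unchanged (uniform E)
        design = default_panel_design(noise_sd_cycles=0.0)
        panel = simulate_ct_panel(design, seed=0)
        shifted = panel.data.copy()
        sid = shifted["sample_id"].iloc[0]
        shifted.loc[shifted.sample_id == sid, "ct"] += 1.7
        panel2 = CtPanel(data=shifted, reference_genes=panel.reference_genes,
                         efficiency=panel.efficiency)
        e1 = relative_expression(panel).data.set_index(["sample_id", "gene"])
        e2 = relative_expression(panel2).data.set_index(["sample_id", "gene"])
        joined = e1.join(e2, rsuffix="_shifted")
        np.testing.assert_allclose(joined["normalized_rel_expr"],
                                   joined["normalized_rel_expr_shifted"],
                                   rtol=1e-9)


class TestCompareGroups:
    def test_identical_groups_give_unit_ratio_and_p_one(self):
        rows = []
        for i in range(3):
            for grp in ("control", "treated"):
                rows += triplicate_rows(f"{grp}{i}", grp, "Ref1", [24.0] * 3)
                rows += triplicate_rows(f"{grp}{i}", grp, "G1", [30.0] * 3)
        expr = relative_expression(make_panel(rows))
        res = compare_groups(expr, stratify_by=())
        assert res["mean_ratio"].iloc[0] == pytest.approx(1.0)

    def test_single_test_adjustment_identity(self):
        design = default_panel_design(noise_sd_cycles=0.1)
        genes = {k: v for k, v in design.genes.items()
                 if k in ("Hlf", "Hprt1", "Eef1a1")}
        d = PanelDesign(genes=genes, zts=(0,), n_per_group=4,
                        noise_sd_cycles=0.1)
        expr = relative_expression(simulate_ct_panel(d, seed=1))
        res = compare_groups(expr)
        assert len(res) == 1
        assert res["p_adjusted"].iloc[0] == res["p"].iloc[0]

    def test_knockdown_power_and_null_specificity(self):
        # Hlf programmed 4-fold down; three null genes; n=5, sigma=0.25
        genes = {
            "Hlf": GeneSpec(24.0, treated_fold_change=0.25),
            "Null1": GeneSpec(26.0), "Null2": GeneSpec(23.0),
            "Null3": GeneSpec(27.0),
            "Hprt1": GeneSpec(22.0), "Eef1a1": GeneSpec(18.0),
        }
        design = PanelDesign(genes=genes, zts=(0,), n_per_group=5,
                             noise_sd_cycles=0.25)
        hlf_hits = null_hits = 0
        for seed in range(20):
            expr = relative_expression(simulate_ct_panel(design, seed=seed))
            res = compare_groups(expr).set_index("gene")
            if res.loc["Hlf", "p_adjusted"] < 0.05:
                hlf_hits += 1
            if (res.drop("Hlf")["p_adjusted"] < 0.05).any():
                null_hits += 1
        assert hlf_hits >= 18
        assert null_hits <= 2

    def test_small_stratum_skipped(self):
        rows = []
        for grp, n in (("control", 2), ("treated", 1)):
            for i in range(n):
                rows += triplicate_rows(f"{grp}{i}", grp, "Ref1", [24.0] * 3)
                rows += triplicate_rows(f"{grp}{i}", grp, "G1",
                                        [30.0 + 0.1 * i] * 3)
        expr = relative_expression(make_panel(rows))
        assert compare_groups(expr, stratify_by=()).empty


class TestSimulatePanel:
    def test_zero_noise_zero_effect_is_constant(self):
        genes = {"G1": GeneSpec(30.0), "Hprt1": GeneSpec(22.0),
                 "Eef1a1": GeneSpec(18.0)}
        d = PanelDesign(genes=genes, noise_sd_cycles=0.0)
        panel = simulate_ct_panel(d, seed=0)
        for g, sub in panel.data.groupby("gene"):
            assert sub["ct"].nunique() == 1

    def test_programmed_fold_change_round_trip(self):
        design = default_panel_design(noise_sd_cycles=0.0)
        expr = relative_expression(simulate_ct_panel(design, seed=0))
        g = expr.data[expr.data.gene == "Hlf"]
        ratio = (g[g.group == "treated"].normalized_rel_expr.mean()
                 / g[g.group == "control"].normalized_rel_expr.mean())
        assert ratio == pytest.approx(0.25, rel=1e-9)

    def test_cosinor_profile_peaks_at_programmed_phase(self):
        # amplitude 1 cycle, peak ZT12: expression (before per-stratum
        # anchoring) peaks at ZT12 and troughs at ZT0
        genes = {"G1": GeneSpec(30.0, amplitude_cycles=1.0, peak_zt=12),
                 "Hprt1": GeneSpec(22.0), "Eef1a1": GeneSpec(18.0)}
        d = PanelDesign(genes=genes, noise_sd_cycles=0.0,
                        groups=("control",))
        expr = relative_expression(simulate_ct_panel(d, seed=0),
                                   rescale=False)
        prof = (expr.data[expr.data.gene == "G1"]
                .groupby("zt")["normalized_rel_expr"].mean())
        assert prof.idxmax() == 12
        assert prof.idxmin() == 0
        assert prof[12] / prof[0] == pytest.approx(4.0, rel=1e-9)  # 2^2

    def test_determinism(self):
        d = default_panel_design()
        p1 = simulate_ct_panel(d, seed=5)
        p2 = simulate_ct_panel(d, seed=5)
        pd.testing.assert_frame_equal(p1.data, p2.data)

    def test_reference_with_effect_rejected(self):
        genes = {"Hprt1": GeneSpec(22.0, treated_fold_change=0.5),
                 "Eef1a1": GeneSpec(18.0), "G1": GeneSpec(30.0)}
        with pytest.raises(ValueError, match="Hprt1"):
            PanelDesign(genes=genes)
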