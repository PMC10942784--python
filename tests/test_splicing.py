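"""Gene-level expression, deviation calls, events/PSI and switch calls."""
import itertools
import math

import numpy as np
import pytest

import sjkit
from conftest import make_matrix
from oracles import enumerate_events_oracle


def pipeline(result):
    m = result.matrix
    factors = sjkit.tmm_factors(m)
    logmat = sjkit.log_cpm(m, factors)
    assignment = sjkit.assign_junctions_to_genes(m, result.models)
    estimates = sjkit.estimate_gene_expression(m, logmat, result.models)
    return m, logmat, assignment, estimates


def two_condition_design(n=3):
    return [
        sjkit.SampleDesign(f"{c}_{r}", c)
        for c in ("control", "knockdown")
        for r in range(1, n + 1)
    ]


# ---------------------------------------------------------------------------
# Gene expression from the most abundant isoform
# ---------------------------------------------------------------------------

class TestEstimateGeneExpression:
    def test_single_isoform_gene_uses_that_isoform(self, sim_small):
        m, logmat, _, estimates = pipeline(sim_small)
        single = [g for g in sim_small.models if len(g.transcripts) == 1][0]
        est = estimates[single.gene_id]
        assert est.transcript_id == single.transcript_ids[0]
        rows = [m.index_of(j) for j in est.junctions]
        assert np.allclose(est.per_sample, logmat[rows].mean(axis=0))

    def test_higher_count_isoform_is_chosen(self):
        design = two_condition_design(1)
        exons = [(100, 200), (300, 400), (500, 600)]
        gene = sjkit.GeneModel(
            "G", "chr1", "+", (100, 600),
            {"hi": list(exons), "lo": [exons[0], exons[2]]},
        )
        per_tx = sjkit.transcript_junctions(gene)
        counts = {}
        for d in design:
            counts[d.sample_id] = {j: 500 for j in per_tx["hi"]}
            counts[d.sample_id][per_tx["lo"][0]] = 10
        m = make_matrix(counts, design)
        lm = sjkit.log_cpm(m, sjkit.NormFactors(m.samples, sjkit.library_sizes(m), np.ones(2)))
        est = sjkit.estimate_gene_expression(m, lm, [gene])["G"]
        assert est.transcript_id == "hi"

    def test_gls_fixture_gac_dominant_in_control_like_layout(self, gls):
        model, matrix, _ = gls
        f = sjkit.tmm_factors(matrix)
        lm = sjkit.log_cpm(matrix, f)
        est = sjkit.estimate_gene_expression(matrix, lm, [model])["GLS"]
        # shared junctions dominate both isoforms; chosen transcript must be
        # one of the two and the gene log2FC equals the hand-computed mean
        # difference over its junction rows
        rows = [matrix.index_of(j) for j in est.junctions]
        mask_b = matrix.sample_mask("knockdown")
        by_hand = lm[rows][:, mask_b].mean() - lm[rows][:, ~mask_b].mean()
        assert est.log2fc == pytest.approx(by_hand, abs=1e-12)

    def test_unexpressed_gene_is_skipped(self, gls):
        model, matrix, _ = gls
        ghost = sjkit.GeneModel("GHOST", "chr5", "+", (1, 2000),
                                {"t": [(1, 100), (1000, 2000)]})
        f = sjkit.tmm_factors(matrix)
        lm = sjkit.log_cpm(matrix, f)
        estimates = sjkit.estimate_gene_expression(matrix, lm, [model, ghost])
        assert "GHOST" not in estimates and "GLS" in estimates


# ---------------------------------------------------------------------------
# Deviation test
# ---------------------------------------------------------------------------

class TestJunctionDeviation:
    def test_delta_is_exactly_fc_difference(self, sim_small):
        m, logmat, assignment, estimates = pipeline(sim_small)
        calls, _ = sjkit.junction_deviation_test(m, logmat, estimates, assignment)
        diff = calls["log2fc_junction"] - calls["log2fc_gene"]
        assert np.allclose(calls["delta"], diff, atol=1e-12)

    def test_uniform_gene_shift_produces_no_deviation(self):
        # every junction of the gene shifts by exactly +2 log2 units
        design = two_condition_design(3)
        exons = [(i * 1000, i * 1000 + 200) for i in range(1, 7)]
        gene = sjkit.GeneModel("G", "chr1", "+", (1000, 6200), {"t": list(exons)})
        js = sjkit.derive_junctions(exons, "chr1", "+")
        counts = {}
        for d in design:
            scale = 4 if d.condition == "knockdown" else 1
            counts[d.sample_id] = {j: 100 * (i + 1) * scale for i, j in enumerate(js)}
        m = make_matrix(counts, design)
        # fixed equal library sizes: the planted 4x shift must survive CPM
        f = sjkit.NormFactors(m.samples, np.full(6, 10**6), np.ones(6))
        lm = sjkit.log_cpm(m, f, prior_count=1e-9)
        assignment = sjkit.assign_junctions_to_genes(m, [gene])
        est = sjkit.estimate_gene_expression(m, lm, [gene])
        calls, _ = sjkit.junction_deviation_test(m, lm, est, assignment, min_count=1)
        assert np.allclose(calls["delta"], 0.0, atol=1e-9)
        assert not calls["is_called"].any()
        assert est["G"].log2fc == pytest.approx(2.0, abs=1e-6)

    def test_translation_invariance_of_delta(self, sim_small):
        # adding a constant to one condition's log-CPM for all junctions of a
        # gene moves the gene log2FC but not the deviations
        m, logmat, assignment, estimates = pipeline(sim_small)
        gene = sim_small.truth.switch_gene_ids()[0]
        rows = [
            i for i, j in enumerate(m.junctions) if assignment.get(j) == gene
        ]
        mask_b = m.sample_mask(m.conditions()[1])
        shifted = logmat.copy()
        shifted[np.ix_(rows, np.where(mask_b)[0])] += 1.7
        est2 = sjkit.estimate_gene_expression(m, shifted, sim_small.models)
        calls1, _ = sjkit.junction_deviation_test(m, logmat, estimates, assignment)
        calls2, _ = sjkit.junction_deviation_test(m, shifted, est2, assignment)
        sub1 = calls1[calls1.gene_id == gene].set_index(["start", "end"])
        sub2 = calls2[calls2.gene_id == gene].set_index(["start", "end"])
        assert np.allclose(sub1["delta"], sub2.loc[sub1.index, "delta"], atol=1e-9)
        g1 = sub1["log2fc_gene"].iloc[0]
        g2 = sub2["log2fc_gene"].iloc[0]
        assert g2 - g1 == pytest.approx(1.7, abs=1e-9)

    def test_null_type_one_error_is_nominal(self):
        config = sjkit.SimConfig(seed=1, n_genes=200, n_switch=0, n_de=0)
        result = sjkit.simulate_study(config)
        m, logmat, assignment, estimates = pipeline(result)
        calls, _ = sjkit.junction_deviation_test(m, logmat, estimates, assignment)
        frac = float((calls["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_ambiguous_junctions_go_to_sidecar(self, sim_small):
        m, logmat, assignment, estimates = pipeline(sim_small)
        j = m.junctions[0]
        assignment = dict(assignment)
        assignment[j] = sjkit.AMBIGUOUS
        calls, side = sjkit.junction_deviation_test(m, logmat, estimates, assignment)
        assert ((side.start == j.start) & (side.end == j.end)).any()
        assert not ((calls.start == j.start) & (calls.end == j.end)).any()

    def test_single_replicate_reports_delta_only(self):
        design = [sjkit.SampleDesign("a", "A"), sjkit.SampleDesign("b", "B")]
        exons = [(i * 1000, i * 1000 + 100) for i in range(1, 5)]
        gene = sjkit.GeneModel("G", "chr1", "+", (1000, 4100), {"t": list(exons)})
        js = sjkit.derive_junctions(exons, "chr1", "+")
        counts = {d.sample_id: {j: 50 for j in js} for d in design}
        m = make_matrix(counts, design)
        f = sjkit.NormFactors(m.samples, sjkit.library_sizes(m), np.ones(2))
        lm = sjkit.log_cpm(m, f)
        est = sjkit.estimate_gene_expression(m, lm, [gene])
        calls, _ = sjkit.junction_deviation_test(
            m, lm, est, sjkit.assign_junctions_to_genes(m, [gene]), min_count=1
        )
        assert calls["p_value"].isna().all()
        assert calls["delta"].notna().all()
        assert not calls["is_called"].any()


# ---------------------------------------------------------------------------
# Splice graph and events
# ---------------------------------------------------------------------------

class TestSpliceGraphEvents:
    def test_single_junction_graph(self):
        j = sjkit.Junction("chr1", 100, 200, "+")
        g = sjkit.build_splice_graph([j])
        assert g.n_nodes == 2 and len(g.junctions) == 1

    def test_node_count_matches_distinct_coordinates(self):
        rng = np.random.default_rng(4)
        js = [
            sjkit.Junction("chr1", int(s), int(s) + int(l), "+")
            for s, l in zip(rng.integers(1, 5000, 30), rng.integers(50, 500, 30))
        ]
        g = sjkit.build_splice_graph(js)
        dedup = set(g.junctions)
        assert g.n_nodes == len({j.start for j in dedup}) + len({j.end for j in dedup})

    def test_cassette_gene_yields_one_se_event(self, three_exon_gene):
        js = sorted(
            sjkit.gene_junctions(three_exon_gene)
        )  # e1-e2, e1-e3(skip), e2-e3
        graph = sjkit.build_splice_graph(js)
        events = sjkit.detect_events(graph, three_exon_gene)
        se = [e for e in events if e.event_type == "SE"]
        assert len(se) == 1
        assert se[0].exons == ((300, 400),)
        # the same junction trio also exposes one A5SS and one A3SS pair
        assert sorted(e.event_type for e in events) == ["A3SS", "A5SS", "SE"]

    def test_shared_donor_pair_is_a3ss(self):
        model = sjkit.GeneModel(
            "G", "chr1", "+", (100, 900),
            {"t1": [(100, 200), (300, 900)], "t2": [(100, 200), (500, 900)]},
        )
        js = sorted(sjkit.gene_junctions(model))
        events = sjkit.detect_events(sjkit.build_splice_graph(js), model)
        assert [e.event_type for e in events] == ["A3SS"]
        # inclusion is the shorter intron (longer exonic form)
        assert events[0].inclusion[0].end == 299

    def test_matches_exhaustive_enumeration_on_toy_genes(self):
        config = sjkit.SimConfig(
            seed=33, n_genes=40, n_switch=0, n_de=0,
            exon_range=(3, 8), multi_exon_range=(6, 8),
        )
        models = sjkit.make_annotation(config)
        checked = 0
        for model in models:
            js = sorted(sjkit.gene_junctions(model))
            events = sjkit.detect_events(sjkit.build_splice_graph(js), model)
            got = {(e.event_type, e.inclusion, e.exclusion) for e in events}
            expected = enumerate_events_oracle(js, model)
            assert got == expected, model.gene_id
            checked += 1
        assert checked == 40

    def test_mxe_requires_annotation_exclusivity(self):
        # two cassette exons between common flanks, never co-occurring
        exons = [(100, 200), (300, 400), (500, 600), (700, 800)]
        model = sjkit.GeneModel(
            "G", "chr1", "+", (100, 800),
            {"t1": [exons[0], exons[1], exons[3]],
             "t2": [exons[0], exons[2], exons[3]]},
        )
        js = sorted(sjkit.gene_junctions(model))
        events = sjkit.detect_events(sjkit.build_splice_graph(js), model)
        mxe = [e for e in events if e.event_type == "MXE"]
        assert len(mxe) == 1
        assert mxe[0].exons == ((300, 400), (500, 600))
        # a transcript containing both exons abolishes the MXE call
        model2 = sjkit.GeneModel(
            "G", "chr1", "+", (100, 800),
            {"t1": [exons[0], exons[1], exons[3]],
             "t2": [exons[0], exons[2], exons[3]],
             "t3": list(exons)},
        )
        events2 = sjkit.detect_events(sjkit.build_splice_graph(js), model2)
        assert not [e for e in events2 if e.event_type == "MXE"]


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

class TestPSI:
    def _se_setup(self, i1, i2, s, n=1):
        design = two_condition_design(n)
        exons = [(100, 200), (300, 400), (500, 600)]
        gene = sjkit.GeneModel(
            "G", "chr1", "+", (100, 600),
            {"t1": list(exons), "t2": [exons[0], exons[2]]},
        )
        j12, j23 = sjkit.derive_junctions(exons, "chr1", "+")
        (j13,) = sjkit.derive_junctions([exons[0], exons[2]], "chr1", "+")
        counts = {
            d.sample_id: {j12: i1, j23: i2, j13: s} for d in design
        }
        m = make_matrix(counts, design)
        events = sjkit.detect_events(
            sjkit.build_splice_graph([j12, j23, j13]), gene
        )
        (se,) = [e for e in events if e.event_type == "SE"]
        return se, m

    @pytest.mark.parametrize(
        "i1,i2,s,expected",
        [
            (0, 0, 7, 0.0),  # only skipping support
            (9, 9, 0, 1.0),  # only inclusion support
            (5, 5, 5, 0.5),  # balanced: (I1+I2)/(I1+I2+2S) by direct arithmetic
            (6, 2, 4, 0.5),
            (10, 10, 5, 2 / 3),
        ],
    )
    def test_se_psi_formula(self, i1, i2, s, expected):
        se, m = self._se_setup(i1, i2, s)
        values = sjkit.psi(se, m)
        assert np.allclose(values, expected)

    def test_psi_undefined_without_support(self):
        se, m = self._se_setup(0, 0, 0)
        assert np.isnan(sjkit.psi(se, m)).all()

    def test_psi_in_unit_interval_wherever_defined(self, sim_small):
        m = sim_small.matrix
        assignment = sjkit.assign_junctions_to_genes(m, sim_small.models)
        for model in sim_small.models[:20]:
            js = [j for j, g in assignment.items() if g == model.gene_id and j in m]
            if not js:
                continue
            events = sjkit.detect_events(sjkit.build_splice_graph(js), model)
            for ev in events:
                values = sjkit.psi(ev, m)
                ok = values[~np.isnan(values)]
                assert ((ok >= 0) & (ok <= 1)).all()


# ---------------------------------------------------------------------------
# Permutation test on delta PSI
# ---------------------------------------------------------------------------

class TestDeltaPSI:
    def test_identical_psi_gives_p_one(self):
        values = np.array([0.4] * 6)
        mask = np.array([False] * 3 + [True] * 3)
        p, obs = sjkit.permutation_pvalue(values, mask)
        assert obs == 0.0 and p == 1.0

    def test_complete_separation_three_v_three_exact_p(self):
        values = np.array([0.1, 0.1, 0.1, 0.9, 0.9, 0.9])
        mask = np.array([False] * 3 + [True] * 3)
        p, obs = sjkit.permutation_pvalue(values, mask)
        assert obs == pytest.approx(0.8)
        assert p == pytest.approx(2 / math.comb(6, 3))  # = 0.1

    def test_monte_carlo_agrees_with_exact_enumeration_4v4(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 1, 8)
        values[4:] += 0.4
        mask = np.array([False] * 4 + [True] * 4)
        p_exact, _ = sjkit.permutation_pvalue(values, mask, max_exact=1000)
        p_mc, _ = sjkit.permutation_pvalue(
            values, mask, max_exact=1, n_perm=1000, seed=123
        )
        se = math.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / 1001

    def test_delta_sign_flips_with_condition_swap(self, sim_small):
        m = sim_small.matrix
        assignment = sjkit.assign_junctions_to_genes(m, sim_small.models)
        gene = sim_small.truth.switch_gene_ids()[0]
        model = next(g for g in sim_small.models if g.gene_id == gene)
        js = [j for j, g in assignment.items() if g == gene and j in m]
        events = sjkit.detect_events(sjkit.build_splice_graph(js), model)
        cond = m.conditions()
        t1 = sjkit.delta_psi_test(events, m, seed=2, conditions=(cond[0], cond[1]))
        t2 = sjkit.delta_psi_test(events, m, seed=2, conditions=(cond[1], cond[0]))
        d1 = t1["delta_psi"].to_numpy()
        d2 = t2["delta_psi"].to_numpy()
        keep = ~np.isnan(d1)
        assert np.allclose(d1[keep], -d2[keep], atol=1e-12)


# ---------------------------------------------------------------------------
# Isoform switch
# ---------------------------------------------------------------------------

class TestIsoformSwitch:
    def test_equal_counts_give_zero_delta(self, three_exon_gene):
        design = two_condition_design(2)
        diag = sjkit.diagnostic_junctions(three_exon_gene)
        ja = sorted(diag["TOY.t1"])  # two inclusion junctions
        jb = sorted(diag["TOY.t2"])  # skip junction
        counts = {d.sample_id: {j: 50 for j in ja + jb} for d in design}
        m = make_matrix(counts, design)
        call = sjkit.isoform_switch_call(three_exon_gene, m, seed=3)
        assert call.delta_proportion == pytest.approx(0.0)
        assert call.direction == "none"

    def test_proportions_match_hand_arithmetic(self, three_exon_gene):
        design = [sjkit.SampleDesign("c1", "control"), sjkit.SampleDesign("k1", "knockdown")]
        diag = sjkit.diagnostic_junctions(three_exon_gene)
        ja = sorted(diag["TOY.t1"])
        jb = sorted(diag["TOY.t2"])
        counts = {
            "c1": {ja[0]: 30, ja[1]: 30, jb[0]: 20},
            "k1": {ja[0]: 10, ja[1]: 10, jb[0]: 60},
        }
        m = make_matrix(counts, design)
        call = sjkit.isoform_switch_call(three_exon_gene, m, seed=3)
        assert call.proportion_a["control"] == pytest.approx(60 / 80)
        assert call.proportion_a["knockdown"] == pytest.approx(20 / 80)
        assert call.delta_proportion == pytest.approx(-0.5)
        assert call.direction == "TOY.t1->TOY.t2"

    def test_gls_fixture_recovers_gac_to_kga_direction(self, gls):
        model, matrix, _ = gls
        call = sjkit.isoform_switch_call(model, matrix, seed=4)
        # knockdown shifts splicing away from GAC: proportion delta < 0
        assert call.isoform_a == "GLS.GAC"
        assert call.delta_proportion < -0.2
        assert call.direction == "GLS.GAC->GLS.KGA"
        assert call.p_value <= 0.2  # 3v3 exact permutation floor is 0.1

    def test_three_diagnosable_isoforms_is_error(self):
        exons = [(i * 1000, i * 1000 + 100) for i in range(1, 6)]
        model = sjkit.GeneModel(
            "G", "chr1", "+", (1000, 5100),
            {"t1": list(exons),
             "t2": [e for i, e in enumerate(exons) if i != 1],
             "t3": [e for i, e in enumerate(exons) if i != 2]},
        )
        design = two_condition_design(1)
        js = sorted(sjkit.gene_junctions(model))
        m = make_matrix({d.sample_id: {j: 10 for j in js} for d in design}, design)
        with pytest.raises(ValueError, match="pairwise"):
            sjkit.isoform_switch_call(model, m, seed=1)

    def test_zero_denominator_is_untested(self, three_exon_gene):
        design = two_condition_design(1)
        diag = sjkit.diagnostic_junctions(three_exon_gene)
        ja = sorted(diag["TOY.t1"])
        counts = {
            "control_1": {ja[0]: 10, ja[1]: 10},
            "knockdown_1": {ja[0]: 1, ja[1]: 1},
        }
        # drop all diagnostic counts of the skip isoform AND zero out one
        # condition entirely for the pair
        counts["knockdown_1"] = {}
        m = make_matrix(counts, design)
        call = sjkit.isoform_switch_call(three_exon_gene, m, seed=1)
        assert call.direction == "untested"
        assert math.isnan(call.p_value)
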