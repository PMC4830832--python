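"""PC12 fixtures, perturbation scenarios and feedback analyses."""

import pytest

from boolfate.core import run_to_attractor
from boolfate.pc12 import (LATE_GENES, SCENARIOS, UPAR_FEEDBACK_EDGES,
                           bistability_check, differentiation_readout,
                           feedback_knockout, load_fixture,
                           load_training_foldchanges, run_scenario)


class TestFixtures:
    def test_pkn_counts(self, pc12_pkn):
        assert len(pc12_pkn.nodes) == 63
        assert len(pc12_pkn.edges) == 109

    def test_final_counts(self, final_model):
        assert final_model.n_nodes == 32
        assert len(final_model.edges()) == 52

    def test_pkn_roles(self, pc12_pkn):
        assert pc12_pkn.stimuli == ["NGF"]
        assert set(pc12_pkn.inhibited) == {"MEK", "JNK", "PI3K"}
        assert len(pc12_pkn.measured) == 27

    def test_pkn_contains_fixed_literature_edges(self, pc12_pkn):
        fixed = {(e.source, e.target) for e in pc12_pkn.fixed_edges()}
        for pair in [("NGF", "PI3K"), ("NGF", "RAS"), ("NGF", "PLC"),
                     ("AP1", "Npy"), ("Mmp10", "RAS"), ("RAS", "MEK"),
                     ("PLC", "MEK"), ("Fosl1", "AP1"), ("Jund", "AP1")]:
            assert pair in fixed

    def test_final_contains_fixed_literature_edges(self, final_model):
        edges = {(s, t) for s, _, t in final_model.edges()}
        for pair in [("NGF", "PI3K"), ("NGF", "RAS"), ("NGF", "PLC"),
                     ("AP1", "Npy"), ("Mmp10", "RAS")]:
            assert pair in edges

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            load_fixture("nope")

    def test_training_table_loads(self):
        table = load_training_foldchanges()
        assert set(table.columns) == {"node", "condition", "time_h", "value"}
        assert (table["value"] > 0).all()
        assert set(table["condition"]) == set(SCENARIOS)


class TestScenarios:
    @pytest.mark.parametrize("name,expected", [
        ("NGF", True), ("NGF+MEKi", False),
        ("NGF+JNKi", False), ("NGF+PI3Ki", True),
    ])
    def test_phenotype_table(self, name, expected):
        _, phenotype = run_scenario(name)
        assert phenotype.differentiation is expected

    def test_differentiation_node_matches_phenotype(self):
        for name in SCENARIOS:
            traj, phenotype = run_scenario(name)
            node_on = all(s["CellDifferentiation"] == 1
                          for s in traj.attractor.cycle)
            assert node_on == phenotype.differentiation

    def test_pi3ki_differs_from_ngf_only_in_pi3k_arm(self, final_model):
        ngf, _ = run_scenario("NGF")
        pi3ki, _ = run_scenario("NGF+PI3Ki")
        a, b = ngf.attractor.cycle[0], pi3ki.attractor.cycle[0]
        differing = {n for n in final_model.nodes if a[n] != b[n]}
        assert differing == {"PI3K", "AKT", "Maff", "Klf10"}

    def test_jnki_inactivates_late_targets(self):
        traj, _ = run_scenario("NGF+JNKi")
        state = traj.attractor.cycle[0]
        assert all(state[g] == 0 for g in LATE_GENES)

    def test_receptor_proximal_nodes_precede_late_genes(self):
        traj, _ = run_scenario("NGF")

        def first_on(node):
            return next((i for i, s in enumerate(traj.states) if s[node] == 1),
                        len(traj.states))

        assert first_on("RAS") < first_on("Klf5")
        assert first_on("MEK_ERK") < first_on("Npy")

    def test_transient_genes_on_then_off(self):
        traj, _ = run_scenario("NGF")
        for gene in ("Klf4", "Btg2", "Zfp36"):
            pre = [s[gene] for s in traj.states[: traj.attractor_start]]
            assert 1 in pre
            assert all(s[gene] == 0 for s in traj.attractor.cycle)

    def test_zfp36_delays_ap1(self, final_model):
        traj, _ = run_scenario("NGF")
        without = final_model.remove_edge("Zfp36", "AP1")
        traj2, _ = run_scenario("NGF", network=without)

        def first_on(t, node):
            return next(i for i, s in enumerate(t.states) if s[node] == 1)

        assert first_on(traj, "AP1") > first_on(traj2, "AP1")


class TestReadout:
    def test_all_late_plus_upar_is_differentiated(self):
        traj, _ = run_scenario("NGF")
        call = differentiation_readout(traj.attractor)
        assert call.differentiation and call.upar_active

    def test_upar_off_blocks_differentiation(self):
        traj, _ = run_scenario("NGF+MEKi")
        call = differentiation_readout(traj.attractor)
        assert not call.upar_active and not call.differentiation

    def test_exact_half_is_not_a_majority(self):
        traj, _ = run_scenario("NGF")
        # pick a 2-gene set with exactly one active under NGF+PI3Ki
        traj2, _ = run_scenario("NGF+PI3Ki")
        call = differentiation_readout(traj2.attractor,
                                       late_gene_set=("Klf5", "Klf10"))
        assert not call.differentiation

    def test_empty_late_set_rejected(self):
        traj, _ = run_scenario("NGF")
        with pytest.raises(ValueError):
            differentiation_readout(traj.attractor, late_gene_set=())


class TestFeedback:
    def test_upar_feedback_removal_blocks_differentiation(self):
        assert feedback_knockout().differentiation is False

    def test_no_removal_is_identity(self, final_model):
        _, reference = run_scenario("NGF")
        phenotype = feedback_knockout(final_model, feedback_edges=())
        assert phenotype.differentiation == reference.differentiation

    def test_off_pathway_edge_removal_leaves_phenotype(self, final_model):
        """Fos is not on any stimulus -> readout path in the final model."""
        net = final_model.remove_edge("MEK_ERK", "Fos")
        _, phenotype = run_scenario("NGF", network=net)
        assert phenotype.differentiation is True

    def test_missing_edge_rejected(self, final_model):
        with pytest.raises(Exception):
            feedback_knockout(final_model, feedback_edges=[("NGF", "Npy")])


class TestBistability:
    def test_report(self):
        report = bistability_check()
        assert report["resting_is_all_off"]
        assert report["differentiation_on"]
        assert report["memory_with_feedback"]
        assert not report["memory_without_feedback"]

    def test_resting_state_is_fixed_point(self, final_model):
        traj = run_to_attractor(final_model, {n: 0 for n in final_model.nodes})
        assert traj.attractor.is_fixed_point
        assert traj.attractor_start == 0
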