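"""Generator: tree parsing/validation, locus construction, neutral evolution,
lineage losses, truth-record consistency."""
import numpy as np
import pytest

from paleoeve import synthsim as ss
from paleoeve.models import jc_p_distance_expectation


class TestBuildHostTree:
    def test_node_ages_from_branch_lengths(self):
        tree = ss.build_host_tree("((A:102,B:102):70,C:172);")
        assert tree.root_age == pytest.approx(172.0)
        assert tree.mrca_age(["A", "B"]) == pytest.approx(102.0)
        assert tree.mrca_age(["A", "C"]) == pytest.approx(172.0)

    def test_degenerate_zero_length_tree_rejected(self):
        with pytest.raises(ss.TreeValidationError):
            ss.build_host_tree("(A:0,B:0);")

    def test_single_taxon_tree(self):
        tree = ss.build_host_tree("A;")
        assert tree.taxa == ("A",)
        assert tree.root.is_leaf

    def test_malformed_newick_reports_parse_error(self):
        with pytest.raises(ss.NewickParseError, match="Newick"):
            ss.build_host_tree("((A:1,B:1):2,C;")

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ss.TreeValidationError, match="ultrametric"):
            ss.build_host_tree("((A:10,B:50):70,C:80);")

    def test_default_tree_geometry(self, host_tree):
        assert host_tree.root_age == pytest.approx(187.0)
        assert host_tree.mrca_age(ss.DEFAULT_PLACENTALS) == pytest.approx(102.0)
        assert host_tree.mrca_age(["Homo", "Didelphis"]) == pytest.approx(172.0)

    def test_restricted_newick_roundtrip(self, host_tree):
        sub = ss.HostTree.from_newick(
            host_tree.restricted_newick(["Homo", "Mus", "Canis", "Loxodonta"]))
        assert set(sub.taxa) == {"Homo", "Mus", "Canis", "Loxodonta"}
        assert sub.mrca_age(["Homo", "Mus"]) == pytest.approx(90.0)
        assert sub.root_age == pytest.approx(102.0)


class TestAncestralLocus:
    def test_feature_layout_matches_template(self, small_config, small_template):
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=1)
        gene_feats = [f for f in anc.features if f.kind == "eve_gene"]
        assert [f.name for f in gene_feats] == ["POLB", "INT", "MCP"]
        starts = [f.start for f in gene_feats]
        assert starts == sorted(starts)
        eve = anc.feature("EVE")
        assert all(eve.start <= f.start and f.end <= eve.end for f in gene_feats)

    def test_tirs_are_reverse_complements(self, small_config, small_template):
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=1)
        t5 = anc.feature("TIR5")
        t3 = anc.feature("TIR3")
        assert (ss.reverse_complement(anc.sequence[t5.start:t5.end])
                == anc.sequence[t3.start:t3.end])

    def test_zero_tir_length_emits_no_tir_features(self, small_config):
        template = ss.EveTemplate(
            genes=(ss.GeneSpec("POLB", 50),), tir_length=0)
        anc = ss.simulate_ancestral_locus(small_config, template, seed=1)
        assert not [f for f in anc.features if f.kind == "TIR"]

    def test_landmark_orfs_are_stop_free(self, small_config, small_template):
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=3)
        for name, protein in anc.landmark_proteins.items():
            assert "*" not in protein
            feat = anc.feature(name)
            orf_aa = ss.translate_codons(anc.sequence[feat.start:feat.end])
            assert orf_aa[: len(protein)] == protein

    def test_determinism(self, small_config, small_template):
        a = ss.simulate_ancestral_locus(small_config, small_template, seed=9)
        b = ss.simulate_ancestral_locus(small_config, small_template, seed=9)
        assert a.sequence == b.sequence
        assert a.features == b.features


class TestEvolveLocus:
    def test_zero_rate_keeps_sequences_identical(self, host_tree, small_template):
        cfg = ss.SimulationConfig(seed=1, clock_rate=0.0, indel_rate_factor=0.0,
                                  flank_noncoding=200, landmark_aa_length=60,
                                  spacer_length=40, gamma_shape=None)
        anc = ss.simulate_ancestral_locus(cfg, small_template, seed=1)
        ds = ss.evolve_locus(host_tree, anc, cfg, ss.DEFAULT_PLACENTALS, seed=2)
        assert ds.sequence("Homo") == anc.sequence
        eve = anc.eve_interval
        expected_outgroup = anc.sequence[:eve[0]] + anc.sequence[eve[1]:]
        assert ds.sequence("Didelphis") == expected_outgroup

    def test_presence_restricted_to_insertion_clade(self, host_tree, small_config,
                                                    small_template):
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=1)
        ds = ss.evolve_locus(host_tree, anc, small_config, ss.DEFAULT_PLACENTALS,
                             seed=4)
        for taxon in ss.DEFAULT_PLACENTALS:
            assert ds.truth.presence[taxon]
        for taxon in ("Didelphis", "Ornithorhynchus"):
            assert not ds.truth.presence[taxon]
        assert ds.truth.insertion_child_age == pytest.approx(102.0)
        assert ds.truth.insertion_parent_age == pytest.approx(172.0)

    def test_truth_consistent_with_emitted_sequences(self, host_tree, small_config,
                                                     small_template):
        """Re-scanning each emitted sequence for EVE-derived sites agrees
        with the presence flags."""
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=1)
        ds = ss.evolve_locus(host_tree, anc, small_config, ss.DEFAULT_PLACENTALS,
                             seed=4)
        for taxon in host_tree.taxa:
            interval = ds.feature_interval(taxon, "EVE")
            assert (interval is not None) == ds.truth.presence[taxon]

    def test_jc_p_distance_matches_closed_form(self, small_template):
        """Mean p-distance between two tips at divergence T follows the
        Jukes-Cantor expectation (3/4)(1 - exp(-8 r T / 3))."""
        T, rate = 60.0, 0.0027
        tree = ss.build_host_tree(f"(A:{T},B:{T});")
        cfg = ss.SimulationConfig(seed=0, indel_rate_factor=0.0, gamma_shape=None,
                                  landmark_rate_factor=1.0, clock_rate=rate,
                                  flank_noncoding=500, landmark_aa_length=60,
                                  spacer_length=40)
        diffs, sites = [], 0
        for rep in range(50):
            anc = ss.simulate_ancestral_locus(cfg, small_template, seed=rep)
            ds = ss.evolve_locus(tree, anc, cfg, ("A", "B"), seed=1000 + rep)
            a = ds.codes["A"]
            b = ds.codes["B"]
            diffs.append((a != b).mean())
            sites = len(a)
        expected = jc_p_distance_expectation(rate, T)
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean - expected) < 3 * max(se, 1e-4), (mean, expected)

    def test_determinism_bytes(self, host_tree, small_config, small_template):
        a = ss.simulate_dataset(small_config, tree=host_tree,
                                template=small_template, seed=5)
        b = ss.simulate_dataset(small_config, tree=host_tree,
                                template=small_template, seed=5)
        assert a.sequences() == b.sequences()

    def test_unknown_insertion_clade_rejected(self, host_tree, small_config,
                                              small_template):
        anc = ss.simulate_ancestral_locus(small_config, small_template, seed=1)
        with pytest.raises(ValueError, match="insertion clade"):
            ss.evolve_locus(host_tree, anc, small_config, ("Homo", "Didelphis"),
                            seed=1)


class TestApplyLosses:
    @pytest.fixture()
    def dataset(self, host_tree, small_config, small_template):
        return ss.simulate_dataset(small_config, tree=host_tree,
                                   template=small_template, seed=11)

    def test_probability_zero_is_identity(self, dataset):
        out = ss.apply_losses(dataset, 0.0, seed=1)
        assert out.truth.presence == dataset.truth.presence
        assert not out.truth.lost

    def test_probability_one_removes_all(self, dataset):
        out = ss.apply_losses(dataset, 1.0, seed=1)
        assert not any(out.truth.presence.values())
        for taxon in dataset.tree.taxa:
            assert out.feature_interval(taxon, "EVE") is None

    def test_loss_count_matches_binomial_expectation(self, dataset):
        """Mean number of losses over many seeds sits inside the binomial
        99% interval around n*p."""
        p, n = 0.2, sum(dataset.truth.presence.values())
        losses = [len(ss.apply_losses(dataset, p, seed=s).truth.lost)
                  for s in range(200)]
        mean = np.mean(losses)
        se = np.sqrt(n * p * (1 - p) / len(losses))
        assert abs(mean - n * p) < 2.58 * se

    def test_flanks_joined_after_loss(self, dataset):
        out = ss.apply_losses(dataset, 1.0, seed=3)
        for taxon in dataset.tree.taxa:
            if dataset.truth.presence[taxon]:
                assert len(out.codes[taxon]) < len(dataset.codes[taxon])


class TestNeighborhood:
    def test_alignment_shape_and_determinism(self, host_tree):
        cfg = ss.SimulationConfig(seed=1, gamma_shape=None)
        a = ss.simulate_neighborhood(host_tree, cfg, 500, seed=3)
        b = ss.simulate_neighborhood(host_tree, cfg, 500, seed=3)
        assert a.n_columns == 500
        assert set(a.ids) == set(host_tree.taxa)
        assert a.rows == b.rows
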