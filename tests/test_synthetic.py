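"""Generator contracts: shapes, determinism, planted-effect recovery,
ledger completeness."""

import numpy as np
import pandas as pd
import pytest

from npcrosstalk.synthetic import (
    CohortConfig,
    SyntheticConfig,
    generate_disease_cohort,
    generate_neuropeptide_panel,
    generate_ppi_and_pathways,
    generate_study,
    verify_ledger,
)

from conftest import small_config


def _single_disease(seed=1, **kw):
    defaults = dict(
        seed=seed, n_genes=500, n_neuropeptides=30,
        diseases={"MDD": CohortConfig(n_case=30, n_control=33, n_batches=2)},
        n_de_up=8, n_de_down=4, n_crosstalk_planted=10,
        n_drl_pairs=3, n_predictive_np=2,
        ppi_n_nodes=100, n_planted_bridges=5, n_pathways=8, n_mixed_sets=2,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestCohortGeneration:
    def test_shape_forced_by_config(self):
        bundle, _ = generate_disease_cohort(_single_disease(seed=1), "MDD")
        assert bundle.matrix.shape == (500, 63)
        assert len(bundle.metadata) == 63
        assert set(bundle.metadata["group"]) == {"case", "control"}

    def test_null_effect_size_gives_null_fold_changes(self):
        config = _single_disease(seed=2, de_lfc=0.0, batch_shift_sd=0.0, batch_scale_sd=0.0)
        bundle, fragment = generate_disease_cohort(config, "MDD")
        planted = list(fragment.de_genes["MDD"])
        case = bundle.matrix.loc[planted, bundle.group_mask("case")].mean(axis=1)
        ctrl = bundle.matrix.loc[planted, ~bundle.group_mask("case")].mean(axis=1)
        lfc = case - ctrl
        se = 1.0 * np.sqrt(1 / 30 + 1 / 33) / np.sqrt(len(planted))
        assert abs(lfc.mean()) < 3 * se

    def test_bit_identical_under_fixed_seed(self):
        config = _single_disease(seed=3)
        b1, _ = generate_disease_cohort(config, "MDD")
        b2, _ = generate_disease_cohort(config, "MDD")
        pd.testing.assert_frame_equal(b1.matrix, b2.matrix)
        pd.testing.assert_frame_equal(b1.metadata, b2.metadata)

    def test_different_seeds_differ(self):
        b1, _ = generate_disease_cohort(_single_disease(seed=4), "MDD")
        b2, _ = generate_disease_cohort(_single_disease(seed=5), "MDD")
        assert not b1.matrix.equals(b2.matrix)

    def test_batches_balanced_across_groups(self):
        bundle, _ = generate_disease_cohort(_single_disease(seed=6), "MDD")
        tab = pd.crosstab(bundle.metadata["group"], bundle.metadata["batch"])
        # round-robin keeps group proportions within one sample per batch
        assert (tab.max(axis=1) - tab.min(axis=1) <= 1).all()

    def test_degenerate_batch_rejected(self):
        config = _single_disease(
            seed=7,
            diseases={"MDD": CohortConfig(n_case=3, n_control=1, n_batches=3)},
        )
        with pytest.raises(ValueError, match="<2 samples"):
            generate_disease_cohort(config, "MDD")

    def test_unknown_disease_rejected(self):
        with pytest.raises(KeyError):
            generate_disease_cohort(_single_disease(seed=8), "nope")

    def test_planted_de_lfc_recovered(self):
        config = _single_disease(seed=9, batch_shift_sd=0.0, batch_scale_sd=0.0)
        bundle, fragment = generate_disease_cohort(config, "MDD")
        for gene, sign in list(fragment.de_genes["MDD"].items())[:5]:
            case = bundle.matrix.loc[gene, bundle.group_mask("case")].mean()
            ctrl = bundle.matrix.loc[gene, ~bundle.group_mask("case")].mean()
            assert case - ctrl == pytest.approx(sign * 2.0, abs=0.8)


class TestNeuropeptidePanel:
    def test_default_panel_size_102(self):
        panel = generate_neuropeptide_panel(SyntheticConfig(seed=0))
        assert len(panel.genes) == 102

    def test_panel_disjoint_from_background_de(self):
        config = _single_disease(seed=10)
        panel = generate_neuropeptide_panel(config)
        _, fragment = generate_disease_cohort(config, "MDD")
        assert not set(panel.genes) & set(fragment.de_genes["MDD"])
        assert not set(panel.genes) & set(fragment.crosstalk)

    def test_panel_not_group_shifted_except_predictive(self):
        config = _single_disease(seed=11, batch_shift_sd=0.0, batch_scale_sd=0.0)
        bundle, fragment = generate_disease_cohort(config, "MDD")
        panel = generate_neuropeptide_panel(config)
        special = set(fragment.predictive_np)
        plain = [g for g in panel.genes if g not in special][:10]
        case_mask = bundle.group_mask("case")
        for gene in plain:
            diff = (
                bundle.matrix.loc[gene, case_mask].mean()
                - bundle.matrix.loc[gene, ~case_mask].mean()
            )
            assert abs(diff) < 1.5  # no planted shift; sampling noise only
        for gene in special:
            diff = (
                bundle.matrix.loc[gene, case_mask].mean()
                - bundle.matrix.loc[gene, ~case_mask].mean()
            )
            assert diff == pytest.approx(2.0, abs=1.0)

    def test_coupled_pair_slopes_recovered_by_refit(self):
        config = _single_disease(
            seed=12, drl_noise_sd=0.1, drl_beta_case=1.5, drl_beta_control=-0.5,
            diseases={"MDD": CohortConfig(n_case=60, n_control=60, n_batches=1)},
            batch_shift_sd=0.0, batch_scale_sd=0.0,
        )
        bundle, fragment = generate_disease_cohort(config, "MDD")
        case_mask = bundle.group_mask("case")
        for pair in fragment.drl_pairs:
            x = bundle.matrix.loc[pair["crosstalk"]].to_numpy()
            y = bundle.matrix.loc[pair["neuropeptide"]].to_numpy()
            for mask, expected in ((case_mask, 1.5), (~case_mask, -0.5)):
                slope = np.polyfit(x[mask], y[mask], 1)[0]
                assert slope == pytest.approx(expected, abs=0.15)

    def test_uncoupled_panel_has_no_strong_case_correlations(self):
        # batch-free: batch shifts induce real gene-gene correlations in raw
        # data, the independence null applies to batch-corrected expression
        config = _single_disease(seed=13, n_drl_pairs=0,
                                 batch_shift_sd=0.0, batch_scale_sd=0.0)
        bundle, fragment = generate_disease_cohort(config, "MDD")
        panel = generate_neuropeptide_panel(config)
        case = bundle.matrix.loc[:, bundle.group_mask("case")]
        crosstalk = list(fragment.crosstalk)
        corr = np.corrcoef(
            np.vstack([case.loc[crosstalk].to_numpy(), case.loc[list(panel.genes)].to_numpy()])
        )
        block = corr[: len(crosstalk), len(crosstalk):]
        # null |r|>0.5 at n=30 has probability ~0.005 per pair
        assert (np.abs(block) > 0.5).mean() < 0.02

    def test_invalid_coupling_rejected(self):
        config = _single_disease(seed=14)
        panel = generate_neuropeptide_panel(config)
        with pytest.raises(ValueError, match="not a planted crosstalk gene"):
            generate_neuropeptide_panel(
                config, couplings=[("G0001_NOT_PLANTED", panel.genes[0], 1.0, -1.0)]
            )


class TestPPIAndPathways:
    def _roles(self, config):
        from npcrosstalk.synthetic import _study_design

        design = _study_design(config)
        roles = {g: "crosstalk" for g in design.crosstalk}
        roles.update({g: "neuropeptide" for g in design.panel.genes})
        return roles

    def test_no_direct_cross_np_edges(self):
        config = small_config(seed=15, ppi_edge_prob=0.1)
        roles = self._roles(config)
        graph, _, _ = generate_ppi_and_pathways(config, roles)
        cs = {g for g, r in roles.items() if r == "crosstalk"}
        ns = {g for g, r in roles.items() if r == "neuropeptide"}
        for a, b in graph.edges:
            assert not ((a in cs and b in ns) or (b in cs and a in ns))

    def test_empty_graph_without_planted_edges(self):
        config = small_config(seed=16, ppi_edge_prob=0.0, n_planted_bridges=0)
        graph, _, _ = generate_ppi_and_pathways(config, self._roles(config))
        assert graph.number_of_edges() == 0

    def test_invalid_edge_prob(self):
        with pytest.raises(ValueError, match="edge_prob"):
            small_config(seed=17, ppi_edge_prob=1.5)

    def test_mixed_pathways_contain_both_roles(self):
        config = small_config(seed=18)
        roles = self._roles(config)
        _, pathways, ledger = generate_ppi_and_pathways(config, roles)
        cs = {g for g, r in roles.items() if r == "crosstalk"}
        ns = {g for g, r in roles.items() if r == "neuropeptide"}
        for name in ledger.mixed_pathways:
            members = set(pathways[name])
            assert members & cs and members & ns
        for name, members in pathways.items():
            if name not in ledger.mixed_pathways:
                assert not set(members) & ns

    def test_unknown_role_gene_rejected(self):
        config = small_config(seed=19)
        with pytest.raises(ValueError, match="unknown gene"):
            generate_ppi_and_pathways(config, {"NOT_A_GENE": "crosstalk"})


class TestStudyLevel:
    def test_ledger_resolves_and_study_deterministic(self):
        config = small_config(seed=20)
        study = generate_study(config)
        verify_ledger(study)
        study2 = generate_study(config)
        for disease in study.bundles:
            pd.testing.assert_frame_equal(
                study.bundles[disease].matrix, study2.bundles[disease].matrix
            )
        assert sorted(study.graph.edges) == sorted(study2.graph.edges)
        assert study.pathways == study2.pathways
        assert study.ledger.to_dict() == study2.ledger.to_dict()

    def test_crosstalk_planted_in_both_diseases(self):
        study = generate_study(small_config(seed=21))
        for disease, signs in study.ledger.de_genes.items():
            for gene in study.ledger.crosstalk:
                assert gene in signs

    def test_config_validation(self):
        with pytest.raises(ValueError):
            small_config(n_crosstalk_planted=100)  # exceeds DE genes
        with pytest.raises(ValueError):
            small_config(n_drl_pairs=20, n_predictive_np=20)  # exceeds panel
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=50, n_neuropeptides=102)
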