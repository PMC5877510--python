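"""Synthetic evidence generator: determinism, faithfulness, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanohazard.bn import BNError, build_network, infer_posterior
from nanohazard.bn.network import DiscreteBayesNet
from nanohazard.loe import MISSING
from nanohazard.scoring import hazard_score
from nanohazard.synthetic import (
    GeneratorConfig,
    default_ground_truth,
    full_joint,
    generate,
    oracle_bayes_accuracy,
)


@pytest.fixture(scope="module")
def bundle():
    return generate(GeneratorConfig(seed=123))


class TestGeneration:
    def test_identical_seed_reproduces_the_bundle_exactly(self, bundle):
        again = generate(GeneratorConfig(seed=123))
        pd.testing.assert_frame_equal(bundle.train, again.train)
        pd.testing.assert_frame_equal(bundle.test, again.test)
        for nm in bundle.woe_tables:
            assert bundle.woe_tables[nm].records == again.woe_tables[nm].records

    def test_zero_missingness_leaves_no_gaps(self):
        cfg = GeneratorConfig(seed=1, missingness=0.0, test_missingness=0.0,
                              cases_per_nm=30, test_per_nm=5)
        b = generate(cfg)
        assert not (b.train == MISSING).any().any()
        assert not (b.test == MISSING).any().any()

    def test_train_and_test_sizes_follow_config(self, bundle):
        assert len(bundle.train) == 3 * 75
        assert len(bundle.test) == 3 * 14
        assert set(bundle.woe_tables) == {"NM_low", "NM_mid", "NM_high"}

    def test_missingness_rate_is_roughly_respected(self, bundle):
        inputs = bundle.truth.config.input_nodes
        rate = (bundle.train[inputs] == MISSING).to_numpy().mean()
        assert rate == pytest.approx(0.2, abs=0.04)

    def test_hazard_marginals_match_enumeration_at_scale(self):
        """10,000 sampled cases per NM reproduce the exact conditional
        hazard marginal within +/-0.02."""
        cfg = GeneratorConfig(seed=9, cases_per_nm=10_000, test_per_nm=1,
                              missingness=0.0)
        b = generate(cfg)
        for nm, marginal in b.truth.hazard_marginals.items():
            sub = b.train[b.train["nanoparticle"] == nm]
            freq = (
                sub["hazard"].value_counts(normalize=True)
                .reindex(cfg.ground_truth.nodes["hazard"].states)
                .fillna(0.0)
                .to_numpy()
            )
            assert np.abs(freq - marginal).max() < 0.02

    def test_sampled_joint_passes_chi_squared_goodness_of_fit(self):
        cfg = GeneratorConfig(seed=21, cases_per_nm=3334, test_per_nm=1,
                              missingness=0.0)
        b = generate(cfg)
        names, joint = full_joint(cfg.ground_truth)
        states = {n: cfg.ground_truth.nodes[n].states for n in names}
        observed = np.zeros(joint.shape)
        idx = {n: {s: i for i, s in enumerate(states[n])} for n in names}
        for _, row in b.train.iterrows():
            observed[tuple(idx[n][row[n]] for n in names)] += 1
        expected = joint * observed.sum()
        keep = expected.ravel() > 5  # standard cell-count rule
        chi2 = ((observed.ravel()[keep] - expected.ravel()[keep]) ** 2
                / expected.ravel()[keep]).sum()
        pvalue = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pvalue > 0.01

    def test_tox_assignments_concentrate_on_the_true_hazard_class(self, bundle):
        cfg = bundle.truth.config
        class_map = cfg.class_map
        hits = total = 0
        for table in bundle.woe_tables.values():
            for rec in table.records:
                if rec.hazard_label == MISSING:
                    continue
                hits += int(np.argmax(rec.tox.as_array) == class_map[rec.hazard_label])
                total += 1
        assert hits / total > 0.6  # concentration 8 vs 1 dominates most draws

    def test_infeasible_nm_conditioning_raises(self):
        net = default_ground_truth()
        cpt = net.cpts["nanoparticle"].copy()
        cpt[:] = [0.5, 0.5, 0.0]
        net.set_cpt("nanoparticle", cpt)
        with pytest.raises(BNError, match="zero prior"):
            generate(GeneratorConfig(ground_truth=net, seed=0,
                                     cases_per_nm=5, test_per_nm=1))


class TestOracleAccuracy:
    def test_deterministic_net_is_perfectly_predictable(self):
        net = build_network(
            {
                "nodes": [
                    {"name": "nanoparticle", "states": ["NM_a", "NM_b"]},
                    {"name": "hazard", "states": ["None", "High"],
                     "category": "hazard"},
                ],
                "edges": [["nanoparticle", "hazard"]],
                "cpts": {"nanoparticle": [0.5, 0.5],
                         "hazard": [[1.0, 0.0], [0.0, 1.0]]},
            }
        )
        cfg = GeneratorConfig(ground_truth=net, seed=0, test_missingness=0.0,
                              cases_per_nm=5, test_per_nm=1)
        assert oracle_bayes_accuracy(cfg) == pytest.approx(1.0)

    def test_uninformative_inputs_leave_the_modal_prior(self):
        net = build_network(
            {
                "nodes": [
                    {"name": "nanoparticle", "states": ["NM_a", "NM_b"]},
                    {"name": "hazard",
                     "states": ["None", "Low", "Medium", "High"],
                     "category": "hazard"},
                ],
                "edges": [],
                "cpts": {"nanoparticle": [0.5, 0.5],
                         "hazard": [0.4, 0.3, 0.2, 0.1]},
            }
        )
        cfg = GeneratorConfig(ground_truth=net, seed=0, cases_per_nm=5,
                              test_per_nm=1)
        assert oracle_bayes_accuracy(cfg) == pytest.approx(0.4)

    def test_default_conditions_beat_the_no_input_baseline(self):
        cfg = GeneratorConfig(seed=0)
        acc = oracle_bayes_accuracy(cfg)
        # best blind guess: modal P(hazard | NM), averaged over NMs
        blind = np.mean(
            [m.max() for m in
             generate(GeneratorConfig(seed=0, cases_per_nm=1, test_per_nm=1)
                      ).truth.hazard_marginals.values()]
        )
        assert acc > blind


class TestPipelineClosure:
    def test_woe_scores_rank_nanomaterials_like_the_true_marginals(self, bundle):
        scores = {
            nm: hazard_score(table, rules=bundle.truth.rules).v
            for nm, table in bundle.woe_tables.items()
        }
        assert scores["NM_low"] < scores["NM_mid"] < scores["NM_high"]

    def test_em_training_recovers_the_nm_hazard_ordering(self, bundle):
        from nanohazard.bn import learn_parameters_em, normalized_hazard_score

        truth = bundle.truth
        blank = DiscreteBayesNet(
            list(truth.net.nodes.values()), list(truth.net.graph.edges)
        )
        fitted = learn_parameters_em(blank, bundle.train).net
        scores = {
            nm: normalized_hazard_score(
                infer_posterior(fitted, {"nanoparticle": nm}, "hazard")
            )
            for nm in bundle.woe_tables
        }
        assert scores["NM_low"] < scores["NM_mid"] < scores["NM_high"]
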