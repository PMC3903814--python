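import itertools

import numpy as np
import pytest

from mutorder import (MISSING, CoalescentConfig, ErrorRates, GenotypeMatrix,
                      OrderRelation, classify_all_pairs, estimate_priors,
                      pair_loglik, pair_observation_prob, pair_posterior,
                      relation_cell_prob)

F, B, I = (OrderRelation.FORWARD, OrderRelation.BACKWARD,
           OrderRelation.INDEPENDENT)


@pytest.fixture(scope="module")
def toy_prior():
    return estimate_priors(CoalescentConfig(7, 0.6, 60, 400, seed=23))


def brute_force_posteriors(m, x, y, prior, e):
    """Independent oracle: enumerate every true-genotype assignment of the
    jointly observed cells and sum the joint probability per relation."""
    xi, yi = m.site_index(x), m.site_index(y)
    obs = [(int(a), int(b)) for a, b in zip(m.calls[xi], m.calls[yi])
           if a != MISSING and b != MISSING]
    joint = np.zeros(3)
    for rel in (F, B, I):
        total = 0.0
        for truth in itertools.product(itertools.product((0, 1), (0, 1)),
                                       repeat=len(obs)):
            w = 1.0
            for tp, op in zip(truth, obs):
                w *= prior.cond_genotype[rel][tp] * \
                    pair_observation_prob(e, tp, op)
            total += w
        joint[rel] = total * prior.order_prior[rel]
    return joint / joint.sum()


class TestRelationCellProb:
    def test_impossible_cells_without_errors(self, toy_prior, no_errors):
        assert relation_cell_prob((0, 1), F, toy_prior, no_errors) == 0.0
        assert relation_cell_prob((1, 0), B, toy_prior, no_errors) == 0.0
        assert relation_cell_prob((1, 1), I, toy_prior, no_errors) == 0.0

    def test_cells_normalize(self, toy_prior, default_errors):
        for rel in (F, B, I):
            total = sum(relation_cell_prob((i, j), rel, toy_prior,
                                           default_errors)
                        for i in range(3) for j in range(3))
            assert total == pytest.approx(1.0)


class TestPairLoglik:
    def test_duplicating_cells_doubles_loglik(self, toy_prior,
                                              default_errors):
        m1 = GenotypeMatrix(["x", "y"], ["a", "b"],
                            np.array([[0, 1], [1, 1]], dtype=np.int8))
        m2 = GenotypeMatrix(["x", "y"], ["a", "b", "c", "d"],
                            np.array([[0, 1, 0, 1], [1, 1, 1, 1]],
                                     dtype=np.int8))
        for rel in (F, B, I):
            ll1 = pair_loglik(m1, "x", "y", rel, toy_prior, default_errors)
            ll2 = pair_loglik(m2, "x", "y", rel, toy_prior, default_errors)
            assert ll2 == pytest.approx(2 * ll1)

    def test_toy_data_excludes_forward_without_errors(self, toy_two_sites,
                                                      toy_prior, no_errors):
        # observed (0,1) cells are incompatible with x -> y
        ll = pair_loglik(toy_two_sites, "x", "y", F, toy_prior, no_errors)
        assert ll == -np.inf

    def test_single_cell_equals_cell_log_prob(self, toy_prior,
                                              default_errors):
        m = GenotypeMatrix(["x", "y"], ["a"],
                           np.array([[0], [0]], dtype=np.int8))
        for rel in (F, B, I):
            assert pair_loglik(m, "x", "y", rel, toy_prior,
                               default_errors) == pytest.approx(
                np.log(relation_cell_prob((0, 0), rel, toy_prior,
                                          default_errors)))

    def test_no_joint_observation_is_an_error(self, toy_prior,
                                              default_errors):
        m = GenotypeMatrix(["x", "y"], ["a", "b"],
                           np.array([[0, MISSING], [MISSING, 1]],
                                    dtype=np.int8))
        with pytest.raises(ValueError, match="'x'.*'y'"):
            pair_loglik(m, "x", "y", F, toy_prior, default_errors)


class TestPairPosterior:
    def test_toy_data_backward_is_map(self, toy_two_sites, toy_prior,
                                      default_errors):
        # carriers of x are a subset of carriers of y: y is ancestral
        r = pair_posterior(toy_two_sites, "x", "y", toy_prior,
                           default_errors)
        assert r.map_relation is B
        assert r.posterior.sum() == pytest.approx(1.0)
        assert r.n_used == 7

    def test_disjoint_carriers_are_independent(self, toy_prior, no_errors):
        calls = np.array([[1, 1, 0, 0, 0, 0],
                          [0, 0, 1, 1, 0, 0]], dtype=np.int8)
        m = GenotypeMatrix(["x", "y"], [f"c{i}" for i in range(6)], calls)
        r = pair_posterior(m, "x", "y", toy_prior, no_errors)
        assert r.map_relation is I

    def test_matches_brute_force_enumeration(self, toy_prior):
        e = ErrorRates(0.05, 0.3, 0.02)
        rng = np.random.default_rng(29)
        for _ in range(10):
            calls = rng.integers(0, 3, size=(2, 3)).astype(np.int8)
            m = GenotypeMatrix(["x", "y"], ["a", "b", "c"], calls)
            r = pair_posterior(m, "x", "y", toy_prior, e)
            expected = brute_force_posteriors(m, "x", "y", toy_prior, e)
            np.testing.assert_allclose(r.posterior, expected, atol=1e-12)


class TestClassifyAllPairs:
    def test_pair_count_on_fixture(self, table1, small_prior,
                                   default_errors):
        pm = classify_all_pairs(table1, small_prior, default_errors)
        assert len(pm.pairs) == 18 * 17 // 2 == 153
        for _, _, r in pm.iter_canonical():
            assert not r.unclassifiable
            assert r.posterior.sum() == pytest.approx(1.0)

    def test_two_site_matrix_single_pair(self, toy_two_sites, toy_prior,
                                         default_errors):
        pm = classify_all_pairs(toy_two_sites, toy_prior, default_errors)
        assert len(pm.pairs) == 1

    def test_antisymmetry_of_orientations(self, table1, small_prior,
                                          default_errors):
        pm = classify_all_pairs(table1, small_prior, default_errors)
        labels = table1.site_labels
        for x, y in [(0, 5), (3, 11), (2, 17)]:
            fwd = pm.result(labels[x], labels[y])
            rev = pm.result(labels[y], labels[x])
            assert fwd.posterior[F] == rev.posterior[B]
            assert fwd.posterior[I] == rev.posterior[I]
            assert fwd.map_relation == rev.map_relation.reverse()

    def test_invariant_under_sample_permutation(self, small_prior,
                                                default_errors):
        rng = np.random.default_rng(31)
        calls = rng.choice([MISSING, 0, 1, 2], size=(4, 58),
                           p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        m = GenotypeMatrix(list("wxyz"), [f"c{i}" for i in range(58)], calls)
        perm = rng.permutation(58)
        mp = GenotypeMatrix(list("wxyz"), [m.sample_ids[i] for i in perm],
                            calls[:, perm])
        a = classify_all_pairs(m, small_prior, default_errors)
        b = classify_all_pairs(mp, small_prior, default_errors)
        for key in a.pairs:
            np.testing.assert_array_equal(a.pairs[key].posterior,
                                          b.pairs[key].posterior)

    def test_unobserved_pair_flagged_not_dropped(self, toy_prior,
                                                 default_errors):
        calls = np.array([[0, MISSING, 1],
                          [MISSING, 1, MISSING],
                          [1, 0, 1]], dtype=np.int8)
        m = GenotypeMatrix(list("abc"), ["c1", "c2", "c3"], calls)
        pm = classify_all_pairs(m, toy_prior, default_errors)
        r = pm.pairs[(0, 1)]
        assert r.unclassifiable and r.n_used == 0
        assert not pm.pairs[(0, 2)].unclassifiable

    def test_export_round_trip(self, toy_two_sites, toy_prior,
                               default_errors, tmp_path):
        pm = classify_all_pairs(toy_two_sites, toy_prior, default_errors)
        pm.to_tsv(tmp_path / "pm.tsv")
        lines = (tmp_path / "pm.tsv").read_text().splitlines()
        assert len(lines) == 2  # header + 1 pair
        recs = pm.to_records()
        assert recs[0]["map_relation"] == "BACKWARD"
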