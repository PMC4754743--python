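"""Within/between score components, combination, and new-entity scoring."""

from __future__ import annotations

import numpy as np
import pytest

from wbsmda.network import MiRNADiseaseNetwork
from wbsmda.scoring import (
    ScoreComponents,
    combine_components,
    score_matrix,
    score_new_disease,
    score_new_mirna,
    within_between_components,
)
from wbsmda.similarity import SimilarityMatrix

from conftest import (
    brute_force_components,
    brute_force_score_matrix,
    random_network,
    random_similarity,
)


def net_from(A, d_prefix="d", m_prefix="m"):
    A = np.asarray(A)
    return MiRNADiseaseNetwork(
        [f"{d_prefix}{i}" for i in range(A.shape[0])],
        [f"{m_prefix}{j}" for j in range(A.shape[1])],
        A,
    )


@pytest.fixture
def toy():
    """d0-{m0,m1}, d1-{m1}; SM/SD with distinct off-diagonal values."""
    net = net_from([[1, 1, 0], [0, 1, 0]])
    SM = SimilarityMatrix.from_values(
        net.mirna_ids,
        np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.3], [0.2, 0.3, 1.0]]),
    )
    SD = SimilarityMatrix.from_values(
        net.disease_ids, np.array([[1.0, 0.4], [0.4, 1.0]])
    )
    return net, SM, SD


class TestWithinBetweenComponents:
    def test_toy_enumeration(self, toy):
        net, SM, SD = toy
        c = within_between_components(net, SM, SD, "d1", "m0")
        # miRNA within group of d1 = {m1}; between = {m2}
        assert c.ws_m == pytest.approx(0.6)
        assert c.bs_m == pytest.approx(0.2)
        # disease within group of m0 = {d0}; between empty (only d1, excluded)
        assert c.ws_d == pytest.approx(0.4)
        assert c.bs_d == 0.0 and c.bs_d_empty

    def test_self_exclusion_for_known_pair(self, toy):
        net, SM, SD = toy
        c = within_between_components(net, SM, SD, "d0", "m1")
        # m1 is associated with d0 but must not appear in its own groups:
        # within group of d0 excluding m1 = {m0}
        assert c.ws_m == pytest.approx(0.6)
        # between = {m2}
        assert c.bs_m == pytest.approx(0.3)

    def test_disease_without_mirnas_flags_empty_within(self):
        net = net_from([[0, 0], [1, 1]])
        SM = random_similarity(np.random.default_rng(0), net.mirna_ids)
        SD = random_similarity(np.random.default_rng(1), net.disease_ids)
        c = within_between_components(net, SM, SD, "d0", "m0")
        assert c.ws_m == 0.0 and c.ws_m_empty

    def test_unknown_identifier_rejected(self, toy):
        net, SM, SD = toy
        with pytest.raises(KeyError, match="unknown"):
            within_between_components(net, SM, SD, "d9", "m0")


class TestCombineComponents:
    def test_balanced_components_give_half(self):
        c = ScoreComponents(0.3, 0.3, 0.7, 0.7)
        assert combine_components(c, "ratio") == pytest.approx(0.5)

    def test_hand_computed_ratio(self):
        c = ScoreComponents(0.8, 0.2, 0.6, 0.4)
        assert combine_components(c, "ratio") == pytest.approx(0.7)
        assert combine_components(c, "difference") == pytest.approx(0.4)

    def test_all_zero_components(self):
        c = ScoreComponents(0, 0, 0, 0, True, True, True, True)
        assert combine_components(c, "ratio") == 0.0
        assert combine_components(c, "difference") == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            combine_components(ScoreComponents(0, 0, 0, 0), "product")


class TestScoreMatrix:
    @pytest.mark.parametrize("mode", ["ratio", "difference"])
    def test_matches_brute_force_on_random_networks(self, mode):
        """Exact agreement with direct set enumeration, 50 random networks."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            nd, nm = int(rng.integers(2, 11)), int(rng.integers(2, 16))
            net = random_network(rng, nd, nm, density=float(rng.uniform(0.1, 0.6)))
            SM = random_similarity(rng, net.mirna_ids)
            SD = random_similarity(rng, net.disease_ids)
            got = score_matrix(net, SM, SD, mode)
            expected = brute_force_score_matrix(net, SM, SD, mode)
            np.testing.assert_array_equal(got, expected)

    def test_matches_componentwise_combination(self, toy):
        net, SM, SD = toy
        S = score_matrix(net, SM, SD, "ratio")
        for i, d in enumerate(net.disease_ids):
            for j, m in enumerate(net.mirna_ids):
                c = within_between_components(net, SM, SD, d, m)
                assert S[i, j] == combine_components(c, "ratio")

    def test_ratio_scores_bounded(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 6, 9)
        SM = random_similarity(rng, net.mirna_ids)
        SD = random_similarity(rng, net.disease_ids)
        S = score_matrix(net, SM, SD, "ratio")
        assert (S >= 0).all() and (S <= 1).all()
        D = score_matrix(net, SM, SD, "difference")
        assert (D >= -1).all() and (D <= 1).all()

    def test_permutation_equivariance(self, toy):
        net, SM, SD = toy
        S = score_matrix(net, SM, SD)
        perm = [2, 0, 1]
        net_p = MiRNADiseaseNetwork(
            net.disease_ids, [net.mirna_ids[p] for p in perm], net.A[:, perm]
        )
        SM_p = SimilarityMatrix.from_values(
            net_p.mirna_ids, SM.values[np.ix_(perm, perm)]
        )
        S_p = score_matrix(net_p, SM_p, SD)
        np.testing.assert_allclose(S_p, S[:, perm])

    def test_without_self_exclusion_between_degenerates(self, toy):
        """SM(j, j) = 1, so including the candidate in its own between group
        would force bs_m = 1 for every unknown pair; the implementation must
        differ from that degenerate variant."""
        net, SM, SD = toy

        def degenerate(i, j):
            within = [k for k in range(net.nm) if net.A[i, k] == 1]
            between = [k for k in range(net.nm) if net.A[i, k] == 0]  # keeps j
            ws = max((SM.values[j][k] for k in within), default=0.0)
            bs = max((SM.values[j][k] for k in between), default=0.0)
            return ws, bs

        # unknown pair (d1, m2): degenerate between-score hits SM(m2, m2) = 1
        _, bs_deg = degenerate(1, 2)
        assert bs_deg == 1.0
        c = within_between_components(net, SM, SD, "d1", "m2")
        assert c.bs_m < 1.0

    def test_raising_within_similarity_never_decreases_score(self, toy):
        net, SM, SD = toy
        base = score_matrix(net, SM, SD, "ratio")[1, 0]  # pair (d1, m0)
        vals = SM.values.copy()
        vals[0, 1] = vals[1, 0] = 0.9  # m1 is in the within group of (d1, m0)
        bumped = score_matrix(
            net, SimilarityMatrix.from_values(net.mirna_ids, vals), SD, "ratio"
        )[1, 0]
        assert bumped >= base


class TestNewEntityScoring:
    def test_new_disease_enumeration(self):
        # dn is a zero row; m0 associated only with d1
        net = net_from([[0, 0], [1, 0], [0, 1]])
        SD = SimilarityMatrix.from_values(
            net.disease_ids,
            np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]]),
        )
        scores = score_new_disease(net, SD, "d0")
        # m0: within = {d1} -> 0.9, between = {d2} -> 0.1
        assert scores[0] == pytest.approx(0.9 / (0.9 + 0.1))
        # m1: within = {d2} -> 0.1, between = {d1} -> 0.9
        assert scores[1] == pytest.approx(0.1 / (0.1 + 0.9))

    def test_new_disease_against_unassociated_mirna_scores_zero(self):
        net = net_from([[0, 0], [1, 0]])
        SD = random_similarity(np.random.default_rng(0), net.disease_ids)
        scores = score_new_disease(net, SD, "d0")
        assert scores[1] == 0.0  # m1 has no known diseases at all

    def test_uniform_similarity_gives_equal_scores(self):
        net = net_from([[0, 0, 0], [1, 0, 1], [0, 1, 0]])
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        SD = SimilarityMatrix.from_values(net.disease_ids, vals)
        scores = score_new_disease(net, SD, "d0")
        assert len(set(np.round(scores, 12))) == 1

    def test_disease_with_associations_rejected(self, toy):
        net, _, SD = toy
        with pytest.raises(ValueError, match="known associations"):
            score_new_disease(net, SD, "d0")

    @pytest.mark.parametrize("mode", ["ratio", "difference"])
    def test_transpose_symmetry(self, mode):
        """score_new_mirna equals score_new_disease on the transposed network."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            net = random_network(rng, 5, 7)
            j = int(rng.integers(net.nm))
            net.A[:, j] = 0
            if net.A.sum() == 0:
                net.A[0, (j + 1) % net.nm] = 1
            net = MiRNADiseaseNetwork(net.disease_ids, net.mirna_ids, net.A)
            SM = random_similarity(rng, net.mirna_ids)
            got = score_new_mirna(net, SM, net.mirna_ids[j], mode)
            expected = score_new_disease(
                net.transpose(), SM, net.mirna_ids[j], mode
            )
            np.testing.assert_array_equal(got, expected)

    def test_new_mirna_with_associations_rejected(self, toy):
        net, SM, _ = toy
        with pytest.raises(ValueError, match="known associations"):
            score_new_mirna(net, SM, "m1")
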