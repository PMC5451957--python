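"""Profile-regression sampler and summaries at unit scale."""

import numpy as np
import pandas as pd
import pytest

from profilemix import bpr, datagen
from profilemix.bpr.model import MCMCDraws


def _draws_from_allocations(Z, theta=None):
    """Minimal MCMCDraws wrapper around hand-written allocation draws."""
    Z = np.asarray(Z, dtype=np.int16)
    D, n = Z.shape
    C = int(Z.max()) + 1
    return MCMCDraws(
        allocations=Z,
        theta=np.asarray(theta, dtype=float) if theta is not None else None,
        beta=np.zeros((D, 0)) if theta is not None else None,
        sigma=np.ones(D) if theta is not None else None,
        alpha=np.ones(D),
        zeta=None,
        phi=np.full((D, C, 1, 2), 0.5, dtype=np.float32),
        subject_ids=[str(i) for i in range(n)],
        pesticide_names=["p1"],
        confounder_names=[],
        confounder_means={},
        outcome_included=theta is not None,
        K=2,
        rho=np.full((1, 2), 0.5),
        max_occupied=C - 1,
        acceptance={},
    )


class TestSimilarity:
    def test_single_draw_matches_partition_exactly(self):
        d = _draws_from_allocations([[0, 0, 1, 1, 2]])
        S = bpr.similarity(d)
        expected = np.array(
            [[1, 1, 0, 0, 0], [1, 1, 0, 0, 0], [0, 0, 1, 1, 0],
             [0, 0, 1, 1, 0], [0, 0, 0, 0, 1]], dtype=float
        )
        assert np.array_equal(S, expected)

    def test_diagonal_is_one_and_symmetric(self, rng):
        Z = rng.integers(0, 4, size=(50, 12))
        S = bpr.similarity(_draws_from_allocations(Z))
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T)

    def test_label_permutation_invariance(self, rng):
        Z = rng.integers(0, 4, size=(30, 10))
        S1 = bpr.similarity(_draws_from_allocations(Z))
        perm = rng.permutation(8)
        S2 = bpr.similarity(_draws_from_allocations(perm[Z]))
        assert np.allclose(S1, S2)


class TestBestPartition:
    def test_perfect_block_similarity_recovers_blocks(self):
        z = np.array([0, 0, 0, 1, 1, 1])
        S = (z[:, None] == z[None, :]).astype(float)
        d = _draws_from_allocations([z, [0, 1, 2, 3, 4, 5]])
        best = bpr.best_partition(S, d)
        assert len(np.unique(best)) == 2
        assert (best[:3] == best[0]).all() and (best[3:] == best[3]).all()

    def test_all_ones_similarity_gives_single_cluster(self):
        S = np.ones((5, 5))
        d = _draws_from_allocations([[0, 0, 0, 0, 0], [0, 1, 0, 1, 0]])
        assert len(np.unique(bpr.best_partition(S, d))) == 1

    def test_default_method_matches_exhaustive_rescoring(self, rng):
        # criterion value of the selected draw equals the exhaustive minimum
        n = 7
        Z = rng.integers(0, 3, size=(40, n))
        S = bpr.similarity(_draws_from_allocations(Z))
        best = bpr.best_partition(S, _draws_from_allocations(Z))

        def score(z):
            eq = (z[:, None] == z[None, :]).astype(float)
            return ((eq - S) ** 2).sum()

        exhaustive = min(score(z) for z in Z)
        assert score(best) == pytest.approx(exhaustive, abs=1e-10)

    def test_medoids_method_on_clean_blocks(self):
        z = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        S = (z[:, None] == z[None, :]).astype(float)
        best = bpr.best_partition(S, method="medoids", k_range=range(1, 5))
        assert len(np.unique(best)) == 3


class TestReferenceCluster:
    def test_all_lowest_quartile_cluster_selected(self):
        profiles = np.array([[1, 1], [1, 1], [4, 4], [3, 4]])
        best = np.array([1, 1, 2, 2])
        assert bpr.select_reference_cluster(best, profiles) == 1

    def test_tie_broken_by_smallest_id(self):
        profiles = np.array([[1, 2], [2, 1], [1, 2], [2, 1]])
        best = np.array([3, 3, 7, 7])
        assert bpr.select_reference_cluster(best, profiles) == 3


class TestClusterOutcomePosteriors:
    def test_deficit_probability_matches_direct_counting(self):
        # 10 hand-written draws, 2 clusters: theta known per draw
        rng = np.random.default_rng(0)
        Z = np.tile([0, 0, 1, 1], (10, 1))
        theta = rng.normal(size=(10, 2))
        d = _draws_from_allocations(Z, theta=theta)
        best = np.array([1, 1, 2, 2])
        rep = bpr.cluster_outcome_posteriors(d, best, reference=1)
        expected = (theta[:, 1] < theta[:, 0]).mean()
        assert rep.deficit_probability(2) == pytest.approx(expected)
        j = list(rep.cluster_ids).index(1)
        assert np.allclose(rep.diff_draws[:, j], 0.0)
        ref_row = rep.table[rep.table["cluster"] == 1].iloc[0]
        assert ref_row["diff_vs_ref"] == "Ref"
        # unweighted overall baseline per sweep
        assert np.allclose(rep.baseline_draws, theta.mean(axis=1))

    def test_reference_must_be_a_cluster(self):
        d = _draws_from_allocations(np.zeros((3, 4)), theta=np.zeros((3, 1)))
        with pytest.raises(ValueError, match="reference"):
            bpr.cluster_outcome_posteriors(d, np.array([1, 1, 1, 1]), reference=9)


class TestComparePartitions:
    def test_identical_partitions(self):
        a = np.array([1, 1, 2, 2, 3])
        tab, ari = bpr.compare_partitions(a, a)
        assert ari == 1.0
        inner = tab.drop(index="Total", columns="Total")
        assert np.array_equal(np.sort(np.diag(inner)), [1, 2, 2])

    def test_degenerate_partitions_have_zero_ari(self):
        a = np.array([1, 2, 3, 4])
        b = np.array([1, 1, 1, 1])
        _, ari = bpr.compare_partitions(a, b)
        assert ari == 0.0

    def test_row_totals_conserve_n(self, rng):
        a = rng.integers(1, 4, size=20)
        b = rng.integers(1, 3, size=20)
        tab, _ = bpr.compare_partitions(a, b)
        assert tab.loc["Total", "Total"] == 20

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bpr.compare_partitions(np.ones(3), np.ones(4))


class TestFit:
    def test_single_cluster_data_concentrates_on_one_block(self):
        # identical profiles, pure-noise outcome: posterior mass on
        # partitions dominated by one large cluster
        rng = np.random.default_rng(4)
        x = np.ones((40, 3), dtype=int)
        x[:, 1] = 2
        y = rng.normal(size=40)
        cfg = bpr.BPRConfig(
            n_burnin=500, n_sweeps=3000, thin=1, truncation_level=20, seed=1
        )
        d = bpr.fit(x, y, None, cfg)
        frac_dominant = np.array([
            np.bincount(z).max() / z.size for z in d.allocations
        ])
        assert (frac_dominant >= 0.9).mean() >= 0.95

    def test_two_cluster_recovery_with_outcome(self):
        rng = np.random.default_rng(9)
        labels = np.arange(120) % 2 + 1
        rng.shuffle(labels)
        truth = datagen.GroundTruth(labels, {1: 0.0, 2: -7.0}, {})
        probs = datagen.recovery_category_probs(2, 8, 4)
        profiles, outcome = datagen.generate_profiles_direct(
            120, 8, 4, truth, probs, seed=3, noise_sd=3.0
        )
        cfg = bpr.BPRConfig(
            n_burnin=500, n_sweeps=4000, truncation_level=30, seed=5
        )
        d = bpr.fit(profiles, outcome["fsiq"], None, cfg)
        S = bpr.similarity(d)
        best = bpr.best_partition(S, d)
        _, ari = bpr.compare_partitions(best, labels)
        assert ari >= 0.9
        ref = bpr.select_reference_cluster(best, profiles)
        rep = bpr.cluster_outcome_posteriors(d, best, ref)
        big = rep.table[rep.table["cluster"] != ref].sort_values("n").iloc[-1]
        assert big["diff_vs_ref"] == pytest.approx(-7.0, abs=1.6)

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..K"):
            bpr.fit(np.zeros((10, 2), dtype=int), None, None, bpr.BPRConfig(n_sweeps=10))

    def test_nonfinite_outcome_rejected(self):
        x = np.ones((5, 2), dtype=int)
        with pytest.raises(ValueError, match="non-finite"):
            bpr.fit(x, [1.0, 2.0, np.nan, 0.0, 1.0], None, bpr.BPRConfig(n_sweeps=10))

    def test_continuous_confounders_centered_and_recorded(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 5, size=(30, 2))
        W = pd.DataFrame({"age": rng.normal(10, 2, 30), "sex": rng.integers(0, 2, 30).astype(float)})
        cfg = bpr.BPRConfig(n_burnin=10, n_sweeps=50, thin=1, truncation_level=10, seed=0)
        d = bpr.fit(x, rng.normal(size=30), W, cfg)
        assert "age" in d.confounder_means
        assert "sex" not in d.confounder_means  # binary left at reference 0
        assert d.confounder_means["age"] == pytest.approx(W["age"].mean())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 4, size=(20, 3))
        y = rng.normal(size=20)
        cfg = bpr.BPRConfig(n_burnin=50, n_sweeps=200, thin=1, truncation_level=10,
                            variable_selection="continuous", seed=123)
        d1 = bpr.fit(x, y, None, cfg)
        d2 = bpr.fit(x, y, None, cfg)
        assert np.array_equal(d1.allocations, d2.allocations)
        assert np.array_equal(d1.zeta, d2.zeta)


def test_outcome_feedback_helps_when_profiles_weakly_separate():
    """With weak profile separation, outcome supervision should on average
    improve agreement of the best partition with the planted clusters."""
    deltas = []
    for rep in range(10):
        rng = np.random.default_rng(300 + rep)
        n = 100
        labels = np.arange(n) % 2 + 1
        rng.shuffle(labels)
        truth = datagen.GroundTruth(labels, {1: 0.0, 2: -8.0}, {})
        probs = datagen.recovery_category_probs(2, 6, 4, peak=0.4)  # weak
        profiles, outcome = datagen.generate_profiles_direct(
            n, 6, 4, truth, probs, seed=rep, noise_sd=2.0
        )
        aris = {}
        for mode in (True, False):
            cfg = bpr.BPRConfig(
                n_burnin=300, n_sweeps=2000, truncation_level=20,
                outcome_included=mode, seed=50 + rep,
            )
            d = bpr.fit(profiles, outcome["fsiq"], None, cfg)
            best = bpr.best_partition(bpr.similarity(d), d)
            _, aris[mode] = bpr.compare_partitions(best, labels)
        deltas.append(aris[True] - aris[False])
    assert np.mean(deltas) >= 0.0


def test_uninformative_pesticide_gets_lower_selection_weight():
    """A pesticide generated independently of the clusters should have a
    smaller posterior mean zeta than every cluster-informative one."""
    wins = 0
    for rep in range(10):
        rng = np.random.default_rng(700 + rep)
        n = 150
        labels = np.arange(n) % 2 + 1
        rng.shuffle(labels)
        truth = datagen.GroundTruth(labels, {1: 0.0, 2: -6.0}, {})
        probs = datagen.recovery_category_probs(2, 5, 4)
        probs[:, 4, :] = 0.25  # last pesticide carries no cluster signal
        profiles, outcome = datagen.generate_profiles_direct(
            n, 5, 4, truth, probs, seed=rep, noise_sd=4.0
        )
        cfg = bpr.BPRConfig(
            n_burnin=500, n_sweeps=3000, truncation_level=20,
            variable_selection="continuous", seed=80 + rep,
        )
        d = bpr.fit(profiles, outcome["fsiq"], None, cfg)
        zbar = d.zeta.mean(axis=0)
        wins += zbar[4] < zbar[:4].min()
    assert wins >= 8
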