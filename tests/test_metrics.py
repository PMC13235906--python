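"""Evaluation metrics vs independent brute-force oracles."""

import numpy as np
import pytest

from taxovision import syndata
from taxovision.metrics import (EvalBatch, alignment_given_miss, ece,
                                error_vs_genus_richness, mcnemar,
                                per_rank_metrics, per_species_error_bins,
                                reliability, tas, tas_random_baseline)

from conftest import one_hot, random_probability_rows


def _batch_from_chains(tree, chains, labels=None):
    """EvalBatch whose argmax triples equal ``chains`` exactly."""
    chains = np.asarray(chains)
    if labels is None:
        labels = np.array([tree.label_triple_for_species(0).as_tuple()
                           ] * len(chains))
    return EvalBatch(
        np.stack([one_hot(c, tree.n_families) for c in chains[:, 0]]),
        np.stack([one_hot(c, tree.n_genera) for c in chains[:, 1]]),
        np.stack([one_hot(c, tree.n_species) for c in chains[:, 2]]),
        labels)


class TestTas:
    def test_fully_consistent_chains_score_one(self, toy_tree):
        chains = [toy_tree.label_triple_for_species(s % 4).as_tuple()
                  for s in range(10)]
        assert tas(_batch_from_chains(toy_tree, chains), toy_tree) == 1.0

    def test_one_violation_in_two_samples_scores_half(self, toy_tree):
        good = toy_tree.label_triple_for_species(0).as_tuple()
        bad = (1, 0, 0)  # genus 0 belongs to family 0, not 1
        batch = _batch_from_chains(toy_tree, [good, bad])
        assert tas(batch, toy_tree) == 0.5

    def test_matches_brute_force_indicator_average(self):
        spec = syndata.SyntheticSpec(3, 6, 12, images_per_species=3, seed=2)
        tree = syndata.make_taxonomy(spec)
        rng = np.random.default_rng(0)
        chains = np.column_stack([rng.integers(0, tree.n_families, 200),
                                  rng.integers(0, tree.n_genera, 200),
                                  rng.integers(0, tree.n_species, 200)])
        batch = _batch_from_chains(
            tree, chains,
            labels=np.array([tree.label_triple_for_species(0).as_tuple()] * 200))
        oracle = np.mean([
            int(tree.family_of_genus(g) == f and tree.genus_of_species(s) == g)
            for f, g, s in chains])
        assert tas(batch, tree) == oracle

    def test_independent_of_label_correctness(self, toy_tree):
        chains = [toy_tree.label_triple_for_species(1).as_tuple()] * 4
        wrong_labels = np.array(
            [toy_tree.label_triple_for_species(3).as_tuple()] * 4)
        batch = _batch_from_chains(toy_tree, chains, labels=wrong_labels)
        assert tas(batch, toy_tree) == 1.0

    def test_uncoupled_random_predictions_match_analytic_probability(self):
        """With independent per-head argmaxes the expected TAS is the
        enumeration probability that a uniform triple is consistent."""
        spec = syndata.SyntheticSpec(3, 6, 12, images_per_species=3, seed=3)
        tree = syndata.make_taxonomy(spec)
        # enumeration oracle
        consistent = sum(
            1 for f in range(3) for g in range(6) for s in range(12)
            if tree.family_of_genus(g) == f and tree.genus_of_species(s) == g)
        p_analytic = consistent / (3 * 6 * 12)
        assert tas_random_baseline(tree) == pytest.approx(p_analytic)
        rng = np.random.default_rng(4)
        n = 5000
        batch = EvalBatch(random_probability_rows(rng, n, 3),
                          random_probability_rows(rng, n, 6),
                          random_probability_rows(rng, n, 12),
                          np.array([tree.label_triple_for_species(0).as_tuple()
                                    ] * n))
        se = np.sqrt(p_analytic * (1 - p_analytic) / n)
        assert abs(tas(batch, tree) - p_analytic) < 3 * se


class TestPerRankMetrics:
    def test_perfect_predictions(self, toy_tree):
        labels = np.array([toy_tree.label_triple_for_species(s).as_tuple()
                           for s in range(4)])
        batch = _batch_from_chains(toy_tree, labels, labels=labels)
        report = per_rank_metrics(batch, toy_tree)
        for rank in report.values():
            assert all(v == 1.0 for v in rank.values())

    def test_hand_confusion_matrix(self, toy_tree):
        """Species head confined to classes {0,1} with TP=2, FP=1, FN=1,
        TN=1 for class 0: macro precision = recall = 2/3."""
        labels = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 1],
                           [0, 0, 1]])
        chains = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 0],
                           [0, 0, 1]])
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        rep = per_rank_metrics(batch, toy_tree)["species"]
        # class 0: p=2/3, r=2/3; class 1: p=1/2, r=1/2 -> macro 7/12
        assert rep["precision"] == pytest.approx((2 / 3 + 1 / 2) / 2)
        assert rep["recall"] == pytest.approx((2 / 3 + 1 / 2) / 2)

    def test_matches_brute_force_oracle(self, toy_tree):
        rng = np.random.default_rng(5)
        n = 60
        labels = np.array([toy_tree.label_triple_for_species(s).as_tuple()
                           for s in rng.integers(0, 4, n)])
        chains = np.column_stack([rng.integers(0, toy_tree.n_families, n),
                                  rng.integers(0, toy_tree.n_genera, n),
                                  rng.integers(0, toy_tree.n_species, n)])
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        rep = per_rank_metrics(batch, toy_tree)["genus"]
        y_true, y_pred = labels[:, 1], chains[:, 1]
        precisions, recalls = [], []
        for cls in np.unique(y_true):
            tp = np.sum((y_pred == cls) & (y_true == cls))
            fp = np.sum((y_pred == cls) & (y_true != cls))
            fn = np.sum((y_pred != cls) & (y_true == cls))
            precisions.append(tp / (tp + fp) if tp + fp else 0.0)
            recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        assert rep["accuracy"] == pytest.approx((y_true == y_pred).mean())
        assert rep["precision"] == pytest.approx(np.mean(precisions))
        assert rep["recall"] == pytest.approx(np.mean(recalls))


class TestAlignmentGivenMiss:
    def test_all_misses_in_correct_parent(self, toy_tree):
        # true species 0 (genus 0); predict species 1 (also genus 0)
        labels = np.array([toy_tree.label_triple_for_species(0).as_tuple()] * 3)
        chains = np.array([toy_tree.label_triple_for_species(1).as_tuple()] * 3)
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        assert alignment_given_miss(batch, toy_tree, "species") == 1.0

    def test_fraction_three_of_four(self, toy_tree):
        # genus misses: 3 within the right family, 1 outside
        labels = np.array([[0, 0, 0]] * 4)
        chains = np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0], [1, 2, 0]])
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        assert alignment_given_miss(batch, toy_tree, "genus") == 0.75

    def test_matches_brute_force(self, toy_tree):
        rng = np.random.default_rng(6)
        n = 80
        labels = np.array([toy_tree.label_triple_for_species(s).as_tuple()
                           for s in rng.integers(0, 4, n)])
        chains = np.column_stack([rng.integers(0, toy_tree.n_families, n),
                                  rng.integers(0, toy_tree.n_genera, n),
                                  rng.integers(0, toy_tree.n_species, n)])
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        hits = total = 0
        for (tf, tg, ts), (pf, pg, ps) in zip(labels, chains):
            if ps != ts:
                total += 1
                hits += int(toy_tree.genus_of_species(ps)
                            == toy_tree.genus_of_species(ts))
        assert alignment_given_miss(batch, toy_tree, "species") == \
            pytest.approx(hits / total)

    def test_no_misses_is_undefined(self, toy_tree):
        labels = np.array([toy_tree.label_triple_for_species(0).as_tuple()] * 2)
        batch = _batch_from_chains(toy_tree, labels, labels=labels)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(alignment_given_miss(batch, toy_tree, "genus"))


class TestCalibration:
    def test_perfectly_matched_bins_score_zero(self):
        conf = np.array([0.75] * 4)
        correct = np.array([1, 1, 1, 0], dtype=bool)  # accuracy 0.75
        assert ece(conf, correct, n_bins=1) == pytest.approx(0.0)

    def test_hand_computed_single_bin(self):
        conf = np.full(10, 0.8)
        correct = np.array([1] * 6 + [0] * 4, dtype=bool)
        assert ece(conf, correct, n_bins=1) == pytest.approx(0.2)

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        conf = rng.random(500)
        correct = rng.random(500) < conf
        perm = rng.permutation(500)
        assert ece(conf, correct) == pytest.approx(ece(conf[perm], correct[perm]))

    def test_counts_partition_samples(self):
        rng = np.random.default_rng(8)
        conf = rng.random(321)
        curve = reliability(conf, rng.random(321) < 0.5, n_bins=10)
        assert curve.count.sum() == 321
        assert curve.bin_edges[0] == 0.0 and curve.bin_edges[-1] == 1.0

    def test_calibrated_generator_approaches_zero(self):
        """Samples whose correctness is Bernoulli(confidence) are perfectly
        calibrated; ECE at N=1e5 should be within 0.01 of zero."""
        rng = np.random.default_rng(9)
        conf = rng.uniform(0.2, 1.0, 100_000)
        correct = rng.random(100_000) < conf
        assert ece(conf, correct, n_bins=10) < 0.01


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        a = np.array([1] * 5 + [0] * 5 + [1] * 10, dtype=bool)
        b = np.array([0] * 5 + [1] * 5 + [1] * 10, dtype=bool)
        res = mcnemar(a, b)
        assert res.b == res.c == 5 and res.exact
        assert res.p_value == pytest.approx(1.0)

    def test_exact_binomial_worked_value(self):
        """b=10, c=2: two-sided exact p = 2*P(X<=2 | n=12) = 158/4096."""
        a = np.array([1] * 12 + [1] * 5, dtype=bool)
        b = np.array([0] * 10 + [1] * 2 + [1] * 5, dtype=bool)
        # construct flags with exactly b=10, c=2
        a = np.concatenate([np.ones(10, bool), np.zeros(2, bool),
                            np.ones(5, bool)])
        b = np.concatenate([np.zeros(10, bool), np.ones(2, bool),
                            np.ones(5, bool)])
        res = mcnemar(a, b)
        assert (res.b, res.c) == (10, 2)
        assert res.p_value == pytest.approx(158 / 4096, abs=1e-12)

    def test_identical_flags_degenerate(self):
        flags = np.array([1, 0, 1, 1], dtype=bool)
        res = mcnemar(flags, flags)
        assert res.degenerate and res.p_value == 1.0

    def test_large_discordance_uses_chi_squared(self):
        a = np.concatenate([np.ones(20, bool), np.zeros(10, bool)])
        b = np.concatenate([np.zeros(20, bool), np.ones(10, bool)])
        res = mcnemar(a, b)
        assert not res.exact
        assert res.statistic == pytest.approx((abs(20 - 10) - 1) ** 2 / 30)


class TestPerSpeciesAnalyses:
    def test_perfect_species_in_low_bin(self, toy_tree):
        labels = np.array([toy_tree.label_triple_for_species(s).as_tuple()
                           for s in (0, 1, 2, 3)])
        batch = _batch_from_chains(toy_tree, labels, labels=labels)
        bins = per_species_error_bins(batch, toy_tree)
        assert bins["low"] == [0, 1, 2, 3]
        assert not bins["moderate"] and not bins["high"]

    def test_boundary_semantics(self, toy_tree):
        """Errors 0.05 / 0.15 / 0.30 land in low / moderate / high."""
        def rows(species, n_wrong, n_total):
            labels, chains = [], []
            for i in range(n_total):
                labels.append(toy_tree.label_triple_for_species(species).as_tuple())
                pred = (species + 1) % 4 if i < n_wrong else species
                chains.append(toy_tree.label_triple_for_species(pred).as_tuple())
            return labels, chains

        labels, chains = [], []
        for species, (wrong, total) in enumerate([(1, 20), (3, 20), (6, 20)]):
            l, c = rows(species, wrong, total)
            labels += l
            chains += c
        batch = _batch_from_chains(toy_tree, chains, labels=np.array(labels))
        bins = per_species_error_bins(batch, toy_tree)
        assert bins["low"] == [0] and bins["moderate"] == [1] \
            and bins["high"] == [2]

    def test_bins_match_recall_oracle(self, toy_tree):
        rng = np.random.default_rng(10)
        n = 100
        labels = np.array([toy_tree.label_triple_for_species(s).as_tuple()
                           for s in rng.integers(0, 4, n)])
        chains = np.column_stack([rng.integers(0, toy_tree.n_families, n),
                                  rng.integers(0, toy_tree.n_genera, n),
                                  rng.integers(0, toy_tree.n_species, n)])
        batch = _batch_from_chains(toy_tree, chains, labels=labels)
        bins = per_species_error_bins(batch, toy_tree)
        for s in np.unique(labels[:, 2]):
            mask = labels[:, 2] == s
            err = 1 - np.mean(chains[mask, 2] == s)
            key = "low" if err <= 0.10 else ("moderate" if err <= 0.25
                                             else "high")
            assert s in bins[key]


class TestErrorVsRichness:
    def _batch(self, tree, errors_by_species):
        labels, chains = [], []
        for s, err in errors_by_species.items():
            n = 20
            n_wrong = round(err * n)
            for i in range(n):
                labels.append(tree.label_triple_for_species(s).as_tuple())
                pred = (s + 1) % tree.n_species if i < n_wrong else s
                chains.append(tree.label_triple_for_species(pred).as_tuple())
        return _batch_from_chains(tree, chains, labels=np.array(labels))

    def test_pearson_on_hand_set_points(self):
        spec = syndata.SyntheticSpec(2, 3, 8, images_per_species=3, seed=11)
        tree = syndata.make_taxonomy(spec)
        errors = {s: 0.05 * s for s in range(tree.n_species)}
        batch = self._batch(tree, errors)
        trend = error_vs_genus_richness(batch, tree)
        richness = tree.species_per_genus()
        x = np.array([richness[tree.genus_of_species(s)] for s in errors],
                     dtype=float)
        y = np.array([1 - np.mean(
            batch.p_spe[batch.labels[:, 2] == s].argmax(axis=1) == s)
            for s in errors])
        # closed-form Pearson
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert trend.pearson_r == pytest.approx(r)

    def test_constant_error_zero_slope(self, toy_tree):
        batch = self._batch(toy_tree, {s: 0.0 for s in range(4)})
        trend = error_vs_genus_richness(batch, toy_tree)
        assert trend.slope == pytest.approx(0.0)
        assert np.isnan(trend.pearson_r) or trend.pearson_r == 0.0
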