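"""Splitting schemes and stochastic model validation."""

import itertools

import numpy as np
import pytest

from naphqsar import synthetic
from naphqsar.smv import (
    flag_frequent,
    kennard_stone_split,
    random_split,
    ranked_split,
    run_smv,
    split_sizes,
)


@pytest.fixture(scope="module")
def informative_population():
    d = synthetic.gen_latent_regression(
        synthetic.SyntheticSpec(n=102, p=30, n_informative=10, rank=3, noise=0.3, seed=9)
    )
    return run_smv(d.X, d.y, n_samples=300, a_max=3, base_seed=17)


class TestRandomSplit:
    def test_102_objects_split_68_34(self):
        assert split_sizes(102) == (68, 34)
        train, test = random_split(range(102), seed=0)
        assert len(train) == 68 and len(test) == 34
        assert set(train) | set(test) == set(range(102))
        assert not set(train) & set(test)

    def test_three_objects_split_two_one(self):
        assert split_sizes(3) == (2, 1)

    def test_test_membership_frequency_binomial(self):
        ids = list(range(102))
        hits = np.zeros(102)
        n_seeds = 10_000
        for seed in range(n_seeds):
            _, test = random_split(ids, seed)
            hits[test] += 1
        freq = hits / n_seeds
        assert np.all(np.abs(freq - 34 / 102) < 0.02)


class TestRankedSplit:
    def test_systematic_thirds(self, rng):
        ids = [f"c{i}" for i in range(102)]
        acts = rng.standard_normal(102)
        train, test = ranked_split(ids, acts)
        assert len(train) == 68 and len(test) == 34

    def test_test_set_spans_activity_terciles(self, rng):
        ids = list(range(99))
        acts = rng.permutation(99).astype(float)
        _, test = ranked_split(ids, acts)
        test_acts = sorted(acts[t] for t in test)
        terciles = np.quantile(acts, [1 / 3, 2 / 3])
        assert test_acts[0] < terciles[0] and test_acts[-1] > terciles[1]

    def test_deterministic(self, rng):
        ids = list(range(30))
        acts = rng.standard_normal(30)
        assert ranked_split(ids, acts) == ranked_split(ids, acts)


class TestKennardStone:
    def test_extremes_chosen_first(self):
        train, test = kennard_stone_split([0.0, 10.0, 5.0, 1.0, 9.0], n_train=2)
        assert train == [0, 1]  # indices of values 0 and 10
        assert test == [2, 3, 4]

    def test_matches_exhaustive_maximin_oracle(self, rng):
        values = rng.uniform(0, 10, size=8)

        def oracle_score(subset):
            return min(
                abs(values[i] - values[j]) for i, j in itertools.combinations(subset, 2)
            )

        train, _ = kennard_stone_split(values, n_train=4)
        # greedy KS must dominate or match every 4-subset containing the extremes
        ext = {int(np.argmin(values)), int(np.argmax(values))}
        assert ext <= set(train)
        best = max(
            oracle_score(s)
            for s in itertools.combinations(range(8), 4)
            if ext <= set(s)
        )
        # maximin greedy guarantee: within the best achievable spread
        assert oracle_score(train) >= 0.5 * best

    def test_deterministic(self, rng):
        v = rng.standard_normal(20)
        assert kennard_stone_split(v, 8) == kennard_stone_split(v, 8)

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            kennard_stone_split([1.0, 2.0], n_train=2)


class TestRunSmv:
    def test_frequency_counts_conserved(self, informative_population):
        pop = informative_population
        counts = pop.test_frequency()
        assert counts.sum() == 34 * len(pop.filtered())

    def test_q2_test_strictly_held_out(self, informative_population):
        row = informative_population.samples.iloc[0]
        assert len(row.test_ids) == 34
        assert row.q2_cv <= 1.0 and row.q2_test <= 1.0

    def test_reproducible_for_fixed_base_seed(self):
        d = synthetic.gen_latent_regression(
            synthetic.SyntheticSpec(n=30, p=8, n_informative=4, rank=2, noise=0.2, seed=3)
        )
        a = run_smv(d.X, d.y, n_samples=40, a_max=2, base_seed=5)
        b = run_smv(d.X, d.y, n_samples=40, a_max=2, base_seed=5)
        assert a.samples.equals(b.samples)

    def test_filter_monotone_in_cv_threshold(self, informative_population):
        pop = informative_population
        sizes = [len(pop.filtered(q2_cv_min=t)) for t in (0.0, 0.3, 0.6, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_passing_sample_warns_with_empty_table(self):
        d = synthetic.gen_latent_regression(
            synthetic.SyntheticSpec(n=24, p=6, n_informative=0, rank=2, noise=1.0, seed=1)
        )
        pop = run_smv(d.X, d.y, n_samples=20, a_max=2, base_seed=2, q2_cv_min=0.999)
        with pytest.warns(UserWarning, match="filter"):
            counts = pop.test_frequency()
        assert counts.sum() == 0


class TestFlagFrequent:
    def test_zero_threshold_flags_everything(self, informative_population):
        assert len(flag_frequent(informative_population, 0)) == 102

    def test_above_max_threshold_flags_nothing(self, informative_population):
        max_count = informative_population.test_frequency().max()
        assert flag_frequent(informative_population, max_count + 1) == []

    def test_planted_outliers_enriched(self):
        from scipy.stats import hypergeom

        pvals = []
        for seed in range(10):
            d = synthetic.gen_latent_regression(
                synthetic.SyntheticSpec(n=60, p=20, n_informative=8, rank=8, noise=0.2, seed=seed)
            )
            y = d.y.copy()
            outliers = [0, 1, 2, 3, 4]
            y[outliers] += 6.0 * np.sign(np.random.default_rng(seed).standard_normal(5))
            pop = run_smv(
                d.X, y, n_samples=300, a_max=3, base_seed=seed,
                q2_cv_min=-np.inf, q2_test_min=-np.inf,
            )
            # best models = top decile by training q2: their training sets
            # avoided the planted outliers, so the outliers pile up in test
            thr = float(np.quantile(pop.samples.q2_cv, 0.9))
            counts = pop.test_frequency(q2_cv_min=thr)
            k = 10
            top = counts.sort_values(ascending=False, kind="stable").head(k).index
            hits = len(set(top) & set(outliers))
            pvals.append(hypergeom.sf(hits - 1, 60, 5, k))
        assert np.median(pvals) < 0.05
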