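"""Hierarchical latent-trait MPT: sampler contracts at desk scale.

Full-scale parameter recovery, group-difference recovery, and posterior
predictive calibration run in the acceptance suite; here the sampler's
structural contracts (determinism, transforms, diagnostics, shrinkage to
the aggregate estimate, small-sample coverage) are checked with short
chains.
"""

import numpy as np
import pytest

from sourcemem.hierarchical_mpt import (LatentTraitConfig, PosteriorDraws,
                                        group_difference, inverse_probit,
                                        posterior_predictive_pvalues, probit,
                                        sample_posterior, split_rhat)
from sourcemem.mpt_model import moment_estimator
from sourcemem.synthetic_data import CohortSpec, gen_cohort
from sourcemem.task_data import CohortTable, Group

FAST = dict(n_iter=800, burn_in=300, thin=1, n_chains=2)


def young_cohort(**spec_kw) -> CohortTable:
    spec = CohortSpec(**spec_kw)
    trials, _ = gen_cohort(spec)
    return CohortTable.from_trials(trials).subset(Group.YOUNG)


class TestTransforms:
    def test_probit_round_trip(self):
        x = np.linspace(-6, 6, 101)
        assert inverse_probit(probit(inverse_probit(x))) == pytest.approx(
            inverse_probit(x), abs=1e-12)
        p = np.linspace(1e-6, 1 - 1e-6, 101)
        assert inverse_probit(probit(p)) == pytest.approx(p, abs=1e-12)


class TestSplitRhat:
    def test_identical_chains_near_one(self, rng):
        draws = rng.standard_normal(400)
        chains = np.stack([draws, draws])
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(400),
                           rng.standard_normal(400) + 5.0])
        assert split_rhat(chains) > 1.5

    def test_matches_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = np.cumsum(rng.standard_normal((2, 500)), axis=1) * 0.05 \
            + rng.standard_normal((2, 500))
        ours = split_rhat(chains)
        theirs = float(arviz.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSamplePosterior:
    def test_deterministic_under_seed(self):
        cohort = young_cohort(n_young=5, n_older=1, trials_per_tree=24, seed=2)
        cfg = LatentTraitConfig(seed=9, **FAST)
        d1 = sample_posterior(cohort, cfg)
        d2 = sample_posterior(cohort, cfg)
        assert np.array_equal(d1.group_prob, d2.group_prob)
        assert np.array_equal(d1.individual_prob, d2.individual_prob)
        assert np.array_equal(d1.rhat, d2.rhat)

    def test_draw_count_and_chain_labels(self):
        cohort = young_cohort(n_young=4, n_older=1, trials_per_tree=16, seed=3)
        cfg = LatentTraitConfig(n_iter=600, burn_in=200, thin=4, n_chains=2, seed=1)
        d = sample_posterior(cohort, cfg)
        assert d.n_draws == 2 * (600 - 200) // 4
        assert set(d.chain) == {0, 1}
        assert ((d.group_prob >= 0) & (d.group_prob <= 1)).all()
        assert d.individual_prob.shape == (d.n_draws, 4, 6)

    def test_zero_variance_cohort_concentrates_at_moment_estimate(self):
        # identical participants, many trials: group mean ~ aggregate moment fit
        cohort = young_cohort(n_young=8, n_older=1, trials_per_tree=400,
                              latent_sd=np.zeros(6), miss_rate=0.0, seed=12)
        agg = cohort.tables[0]
        for t in cohort.tables[1:]:
            agg = agg + t
        target = moment_estimator(agg).params.as_array()
        cfg = LatentTraitConfig(n_iter=1500, burn_in=500, thin=2, n_chains=2, seed=4)
        d = sample_posterior(cohort, cfg)
        assert d.group_prob.mean(axis=0) == pytest.approx(target, abs=0.05)

    def test_single_group_required(self):
        spec = CohortSpec(n_young=2, n_older=2, trials_per_tree=8, seed=1)
        trials, _ = gen_cohort(spec)
        mixed = CohortTable.from_trials(trials)
        with pytest.raises(ValueError, match="single-group"):
            sample_posterior(mixed, LatentTraitConfig(seed=0, **FAST))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LatentTraitConfig(n_iter=100, burn_in=200)
        with pytest.raises(ValueError):
            LatentTraitConfig(n_chains=1)

    def test_bci_coverage_at_reduced_scale(self):
        """95% intervals for group means cover truth in >=80% of replications."""
        truth = {g: m.as_array() for g, m in
                 CohortSpec().group_means.items()}[Group.YOUNG]
        covered = total = 0
        for rep in range(20):
            cohort = young_cohort(n_young=10, n_older=1, trials_per_tree=40,
                                  seed=1000 + rep)
            cfg = LatentTraitConfig(n_iter=700, burn_in=300, thin=1,
                                    n_chains=2, seed=rep)
            d = sample_posterior(cohort, cfg)
            lo = np.quantile(d.group_prob, 0.025, axis=0)
            hi = np.quantile(d.group_prob, 0.975, axis=0)
            covered += int(((lo <= truth) & (truth <= hi)).sum())
            total += 6
        assert covered / total >= 0.80


class TestPosteriorPredictive:
    def test_requires_enough_draws(self):
        cohort = young_cohort(n_young=3, n_older=1, trials_per_tree=8, seed=1)
        cfg = LatentTraitConfig(n_iter=400, burn_in=300, thin=10, n_chains=2, seed=0)
        d = sample_posterior(cohort, cfg)
        with pytest.raises(ValueError, match="100 draws"):
            posterior_predictive_pvalues(d, cohort)

    def test_copy_replicate_symmetry(self):
        # when observed data are themselves a draw from the model the p-values
        # hover near 0.5
        cohort = young_cohort(n_young=10, n_older=1, trials_per_tree=60, seed=8)
        cfg = LatentTraitConfig(n_iter=1200, burn_in=400, thin=2, n_chains=2, seed=3)
        d = sample_posterior(cohort, cfg)
        p1, p2 = posterior_predictive_pvalues(d, cohort, seed=1)
        assert 0.1 < p1 < 0.9
        assert 0.1 < p2 < 0.9

    def test_gross_misspecification_detected(self):
        """Counts outside the tree's reachable mean frequencies give p_T1 < 0.05.

        The NEW tree demands o*g near 0.9, which forces P(old_up | UP) of at
        least 0.9; observing mostly 'new' answers on UP trials is therefore
        infeasible for every parameter setting.
        """
        from sourcemem.task_data import FrequencyTable
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(10):
            base = np.array([[5, 5, 50], [5, 5, 50], [54, 3, 3]])
            jitter = rng.integers(0, 3, size=(3, 3))
            tables.append(FrequencyTable(base + jitter))
        cohort = CohortTable([f"p{i}" for i in range(10)],
                             [Group.YOUNG] * 10, tables)
        cfg = LatentTraitConfig(n_iter=1200, burn_in=400, thin=2, n_chains=2, seed=5)
        d = sample_posterior(cohort, cfg)
        p1, _ = posterior_predictive_pvalues(d, cohort, seed=2)
        assert p1 < 0.05


class TestGroupDifference:
    def _draws(self, values: np.ndarray) -> PosteriorDraws:
        n = values.shape[0]
        return PosteriorDraws(
            group_prob=values,
            individual_prob=np.zeros((n, 1, 6)),
            mu=probit(np.clip(values, 1e-9, 1 - 1e-9)),
            beta=None,
            chain=np.zeros(n, dtype=int),
            rhat=np.ones(6),
            converged=True,
            config=LatentTraitConfig(n_iter=20, burn_in=0, thin=1, seed=0),
        )

    def test_identical_draws_give_zero_mean(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(500, 6))
        diff = group_difference(self._draws(vals), self._draws(vals), seed=0)
        assert diff.mean == pytest.approx(np.zeros(6), abs=0.02)
        assert not diff.credible.any()
        assert (diff.lower <= diff.mean).all() and (diff.mean <= diff.upper).all()

    def test_constant_shift_recovered(self, rng):
        vals = rng.uniform(0.3, 0.6, size=(500, 6))
        shifted = np.clip(vals + 0.15, 0, 1)
        diff = group_difference(self._draws(shifted), self._draws(vals), seed=1)
        assert diff.mean == pytest.approx(np.full(6, 0.15), abs=0.03)

    def test_unequal_draw_counts_subsampled(self, rng):
        a = self._draws(rng.uniform(0.4, 0.6, size=(400, 6)))
        b = self._draws(rng.uniform(0.4, 0.6, size=(250, 6)))
        diff = group_difference(a, b, seed=2)
        assert np.isfinite(diff.mean).all()
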