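import numpy as np
import pytest

import salmix as sx
from salmix.freqs import AlleleFreqTable
from salmix.genotype_io import Locus
from salmix.mixture import (
    LikelihoodMatrix,
    aggregate,
    assign_individuals,
    bayes_mixture_mcmc,
    em_bootstrap_sd,
    em_mixture,
    gelman_rubin,
    genotype_loglik,
)
from salmix.synthetic import MixtureSample

from conftest import disjoint_registry

AB = Locus("L1", (1, 2))


class TestPosteriorFreqs:
    def test_pseudocount_smoothing(self):
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[np.array([[3, 1]])])
        np.testing.assert_allclose(t.posterior_freqs(0), [[0.7, 0.3]])

    def test_untyped_unit_uniform(self):
        loc = Locus("L", (1, 2, 3, 4))
        t = AlleleFreqTable(loci=[loc], units=["u"], counts=[np.zeros((1, 4), int)])
        np.testing.assert_allclose(t.posterior_freqs(0), 0.25)

    def test_rows_sum_to_one(self, clean_registry):
        registry, _ = clean_registry
        t = AlleleFreqTable.from_registry(registry)
        for j in range(len(registry.loci)):
            np.testing.assert_allclose(t.posterior_freqs(j).sum(axis=1), 1.0, atol=1e-12)


class TestGenotypeLoglik:
    def test_homozygote_plugin_value(self):
        n = 10
        counts = np.array([[2 * n, 0]])
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[counts])
        mix = MixtureSample(loci=[AB], genotypes=np.array([[[1, 1]]]))
        L = genotype_loglik(t, mix)
        p = (2 * n + 0.5) / (2 * n + 1)
        assert L.loglik[0, 0] == pytest.approx(2 * np.log(p), abs=1e-12)

    def test_heterozygote_hardy_weinberg_factor(self):
        counts = np.array([[10, 10]])
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[counts])
        het = MixtureSample(loci=[AB], genotypes=np.array([[[1, 2]]]))
        L = genotype_loglik(t, het)
        p = t.posterior_freqs(0)[0]
        assert L.loglik[0, 0] - (np.log(p[0]) + np.log(p[1])) == pytest.approx(np.log(2.0))

    def test_loo_singleton_reduces_to_prior(self):
        # one individual in the unit: removing it leaves prior-only frequencies
        counts = np.array([[2, 0]])  # one AA diploid
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[counts])
        mix = MixtureSample(loci=[AB], genotypes=np.array([[[1, 1]]]), true_origins=["u"])
        L = genotype_loglik(t, mix, loo_origins=["u"])
        assert L.loglik[0, 0] == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_loo_never_exceeds_plugin_for_own_unit(self, clean_registry):
        registry, _ = clean_registry
        t = AlleleFreqTable.from_registry(registry)
        coll = registry.collections[0]
        mix = MixtureSample(loci=registry.loci, genotypes=coll.genotypes)
        own = [coll.id] * coll.n
        plain = genotype_loglik(t, mix)
        loo = genotype_loglik(t, mix, loo_origins=own)
        u = t.units.index(coll.id)
        assert np.all(loo.loglik[:, u] <= plain.loglik[:, u] + 1e-9)

    def test_untyped_individual_flagged(self):
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[np.array([[2, 2]])])
        mix = MixtureSample(loci=[AB], genotypes=np.array([[[-1, -1]]]))
        L = genotype_loglik(t, mix)
        assert L.n_typed_loci[0] == 0
        assert L.loglik[0, 0] == 0.0

    def test_unseen_allele_extends_panel(self):
        t = AlleleFreqTable(loci=[AB], units=["u"], counts=[np.array([[4, 0]])])
        mix = MixtureSample(loci=[AB], genotypes=np.array([[[9, 9]]]))
        L = genotype_loglik(t, mix)
        assert np.isfinite(L.loglik[0, 0]) and L.loglik[0, 0] < np.log(1 / 3)


class TestEm:
    def test_separable_units(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1",), proportions=(1.0,), n=50, seed=1),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        est = em_mixture(genotype_loglik(t, mix))
        assert est.proportions[t.units.index("U1")] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_two_units(self):
        lik = np.array([[0.9, 0.1], [0.2, 0.8]])
        L = LikelihoodMatrix(
            units=["a", "b"], loglik=np.log(lik), n_typed_loci=np.array([1, 1])
        )
        est = em_mixture(L, tol=1e-12)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        ll = np.log(grid[:, None] * lik[:, 0] + (1 - grid[:, None]) * lik[:, 1]).sum(axis=1)
        assert est.proportions[0] == pytest.approx(grid[ll.argmax()], abs=1e-3)

    def test_identical_units_sum_identifiable(self):
        rng = np.random.default_rng(0)
        base = rng.random((40, 2))
        lik3 = np.column_stack([base[:, 0], base[:, 0], base[:, 1]])
        L2 = LikelihoodMatrix(
            units=["a", "b"], loglik=np.log(base), n_typed_loci=np.ones(40, int)
        )
        L3 = LikelihoodMatrix(
            units=["a1", "a2", "b"], loglik=np.log(lik3), n_typed_loci=np.ones(40, int)
        )
        two = em_mixture(L2, tol=1e-10).proportions
        three = em_mixture(L3, tol=1e-10).proportions
        assert three[0] + three[1] == pytest.approx(two[0], abs=1e-4)

    def test_proportions_on_simplex(self, clean_registry):
        registry, _ = clean_registry
        mix = sx.make_mixture(
            registry,
            sx.MixtureSpec(units=tuple(registry.unit_ids[:3]), proportions=(0.5, 0.3, 0.2), n=60, seed=4),
        )
        t = AlleleFreqTable.from_registry(registry)
        est = em_mixture(genotype_loglik(t, mix))
        assert est.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(est.proportions >= 0)


class TestEmBootstrap:
    def test_deterministic(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U2"), proportions=(0.5, 0.5), n=40, seed=2),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        L = genotype_loglik(t, mix)
        sd1, ci1 = em_bootstrap_sd(L, n_boot=30, seed=9)
        sd2, _ = em_bootstrap_sd(L, n_boot=30, seed=9)
        np.testing.assert_array_equal(sd1, sd2)
        assert np.all(ci1[0] <= ci1[1])

    def test_sd_shrinks_with_mixture_size(self, clean_registry):
        registry, _ = clean_registry
        t = AlleleFreqTable.from_registry(registry)
        units = tuple(registry.unit_ids[:2])
        sds = {}
        for n in (50, 500):
            vals = []
            for seed in range(5):
                mix = sx.make_mixture(
                    registry,
                    sx.MixtureSpec(units=units, proportions=(0.5, 0.5), n=n, seed=seed),
                )
                sd, _ = em_bootstrap_sd(genotype_loglik(t, mix), n_boot=30, seed=seed)
                vals.append(sd[t.units.index(units[0])])
            sds[n] = np.mean(vals)
        assert sds[500] < sds[50]


class TestGelmanRubin:
    def test_constant_identical_chains(self):
        assert gelman_rubin([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]) == 1.0

    def test_equal_nonconstant_chains_below_one(self):
        assert gelman_rubin([[1, 2, 3], [1, 2, 3]]) == pytest.approx(np.sqrt(2 / 3))

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(chains) > 1.2

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([[1, 2, 3]])


class TestMcmc:
    def test_prior_recovery_without_data(self):
        t = AlleleFreqTable(
            loci=[AB], units=["a", "b"], counts=[np.array([[4, 0], [0, 4]])]
        )
        empty = MixtureSample(loci=[AB], genotypes=np.empty((0, 1, 2), dtype=np.int64))
        est = bayes_mixture_mcmc(t, empty, chains=4, iters=600, burn_keep=300, seed=1)
        # Dirichlet(1/2, 1/2) has mean 1/2
        assert est.proportions[0] == pytest.approx(0.5, abs=0.05)

    def test_disjoint_even_mixture_converges(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U2"), proportions=(0.5, 0.5), n=100, seed=3),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        est = bayes_mixture_mcmc(t, mix, chains=4, iters=2000, burn_keep=500, seed=2)
        assert est.converged
        props = est.as_dict()
        assert abs(props["U1"] - 0.5) < 0.05 and abs(props["U2"] - 0.5) < 0.05

    def test_posterior_mean_close_to_em_at_large_n(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U2", "U3"), proportions=(0.5, 0.3, 0.2), n=1000, seed=5),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        L = genotype_loglik(t, mix)
        em = em_mixture(L).proportions
        mc = bayes_mixture_mcmc(t, mix, chains=4, iters=2000, burn_keep=500, seed=6).proportions
        assert np.abs(em - mc).max() < 0.03

    def test_baseline_update_variant_runs(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U2"), proportions=(0.5, 0.5), n=40, seed=7),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        est = bayes_mixture_mcmc(
            t, mix, chains=2, iters=300, burn_keep=100, seed=8, update_baseline=True
        )
        assert est.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U2"), proportions=(0.5, 0.5), n=30, seed=9),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        e1 = bayes_mixture_mcmc(t, mix, chains=2, iters=400, burn_keep=100, seed=3)
        e2 = bayes_mixture_mcmc(t, mix, chains=2, iters=400, burn_keep=100, seed=3)
        np.testing.assert_array_equal(e1.proportions, e2.proportions)


class TestAssignment:
    def test_min_loci_filter(self):
        reg = disjoint_registry(n_units=2, n=20, n_loci=10)
        g = np.concatenate([c.genotypes[:2] for c in reg.collections], axis=0)
        g[0, 2:, :] = -1  # first fish typed at only 2 loci
        mix = MixtureSample(loci=reg.loci, genotypes=g)
        res = assign_individuals(reg, mix, min_loci=9)
        assert not res.passed[0]
        assert res.best_unit[0] is None
        assert np.isnan(res.posterior[0])

    def test_disjoint_units_fully_correct(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U2",), proportions=(1.0,), n=40, seed=4),
        )
        res = assign_individuals(separable_registry, mix, min_loci=1)
        assert all(b == "U2" for b in res.best_unit)
        assert res.percent_by_unit["U2"] == pytest.approx(100.0)

    def test_symmetric_tie_flagged(self):
        t_reg = disjoint_registry(n_units=2, n=10, n_loci=1)
        # individual typed with an allele unseen anywhere: equal posterior
        mix = MixtureSample(loci=t_reg.loci, genotypes=np.array([[[99, 99]]]))
        res = assign_individuals(t_reg, mix, min_loci=1)
        assert res.tied[0]
        # equal posteriors: 1/B each
        assert res.posterior[0] == pytest.approx(0.5, abs=1e-9)

    def test_all_filtered_rejected(self, separable_registry):
        mix = MixtureSample(
            loci=separable_registry.loci, genotypes=np.full((3, 2, 2), -1)
        )
        with pytest.raises(ValueError, match="loci"):
            assign_individuals(separable_registry, mix, min_loci=1)


class TestAggregate:
    def test_allocate_and_sum_arithmetic(self):
        reg = disjoint_registry(n_units=3)
        est = sx.MixtureEstimate(
            units=["U1", "U2", "U3"], proportions=np.array([0.3, 0.2, 0.5])
        )
        by_region = aggregate(est, reg, level="region")
        assert by_region["R1"] == pytest.approx(0.3 + 0.5)  # U1, U3
        assert by_region["R2"] == pytest.approx(0.2)
        assert sum(by_region.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pool_and_allocate_identity_for_single_site_catchments(self, separable_registry):
        mix = sx.make_mixture(
            separable_registry,
            sx.MixtureSpec(units=("U1", "U3"), proportions=(0.5, 0.5), n=60, seed=6),
        )
        t = AlleleFreqTable.from_registry(separable_registry)
        est = em_mixture(genotype_loglik(t, mix))
        summed = aggregate(est, separable_registry, level="catchment")
        pooled = aggregate(
            est, separable_registry, level="catchment", method="pool_and_allocate", mixture=mix
        )
        for unit in summed:
            assert pooled[unit] == pytest.approx(summed[unit], abs=1e-4)

    def test_unknown_unit_rejected(self, separable_registry):
        est = sx.MixtureEstimate(units=["NOPE"], proportions=np.array([1.0]))
        with pytest.raises(KeyError):
            aggregate(est, separable_registry, level="region")
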