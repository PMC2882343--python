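import numpy as np
import pytest

import salmix as sx
from salmix.fstats import (
    DistanceMatrix,
    da_distance,
    da_matrix,
    pairwise_fst,
    variance_components,
    wc_theta,
)
from salmix.genotype_io import BaselineRegistry, HierarchyMap, Locus, SampleCollection

AB = Locus("L1", (1, 2))


def _coll(geno, id):
    return SampleCollection(id=id, site=id, catchment=id, genotypes=np.asarray(geno))


def _registry(colls, loci, groups=None):
    s2c = {c.id: c.id for c in colls}
    c2r = {c.id: (groups[c.id] if groups else c.id) for c in colls}
    return BaselineRegistry(loci=loci, collections=colls, hierarchy=HierarchyMap(s2c, c2r))


def _oracle_wc_two_pop_biallelic(n1, p1, h1, n2, p2, h2):
    """Independent textbook Weir-Cockerham theta for 2 pops, 2 alleles.

    Written directly from the published component formulas, per allele.
    """
    r = 2
    num = den = 0.0
    for p_1, p_2, hh1, hh2 in (((p1, p2, h1, h2)), ((1 - p1, 1 - p2, h1, h2))):
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p_1 + n2 * p_2) / (n1 + n2)
        s2 = (n1 * (p_1 - pbar) ** 2 + n2 * (p_2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * hh1 + n2 * hh2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWcTheta:
    def test_identical_compositions_near_zero(self):
        rng = np.random.default_rng(0)
        g = rng.choice((1, 2), size=(100, 1, 2))
        res = wc_theta([_coll(g, "A"), _coll(g.copy(), "B")], [AB])
        assert abs(res.estimate) < 0.02

    def test_complete_fixation(self):
        a = _coll(np.full((30, 1, 2), 1), "A")
        b = _coll(np.full((30, 1, 2), 2), "B")
        res = wc_theta([a, b], [AB])
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        # counts: pop1 AA=10, AB=10; pop2 AB=10, BB=10
        g1 = np.array([[[1, 1]]] * 10 + [[[1, 2]]] * 10)
        g2 = np.array([[[1, 2]]] * 10 + [[[2, 2]]] * 10)
        res = wc_theta([_coll(g1, "A"), _coll(g2, "B")], [AB])
        p1, h1 = 30 / 40, 0.5
        p2, h2 = 10 / 40, 0.5
        expected = _oracle_wc_two_pop_biallelic(20, p1, h1, 20, p2, h2)
        assert res.estimate == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(1)
        g1 = rng.choice((1, 2), size=(40, 1, 2), p=[0.8, 0.2])
        g2 = rng.choice((1, 2), size=(40, 1, 2), p=[0.3, 0.7])
        t1 = wc_theta([_coll(g1, "A"), _coll(g2, "B")], [AB]).estimate
        # swap allele labels 1 <-> 2 and collection order
        t2 = wc_theta([_coll(3 - g2, "B"), _coll(3 - g1, "A")], [AB]).estimate
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_all_monomorphic_rejected(self):
        a = _coll(np.full((5, 1, 2), 1), "A")
        b = _coll(np.full((5, 1, 2), 1), "B")
        with pytest.raises(ValueError, match="polymorphic"):
            wc_theta([a, b], [AB])


class TestPairwise:
    def test_matrix_structure(self, clean_registry):
        registry, _ = clean_registry
        pw = pairwise_fst(registry, n_perm=0)
        U = len(registry.collections)
        assert pw.n_pairs == U * (U - 1) // 2
        np.testing.assert_allclose(pw.theta, pw.theta.T)
        assert np.all(np.diag(pw.theta) == 0)

    def test_permutation_p_small_for_differentiated_pair(self):
        spec = sx.HierarchySpec(
            regions=2, catchments_per_region=1, sites_per_catchment=1,
            F_region=0.1, F_catchment=1e-4, F_site=1e-4, loci=6, seed=2,
        )
        reg, _ = sx.simulate_registry(
            spec, n_per_site=30, missing_rate=0.0, error_rate=0.0, null_loci={}
        )
        pw = pairwise_fst(reg, n_perm=200, seed=0)
        assert pw.p[0, 1] < 0.05

    def test_permutation_size_for_identical_pops(self):
        loc = Locus("L", tuple(range(1, 7)))
        fr = [np.full(6, 1 / 6)]
        rejections = []
        for seed in range(60):
            a = sx.sample_collection([loc], fr, 20, seed=3 * seed, id="A")
            b = sx.sample_collection([loc], fr, 20, seed=3 * seed + 1, id="B")
            reg = _registry([a, b], [loc])
            pw = pairwise_fst(reg, n_perm=100, seed=seed)
            rejections.append(pw.p[0, 1] <= 0.05)
        assert abs(np.mean(rejections) - 0.05) <= 0.07

    def test_global_theta_tracks_generator_target(self):
        means = []
        for f in (0.01, 0.04, 0.10):
            vals = []
            for seed in range(5):
                spec = sx.HierarchySpec(
                    regions=2, catchments_per_region=1, sites_per_catchment=2,
                    F_region=f, F_catchment=f / 2, F_site=f / 2, loci=6, seed=seed,
                )
                reg, _ = sx.simulate_registry(
                    spec, n_per_site=30, missing_rate=0.0, error_rate=0.0, null_loci={}
                )
                vals.append(wc_theta(reg.collections, reg.loci).estimate)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestVarianceComponents:
    def test_identical_replicas_mostly_within(self):
        spec = sx.HierarchySpec(
            regions=1, catchments_per_region=1, sites_per_catchment=1, loci=6, seed=3
        )
        truth = sx.simulate_allele_freqs(spec)
        fr = [truth.true_freqs[j][0] for j in range(6)]
        colls = [
            sx.sample_collection(truth.loci, fr, 40, seed=i, id=f"P{i}") for i in range(4)
        ]
        reg = _registry(colls, truth.loci, groups={f"P{i}": ("G1" if i < 2 else "G2") for i in range(4)})
        vc = variance_components(reg)
        assert vc.percent[2] > 98.0
        assert abs(vc.percent[0]) < 1.0 and abs(vc.percent[1]) < 1.0

    def test_percents_sum_to_100(self, clean_registry):
        registry, _ = clean_registry
        vc = variance_components(registry)
        assert sum(vc.percent) == pytest.approx(100.0, abs=0.01)
        assert vc.F_CT == pytest.approx(vc.among_groups / (vc.among_groups + vc.among_within + vc.within))

    def test_brute_force_oracle_small(self):
        # 3 collections, 2 groups, one biallelic locus; direct SS computation
        g1 = np.array([[[1, 1]]] * 4 + [[[1, 2]]] * 2)
        g2 = np.array([[[1, 2]]] * 3 + [[[2, 2]]] * 3)
        g3 = np.array([[[2, 2]]] * 5 + [[[1, 2]]] * 1)
        colls = [_coll(g1, "A"), _coll(g2, "B"), _coll(g3, "C")]
        reg = _registry(colls, [AB], groups={"A": "G1", "B": "G1", "C": "G2"})
        vc = variance_components(reg)

        # direct sums of squares on 0/1 allele-identity distances
        copies = [c.genotypes[:, 0, :].reshape(-1) for c in colls]
        group_of = [0, 0, 1]

        def ssd(groups_of_copies):
            all_ = np.concatenate(groups_of_copies)
            n = len(all_)
            d = (all_[:, None] != all_[None, :]).astype(float)
            return d[np.triu_indices(n, 1)].sum() / n

        ssd_total = ssd([np.concatenate(copies)])
        ssd_wp = sum(ssd([c]) for c in copies)
        ssd_wg = ssd([np.concatenate([copies[0], copies[1]])]) + ssd([copies[2]])
        N = sum(len(c) for c in copies)
        P, G = 3, 2
        ms_wp = ssd_wp / (N - P)
        ms_apwg = (ssd_wg - ssd_wp) / (P - G)
        ms_ag = (ssd_total - ssd_wg) / (G - 1)
        n_p = np.array([len(c) for c in copies], dtype=float)
        n_g = np.array([len(copies[0]) + len(copies[1]), len(copies[2])], dtype=float)
        sum_npsq_over_ng = (n_p[0] ** 2 + n_p[1] ** 2) / n_g[0] + n_p[2] ** 2 / n_g[1]
        n1 = (N - sum_npsq_over_ng) / (P - G)
        n2 = (sum_npsq_over_ng - (n_p**2).sum() / N) / (G - 1)
        n3 = (N - (n_g**2).sum() / N) / (G - 1)
        sigma_c = ms_wp
        sigma_b = (ms_apwg - sigma_c) / n1
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
        assert vc.within == pytest.approx(sigma_c, abs=1e-10)
        assert vc.among_within == pytest.approx(sigma_b, abs=1e-10)
        assert vc.among_groups == pytest.approx(sigma_a, abs=1e-10)
        _ = group_of

    def test_one_group_per_collection_has_zero_within_group_component(self, clean_registry):
        registry, _ = clean_registry
        grouping = {site: site for site in registry.hierarchy.sites()}
        vc = variance_components(registry, grouping=grouping)
        assert vc.among_within == 0.0

    def test_recovers_group_level_drift(self):
        vals = []
        for s in range(8):
            spec = sx.HierarchySpec(
                regions=2, catchments_per_region=1, sites_per_catchment=4,
                F_region=0.02, F_catchment=1e-6, F_site=0.02, loci=12, seed=s,
            )
            reg, _ = sx.simulate_registry(
                spec, n_per_site=30, missing_rate=0.0, error_rate=0.0, null_loci={}
            )
            vals.append(variance_components(reg).F_CT)
        assert abs(np.mean(vals) - 0.02) < 0.01


class TestDa:
    def test_identical_zero(self):
        f = [np.array([0.2, 0.8]), np.array([0.5, 0.5])]
        assert da_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_one(self):
        assert da_distance([np.array([1.0, 0.0])], [np.array([0.0, 1.0])]) == 1.0

    def test_hand_value(self):
        d = da_distance([np.array([1.0, 0.0])], [np.array([0.5, 0.5])])
        assert d == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)

    def test_matrix_properties(self, clean_registry):
        registry, _ = clean_registry
        d = da_matrix(registry)
        v = d.values
        assert np.all((v >= 0) & (v <= 1))
        np.testing.assert_allclose(v, v.T)
        assert np.all(np.diag(v) == 0)

    def test_no_shared_loci_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            da_distance([np.zeros(2)], [np.array([0.5, 0.5])])


def test_phylip_output_readable(tmp_path, clean_registry):
    registry, _ = clean_registry
    d = da_matrix(registry)
    out = tmp_path / "d.phy"
    d.to_phylip(out)
    lines = out.read_text().splitlines()
    assert lines[0].strip() == str(len(d.labels))
    assert len(lines) == len(d.labels) + 1
    first = np.array(lines[1].split()[1:], dtype=float)
    np.testing.assert_allclose(first, d.values[0], atol=1e-6)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(labels=["a", "b"], values=np.array([[1, 1], [1, 0]], float))
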