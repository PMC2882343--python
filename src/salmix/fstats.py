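"""Differentiation statistics.

Weir & Cockerham (1984) theta (global, per-locus, and pairwise with
permutation tests), three-level hierarchical variance components (AMOVA on
allele-identity distances, the unordered-allele default), and the Nei et
al. (1983) D_A allele-sharing distance.  Missing genotypes are excluded per
locus (pairwise deletion) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .freqs import AlleleFreqTable
from .genotype_io import MISSING, BaselineRegistry, Locus, SampleCollection

__all__ = [
    "FstResult",
    "PairwiseFst",
    "VarianceComponents",
    "DistanceMatrix",
    "wc_theta",
    "pairwise_fst",
    "variance_components",
    "da_distance",
    "da_matrix",
]


@dataclass
class FstResult:
    estimate: float
    per_locus: dict[str, float]
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class PairwiseFst:
    labels: list[str]
    theta: np.ndarray  # (U, U), symmetric, zero diagonal
    p: np.ndarray | None  # same shape, NaN diagonal
    n_pairs: int
    n_permutations: int = 0


@dataclass
class VarianceComponents:
    """Three-level hierarchical variance components.

    ``among_groups``/``among_within``/``within`` are absolute components
    (summed over loci); percents are of their total.  F_CT is the
    among-group fraction, F_SC the among-collections-within-groups fraction
    of the within-group total, F_ST the combined among fraction.
    """

    among_groups: float
    among_within: float
    within: float
    percent: tuple[float, float, float] = field(init=False)
    F_CT: float | None = None
    F_SC: float | None = None
    F_ST: float | None = None

    def __post_init__(self) -> None:
        total = self.among_groups + self.among_within + self.within
        self.percent = tuple(
            100.0 * x / total for x in (self.among_groups, self.among_within, self.within)
        )
        if self.F_CT is None and total > 0:
            self.F_CT = self.among_groups / total
            self.F_SC = (
                self.among_within / (self.among_within + self.within)
                if (self.among_within + self.within) > 0
                else 0.0
            )
            self.F_ST = (self.among_groups + self.among_within) / total


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, path) -> None:
        """Write the square PHYLIP distance format (names padded to 10)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                name = lab[:10].ljust(10)
                fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")


def _locus_stats(
    collections: list[SampleCollection], locus: Locus, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population typed counts, allele frequencies and per-allele
    heterozygote proportions at one locus."""
    K = locus.n_alleles
    idx = locus.index_of()
    r = len(collections)
    n = np.zeros(r)
    p = np.zeros((r, K))
    h = np.zeros((r, K))
    for i, coll in enumerate(collections):
        g = coll.genotypes[:, j, :]
        typed = g[g[:, 0] != MISSING]
        n[i] = typed.shape[0]
        if n[i] == 0:
            continue
        for a, b in typed.tolist():
            ia, ib = idx[a], idx[b]
            p[i, ia] += 1
            p[i, ib] += 1
            if ia != ib:
                h[i, ia] += 1
                h[i, ib] += 1
        p[i] /= 2 * n[i]
        h[i] /= n[i]
    return n, p, h


def _wc_locus_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, float] | None:
    """Sum over alleles of the W&C (a, a+b+c) variance components."""
    keep = n > 0
    n, p, h = n[keep], p[keep], h[keep]
    r = len(n)
    if r < 2:
        return None
    nbar = n.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float((a + b + c).sum())


def wc_theta(collections: list[SampleCollection], loci: list[Locus]) -> FstResult:
    """Weir-Cockerham multi-locus theta: ratio of summed among-population
    variance components over loci and alleles.  Negative per-locus values
    are retained in the sums (standard practice)."""
    if len(collections) < 2:
        raise ValueError("theta needs at least two collections")
    num = 0.0
    den = 0.0
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(loci):
        stats = _locus_stats(collections, locus, j)
        comp = _wc_locus_components(*stats)
        if comp is None:
            continue
        a, abc = comp
        if abc != 0.0:
            per_locus[locus.name] = a / abc
        num += a
        den += abc
    if den == 0.0:
        raise ValueError("no polymorphic locus with data in >= 2 collections")
    return FstResult(estimate=num / den, per_locus=per_locus)


def _index_genotypes(g: np.ndarray, loci: list[Locus]) -> np.ndarray:
    """Map allele labels to per-locus registry indices (-1 = missing)."""
    out = np.full(g.shape, -1, dtype=np.int32)
    for j, locus in enumerate(loci):
        alleles = np.asarray(locus.alleles)
        order = np.argsort(alleles)
        gl = g[:, j, :]
        typed = gl[:, 0] != MISSING
        if typed.any():
            pos = np.searchsorted(alleles[order], gl[typed])
            out[typed, j, :] = order[pos]
    return out


def _two_pop_theta_indexed(
    giA: np.ndarray, giB: np.ndarray, n_alleles: list[int]
) -> float:
    """theta for two allele-index genotype arrays; NaN when undefined."""
    num = den = 0.0
    for j, K in enumerate(n_alleles):
        n = np.zeros(2)
        p = np.zeros((2, K))
        h = np.zeros((2, K))
        for i, gi in enumerate((giA, giB)):
            gl = gi[:, j, :]
            typed = gl[gl[:, 0] >= 0]
            n[i] = typed.shape[0]
            if n[i] == 0:
                continue
            p[i] = np.bincount(typed.reshape(-1), minlength=K) / (2 * n[i])
            het = typed[:, 0] != typed[:, 1]
            if het.any():
                h[i] = np.bincount(typed[het].reshape(-1), minlength=K) / n[i]
        comp = _wc_locus_components(n, p, h)
        if comp is None:
            continue
        num += comp[0]
        den += comp[1]
    return num / den if den != 0.0 else np.nan


def _two_pop_theta(gA: np.ndarray, gB: np.ndarray, loci: list[Locus]) -> float:
    return _two_pop_theta_indexed(
        _index_genotypes(gA, loci), _index_genotypes(gB, loci), [l.n_alleles for l in loci]
    )


def _all_pairs_theta(registry: BaselineRegistry) -> np.ndarray:
    """theta for every unordered pair, vectorised over pairs per locus.

    For two populations W&C theta depends only on per-population typed
    counts, allele frequencies and per-allele heterozygote proportions, so
    those sufficient statistics are computed once per collection and
    combined across all pairs by broadcasting.
    """
    colls = registry.collections
    U = len(colls)
    num = np.zeros((U, U))
    den = np.zeros((U, U))
    for j, locus in enumerate(registry.loci):
        n, p, h = _locus_stats(colls, locus, j)
        N1, N2 = n[:, None], n[None, :]
        valid = (N1 > 0) & (N2 > 0)
        nbar = (N1 + N2) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            nc = 2.0 * nbar - (N1**2 + N2**2) / (2.0 * nbar)
            ok = valid & (nbar > 1) & (nc > 0)
            w1 = (N1 / (2.0 * nbar))[:, :, None]
            w2 = (N2 / (2.0 * nbar))[:, :, None]
            pbar = w1 * p[:, None, :] + w2 * p[None, :, :]
            s2 = (
                N1[:, :, None] * (p[:, None, :] - pbar) ** 2
                + N2[:, :, None] * (p[None, :, :] - pbar) ** 2
            ) / nbar[:, :, None]
            hbar = w1 * h[:, None, :] + w2 * h[None, :, :]
            inner = pbar * (1.0 - pbar) - s2 / 2.0
            nb = nbar[:, :, None]
            ncb = nc[:, :, None]
            a = nb / ncb * (s2 - (inner - hbar / 4.0) / (nb - 1.0))
            b = nb / (nb - 1.0) * (inner - (2.0 * nb - 1.0) / (4.0 * nb) * hbar)
            c = hbar / 2.0
            num += np.sum(np.where(ok[:, :, None], a, 0.0), axis=2)
            den += np.sum(np.where(ok[:, :, None], a + b + c, 0.0), axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(den != 0.0, num / den, np.nan)
    np.fill_diagonal(theta, 0.0)
    return theta


def pairwise_fst(
    registry: BaselineRegistry, n_perm: int = 10_000, seed: int = 0
) -> PairwiseFst:
    """theta for every unordered pair of collections, with a permutation
    p-value (individuals shuffled between the pair, sizes preserved;
    ``p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1)``).  Set
    ``n_perm=0`` to skip the tests."""
    colls = registry.collections
    U = len(colls)
    if U < 2:
        raise ValueError("need at least two collections")
    labels = [c.id for c in colls]
    theta = np.zeros((U, U))
    p = np.full((U, U), np.nan) if n_perm > 0 else None
    rng = np.random.default_rng(seed)
    n_alleles = [l.n_alleles for l in registry.loci]
    theta = _all_pairs_theta(registry)
    indexed = (
        [_index_genotypes(c.genotypes, registry.loci) for c in colls] if n_perm > 0 else []
    )
    n_pairs = 0
    for i in range(U):
        for k in range(i + 1, U):
            n_pairs += 1
            obs = theta[i, k]
            if n_perm > 0 and np.isfinite(obs):
                giA, giB = indexed[i], indexed[k]
                combined = np.concatenate([giA, giB], axis=0)
                nA = giA.shape[0]
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(combined.shape[0])
                    t = _two_pop_theta_indexed(
                        combined[perm[:nA]], combined[perm[nA:]], n_alleles
                    )
                    if np.isfinite(t) and t >= obs:
                        hits += 1
                p[i, k] = p[k, i] = (hits + 1) / (n_perm + 1)
    return PairwiseFst(labels=labels, theta=theta, p=p, n_pairs=n_pairs, n_permutations=n_perm)


def _amova_locus(
    counts: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float] | None:
    """Variance components for one locus from a (pops, alleles) gene-copy
    count matrix and a group index per pop.  Allele-identity distances make
    the sums of squares functions of the counts alone."""
    n_p = counts.sum(axis=1).astype(float)
    keep = n_p > 0
    counts, groups, n_p = counts[keep], groups[keep], n_p[keep]
    P = len(n_p)
    G = len(np.unique(groups))
    N = n_p.sum()
    if P < 2 or N <= P:
        return None
    ssd_wp = float(np.sum((n_p - (counts**2).sum(axis=1) / n_p) / 2.0))
    c_tot = counts.sum(axis=0)
    ssd_total = float((N - np.sum(c_tot**2) / N) / 2.0)
    if G >= 2:
        ssd_wg = 0.0
        sum_npsq_over_ng = 0.0
        sum_ngsq = 0.0
        for g in np.unique(groups):
            sel = groups == g
            n_g = n_p[sel].sum()
            c_g = counts[sel].sum(axis=0)
            ssd_wg += (n_g - np.sum(c_g**2) / n_g) / 2.0
            sum_npsq_over_ng += np.sum(n_p[sel] ** 2) / n_g
            sum_ngsq += n_g**2
        ssd_apwg = ssd_wg - ssd_wp
        ssd_ag = ssd_total - ssd_wg
        df_ag, df_apwg, df_wp = G - 1, P - G, N - P
        if df_apwg <= 0:
            # one collection per group: the within-group level is empty and
            # the among-group component is the plain among-population one
            ms_wp = ssd_wp / df_wp
            ms_ag = ssd_ag / df_ag
            ncoef = (N - np.sum(n_p**2) / N) / df_ag
            sigma_c = ms_wp
            sigma_a = (ms_ag - sigma_c) / ncoef if ncoef > 0 else 0.0
            return sigma_a, 0.0, sigma_c
        ms_wp = ssd_wp / df_wp
        ms_apwg = ssd_apwg / df_apwg
        ms_ag = ssd_ag / df_ag
        n1 = (N - sum_npsq_over_ng) / df_apwg
        n2 = (sum_npsq_over_ng - np.sum(n_p**2) / N) / df_ag
        n3 = (N - sum_ngsq / N) / df_ag
        sigma_c = ms_wp
        sigma_b = (ms_apwg - sigma_c) / n1 if n1 > 0 else 0.0
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        return sigma_a, sigma_b, sigma_c
    # two-level collapse
    ssd_ap = ssd_total - ssd_wp
    ms_wp = ssd_wp / (N - P)
    ms_ap = ssd_ap / (P - 1)
    ncoef = (N - np.sum(n_p**2) / N) / (P - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / ncoef if ncoef > 0 else 0.0
    return 0.0, sigma_b, sigma_c


def variance_components(
    registry: BaselineRegistry, grouping: dict[str, str] | None = None
) -> VarianceComponents:
    """Hierarchical AMOVA over (groups, collections within groups,
    within-collection gene copies).

    ``grouping`` maps each collection's site to a group label; by default
    the registry hierarchy's reporting regions are used.  Components are
    summed across loci.  With a single group the analysis collapses to two
    levels and F_CT is unset.
    """
    if grouping is None:
        grouping = {
            site: registry.hierarchy.region_of(site) for site in registry.hierarchy.sites()
        }
    group_labels = [grouping[c.site] for c in registry.collections]
    uniq = sorted(set(group_labels))
    gidx = np.array([uniq.index(g) for g in group_labels])
    table = AlleleFreqTable.from_registry(registry)
    tot_a = tot_b = tot_c = 0.0
    for j in range(len(registry.loci)):
        comp = _amova_locus(table.counts[j], gidx)
        if comp is None:
            continue
        tot_a += comp[0]
        tot_b += comp[1]
        tot_c += comp[2]
    if tot_a + tot_b + tot_c == 0.0:
        raise ValueError("no locus with enough data for variance components")
    vc = VarianceComponents(among_groups=tot_a, among_within=tot_b, within=tot_c)
    if len(uniq) < 2:
        vc.F_CT = None
    return vc


def da_distance(freqsA: list[np.ndarray], freqsB: list[np.ndarray]) -> float:
    """Nei et al. (1983) D_A between two units from per-locus frequency
    vectors: ``1 - (1/L) sum_l sum_a sqrt(x_a y_a)``."""
    if len(freqsA) != len(freqsB) or not freqsA:
        raise ValueError("frequency lists must be non-empty and of equal length")
    total = 0.0
    L = 0
    for x, y in zip(freqsA, freqsB):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.sum() == 0 or y.sum() == 0:
            continue
        total += float(np.sqrt(x * y).sum())
        L += 1
    if L == 0:
        raise ValueError("no shared typed loci")
    return float(np.clip(1.0 - total / L, 0.0, 1.0))


def da_matrix(registry: BaselineRegistry) -> DistanceMatrix:
    """Pairwise D_A over all collections from plain count frequencies; loci
    untyped in either member of a pair are dropped for that pair."""
    table = AlleleFreqTable.from_registry(registry)
    U = table.n_units
    L = len(table.loci)
    typed_l = np.zeros((U, L), dtype=bool)
    per_locus_share = []
    for j in range(L):
        f = table.ml_freqs(j)
        typed = table.totals[j] > 0
        typed_l[:, j] = typed
        s = np.sqrt(f) @ np.sqrt(f).T
        per_locus_share.append(s)
    d = np.zeros((U, U))
    for u in range(U):
        for v in range(u + 1, U):
            shared = typed_l[u] & typed_l[v]
            if not shared.any():
                raise ValueError(
                    f"no shared typed loci between {table.units[u]} and {table.units[v]}"
                )
            val = 1.0 - np.mean([per_locus_share[j][u, v] for j in np.flatnonzero(shared)])
            d[u, v] = d[v, u] = min(max(val, 0.0), 1.0)
    return DistanceMatrix(labels=list(table.units), values=d)
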