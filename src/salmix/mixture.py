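"""Mixed-stock analysis and individual assignment.

The model: a mixture fish's multilocus genotype, given that it originates
from baseline unit ``b``, has probability per locus ``2 p_a p_b`` for a
heterozygote and ``p_a^2`` for a homozygote, with loci independent and
``p`` the unit's posterior-mean allele frequencies (1/K pseudo-counts, see
:mod:`salmix.freqs`).  Stock proportions are estimated either by EM
maximum likelihood (uncertainty by bootstrap over mixture individuals) or
by a conditional Gibbs sampler (Dirichlet(1/B) prior over proportions,
baseline frequencies fixed at posterior means, with an optional variant
that resamples baseline frequencies each sweep).  Multi-chain convergence
is monitored with the Gelman-Rubin shrink factor.

Baseline self-tests use leave-one-out: an individual's two alleles are
removed from its own unit's counts before computing its likelihood there,
avoiding self-inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .freqs import AlleleFreqTable
from .genotype_io import MISSING, BaselineRegistry, Locus
from .synthetic import MixtureSample
from .util import rng_for

__all__ = [
    "LikelihoodMatrix",
    "MixtureEstimate",
    "AssignmentResult",
    "extend_panel",
    "genotype_loglik",
    "em_mixture",
    "em_bootstrap_sd",
    "bayes_mixture_mcmc",
    "gelman_rubin",
    "assign_individuals",
    "aggregate",
]

LOGLIK_FLOOR = -700.0


@dataclass
class LikelihoodMatrix:
    """Per-individual, per-baseline-unit multilocus log-likelihoods."""

    units: list[str]
    loglik: np.ndarray  # (n, U), floored at LOGLIK_FLOOR
    n_typed_loci: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return self.loglik.shape[0]

    def scaled_likelihood(self) -> np.ndarray:
        """exp(loglik) scaled per row by the row maximum (rows sum > 0)."""
        shift = self.loglik.max(axis=1, keepdims=True)
        return np.exp(self.loglik - shift)


@dataclass
class MixtureEstimate:
    """Stock-proportion estimate with uncertainty and diagnostics."""

    units: list[str]
    proportions: np.ndarray
    sd: np.ndarray | None = None
    ci: tuple[np.ndarray, np.ndarray] | None = None  # 2.5-97.5 bootstrap percentiles
    method: str = "EM"
    converged: bool = True
    iterations: int = 0
    shrink_factors: np.ndarray | None = None
    by_catchment: dict[str, float] | None = None
    by_region: dict[str, float] | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.units, self.proportions.tolist()))


@dataclass
class AssignmentResult:
    units: list[str]
    best_unit: list[str | None]  # None where the min-loci filter failed
    posterior: np.ndarray  # (n,) posterior of the best unit (NaN if failed)
    n_typed_loci: np.ndarray
    passed: np.ndarray
    tied: np.ndarray
    percent_by_unit: dict[str, float] = field(default_factory=dict)
    percent_by_catchment: dict[str, float] = field(default_factory=dict)
    percent_by_region: dict[str, float] = field(default_factory=dict)


def extend_panel(table: AlleleFreqTable, mixture: MixtureSample) -> AlleleFreqTable:
    """Extend the baseline allele sets with any mixture allele unseen in the
    whole baseline; the new alleles receive prior-only (1/K) mass."""
    new_loci: list[Locus] = []
    new_counts: list[np.ndarray] = []
    changed = False
    for j, locus in enumerate(table.loci):
        g = mixture.genotypes[:, j, :]
        present = set(g[g != MISSING].tolist())
        extra = sorted(present - set(locus.alleles))
        if not extra:
            new_loci.append(locus)
            new_counts.append(table.counts[j])
            continue
        changed = True
        new_loci.append(Locus(locus.name, tuple(locus.alleles) + tuple(extra)))
        pad = np.zeros((table.n_units, len(extra)), dtype=np.int64)
        new_counts.append(np.hstack([table.counts[j], pad]))
    if not changed:
        return table
    if table.true_freqs is not None:
        raise ValueError("cannot extend a truth-frequency table with unseen alleles")
    return AlleleFreqTable(
        loci=new_loci, units=list(table.units), counts=new_counts, totals=list(table.totals)
    )


def genotype_loglik(
    table: AlleleFreqTable,
    mixture: MixtureSample,
    loo_origins: list[str | None] | None = None,
) -> LikelihoodMatrix:
    """Log-likelihood of every mixture genotype under every baseline unit.

    With ``loo_origins`` set (one baseline unit id, or None, per
    individual), that individual's alleles are removed from its own unit's
    counts before computing the entry for that unit (leave-one-out).
    Individuals typed at zero loci get an all-zero row and are flagged by
    ``n_typed_loci == 0``.
    """
    table = extend_panel(table, mixture)
    units = table.units
    U = len(units)
    n = mixture.n
    total = np.zeros((n, U))
    typed_count = np.zeros(n, dtype=np.int64)
    loo_idx = None
    if loo_origins is not None:
        if len(loo_origins) != n:
            raise ValueError("one LOO origin (or None) per mixture individual required")
        loo_idx = np.array([units.index(o) if o is not None else -1 for o in loo_origins])

    for j, locus in enumerate(table.loci):
        idx = locus.index_of()
        K = locus.n_alleles
        g = mixture.genotypes[:, j, :]
        typed = g[:, 0] != MISSING
        if not typed.any():
            continue
        typed_count += typed.astype(np.int64)
        rows = np.flatnonzero(typed)
        A = np.array([idx[a] for a in g[rows, 0].tolist()])
        B = np.array([idx[b] for b in g[rows, 1].tolist()])
        P = table.posterior_freqs(j)  # (U, K)
        logP = np.log(P)
        het = (A != B).astype(float)
        contrib = logP[:, A].T + logP[:, B].T + het[:, None] * np.log(2.0)
        if loo_idx is not None and table.true_freqs is None:
            c = table.counts[j]
            tot = table.totals[j]
            for r_pos, i in enumerate(rows):
                u = loo_idx[i]
                if u < 0:
                    continue
                denom = max(tot[u] - 2, 0) + 1.0
                if A[r_pos] == B[r_pos]:
                    pa = (max(c[u, A[r_pos]] - 2, 0) + 1.0 / K) / denom
                    contrib[r_pos, u] = 2.0 * np.log(pa)
                else:
                    pa = (max(c[u, A[r_pos]] - 1, 0) + 1.0 / K) / denom
                    pb = (max(c[u, B[r_pos]] - 1, 0) + 1.0 / K) / denom
                    contrib[r_pos, u] = np.log(2.0) + np.log(pa) + np.log(pb)
        total[rows] += contrib
    total = np.maximum(total, LOGLIK_FLOOR)
    total[typed_count == 0] = 0.0
    return LikelihoodMatrix(units=list(units), loglik=total, n_typed_loci=typed_count)


def em_mixture(
    L: LikelihoodMatrix, tol: float = 1e-7, max_iter: int = 20_000
) -> MixtureEstimate:
    """EM maximum-likelihood stock proportions.

    Starts uniform; E-step computes origin responsibilities, M-step sets
    proportions to their mean.  The observed-data log-likelihood is checked
    to be non-decreasing every iteration; iteration stops when the largest
    proportion change drops below ``tol``.
    """
    lik = L.scaled_likelihood()
    informative = L.n_typed_loci > 0
    if not informative.any():
        raise ValueError("no informative mixture individuals")
    lik = lik[informative]
    n, U = lik.shape
    theta = np.full(U, 1.0 / U)
    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = lik * theta
        rowsum = mix.sum(axis=1, keepdims=True)
        ll = float(np.log(rowsum).sum())
        if ll < last_ll - 1e-9 * max(1.0, abs(last_ll)):
            raise AssertionError("EM log-likelihood decreased")
        last_ll = ll
        w = mix / rowsum
        new_theta = w.mean(axis=0)
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return MixtureEstimate(
        units=list(L.units),
        proportions=theta,
        method="EM",
        converged=converged,
        iterations=it,
    )


def em_bootstrap_sd(
    L: LikelihoodMatrix, n_boot: int = 100, seed: int = 0, tol: float = 1e-6
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Bootstrap uncertainty of the EM proportions: resample mixture
    individuals with replacement, rerun EM, return the SD per unit and the
    2.5-97.5 percentile interval."""
    rng = rng_for(seed, "em-bootstrap")
    n = L.n
    reps = np.empty((n_boot, len(L.units)))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        sub = LikelihoodMatrix(
            units=list(L.units),
            loglik=L.loglik[take],
            n_typed_loci=L.n_typed_loci[take],
        )
        reps[b] = em_mixture(sub, tol=tol).proportions
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return reps.std(axis=0, ddof=1), (lo, hi)


def gelman_rubin(chains) -> float:
    """Gelman-Rubin potential scale reduction (shrink) factor.

    ``chains`` is an (m, n) array of m scalar series.  R-hat =
    sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain variance and
    B/n the between-chain variance of the means.  Zero total variance
    (constant identical chains) returns 1 by convention; the value is
    reported unclamped and can fall below 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    n = x.shape[1]
    W = float(x.var(axis=1, ddof=1).mean())
    B_over_n = float(x.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def bayes_mixture_mcmc(
    table: AlleleFreqTable,
    mixture: MixtureSample,
    chains: int = 8,
    iters: int = 20_000,
    burn_keep: int = 1000,
    start_mass: float = 0.90,
    shrink_max: float = 1.2,
    seed: int = 0,
    update_baseline: bool = False,
) -> MixtureEstimate:
    """Bayesian stock-proportion estimation by multi-chain Gibbs sampling.

    Each of ``chains`` chains starts with ``start_mass`` of the proportion
    vector on a designated unit (the top units of a preliminary EM fit,
    ties broken by label) and sweeps: origin indicators z_i ~
    Categorical(theta_b L_ib), then theta ~ Dirichlet(1/B + n_b(z)).  The
    last ``burn_keep`` draws of every chain are pooled for the posterior
    mean and SD; the per-unit shrink factor is computed on those same
    retained segments and the estimate is flagged unconverged when any
    exceeds ``shrink_max``.  ``update_baseline`` additionally resamples
    baseline allele frequencies each sweep from their Dirichlet posterior
    given the baseline counts plus currently assigned mixture genotypes
    (full baseline-uncertainty variant).
    """
    if table.n_units < 2:
        raise ValueError("need at least two baseline units")
    if not (0 < burn_keep <= iters):
        raise ValueError("burn_keep must be in (0, iters]")
    table = extend_panel(table, mixture)
    L = genotype_loglik(table, mixture)
    lik = L.scaled_likelihood()
    n, U = lik.shape
    if np.any(L.n_typed_loci > 0):
        prelim = em_mixture(L).proportions
    else:  # no data: prior recovery, chains start on the first units
        prelim = np.full(U, 1.0 / U)
    order = sorted(range(U), key=lambda u: (-prelim[u], table.units[u]))
    start_units = [order[c % U] for c in range(chains)]

    # per-locus structures for the baseline-update variant
    if update_baseline:
        locus_A: list[np.ndarray] = []
        locus_B: list[np.ndarray] = []
        locus_rows: list[np.ndarray] = []
        for j, locus in enumerate(table.loci):
            idx = locus.index_of()
            g = mixture.genotypes[:, j, :]
            rows = np.flatnonzero(g[:, 0] != MISSING)
            locus_rows.append(rows)
            locus_A.append(np.array([idx[a] for a in g[rows, 0].tolist()], dtype=np.int64))
            locus_B.append(np.array([idx[b] for b in g[rows, 1].tolist()], dtype=np.int64))

    kept = np.empty((chains, burn_keep, U))
    for c in range(chains):
        rng = rng_for(seed, "mcmc-chain", c)
        theta = np.full(U, (1.0 - start_mass) / (U - 1))
        theta[start_units[c]] = start_mass
        lik_c = lik
        keep_from = iters - burn_keep
        for t in range(iters):
            probs = lik_c * theta
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            z = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            counts = np.bincount(z, minlength=U)
            theta = rng.dirichlet(1.0 / U + counts)
            if update_baseline:
                loglik = np.zeros((n, U))
                for j, locus in enumerate(table.loci):
                    K = locus.n_alleles
                    alpha = table.counts[j].astype(float) + 1.0 / K
                    add = np.zeros_like(alpha)
                    rows, A, B = locus_rows[j], locus_A[j], locus_B[j]
                    zz = z[rows]
                    np.add.at(add, (zz, A), 1.0)
                    np.add.at(add, (zz, B), 1.0)
                    gam = rng.gamma(alpha + add)
                    P = gam / gam.sum(axis=1, keepdims=True)
                    logP = np.log(np.maximum(P, 1e-300))
                    het = (A != B).astype(float)
                    loglik[rows] += logP[:, A].T + logP[:, B].T + het[:, None] * np.log(2.0)
                loglik = np.maximum(loglik, LOGLIK_FLOOR)
                lik_c = np.exp(loglik - loglik.max(axis=1, keepdims=True))
            if t >= keep_from:
                kept[c, t - keep_from] = theta

    pooled = kept.reshape(chains * burn_keep, U)
    shrink = np.array([gelman_rubin(kept[:, :, b]) for b in range(U)])
    converged = bool(np.all(shrink < shrink_max))
    return MixtureEstimate(
        units=list(table.units),
        proportions=pooled.mean(axis=0),
        sd=pooled.std(axis=0, ddof=1),
        method="MCMC",
        converged=converged,
        iterations=iters,
        shrink_factors=shrink,
    )


def assign_individuals(
    registry: BaselineRegistry,
    mixture: MixtureSample,
    min_loci: int = 9,
    loo_origins: list[str | None] | None = None,
) -> AssignmentResult:
    """Assign each mixture fish to the baseline unit with the highest
    posterior probability (uniform prior over units).

    Individuals typed at fewer than ``min_loci`` loci are excluded from the
    assignment and from the aggregated percentages; exact posterior ties
    are flagged and broken by unit order.
    """
    table = AlleleFreqTable.from_registry(registry)
    L = genotype_loglik(table, mixture, loo_origins=loo_origins)
    lik = L.scaled_likelihood()
    post = lik / lik.sum(axis=1, keepdims=True)
    passed = L.n_typed_loci >= min_loci
    if not passed.any():
        raise ValueError(f"no individual typed at >= {min_loci} loci")
    best_idx = post.argmax(axis=1)
    tied = (np.abs(post - post.max(axis=1, keepdims=True)) < 1e-12).sum(axis=1) > 1
    best = [L.units[b] if ok else None for b, ok in zip(best_idx, passed)]
    posterior = np.where(passed, post[np.arange(L.n), best_idx], np.nan)

    site_of = {c.id: c.site for c in registry.collections}
    hier = registry.hierarchy
    pct_unit: dict[str, float] = {}
    pct_catch: dict[str, float] = {}
    pct_region: dict[str, float] = {}
    n_pass = int(passed.sum())
    for b, ok in zip(best, passed):
        if not ok:
            continue
        pct_unit[b] = pct_unit.get(b, 0.0) + 100.0 / n_pass
        catch = hier.catchment_of(site_of[b])
        pct_catch[catch] = pct_catch.get(catch, 0.0) + 100.0 / n_pass
        region = hier.catchment_to_region.get(catch)
        if region is not None:
            pct_region[region] = pct_region.get(region, 0.0) + 100.0 / n_pass
    return AssignmentResult(
        units=list(L.units),
        best_unit=best,
        posterior=posterior,
        n_typed_loci=L.n_typed_loci,
        passed=passed,
        tied=tied,
        percent_by_unit=pct_unit,
        percent_by_catchment=pct_catch,
        percent_by_region=pct_region,
    )


def aggregate(
    estimate: MixtureEstimate,
    registry: BaselineRegistry,
    level: str = "region",
    method: str = "allocate_and_sum",
    mixture: MixtureSample | None = None,
    **estimator_kwargs,
):
    """Aggregate unit-level proportions to catchment or region level.

    ``allocate_and_sum`` sums the existing unit estimates within each
    group; ``pool_and_allocate`` rebuilds the baseline with
    :func:`~salmix.genotype_io.pool_collections` (catchment level), reruns
    the EM estimator on the pooled units, and reports those directly (the
    mixture must be supplied).  Both conserve total mass.
    """
    hier = registry.hierarchy
    site_of = {c.id: c.site for c in registry.collections}
    if method == "allocate_and_sum":
        out: dict[str, float] = {}
        for unit, p in zip(estimate.units, estimate.proportions):
            site = site_of[unit]
            if level == "catchment":
                group = hier.catchment_of(site)
            elif level == "region":
                group = hier.region_of(site)
            else:
                raise ValueError(f"unknown level {level!r}")
            out[group] = out.get(group, 0.0) + float(p)
        return out
    if method == "pool_and_allocate":
        if level != "catchment":
            raise ValueError("pool_and_allocate pools at catchment level")
        if mixture is None:
            raise ValueError("pool_and_allocate needs the mixture sample")
        from .genotype_io import pool_collections

        pooled = pool_collections(registry, level="catchment")
        table = AlleleFreqTable.from_registry(pooled)
        L = genotype_loglik(table, mixture)
        est = em_mixture(L, **estimator_kwargs)
        return est.as_dict()
    raise ValueError(f"unknown aggregation method {method!r}")
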