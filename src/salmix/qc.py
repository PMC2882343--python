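"""Baseline quality control.

Per collection x locus: observed and unbiased expected heterozygosity, an
exact Hardy-Weinberg conformity test (Levene's conditional distribution,
complete enumeration of genotype tables where feasible, otherwise Monte
Carlo sampling of the same distribution), a null-allele screen (one-sided
homozygote-excess test plus the Brookfield-1 null frequency estimator), a
Holm step-down correction for the test grid, Fisher-style exact tests of
temporal allele-frequency homogeneity, and the allelic mismatch rate
between duplicate genotyping runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .freqs import collection_counts
from .genotype_io import MISSING, Locus, SampleCollection
from .util import substream_seed

__all__ = [
    "LocusSummary",
    "HWEResult",
    "heterozygosities",
    "hwe_test",
    "null_allele_scan",
    "holm_correct",
    "temporal_test",
    "duplicate_error_rate",
    "expected_false_positives",
    "qc_report",
]

_REL_TOL = 1e-9


def _log_fact(max_n: int) -> np.ndarray:
    """log m! lookup for m = 0..max_n."""
    return gammaln(np.arange(max_n + 1) + 1.0)


@dataclass(frozen=True)
class LocusSummary:
    H_O: float
    H_E: float
    n_alleles: int
    n_typed: int


@dataclass(frozen=True)
class HWEResult:
    collection_id: str
    locus: str
    p_value: float
    method: str  # "enumeration" | "monte-carlo"
    mc_reps: int = 0
    seed: int | None = None


def _locus_genotypes(collection: SampleCollection, locus_index: int) -> np.ndarray:
    g = collection.genotypes[:, locus_index, :]
    return g[g[:, 0] != MISSING]


def heterozygosities(collection: SampleCollection, locus: Locus, locus_index: int) -> LocusSummary:
    """H_O = fraction of typed individuals heterozygous; H_E = Nei's
    unbiased expected heterozygosity (2n/(2n-1)) (1 - sum p_i^2)."""
    g = _locus_genotypes(collection, locus_index)
    n = g.shape[0]
    if n == 0:
        raise ValueError(
            f"no typed individuals at locus {locus.name!r} in collection {collection.id!r}"
        )
    h_o = float(np.mean(g[:, 0] != g[:, 1]))
    vals, counts = np.unique(g.reshape(-1), return_counts=True)
    p = counts / counts.sum()
    h_e = 0.0 if len(vals) < 2 else (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    return LocusSummary(H_O=h_o, H_E=h_e, n_alleles=len(vals), n_typed=n)


def _genotype_table(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed genotype count table (upper triangle, k x k) and allele counts."""
    alleles = np.unique(g.reshape(-1))
    idx = {a: i for i, a in enumerate(alleles.tolist())}
    k = len(alleles)
    table = np.zeros((k, k), dtype=np.int64)
    for a, b in g.tolist():
        i, j = sorted((idx[a], idx[b]))
        table[i, j] += 1
    # allele i appears 2*n_ii + sum over heterozygote cells containing i
    c = np.zeros(k, dtype=np.int64)
    for i in range(k):
        c[i] = 2 * table[i, i]
        for j in range(k):
            if j != i:
                c[i] += table[min(i, j), max(i, j)]
    return table, c


def _log_levene(n: int, c: np.ndarray, log_fact) -> float:
    """Constant part of Levene's conditional table probability."""
    return float(log_fact[n] + np.sum(log_fact[c]) - log_fact[2 * n])


def _table_log_prob(table: np.ndarray, n: int, c: np.ndarray, log_fact) -> float:
    k = table.shape[0]
    het = int(table.sum() - np.trace(table))
    s = het * np.log(2.0)
    for i in range(k):
        for j in range(i, k):
            s -= log_fact[table[i, j]]
    return _log_levene(n, c, log_fact) + s


def _enumerate_tables(c: np.ndarray, cap: int):
    """Yield (log_prob_kernel, n_het) over all genotype tables with allele
    margins ``c``; returns None via StopIteration flag if > cap tables.

    The kernel omits the Levene constant: het*log2 - sum log n_ij!.
    """
    k = len(c)
    n = int(c.sum()) // 2
    log_fact = _log_fact(2 * n + 1)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    results: list[tuple[float, int]] = []
    count = 0

    def rec(cell_idx: int, remaining: np.ndarray, kernel: float, het: int):
        nonlocal count
        count += 1  # nodes visited, so the cap bounds work, not just output
        if count > cap:
            raise _EnumerationOverflow
        if cell_idx == len(cells):
            if np.all(remaining == 0):
                results.append((kernel, het))
            return
        i, j = cells[cell_idx]
        last_of_row = j == k - 1
        if i == j:
            hi = remaining[i] // 2
            for m in range(hi + 1):
                rem_i = remaining[i] - 2 * m
                if last_of_row and rem_i != 0:
                    continue
                remaining[i] -= 2 * m
                rec(cell_idx + 1, remaining, kernel - log_fact[m], het)
                remaining[i] += 2 * m
        else:
            hi = min(remaining[i], remaining[j])
            for m in range(hi + 1):
                if last_of_row and remaining[i] - m != 0:
                    continue
                remaining[i] -= m
                remaining[j] -= m
                rec(
                    cell_idx + 1,
                    remaining,
                    kernel + m * np.log(2.0) - log_fact[m],
                    het + m,
                )
                remaining[i] += m
                remaining[j] += m

    rec(0, c.copy(), 0.0, 0)
    return results


class _EnumerationOverflow(Exception):
    pass


def _mc_tables(
    c: np.ndarray, reps: int, seed: int, chunk: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo from Levene's distribution: shuffle the 2n gene copies,
    pair consecutively.  Returns (log_prob_kernels, het_counts)."""
    rng = np.random.default_rng(seed)
    k = len(c)
    copies = np.repeat(np.arange(k), c)
    n = len(copies) // 2
    log_fact = _log_fact(2 * n + 1)
    kernels = np.empty(reps)
    hets = np.empty(reps, dtype=np.int64)
    k2 = k * k
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        keys = rng.random((m, 2 * n))
        order = np.argsort(keys, axis=1)
        perm = copies[order]
        a, b = perm[:, ::2], perm[:, 1::2]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        codes = lo * k + hi + (np.arange(m) * k2)[:, None]
        counts = np.bincount(codes.reshape(-1), minlength=m * k2).reshape(m, k2)
        het = (lo != hi).sum(axis=1)
        kernels[done : done + m] = het * np.log(2.0) - log_fact[counts].sum(axis=1)
        hets[done : done + m] = het
        done += m
    return kernels, hets


def hwe_test(
    collection: SampleCollection,
    locus: Locus,
    locus_index: int,
    mc_reps: int = 100_000,
    seed: int = 0,
    enum_cap: int = 100_000,
) -> HWEResult:
    """Exact conditional test of Hardy-Weinberg conformity.

    The p-value is the probability mass of genotype tables (with the
    observed allele counts) no more probable than the observed table.
    Complete enumeration is used when the number of tables is modest,
    otherwise Monte Carlo sampling of the same conditional distribution.
    """
    g = _locus_genotypes(collection, locus_index)
    if g.shape[0] < 2 or len(np.unique(g.reshape(-1))) < 2:
        return HWEResult(collection.id, locus.name, 1.0, "enumeration")
    table, c = _genotype_table(g)
    n = g.shape[0]
    log_fact = _log_fact(2 * n + 1)
    het_obs = int(table.sum() - np.trace(table))
    kernel_obs = het_obs * np.log(2.0) - sum(
        log_fact[table[i, j]] for i in range(len(c)) for j in range(i, len(c))
    )
    const = _log_levene(n, c, log_fact)
    try:
        tables = _enumerate_tables(c, enum_cap)
        kernels = np.array([t[0] for t in tables])
        probs = np.exp(kernels + const)
        p = float(probs[kernels <= kernel_obs + _REL_TOL].sum())
        return HWEResult(collection.id, locus.name, min(p, 1.0), "enumeration")
    except _EnumerationOverflow:
        pass
    sub = substream_seed(seed, "hwe", collection.id, locus.name)
    kernels, _ = _mc_tables(c, mc_reps, sub)
    hits = int(np.sum(kernels <= kernel_obs + _REL_TOL))
    p = (hits + 1) / (mc_reps + 1)
    return HWEResult(collection.id, locus.name, p, "monte-carlo", mc_reps, sub)


def null_allele_scan(
    collection: SampleCollection,
    locus: Locus,
    locus_index: int,
    alpha: float = 0.05,
    mc_reps: int = 20_000,
    seed: int = 0,
    enum_cap: int = 100_000,
) -> tuple[bool, float]:
    """Screen one locus for null alleles.

    Returns ``(flag, r)``: flag is a significant general homozygote excess
    (one-sided exact test of too few heterozygotes under Levene's
    conditional distribution), and r is the Brookfield-1 null frequency
    estimator (H_E - H_O)/(1 + H_E), floored at zero.
    """
    summ = heterozygosities(collection, locus, locus_index)
    r = max(0.0, (summ.H_E - summ.H_O) / (1.0 + summ.H_E))
    g = _locus_genotypes(collection, locus_index)
    if summ.n_alleles < 2:
        return False, 0.0
    table, c = _genotype_table(g)
    het_obs = int(table.sum() - np.trace(table))
    n = g.shape[0]
    log_fact = _log_fact(2 * n + 1)
    const = _log_levene(n, c, log_fact)
    try:
        tables = _enumerate_tables(c, enum_cap)
        kernels = np.array([t[0] for t in tables])
        hets = np.array([t[1] for t in tables])
        p = float(np.exp(kernels + const)[hets <= het_obs].sum())
    except _EnumerationOverflow:
        sub = substream_seed(seed, "nullscan", collection.id, locus.name)
        _, hets = _mc_tables(c, mc_reps, sub)
        p = (int(np.sum(hets <= het_obs)) + 1) / (mc_reps + 1)
    return bool(p <= alpha), r


def holm_correct(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm (1979) step-down sequential-Bonferroni: sorted ascending, reject
    p_(k) while p_(k) <= alpha/(m-k+1); the first failure stops rejections."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    flags = np.zeros(m, dtype=bool)
    order = np.argsort(p, kind="stable")
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            flags[idx] = True
        else:
            break
    return flags.tolist()


def _contingency_exact_p(
    x1: np.ndarray, x2: np.ndarray, mc_reps: int, seed: int, enum_cap: int
) -> float:
    """Exact/MC probability test on an alleles x 2-samples count table.

    Conditional on margins, P(table) is multivariate hypergeometric; the
    p-value sums tables no more probable than observed.  2x2 tables go
    through Fisher's exact test.
    """
    keep = (x1 + x2) > 0
    x1, x2 = x1[keep], x2[keep]
    k = len(x1)
    if k < 2:
        return 1.0
    if k == 2:
        return float(fisher_exact([[x1[0], x1[1]], [x2[0], x2[1]]])[1])
    c = x1 + x2
    n1 = int(x1.sum())
    total = int(c.sum())
    log_fact = _log_fact(total + 1)

    def log_p(v: np.ndarray) -> float:
        return float(
            np.sum(log_fact[c] - log_fact[v] - log_fact[c - v])
            - (log_fact[total] - log_fact[n1] - log_fact[total - n1])
        )

    obs = log_p(x1)
    # enumeration over sample-1 allele counts
    n_tables = np.prod(np.minimum(c, n1) + 1.0)
    if n_tables <= enum_cap:
        p_sum = 0.0
        v = np.zeros(k, dtype=np.int64)

        def rec(a: int, left: int):
            nonlocal p_sum
            if a == k - 1:
                if left <= c[a]:
                    v[a] = left
                    lp = log_p(v)
                    if lp <= obs + _REL_TOL:
                        p_sum += np.exp(lp)
                return
            for m in range(min(c[a], left) + 1):
                v[a] = m
                rec(a + 1, left - m)

        rec(0, n1)
        return min(float(p_sum), 1.0)
    # Monte Carlo: permute gene copies between the samples
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(k), c)
    hits = 0
    chunk = 2000
    done = 0
    while done < mc_reps:
        m = min(chunk, mc_reps - done)
        keys = rng.random((m, total))
        take = np.argsort(keys, axis=1)[:, :n1]
        sel = copies[take]
        counts = np.bincount(
            (sel + (np.arange(m) * k)[:, None]).reshape(-1), minlength=m * k
        ).reshape(m, k)
        lp = np.sum(
            log_fact[c] - log_fact[counts] - log_fact[c - counts], axis=1
        ) - (log_fact[total] - log_fact[n1] - log_fact[total - n1])
        hits += int(np.sum(lp <= obs + _REL_TOL))
        done += m
    return (hits + 1) / (mc_reps + 1)


def temporal_test(
    a: SampleCollection,
    b: SampleCollection,
    loci: list[Locus],
    mc_reps: int = 20_000,
    seed: int = 0,
    enum_cap: int = 50_000,
) -> dict[str, float | None]:
    """Per-locus exact tests of allele-frequency homogeneity between two
    temporal samples; a locus untyped in either sample reports ``None``."""
    if a.n_loci != b.n_loci or a.n_loci != len(loci):
        raise ValueError("collections must share the locus panel")
    out: dict[str, float | None] = {}
    for j, locus in enumerate(loci):
        ca = np.array(
            [np.sum(_locus_genotypes(a, j).reshape(-1) == al) for al in locus.alleles],
            dtype=np.int64,
        )
        cb = np.array(
            [np.sum(_locus_genotypes(b, j).reshape(-1) == al) for al in locus.alleles],
            dtype=np.int64,
        )
        if ca.sum() == 0 or cb.sum() == 0:
            out[locus.name] = None
            continue
        out[locus.name] = _contingency_exact_p(
            ca, cb, mc_reps, substream_seed(seed, "temporal", locus.name), enum_cap
        )
    return out


def duplicate_error_rate(
    run1: np.ndarray, run2: np.ndarray
) -> tuple[np.ndarray, float]:
    """Allelic mismatch rate between duplicate genotyping runs.

    Both runs are ``(n, L, 2)`` genotype arrays of the same individuals;
    genotype pairs are compared as unordered allele multisets, loci missing
    in either run are excluded.  Returns (per-locus rates, mean rate over
    loci with comparable calls).
    """
    g1, g2 = np.asarray(run1), np.asarray(run2)
    if g1.shape != g2.shape:
        raise ValueError("runs must contain the same individuals and loci")
    L = g1.shape[1]
    rates = np.full(L, np.nan)
    for j in range(L):
        both = (g1[:, j, 0] != MISSING) & (g2[:, j, 0] != MISSING)
        if not both.any():
            continue
        p1 = np.sort(g1[both, j, :], axis=1)
        p2 = np.sort(g2[both, j, :], axis=1)
        full = (p1[:, 0] == p2[:, 0]) & (p1[:, 1] == p2[:, 1])
        any_share = (
            (p1[:, 0] == p2[:, 0])
            | (p1[:, 0] == p2[:, 1])
            | (p1[:, 1] == p2[:, 0])
            | (p1[:, 1] == p2[:, 1])
        )
        matches = np.where(full, 2, np.where(any_share, 1, 0))
        rates[j] = float(np.sum(2 - matches) / (2 * both.sum()))
    if np.all(np.isnan(rates)):
        raise ValueError("no comparable allele calls between the runs")
    return rates, float(np.nanmean(rates))


def expected_false_positives(n_tests: int, alpha: float = 0.05) -> float:
    """Expected count of chance-significant tests at level alpha over a grid
    of independent null tests (n * alpha)."""
    return n_tests * alpha


def qc_report(
    registry,
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    seed: int = 0,
    excluded_collections: set[str] | None = None,
):
    """Full QC table: one row per (collection, locus) with heterozygosities,
    HWE p-value, Holm flag over the whole grid, and the null-allele screen."""
    import pandas as pd

    excluded = excluded_collections or set()
    rows = []
    for coll in registry.collections:
        if coll.id in excluded:
            continue
        for j, locus in enumerate(registry.loci):
            try:
                summ = heterozygosities(coll, locus, j)
            except ValueError:
                continue
            res = hwe_test(coll, locus, j, mc_reps=mc_reps, seed=seed)
            flag, r = null_allele_scan(coll, locus, j, alpha=alpha, seed=seed)
            rows.append(
                {
                    "collection": coll.id,
                    "locus": locus.name,
                    "n_typed": summ.n_typed,
                    "n_alleles": summ.n_alleles,
                    "H_O": summ.H_O,
                    "H_E": summ.H_E,
                    "p_HWE": res.p_value,
                    "hwe_method": res.method,
                    "null_flag": flag,
                    "r_null": r,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["holm_flag"] = holm_correct(df["p_HWE"].tolist(), alpha=alpha)
    return df
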