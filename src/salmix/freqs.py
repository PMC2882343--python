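"""Per-unit allele count / frequency tables.

The :class:`AlleleFreqTable` is the bridge between the raw baseline and
every estimator: per (unit, locus) it records the allele count vector and
the total gene count, and exposes both plain (maximum-likelihood) and
posterior-mean frequencies.  Posterior-mean smoothing uses 1/K pseudo-counts
(K = number of registry alleles at the locus), i.e.

    freq(a) = (count_a + 1/K) / (2 n_typed + 1),

so that every registry allele has positive probability in every unit and a
mixture fish carrying an allele unseen in some baseline unit is penalised
rather than given an impossible genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, BaselineRegistry, Locus, SampleCollection

__all__ = ["AlleleFreqTable", "collection_counts"]


def collection_counts(collection: SampleCollection, loci: list[Locus]) -> list[np.ndarray]:
    """Allele count vector per locus for one collection (registry order)."""
    out = []
    for j, locus in enumerate(loci):
        idx = locus.index_of()
        counts = np.zeros(locus.n_alleles, dtype=np.int64)
        g = collection.genotypes[:, j, :]
        for a in g[g != MISSING].tolist():
            counts[idx[a]] += 1
        out.append(counts)
    return out


@dataclass
class AlleleFreqTable:
    """Allele counts and frequencies for a set of baseline units.

    ``counts[j]`` is a ``(U, K_j)`` integer array of allele counts for locus
    ``j``; ``totals[j]`` its ``(U,)`` row sums (2 x typed diploids).  A table
    built from known truth frequencies (synthetic data) stores them in
    ``true_freqs`` and has zero counts.
    """

    loci: list[Locus]
    units: list[str]
    counts: list[np.ndarray]
    totals: list[np.ndarray] = field(default_factory=list)
    true_freqs: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.totals:
            self.totals = [c.sum(axis=1) for c in self.counts]
        for j, c in enumerate(self.counts):
            if c.shape != (len(self.units), self.loci[j].n_alleles):
                raise ValueError(f"counts[{j}] has shape {c.shape}, inconsistent with panel")

    @classmethod
    def from_registry(cls, registry: BaselineRegistry) -> AlleleFreqTable:
        units = registry.unit_ids
        counts = [
            np.zeros((len(units), locus.n_alleles), dtype=np.int64) for locus in registry.loci
        ]
        for u, coll in enumerate(registry.collections):
            per_locus = collection_counts(coll, registry.loci)
            for j in range(len(registry.loci)):
                counts[j][u] = per_locus[j]
        return cls(loci=list(registry.loci), units=list(units), counts=counts)

    @classmethod
    def from_frequencies(
        cls, loci: list[Locus], units: list[str], freqs: list[np.ndarray]
    ) -> AlleleFreqTable:
        """Table of known truth frequencies (rows on the simplex per locus)."""
        freqs = [np.asarray(f, dtype=float) for f in freqs]
        for j, f in enumerate(freqs):
            if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"locus {loci[j].name!r}: frequencies not on the simplex")
        counts = [np.zeros((len(units), locus.n_alleles), dtype=np.int64) for locus in loci]
        return cls(loci=list(loci), units=list(units), counts=counts, true_freqs=freqs)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def posterior_freqs(self, locus_index: int) -> np.ndarray:
        """Posterior-mean frequencies ``(U, K)`` with 1/K pseudo-counts.

        For a synthetic truth table the stored frequencies are returned
        unchanged.  A unit with zero typed genotypes falls back to the
        uniform prior 1/K.
        """
        if self.true_freqs is not None:
            return self.true_freqs[locus_index]
        K = self.loci[locus_index].n_alleles
        c = self.counts[locus_index].astype(float)
        tot = self.totals[locus_index].astype(float)
        return (c + 1.0 / K) / (tot + 1.0)[:, None]

    def ml_freqs(self, locus_index: int) -> np.ndarray:
        """Plain count-proportion frequencies; uniform where untyped."""
        if self.true_freqs is not None:
            return self.true_freqs[locus_index]
        K = self.loci[locus_index].n_alleles
        c = self.counts[locus_index].astype(float)
        tot = self.totals[locus_index].astype(float)
        out = np.full_like(c, 1.0 / K)
        typed = tot > 0
        out[typed] = c[typed] / tot[typed, None]
        return out

    def subset(self, unit_ids: list[str]) -> AlleleFreqTable:
        pos = [self.units.index(u) for u in unit_ids]
        return AlleleFreqTable(
            loci=list(self.loci),
            units=list(unit_ids),
            counts=[c[pos] for c in self.counts],
            totals=[t[pos] for t in self.totals],
            true_freqs=None if self.true_freqs is None else [f[pos] for f in self.true_freqs],
        )
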