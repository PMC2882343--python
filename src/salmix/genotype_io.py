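"""Genotype containers and I/O for codominant microsatellite data.

The package's in-memory model is deliberately simple: a
:class:`BaselineRegistry` holds a shared locus panel, a list of
:class:`SampleCollection` objects (one per sampling unit, i.e. site x year),
and a :class:`HierarchyMap` relating sample sites to river catchments and
reporting regions.  Genotypes are stored as integer arrays of allele labels
(fragment sizes in bp), shape ``(n_individuals, n_loci, 2)``, with ``-1``
marking a missing locus.

GENEPOP text files are the exchange format: one ``Pop`` block per
collection, 2- or 3-digit allele codes on input, 3-digit codes on output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "SampleCollection",
    "HierarchyMap",
    "BaselineRegistry",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_hierarchy",
    "combine_temporal",
    "pool_collections",
    "allele_counts",
]


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its ordered set of allele labels.

    Allele labels are PCR fragment sizes in base pairs, so they are positive
    integers and unique within the locus.
    """

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"locus {self.name!r} has non-positive allele labels")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self) -> dict[int, int]:
        return {a: i for i, a in enumerate(self.alleles)}


@dataclass
class SampleCollection:
    """Genotypes of one baseline sampling unit (site, optionally a year).

    ``genotypes`` is an ``(n, L, 2)`` integer array of allele labels with
    ``-1`` for missing loci; both allele slots of a locus are missing or
    present together (whole-locus missingness).
    """

    id: str
    site: str
    catchment: str
    genotypes: np.ndarray
    region: str | None = None
    year: int | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int64)
        if g.ndim != 3 or g.shape[2] != 2 or g.shape[0] < 1:
            raise ValueError("genotypes must have shape (n>=1, n_loci, 2)")
        half = (g == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"collection {self.id!r}: {int(half.sum())} half-missing genotypes "
                "coerced to missing",
                stacklevel=2,
            )
            g[half] = MISSING
        self.genotypes = g
        if not self.labels:
            self.labels = [f"{self.id}_{i + 1}" for i in range(g.shape[0])]
        if len(self.labels) != g.shape[0]:
            raise ValueError("labels length must match number of individuals")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class HierarchyMap:
    """Site -> catchment -> reporting-region mapping.

    Reporting regions are an *input* here: they encode the expert grouping
    of baseline collections into units within which stocks are reported
    jointly, not something the package derives.
    """

    site_to_catchment: dict[str, str]
    catchment_to_region: dict[str, str]
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = dict.fromkeys(self.catchment_to_region.values())
        for r in self.regions:
            seen.setdefault(r, None)
        self.regions = list(seen)

    def catchment_of(self, site: str) -> str:
        return self.site_to_catchment[site]

    def region_of(self, site: str) -> str:
        return self.catchment_to_region[self.site_to_catchment[site]]

    def sites(self) -> list[str]:
        return list(self.site_to_catchment)


@dataclass
class BaselineRegistry:
    """The complete baseline: locus panel, collections, and hierarchy."""

    loci: list[Locus]
    collections: list[SampleCollection]
    hierarchy: HierarchyMap

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.id for c in self.collections]
        if len(set(ids)) != len(ids):
            raise ValueError("collection ids must be unique")
        n_loci = len(self.loci)
        for c in self.collections:
            if c.n_loci != n_loci:
                raise ValueError(
                    f"collection {c.id!r} has {c.n_loci} loci, registry panel has {n_loci}"
                )
            if c.site not in self.hierarchy.site_to_catchment:
                raise ValueError(f"site {c.site!r} not covered by the hierarchy")
        for c in self.collections:
            for j, locus in enumerate(self.loci):
                observed = c.genotypes[:, j, :]
                present = observed[observed != MISSING]
                unknown = set(present.tolist()) - set(locus.alleles)
                if unknown:
                    raise ValueError(
                        f"collection {c.id!r}, locus {locus.name!r}: alleles "
                        f"{sorted(unknown)} absent from the registry allele set"
                    )

    @property
    def unit_ids(self) -> list[str]:
        return [c.id for c in self.collections]

    def collection(self, unit_id: str) -> SampleCollection:
        for c in self.collections:
            if c.id == unit_id:
                return c
        raise KeyError(unit_id)

    def summary(self) -> dict:
        return {
            "n_collections": len(self.collections),
            "n_loci": len(self.loci),
            "loci": {l.name: l.n_alleles for l in self.loci},
            "collections": {c.id: c.n for c in self.collections},
        }


class GenepopParseError(ValueError):
    """Malformed GENEPOP input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _split_allele_code(token: str, line_no: int) -> tuple[int, int]:
    if len(token) % 2 != 0 or len(token) not in (4, 6):
        raise GenepopParseError(
            f"allele code {token!r} is not a 2x2- or 2x3-digit genotype", line_no
        )
    w = len(token) // 2
    try:
        a, b = int(token[:w]), int(token[w:])
    except ValueError as exc:
        raise GenepopParseError(f"non-numeric allele code {token!r}", line_no) from exc
    return (MISSING if a == 0 else a, MISSING if b == 0 else b)


def read_genepop(path) -> tuple[list[Locus], list[SampleCollection]]:
    """Parse a GENEPOP file into a locus panel and one collection per Pop.

    Allele code 0 (``00``/``000``) denotes a missing allele; genotypes with
    exactly one missing allele are coerced to whole-locus missing.  The
    allele set of each locus is the union of alleles observed anywhere in
    the file.  Collection ids are taken from the first individual label of
    each Pop block (the GENEPOP convention); site is the id with any
    trailing two-digit year suffix stripped.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)

    # header: title line, then locus names until the first Pop
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        name = lines[i].strip()
        if name:
            if "," in name:  # all loci on one line
                locus_names.extend(t.strip() for t in name.split(",") if t.strip())
            else:
                locus_names.append(name)
        i += 1
    if not locus_names:
        raise GenepopParseError("no locus names before first Pop", i + 1)
    if i >= len(lines):
        raise GenepopParseError("no Pop block found", len(lines))

    n_loci = len(locus_names)
    pops: list[tuple[list[str], list[list[tuple[int, int]]], int]] = []
    current: tuple[list[str], list[list[tuple[int, int]]], int] | None = None
    for line_no in range(i, len(lines)):
        raw = lines[line_no].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            current = ([], [], line_no + 1)
            pops.append(current)
            continue
        if current is None:
            raise GenepopParseError("genotype record before first Pop", line_no + 1)
        if "," not in raw:
            raise GenepopParseError("individual record lacks comma after label", line_no + 1)
        label, _, rest = raw.partition(",")
        tokens = rest.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                f"individual {label.strip()!r} has {len(tokens)} loci, expected {n_loci}",
                line_no + 1,
            )
        current[0].append(label.strip())
        current[1].append([_split_allele_code(t, line_no + 1) for t in tokens])

    collections: list[SampleCollection] = []
    allele_sets: list[set[int]] = [set() for _ in range(n_loci)]
    for labels, rows, first_line in pops:
        if not rows:
            raise GenepopParseError("empty Pop block", first_line)
        g = np.asarray(rows, dtype=np.int64)  # (n, L, 2)
        half = (g == MISSING).sum(axis=2) == 1
        g[half] = MISSING
        for j in range(n_loci):
            present = g[:, j, :][g[:, j, :] != MISSING]
            allele_sets[j].update(present.tolist())
        # collection id: common prefix of the individual labels (our writer
        # emits "<id>_<k>"), falling back to the first label
        import os

        cid = os.path.commonprefix(labels).rstrip("_") or labels[0]
        if any(c.id == cid for c in collections):
            cid = f"{cid}.{len(collections) + 1}"
        site = cid[:-2] if len(cid) > 2 and cid[-2:].isdigit() else cid
        collections.append(
            SampleCollection(id=cid, site=site, catchment=site, genotypes=g, labels=labels)
        )
    loci = [
        Locus(name, tuple(sorted(s)) if s else (1,)) for name, s in zip(locus_names, allele_sets)
    ]
    return loci, collections


def write_genepop(loci, collections, path, title: str = "salmix export") -> None:
    """Write collections to a 3-digit GENEPOP file (re-readable by
    :func:`read_genepop`); ordering of collections, individuals and loci is
    preserved."""
    if not collections:
        raise ValueError("GENEPOP requires at least one Pop block")
    for locus in loci:
        if any(a > 999 for a in locus.alleles):
            raise ValueError(
                f"locus {locus.name!r} has allele labels > 999, unrepresentable "
                "in the 3-digit GENEPOP dialect"
            )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus.name + "\n")
        for c in collections:
            fh.write("Pop\n")
            for ind, label in enumerate(c.labels):
                toks = []
                for j in range(len(loci)):
                    a, b = c.genotypes[ind, j, :]
                    if a == MISSING:
                        toks.append("000000")
                    else:
                        toks.append(f"{a:03d}{b:03d}")
                fh.write(f"{label} , " + " ".join(toks) + "\n")


def read_hierarchy(path) -> HierarchyMap:
    """Read a ``site,catchment,region`` CSV into a validated HierarchyMap.

    Duplicate identical rows are deduplicated; a site mapped to two
    different catchments (or a catchment to two regions) is an error.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"site", "catchment", "region"}
    if df.empty and not required.issubset(df.columns):
        return HierarchyMap({}, {}, [])
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"hierarchy CSV lacks columns: {sorted(missing_cols)}")
    s2c: dict[str, str] = {}
    c2r: dict[str, str] = {}
    for row in df.itertuples(index=False):
        site, catchment, region = row.site, row.catchment, row.region
        if site in s2c and s2c[site] != catchment:
            raise ValueError(f"site {site!r} mapped to both {s2c[site]!r} and {catchment!r}")
        if catchment in c2r and c2r[catchment] != region:
            raise ValueError(
                f"catchment {catchment!r} mapped to both {c2r[catchment]!r} and {region!r}"
            )
        s2c[site] = catchment
        c2r[catchment] = region
    return HierarchyMap(s2c, c2r)


def combine_temporal(registry: BaselineRegistry, site: str) -> SampleCollection:
    """Merge all temporal samples at one site into a single collection.

    Temporal replicates at a site estimate the same population's allele
    frequencies, so they are concatenated (year unset, id = site).
    """
    members = [c for c in registry.collections if c.site == site]
    if not members:
        raise KeyError(f"no collection sampled at site {site!r}")
    if len(members) == 1:
        return members[0]
    g = np.concatenate([c.genotypes for c in members], axis=0)
    labels = [lab for c in members for lab in c.labels]
    return SampleCollection(
        id=site,
        site=site,
        catchment=members[0].catchment,
        region=members[0].region,
        genotypes=g,
        labels=labels,
    )


def pool_collections(registry: BaselineRegistry, level: str = "catchment") -> BaselineRegistry:
    """Pool collections into one unit per catchment (the pool-and-allocate
    baseline): genotypes of all member sites are merged before any
    estimation, and the hierarchy is rewritten with the pooled units as
    sites."""
    if level != "catchment":
        raise ValueError(f"unsupported pooling level {level!r}")
    hier = registry.hierarchy
    by_catchment: dict[str, list[SampleCollection]] = {}
    for c in registry.collections:
        by_catchment.setdefault(hier.catchment_of(c.site), []).append(c)
    pooled = []
    s2c = {}
    for catchment, members in by_catchment.items():
        g = np.concatenate([c.genotypes for c in members], axis=0)
        labels = [lab for c in members for lab in c.labels]
        region = hier.catchment_to_region.get(catchment)
        pooled.append(
            SampleCollection(
                id=catchment,
                site=catchment,
                catchment=catchment,
                region=region,
                genotypes=g,
                labels=labels,
            )
        )
        s2c[catchment] = catchment
    new_hier = HierarchyMap(s2c, dict(hier.catchment_to_region), list(hier.regions))
    return BaselineRegistry(loci=list(registry.loci), collections=pooled, hierarchy=new_hier)


def load_registry(genepop_path, hierarchy_path) -> BaselineRegistry:
    """Read a baseline GENEPOP file plus hierarchy CSV into a registry.

    Collection sites are matched against the hierarchy by id, then by id
    with a trailing two-digit year suffix stripped.
    """
    loci, collections = read_genepop(genepop_path)
    hier = read_hierarchy(hierarchy_path)
    known = set(hier.site_to_catchment)
    for c in collections:
        site = c.id if c.id in known else c.site
        if site not in known:
            raise ValueError(f"collection {c.id!r}: site {site!r} not in hierarchy")
        c.site = site
        c.catchment = hier.catchment_of(site)
        c.region = hier.catchment_to_region.get(c.catchment)
    return BaselineRegistry(loci=loci, collections=collections, hierarchy=hier)


def allele_counts(collection: SampleCollection, locus: Locus, locus_index: int) -> np.ndarray:
    """Allele counts for one collection at one locus, in registry allele order."""
    idx = locus.index_of()
    counts = np.zeros(locus.n_alleles, dtype=np.int64)
    g = collection.genotypes[:, locus_index, :]
    for a in g[g != MISSING].tolist():
        counts[idx[a]] += 1
    return counts
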