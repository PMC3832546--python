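"""Gene/isoform structures and the read-sampling-rate machinery.

A gene is a set of exons (0-based, half-open genomic intervals) and a set of
isoforms, each an ordered subset of those exons.  Under the uniform
single-end sampling model every start position on a transcript generates a
*read type* — the equivalence class of reads with the same genomic
footprint — at the same rate.  Two isoforms share a read type iff the
footprint is contiguous in both transcripts.  Read types are collapsed into
*read categories* (groups with identical isoform-compatibility pattern),
which preserves the Poisson log-likelihood up to an additive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "SamplingRateMatrix",
    "ReadCategoryTable",
    "enumerate_read_types",
    "build_sampling_rates",
    "reduce_to_categories",
]

#: A genomic footprint: ordered tuple of (start, end) blocks.
Footprint = tuple[tuple[int, int], ...]


class UnquantifiableGeneError(ValueError):
    """All isoforms are shorter than the read length."""


@dataclass(frozen=True)
class GeneModel:
    """Exon structure and isoform composition of one gene.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    exons : tuple of (start, end)
        Genomic intervals, 0-based half-open, each with ``end > start``.
    isoforms : tuple of (isoform_id, exon-index tuple)
        Each isoform lists the indices (into ``exons``) of the exons it
        contains, strictly increasing.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unknown).  Recorded for reporting only;
        sampling rates depend only on exon structure.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    isoforms: tuple[tuple[str, tuple[int, ...]], ...]
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(
            self, "isoforms", tuple((i, tuple(ix)) for i, ix in self.isoforms)
        )
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"{self.gene_id}: exon ({start}, {end}) has non-positive length"
                )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        for iso_id, idx in self.isoforms:
            if len(idx) == 0:
                raise ValueError(f"isoform {iso_id} references no exons")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"isoform {iso_id}: exon indices must be strictly increasing"
                )
            if max(idx) >= len(self.exons):
                raise ValueError(f"isoform {iso_id}: exon index out of range")

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)

    @property
    def isoform_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.isoforms)

    def exon_length(self, i: int) -> int:
        s, e = self.exons[i]
        return e - s

    def isoform_length(self, i: int) -> int:
        """Transcript length of isoform ``i`` (sum of its exon lengths)."""
        return sum(self.exon_length(j) for j in self.isoforms[i][1])

    def isoform_exons(self, i: int) -> tuple[tuple[int, int], ...]:
        return tuple(self.exons[j] for j in self.isoforms[i][1])


@dataclass
class SamplingRateMatrix:
    """Per-condition read sampling rates ``a_ij`` for one gene.

    ``rates`` is I×J (isoforms × read types); under the uniform model each
    entry is either 0 or the per-condition ``depth_scale``.  ``isoform_totals``
    holds ``a_i = Σ_j a_ij``, the total rate over *all* read types of
    isoform i — the Poisson penalty term needs these even after read types
    with zero counts are discarded.
    """

    condition_id: str
    read_types: list[Footprint]
    rates: np.ndarray
    isoform_totals: np.ndarray
    depth_scale: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.isoform_totals = np.asarray(self.isoform_totals, dtype=float)
        if np.any(self.rates < 0) or np.any(self.isoform_totals < 0):
            raise ValueError("sampling rates must be non-negative")
        if not np.allclose(self.rates.sum(axis=1), self.isoform_totals):
            raise ValueError("isoform_totals must equal row sums of rates")

    @property
    def n_isoforms(self) -> int:
        return self.rates.shape[0]


@dataclass
class ReadCategoryTable:
    """Reduced read evidence for one gene in one condition.

    ``counts[j]`` is the number of reads in category j and ``rates[j]`` the
    length-I category rate vector (sum of the member read-type rate
    vectors).  ``isoform_totals`` are the totals over all read types,
    including the zero-count ones that are not stored.
    """

    condition_id: str
    counts: np.ndarray
    rates: np.ndarray
    isoform_totals: np.ndarray
    total_reads_mapped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.atleast_1d(np.asarray(self.counts, dtype=float))
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim == 1 and len(self.counts) > 0:
            self.rates = self.rates.reshape(len(self.counts), -1)
        self.isoform_totals = np.asarray(self.isoform_totals, dtype=float)
        if self.rates.shape[0] != self.counts.shape[0]:
            raise ValueError("counts and rates row count mismatch")
        if self.rates.shape[1] != self.isoform_totals.shape[0]:
            raise ValueError("rates column count must match isoform_totals")
        if np.any(self.counts < 0):
            raise ValueError("negative category count")
        if np.any(self.rates < 0):
            raise ValueError("negative sampling rate")
        dead = (self.counts == 0) & ~self.rates.any(axis=1)
        if np.any(dead):
            raise ValueError("empty categories (zero count, zero rates) must be dropped")
        zero_rate_with_count = (self.counts > 0) & ~self.rates.any(axis=1)
        if np.any(zero_rate_with_count):
            raise ValueError("category with reads but zero rate for every isoform")

    @property
    def n_isoforms(self) -> int:
        return self.isoform_totals.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[0]

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())


def _isoform_footprints(
    exons: Sequence[tuple[int, int]], read_length: int
) -> list[Footprint]:
    """Genomic footprints of every read start position on one transcript."""
    lengths = [e - s for s, e in exons]
    total = sum(lengths)
    n = total - read_length + 1
    if n <= 0:
        return []
    out: list[Footprint] = []
    # cumulative transcript offsets of exon starts
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    for start in range(n):
        remaining = read_length
        blocks: list[tuple[int, int]] = []
        # locate exon containing `start`
        e = int(np.searchsorted(offsets, start, side="right")) - 1
        pos_in_exon = start - int(offsets[e])
        while remaining > 0:
            ex_start, ex_end = exons[e]
            g_start = ex_start + pos_in_exon
            take = min(remaining, ex_end - g_start)
            if blocks and blocks[-1][1] == g_start:  # abutting exons: one region
                blocks[-1] = (blocks[-1][0], g_start + take)
            else:
                blocks.append((g_start, g_start + take))
            remaining -= take
            e += 1
            pos_in_exon = 0
        out.append(tuple(blocks))
    return out


def enumerate_read_types(
    gene: GeneModel, read_length: int
) -> list[tuple[Footprint, np.ndarray]]:
    """Enumerate distinct read types and their isoform-compatibility vectors.

    A read type is a distinct genomic footprint of a read of ``read_length``
    laid contiguously along some isoform; its compatibility vector marks
    every isoform containing that footprint contiguously in transcript
    coordinates.  Isoforms shorter than the read length contribute no read
    types.

    Returns a deterministically ordered list of ``(footprint, bool vector)``.

    Raises
    ------
    UnquantifiableGeneError
        If every isoform is shorter than ``read_length``.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    I = gene.n_isoforms
    compat: dict[Footprint, np.ndarray] = {}
    any_long_enough = False
    for i in range(I):
        fps = _isoform_footprints(gene.isoform_exons(i), read_length)
        if fps:
            any_long_enough = True
        for fp in fps:
            vec = compat.get(fp)
            if vec is None:
                vec = np.zeros(I, dtype=bool)
                compat[fp] = vec
            vec[i] = True
    if not any_long_enough:
        raise UnquantifiableGeneError(
            f"gene {gene.gene_id} unquantifiable at read length {read_length}: "
            "all isoforms are shorter than the read length"
        )
    return [(fp, compat[fp]) for fp in sorted(compat)]


def build_sampling_rates(
    gene: GeneModel,
    read_length: int,
    depth_scale: float,
    condition_id: str = "",
) -> SamplingRateMatrix:
    """Uniform-sampling-model rate matrix: ``a_ij = depth_scale`` if read
    type j is compatible with isoform i, else 0.

    ``depth_scale`` is the per-condition constant converting abundance units
    to expected read counts (conventionally total mapped reads / 1e9, giving
    RPKM-like abundance units); it must be positive.
    """
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    read_types = enumerate_read_types(gene, read_length)
    I = gene.n_isoforms
    J = len(read_types)
    rates = np.zeros((I, J))
    for j, (_, vec) in enumerate(read_types):
        rates[vec, j] = depth_scale
    return SamplingRateMatrix(
        condition_id=condition_id,
        read_types=[fp for fp, _ in read_types],
        rates=rates,
        isoform_totals=rates.sum(axis=1),
        depth_scale=depth_scale,
    )


def reduce_to_categories(
    rates: SamplingRateMatrix,
    observed_counts: Mapping[Footprint, int],
    condition_id: str | None = None,
) -> ReadCategoryTable:
    """Collapse observed read types into maximal read categories.

    Read types with identical compatibility patterns merge: counts add and
    rate vectors add.  Zero-count read types are dropped from the category
    list but still contribute to ``isoform_totals`` (the penalty term), so
    the reduced log-likelihood differs from the full one only by a constant
    independent of the abundances.

    Reads observed on a footprint compatible with no isoform are excluded
    with a warning (unassignable) and do not enter ``total_reads_mapped``.
    """
    index = {fp: j for j, fp in enumerate(rates.read_types)}
    groups: dict[tuple, list[float]] = {}  # pattern key -> [count, n_types]
    unassignable = 0
    pattern_rates: dict[tuple, np.ndarray] = {}
    for fp, count in observed_counts.items():
        if count < 0:
            raise ValueError("negative read count")
        if count == 0:
            continue
        j = index.get(fp)
        if j is None or not rates.rates[:, j].any():
            # footprint incompatible with every isoform of this gene
            unassignable += int(count)
            continue
        col = rates.rates[:, j]
        key = tuple(col)
        if key not in groups:
            groups[key] = [0.0, 0.0]
            pattern_rates[key] = np.zeros(rates.n_isoforms)
        groups[key][0] += count
        pattern_rates[key] += col
    if unassignable:
        warnings.warn(
            f"{unassignable} reads on read types compatible with no isoform "
            "were excluded as unassignable",
            stacklevel=2,
        )
    keys = sorted(groups)
    counts = np.array([groups[k][0] for k in keys])
    cat_rates = (
        np.vstack([pattern_rates[k] for k in keys])
        if keys
        else np.zeros((0, rates.n_isoforms))
    )
    return ReadCategoryTable(
        condition_id=rates.condition_id if condition_id is None else condition_id,
        counts=counts,
        rates=cat_rates,
        isoform_totals=rates.isoform_totals.copy(),
        total_reads_mapped=int(counts.sum()),
    )


@lru_cache(maxsize=128)
def category_pattern_table(
    gene: GeneModel, read_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Full partition of read types into compatibility-pattern categories.

    Returns ``(patterns, n_types)`` where ``patterns`` is a C×I boolean
    matrix of the distinct compatibility patterns and ``n_types[c]`` the
    number of read types in pattern c.  Used by the simulator, which draws
    Poisson counts directly at category level.
    """
    read_types = enumerate_read_types(gene, read_length)
    seen: dict[tuple, int] = {}
    counts: list[int] = []
    pats: list[np.ndarray] = []
    for _, vec in read_types:
        key = tuple(vec)
        if key not in seen:
            seen[key] = len(pats)
            pats.append(vec.copy())
            counts.append(0)
        counts[seen[key]] += 1
    order = sorted(range(len(pats)), key=lambda c: tuple(pats[c]))
    patterns = np.vstack([pats[c] for c in order])
    n_types = np.array([counts[c] for c in order], dtype=float)
    return patterns, n_types
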