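"""Count-matrix I/O, validation, median-of-ratios normalization, and gene filtering.

Conventions
-----------
A count matrix is a :class:`pandas.DataFrame` with gene identifiers in the
index (rows) and sample identifiers in the columns, holding non-negative
integers.  Sample metadata is a DataFrame indexed by sample id with at least
the columns ``group`` (e.g. ``HD``, ``HD+``, ``C``, ``GTEx``), ``region``
(``BA9`` or ``CAU``), ``age_at_death`` (years) and ``sex`` (two-level factor,
``M``/``F``).  Extra columns (PMI, RIN, ...) pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "validate_counts",
    "validate_metadata",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "compute_size_factors",
    "FilterRule",
    "zero_fraction",
    "zero_count",
    "filter_genes",
    "GroupSelector",
    "ContrastSpec",
    "STUDY_CONTRASTS",
]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants and return the (unchanged) frame.

    Raises ``ValueError`` on duplicate gene/sample ids, negative or
    non-integral values.
    """
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (values < 0).any():
        raise ValueError("count matrix contains negative values")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integral values")
    return counts


def validate_metadata(meta: pd.DataFrame, counts: pd.DataFrame | None = None,
                      required: Sequence[str] = ("group", "region", "age_at_death", "sex")) -> pd.DataFrame:
    """Check metadata invariants; optionally cross-check against a count matrix."""
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required column(s): {missing_cols}")
    if meta.index.has_duplicates:
        raise ValueError("metadata has duplicate sample ids")
    if counts is not None:
        absent = [s for s in counts.columns if s not in meta.index]
        if absent:
            raise ValueError(f"samples absent from metadata: {absent[:5]}")
    return meta


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix (first column gene id, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of the ratio of its
    count to the gene's geometric mean across samples.
    """
    validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; pre-filter all-zero-prone "
            "genes before computing size factors"
        )
    ref = values[reference]
    log_geomean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass(frozen=True)
class FilterRule:
    """Zero-count gene filter applied per contrast.

    ``zero_fraction``: a gene is removed if its fraction of zero counts
    exceeds ``value`` (strictly) in any group (``scope='any'``) or in every
    group (``scope='all'``).  ``zero_count``: a gene is removed if its total
    number of zeros across the contrast's samples exceeds ``value`` strictly.
    """

    kind: str  # 'zero_fraction' | 'zero_count'
    value: float
    scope: str = "any"  # zero_fraction only: removed if failing in 'any'/'all' groups

    def __post_init__(self):
        if self.kind not in ("zero_fraction", "zero_count"):
            raise ValueError(f"unknown filter rule kind: {self.kind!r}")
        if self.scope not in ("any", "all"):
            raise ValueError(f"scope must be 'any' or 'all', got {self.scope!r}")
        if self.kind == "zero_fraction" and not (0 <= self.value <= 1):
            raise ValueError("zero_fraction threshold must be in [0, 1]")
        if self.kind == "zero_count" and self.value < 0:
            raise ValueError("zero_count maximum must be >= 0")


def zero_fraction(threshold: float, scope: str = "any") -> FilterRule:
    return FilterRule("zero_fraction", threshold, scope)


def zero_count(max_zeros: int) -> FilterRule:
    return FilterRule("zero_count", max_zeros)


def filter_genes(counts: pd.DataFrame, groups: dict[str, Sequence[str]],
                 rule: FilterRule) -> list[str]:
    """Return the retained gene ids (input order preserved) under ``rule``.

    ``groups`` maps group label -> sample ids; the union of the groups is the
    contrast's sample set.  Removal thresholds use strict inequality ("more
    than N zeros" removes only genes with > N zeros).
    """
    for label, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {label!r} is empty")
    all_samples = [s for samples in groups.values() for s in samples]
    sub = counts[all_samples]
    if rule.kind == "zero_count":
        n_zeros = (sub == 0).sum(axis=1)
        keep = n_zeros <= rule.value
    else:
        fails = []
        for samples in groups.values():
            frac = (counts[list(samples)] == 0).mean(axis=1)
            fails.append(frac > rule.value)
        fails = pd.concat(fails, axis=1)
        removed = fails.any(axis=1) if rule.scope == "any" else fails.all(axis=1)
        keep = ~removed
    return counts.index[keep].tolist()


@dataclass(frozen=True)
class GroupSelector:
    """Selects samples by group label(s) and optionally region(s)."""

    groups: tuple[str, ...]
    regions: tuple[str, ...] | None = None

    def select(self, meta: pd.DataFrame) -> list[str]:
        mask = meta["group"].isin(self.groups)
        if self.regions is not None:
            mask &= meta["region"].isin(self.regions)
        return meta.index[mask].tolist()


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise differential-expression contrast.

    ``group_a`` is the numerator of the fold change (L2FC > 0 means higher in
    A).  ``covariates`` are metadata columns adjusted for in the model.
    """

    name: str
    group_a: GroupSelector
    group_b: GroupSelector
    covariates: tuple[str, ...] = ("age_at_death", "sex")
    filter_rule: FilterRule = field(default_factory=lambda: zero_fraction(0.5))

    def samples(self, meta: pd.DataFrame) -> tuple[list[str], list[str]]:
        a = self.group_a.select(meta)
        b = self.group_b.select(meta)
        if not a or not b:
            raise ValueError(f"contrast {self.name!r}: empty side (|A|={len(a)}, |B|={len(b)})")
        overlap = set(a) & set(b)
        if overlap:
            raise ValueError(f"contrast {self.name!r}: sides overlap: {sorted(overlap)[:5]}")
        return a, b


def _sel(group: str, region: str) -> GroupSelector:
    return GroupSelector(groups=(group,), regions=(region,))


#: The study's five contrasts: symptomatic disease vs control cortex (1),
#: asymptomatic gene-positive vs control cortex (2), asymptomatic caudate vs
#: cortex within carriers (3), asymptomatic caudate vs control caudate (4),
#: and the region contrast in the reference population (5).
STUDY_CONTRASTS: dict[str, ContrastSpec] = {
    "1": ContrastSpec("1", _sel("HD", "BA9"), _sel("C", "BA9"),
                      filter_rule=zero_fraction(0.5)),
    "2": ContrastSpec("2", _sel("HD+", "BA9"), _sel("C", "BA9"),
                      filter_rule=zero_fraction(0.5)),
    "3": ContrastSpec("3", _sel("HD+", "CAU"), _sel("HD+", "BA9"),
                      filter_rule=zero_count(2)),
    "4": ContrastSpec("4", _sel("HD+", "CAU"), _sel("C", "CAU"),
                      filter_rule=zero_count(4)),
    # numerator CAU so the region effect has the same orientation as contrast 3
    "5": ContrastSpec("5", _sel("GTEx", "CAU"), _sel("GTEx", "BA9"),
                      filter_rule=zero_fraction(0.5)),
}
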