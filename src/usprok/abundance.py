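"""Cross-sample abundance normalization and community summaries.

Matrices are plain :class:`pandas.DataFrame` objects with taxa (MAGs or
OTUs/ASVs) as rows and samples as columns.  Counts from samples of unequal
sequencing depth are made comparable by up-scaling every sample to the
highest per-sample read total; relative abundances divide each sample by
its total.  Enrichment factors compare a taxon's mean relative abundance
between two sample groups (e.g. oxic vs anoxic-to-dysoxic, or planktonic
vs sediment-enriched), with taxa absent from the denominator group called
exclusive.  Also here: prevalence, fraction-sharing (Venn partitions),
rarefaction / richness / Shannon diversity, Bray–Curtis dissimilarity and
min–max scaling of physicochemistry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

ENRICHMENT_CLASSES = (
    "enriched-A",
    "enriched-B",
    "exclusive-A",
    "exclusive-B",
    "neutral",
    "absent",
)


def _check_non_negative(m: pd.DataFrame, what: str = "matrix") -> None:
    if (m.to_numpy() < 0).any():
        raise ValueError(f"{what} contains negative values")


def normalize_counts(raw: pd.DataFrame, mode: str = "max") -> pd.DataFrame:
    """Equalize sequencing depth across samples.

    ``mode="max"`` (default) scales every sample's counts up so each
    column total equals the highest original total — normalization based
    on the highest read count between samples.  ``mode="min"`` instead
    down-scales to the smallest non-zero total.  Either way within-sample
    proportions are preserved exactly.

    All-zero samples are left all-zero with a warning.
    """
    _check_non_negative(raw, "count matrix")
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        logger.warning(
            "%d sample(s) have zero total counts and are left unscaled",
            int((totals == 0).sum()),
        )
    nonzero = totals[totals > 0]
    if nonzero.empty:
        return raw.copy()
    if mode == "max":
        target = nonzero.max()
    elif mode == "min":
        target = nonzero.min()
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'max' or 'min'")
    factors = pd.Series(
        np.where(totals > 0, target / totals.replace(0, np.nan), 0.0), index=totals.index
    ).fillna(0.0)
    return raw * factors


def relative_abundance(m: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1; all-zero stay 0)."""
    _check_non_negative(m)
    totals = m.sum(axis=0)
    safe = totals.replace(0, np.nan)
    return (m / safe).fillna(0.0)


@dataclass
class EnrichmentResult:
    """Per-taxon enrichment factor and class between two sample groups."""

    table: pd.DataFrame  # columns: mean_a, mean_b, factor, enrichment_class
    grouping: str

    def classes(self) -> pd.Series:
        return self.table["enrichment_class"]


def enrichment(
    rel: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    grouping: str = "A-vs-B",
    neutral_band: float = 1.05,
) -> EnrichmentResult:
    """Enrichment factor = mean relative abundance in A / mean in B.

    Factor > 1 means enriched in the numerator group A; a taxon present in
    A but with zero mean in B is ``exclusive-A`` (factor +inf), the mirror
    case ``exclusive-B`` (factor 0), absent everywhere ``absent`` (factor
    NaN).  Factors within ``[1/neutral_band, neutral_band]`` are called
    neutral to avoid knife-edge classification.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("sample groups must be disjoint")
    if neutral_band < 1:
        raise ValueError("neutral_band must be >= 1")
    mean_a = rel[group_a].mean(axis=1)
    mean_b = rel[group_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = mean_a / mean_b
    cls = pd.Series("neutral", index=rel.index, dtype=object)
    cls[(mean_a == 0) & (mean_b == 0)] = "absent"
    cls[(mean_a > 0) & (mean_b == 0)] = "exclusive-A"
    cls[(mean_a == 0) & (mean_b > 0)] = "exclusive-B"
    both = (mean_a > 0) & (mean_b > 0)
    cls[both & (factor > neutral_band)] = "enriched-A"
    cls[both & (factor < 1 / neutral_band)] = "enriched-B"
    factor = factor.where(~((mean_a == 0) & (mean_b == 0)))  # absent -> NaN
    table = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "factor": factor, "enrichment_class": cls}
    )
    return EnrichmentResult(table=table, grouping=grouping)


def prevalence(m: pd.DataFrame, min_fraction: float, *, floor: float = 0.0) -> pd.Index:
    """Taxa present (value > ``floor``) in at least ceil(f * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    needed = math.ceil(min_fraction * m.shape[1])
    present = (m > floor).sum(axis=1)
    return m.index[present >= needed]


def shared_taxa(
    m: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> dict[str, object]:
    """Venn partition of taxa between two sample fractions.

    Presence = non-zero in at least one sample of the group.  Returns the
    three partitions (taxon indexes and counts) plus, per group, the share
    of that group's summed relative abundance carried by each partition.
    Percentages are over taxa present in at least one of the two groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    in_a = (m[group_a] > 0).any(axis=1)
    in_b = (m[group_b] > 0).any(axis=1)
    only_a = m.index[in_a & ~in_b]
    only_b = m.index[in_b & ~in_a]
    shared = m.index[in_a & in_b]
    n_present = int((in_a | in_b).sum())
    rel = relative_abundance(m)
    abundance_share = {}
    for label, samples in (("A", group_a), ("B", group_b)):
        total = rel[samples].to_numpy().sum()
        shares = {}
        for part, taxa in (("only_a", only_a), ("shared", shared), ("only_b", only_b)):
            mass = rel.loc[taxa, samples].to_numpy().sum()
            shares[part] = mass / total if total > 0 else 0.0
        abundance_share[label] = shares
    return {
        "only_a": only_a,
        "shared": shared,
        "only_b": only_b,
        "counts": (len(only_a), len(shared), len(only_b)),
        "n_present": n_present,
        "abundance_share": abundance_share,
    }


def rarefy(
    counts: pd.Series | np.ndarray,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> pd.Series | np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A multivariate-hypergeometric draw; the output sums to ``depth``
    exactly.  ``seed`` may be an integer or a Generator.
    """
    values = np.asarray(counts, dtype=np.int64)
    if (values < 0).any():
        raise ValueError("counts must be non-negative integers")
    total = int(values.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(values, depth)
    if isinstance(counts, pd.Series):
        return pd.Series(drawn, index=counts.index, name=counts.name)
    return drawn


def richness(m: pd.DataFrame, *, floor: float = 0.0) -> pd.Series:
    """Number of taxa with value > ``floor``, per sample."""
    return (m > floor).sum(axis=0)


def shannon(m: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p ln p (nats), per sample."""
    _check_non_negative(m)
    rel = relative_abundance(m).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=m.columns)


def bray_curtis(m: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between samples (columns).

    BC(u, v) = 1 - 2 * sum(min(u_i, v_i)) / (sum u + sum v), in [0, 1].
    A pair of all-zero samples has undefined BC; it is reported as 0 with
    a warning.
    """
    _check_non_negative(m)
    data = m.to_numpy(dtype=float).T  # samples x taxa
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(data, metric="braycurtis"))
    if np.isnan(d).any():
        logger.warning("all-zero sample pair(s): Bray–Curtis set to 0")
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def scale_minmax(
    values: Sequence[float] | pd.Series | np.ndarray, lo: float = 0.0, hi: float = 1.0
) -> pd.Series | np.ndarray:
    """Affine map of [min(values), max(values)] onto [lo, hi].

    A constant vector maps everywhere to ``lo`` with a warning.
    """
    arr = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(arr), np.nanmax(arr)
    if vmax == vmin:
        logger.warning("constant vector in scale_minmax; mapping all values to lo")
        scaled = np.full_like(arr, lo)
    else:
        scaled = lo + (arr - vmin) * (hi - lo) / (vmax - vmin)
    if isinstance(values, pd.Series):
        return pd.Series(scaled, index=values.index, name=values.name)
    return scaled


def group_fraction(rel: pd.DataFrame, taxa: Iterable[str]) -> pd.Series:
    """Per-sample summed relative abundance of a taxon subset.

    E.g. the proportion of the whole community contributed by ultra-small
    prokaryotes in each sample.
    """
    taxa = pd.Index(taxa)
    missing = taxa.difference(rel.index)
    if len(missing):
        raise KeyError(f"taxa not in matrix: {list(missing)[:5]}")
    return rel.loc[taxa].sum(axis=0)
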