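"""Modified-TPM metatranscriptome normalization and expression summaries.

Per-gene read counts are normalized with the modified transcripts-per-
kilobase-per-million formula using library size::

    modified_tpm = reads_mapped * (1000 / gene_length) * (1e6 / library_size)

Downstream summaries: per-MAG expression totals (optionally normalized to
estimated genome size in Mbp) and community shares, COG-category totals
split between oxic and dysoxic samples, condition-exclusive feature sets,
oxic:dysoxic fold changes, row/column Z-scaling for heatmaps, the share of
expression lacking any functional category, and top expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# cold-shock genes whose apparent expression is attributable to sample
# preservation rather than in-situ activity; flagged, never dropped
COLD_SHOCK_GENES = ("cspA", "cspB", "cspC")


def modified_tpm(count, gene_length, library_size):
    """Modified TPM for scalar or array inputs.

    ``count * (1000 / gene_length) * (1_000_000 / library_size)`` — linear
    in count; doubling library size halves every value.
    """
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (gene_length <= 0).any():
        raise ValueError("gene_length must be positive")
    if (library_size <= 0).any():
        raise ValueError("library_size must be positive")
    result = np.asarray(count, dtype=float) * (1000.0 / gene_length) * (1_000_000.0 / library_size)
    if np.ndim(result) == 0:
        return float(result)
    return result


def modified_tpm_matrix(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Apply the modified-TPM formula to a gene x sample count matrix.

    ``gene_lengths`` is indexed by gene, ``library_sizes`` by sample; each
    cell uses its own gene's length and its column's library size.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()]
        raise KeyError(f"genes without length: {list(missing)[:5]}")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any():
        missing = counts.columns[libs.isna()]
        raise KeyError(f"samples without library size: {list(missing)[:5]}")
    values = modified_tpm(
        counts.to_numpy(dtype=float),
        lengths.to_numpy()[:, None],
        libs.to_numpy()[None, :],
    )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


@dataclass
class MagExpression:
    """Per-MAG expression totals and per-sample community shares."""

    total: pd.DataFrame  # MAG x sample summed tpm (possibly size-normalized)
    share: pd.DataFrame  # MAG x sample, columns sum to 1 where any expression
    not_detected: list[str] = field(default_factory=list)  # MAGs with zero tpm everywhere
    orphan_genes: list[str] = field(default_factory=list)


def mag_expression(
    tpm: pd.DataFrame,
    genes: pd.DataFrame,
    mags: pd.DataFrame | None = None,
    *,
    normalize_by_genome_size: bool = False,
) -> MagExpression:
    """Aggregate gene-level modified-TPM to per-MAG totals and shares.

    ``genes`` maps gene_id (index) to ``mag_id``.  With
    ``normalize_by_genome_size`` the per-MAG total is divided by the MAG's
    ``estimated_size`` in Mbp (``mags`` must then carry that column), so
    large genomes do not dominate purely by gene count.  Genes whose MAG is
    unknown are excluded with a warning; MAGs with no transcripts anywhere
    are listed as not detected.
    """
    mag_of = genes["mag_id"].reindex(tpm.index)
    orphans = list(tpm.index[mag_of.isna()])
    if orphans:
        logger.warning("%d gene(s) with no MAG assignment excluded", len(orphans))
    kept = tpm.loc[mag_of.notna()]
    total = kept.groupby(mag_of.dropna()).sum()
    total.index.name = "mag_id"
    if normalize_by_genome_size:
        if mags is None or "estimated_size" not in mags:
            raise ValueError("normalize_by_genome_size requires mags with estimated_size")
        sizes_mbp = mags["estimated_size"].reindex(total.index) / 1e6
        if (sizes_mbp <= 0).any() or sizes_mbp.isna().any():
            bad = total.index[(sizes_mbp <= 0) | sizes_mbp.isna()]
            raise ValueError(f"non-positive or missing estimated size for {list(bad)[:5]}")
        total = total.div(sizes_mbp, axis=0)
    col_sums = total.sum(axis=0)
    share = (total / col_sums.replace(0, np.nan)).fillna(0.0)
    not_detected = list(total.index[(total.sum(axis=1) == 0)])
    return MagExpression(total=total, share=share, not_detected=not_detected, orphan_genes=orphans)


def _split_conditions(condition_labels: Mapping[str, str]) -> tuple[list[str], list[str]]:
    oxic = [s for s, c in condition_labels.items() if c == "oxic"]
    dysoxic = [s for s, c in condition_labels.items() if c == "dysoxic"]
    if not oxic or not dysoxic:
        raise ValueError("both conditions (oxic, dysoxic) must be represented")
    return oxic, dysoxic


def category_condition_proportion(
    tpm: pd.DataFrame, genes: pd.DataFrame, condition_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-COG-category percentage of expression by condition.

    For each category, the per-sample category totals are averaged within
    the oxic and dysoxic sample groups; the reported percentages are
    ``100 * mean_oxic / (mean_oxic + mean_dysoxic)`` and its complement,
    so the pair always sums to 100.  Categories with zero expression
    everywhere are excluded with a note.
    """
    oxic, dysoxic = _split_conditions(condition_labels)
    cats = genes["cog_category"].reindex(tpm.index)
    with_cat = cats.notna()
    totals = tpm.loc[with_cat].groupby(cats[with_cat]).sum()
    mean_oxic = totals[oxic].mean(axis=1)
    mean_dys = totals[dysoxic].mean(axis=1)
    denom = mean_oxic + mean_dys
    zero = denom == 0
    if zero.any():
        logger.info("categories with zero expression excluded: %s", list(totals.index[zero]))
    out = pd.DataFrame(
        {
            "mean_oxic": mean_oxic,
            "mean_dysoxic": mean_dys,
            "pct_oxic": 100 * mean_oxic / denom.where(~zero),
            "pct_dysoxic": 100 * mean_dys / denom.where(~zero),
        }
    )
    return out.loc[~zero]


@dataclass
class ExclusiveSets:
    """Features detected only under one condition."""

    exclusive_a: pd.Index
    exclusive_b: pd.Index
    shared: pd.Index
    pct_exclusive_a: float
    pct_exclusive_b: float
    n_expressed: int


def exclusive_detection(
    tpm: pd.DataFrame,
    condition_labels: Mapping[str, str],
    *,
    level: str = "gene",
    genes: pd.DataFrame | None = None,
    threshold: float = 0.0,
) -> ExclusiveSets:
    """Condition-exclusive features (genes or MAGs).

    A feature is exclusive to condition A when it is detected
    (value > ``threshold``) in at least one A sample and in no B sample.
    Percentages are over all expressed features.  ``level="mag"``
    aggregates gene tpm per MAG first (requires ``genes``).
    """
    oxic, dysoxic = _split_conditions(condition_labels)
    if level == "mag":
        if genes is None:
            raise ValueError("level='mag' requires the gene table")
        matrix = mag_expression(tpm, genes).total
    elif level == "gene":
        matrix = tpm
    else:
        raise ValueError(f"unknown level {level!r}")
    in_a = (matrix[oxic] > threshold).any(axis=1)
    in_b = (matrix[dysoxic] > threshold).any(axis=1)
    expressed = in_a | in_b
    excl_a = matrix.index[in_a & ~in_b]
    excl_b = matrix.index[in_b & ~in_a]
    shared = matrix.index[in_a & in_b]
    n = int(expressed.sum())
    return ExclusiveSets(
        exclusive_a=excl_a,
        exclusive_b=excl_b,
        shared=shared,
        pct_exclusive_a=100 * len(excl_a) / n if n else 0.0,
        pct_exclusive_b=100 * len(excl_b) / n if n else 0.0,
        n_expressed=n,
    )


def condition_fold_change(
    mag_totals: pd.DataFrame, condition_labels: Mapping[str, str]
) -> pd.Series:
    """Oxic:dysoxic ratio of mean per-sample expression, per MAG.

    +inf where the dysoxic mean is zero but the oxic mean positive; MAGs
    with zero expression in both conditions are excluded.
    """
    oxic, dysoxic = _split_conditions(condition_labels)
    mean_oxic = mag_totals[oxic].mean(axis=1)
    mean_dys = mag_totals[dysoxic].mean(axis=1)
    defined = (mean_oxic > 0) | (mean_dys > 0)
    with np.errstate(divide="ignore"):
        ratio = mean_oxic / mean_dys
    ratio[(mean_dys == 0) & (mean_oxic > 0)] = np.inf
    return ratio[defined]


def zscore_scale(matrix: pd.DataFrame, mode: str = "row") -> pd.DataFrame:
    """Z-score a matrix by row, column, or row then column.

    Constant vectors become all-zero with a warning (sd undefined).
    """

    def _scale(df: pd.DataFrame, axis: int) -> pd.DataFrame:
        mean = df.mean(axis=axis)
        sd = df.std(axis=axis, ddof=1)
        constant = sd == 0
        if constant.any():
            logger.warning("%d constant vector(s) zeroed during Z-scaling", int(constant.sum()))
        sd = sd.replace(0, np.nan)
        out = df.sub(mean, axis=1 - axis).div(sd, axis=1 - axis)
        return out.fillna(0.0)

    if mode == "row":
        return _scale(matrix, axis=1)
    if mode == "column":
        return _scale(matrix, axis=0)
    if mode == "row-then-column":
        return _scale(_scale(matrix, axis=1), axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def annotated_fraction(
    tpm: pd.DataFrame,
    genes: pd.DataFrame,
    ultrasmall_mags: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percent of expression from genes without a functional category.

    Computed per sample; when ``ultrasmall_mags`` is given, separately for
    ultra-small and other MAGs (rows ``ultra-small`` / ``other``),
    otherwise a single ``all`` row.
    """
    no_cat = genes["cog_category"].reindex(tpm.index).isna()
    if ultrasmall_mags is None:
        groups = {"all": pd.Series(True, index=tpm.index)}
    else:
        is_us = genes["mag_id"].reindex(tpm.index).isin(set(ultrasmall_mags))
        groups = {"ultra-small": is_us, "other": ~is_us}
    rows = {}
    for label, mask in groups.items():
        total = tpm.loc[mask].sum(axis=0)
        unann = tpm.loc[mask & no_cat].sum(axis=0)
        rows[label] = 100 * unann / total.replace(0, np.nan)
    return pd.DataFrame(rows).T


def top_expressed(
    tpm: pd.DataFrame,
    genes: pd.DataFrame,
    k: int,
    *,
    named_only: bool = False,
) -> pd.DataFrame:
    """Top ``k`` genes by total modified-TPM across samples.

    With ``named_only`` only genes carrying a gene name are ranked.  Ties
    break by gene id, lexicographic.  Cold-shock genes (cspA/B/C), whose
    expression is a known sample-preservation artifact, are flagged in the
    ``preservation_artifact`` column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = tpm.sum(axis=1)
    info = genes.reindex(totals.index)
    if named_only:
        keep = info["gene_name"].notna()
        totals, info = totals[keep], info.loc[keep]
    order = pd.DataFrame({"total_tpm": totals, "gene_id": totals.index}).sort_values(
        ["total_tpm", "gene_id"], ascending=[False, True]
    )
    top = order.head(k).index
    out = pd.DataFrame(
        {
            "mag_id": info.loc[top, "mag_id"],
            "gene_name": info.loc[top, "gene_name"] if "gene_name" in info else None,
            "total_tpm": totals.loc[top],
        }
    )
    out["preservation_artifact"] = out["gene_name"].isin(COLD_SHOCK_GENES)
    return out
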