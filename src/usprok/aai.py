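"""Average amino-acid identity (AAI) between genome pairs.

AAI is the mean percent identity over filtered protein best-hit pairs
between two genomes' proteomes.  Hits (blastp outfmt-6 style rows) are
kept when they share >= 30% identity over >= 70% of the alignment length
— operationalized against the shorter protein of the pair, the common AAI
convention; a literal mode drops the coverage filter.  Pairing is by
reciprocal best hits (default) or one-way best hits.  The 45–65% AAI band
is used as the range spanned by genomes of the same family, giving a
coarse novelty call for genomes whose best reference match falls below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a hit table (blast outfmt-6 style plus genome ids).
HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "query_genome",
    "subject_genome",
    "percent_identity",
    "alignment_length",
    "query_length",
    "subject_length",
    "bitscore",
)

#: AAI range spanned by genomes of the same family (percent identity).
FAMILY_AAI_BAND = (45.0, 65.0)


@dataclass
class AaiResult:
    genome_a: str
    genome_b: str
    aai: float  # NaN when undefined
    n_pairs: int
    mode: str
    family_call: str  # within-family-band / below-band / above-band / no-confident-match


def _validate(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    bad_rows = []
    ident = hits["percent_identity"].astype(float)
    for idx in hits.index[(ident < 0) | (ident > 100) | ident.isna()]:
        bad_rows.append((idx, "percent_identity out of [0, 100]"))
    for col in ("alignment_length", "query_length", "subject_length"):
        vals = hits[col].astype(float)
        for idx in hits.index[(vals <= 0) | vals.isna()]:
            bad_rows.append((idx, f"{col} must be positive"))
    if bad_rows:
        report = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValueError(f"malformed hit rows rejected: {report}")
    return hits


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    *,
    coverage_mode: str = "shorter",
) -> pd.DataFrame:
    """Keep hits with identity >= ``min_identity`` and sufficient coverage.

    Coverage requires ``alignment_length >= min_coverage * L`` where L is
    the shorter of the two protein lengths (``coverage_mode="shorter"``).
    ``coverage_mode="none"`` disables the coverage filter (literal reading
    of a filter defined on the alignment length itself, which is
    self-referential and therefore vacuous).  Both bounds are inclusive.
    """
    hits = _validate(hits)
    keep = hits["percent_identity"].astype(float) >= min_identity
    if coverage_mode == "shorter":
        shorter = hits[["query_length", "subject_length"]].astype(float).min(axis=1)
        keep &= hits["alignment_length"].astype(float) >= min_coverage * shorter
    elif coverage_mode != "none":
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    return hits.loc[keep]


def _directed_best(hits: pd.DataFrame) -> pd.DataFrame:
    """Best subject per query: highest bitscore, ties by identity then id."""
    ordered = hits.sort_values(
        ["query_id", "bitscore", "percent_identity", "subject_id"],
        ascending=[True, False, False, True],
    )
    return ordered.drop_duplicates(subset="query_id", keep="first")


def best_hits(hits: pd.DataFrame, mode: str = "reciprocal") -> pd.DataFrame:
    """Best-hit pairs between the two genomes present in ``hits``.

    one-way: for each query protein its top subject (bitscore, then
    identity, then lexicographic subject id).  reciprocal: mutual best
    hits only — protein q's best is s and s's best (in the reverse
    direction) is q; the returned row carries the mean identity of the
    two directions.
    """
    if hits.empty:
        return hits.copy()
    genomes = set(hits["query_genome"]) | set(hits["subject_genome"])
    if len(genomes) != 2:
        raise ValueError(f"best_hits expects a two-genome table, found {sorted(genomes)}")
    a, b = sorted(genomes)
    fwd = _directed_best(hits[(hits["query_genome"] == a) & (hits["subject_genome"] == b)])
    if mode == "one-way":
        return fwd
    if mode != "reciprocal":
        raise ValueError(f"unknown mode {mode!r}")
    rev = _directed_best(hits[(hits["query_genome"] == b) & (hits["subject_genome"] == a)])
    rev_best = dict(zip(rev["query_id"], rev["subject_id"]))
    mutual = fwd[fwd.apply(lambda r: rev_best.get(r["subject_id"]) == r["query_id"], axis=1)]
    if mutual.empty:
        return mutual
    rev_ident = dict(zip(rev["query_id"], rev["percent_identity"].astype(float)))
    mutual = mutual.copy()
    mutual["percent_identity"] = [
        (float(pi) + rev_ident[s]) / 2.0
        for pi, s in zip(mutual["percent_identity"], mutual["subject_id"])
    ]
    return mutual


def classify_family(aai_value: float) -> str:
    """Place an AAI value relative to the 45–65% same-family band."""
    lo, hi = FAMILY_AAI_BAND
    if np.isnan(aai_value):
        return "no-confident-match"
    if aai_value < lo:
        return "below-band"
    if aai_value > hi:
        return "above-band"
    return "within-family-band"


def aai(
    genome_a: str,
    genome_b: str,
    hits: pd.DataFrame,
    mode: str = "reciprocal",
    *,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    length_weighted: bool = False,
) -> AaiResult:
    """AAI between two genomes from a protein alignment hit table.

    Filters hits, pairs proteins, then averages percent identity over the
    retained pairs (unweighted by default; ``length_weighted`` weights by
    alignment length).  Zero retained pairs gives an undefined (NaN) AAI
    with ``family_call="no-confident-match"``.
    """
    pair_genomes = {genome_a, genome_b}
    sub = hits[
        hits["query_genome"].isin(pair_genomes) & hits["subject_genome"].isin(pair_genomes)
        & (hits["query_genome"] != hits["subject_genome"])
    ]
    retained = best_hits(filter_hits(sub, min_identity, min_coverage), mode) if len(sub) else sub
    n = len(retained)
    if n == 0:
        return AaiResult(genome_a, genome_b, np.nan, 0, mode, "no-confident-match")
    ident = retained["percent_identity"].astype(float).to_numpy()
    if length_weighted:
        w = retained["alignment_length"].astype(float).to_numpy()
        value = float(np.average(ident, weights=w))
    else:
        value = float(ident.mean())
    return AaiResult(genome_a, genome_b, value, n, mode, classify_family(value))


def novelty_summary(
    query_genomes: Sequence[str],
    reference_genomes: Sequence[str],
    hits: pd.DataFrame,
    mode: str = "reciprocal",
    **aai_kwargs,
) -> pd.DataFrame:
    """Maximum AAI of each query genome against a reference set.

    Per query: the best-matching reference, the AAI at that maximum and
    its family-band call; queries with no retained pairs against any
    reference are reported ``no-confident-match``.
    """
    rows = []
    for q in query_genomes:
        best_val, best_ref, best_n = np.nan, None, 0
        for r in reference_genomes:
            res = aai(q, r, hits, mode, **aai_kwargs)
            if res.n_pairs and (np.isnan(best_val) or res.aai > best_val):
                best_val, best_ref, best_n = res.aai, r, res.n_pairs
        rows.append(
            {
                "query_genome": q,
                "best_reference": best_ref,
                "max_aai": best_val,
                "n_pairs": best_n,
                "family_call": classify_family(best_val),
            }
        )
    return pd.DataFrame(rows).set_index("query_genome")


def aai_matrix(
    genomes: Sequence[str], hits: pd.DataFrame, mode: str = "reciprocal", **aai_kwargs
) -> pd.DataFrame:
    """Symmetric AAI matrix over a genome set (NaN where undefined)."""
    genomes = list(genomes)
    out = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    for i, a in enumerate(genomes):
        out.loc[a, a] = 100.0
        for b in genomes[i + 1 :]:
            res = aai(a, b, hits, mode, **aai_kwargs)
            out.loc[a, b] = out.loc[b, a] = res.aai
    return out
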