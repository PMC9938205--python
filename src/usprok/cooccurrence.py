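"""Co-occurrence networks and cohort detection for ultra-small MAGs.

The network links pairs of MAGs whose relative-abundance profiles across
samples show a significant, strong positive Spearman correlation
(rho > 0.8, p < 0.001 by default).  Cohorts — groups of MAGs with
consistently co-varying profiles — are found by Ward minimum-variance
hierarchical clustering of per-MAG standardized profiles, then confirmed
by rank correlation: starting from the dendrogram root, any cluster whose
median pairwise Spearman rho falls below the confirmation threshold is
split into its children, recursively, so the returned cohorts are the
maximal confirmed clusters.  Singletons stay unassigned.  Cohort
preference consistency asks whether all members of a cohort share the
same enrichment class for a grouping (aquifer fraction, or dissolved
oxygen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .abundance import EnrichmentResult

logger = logging.getLogger(__name__)


def spearman_matrix(rel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided t-approximation p over rows.

    Rows with constant profiles get NaN against every partner (their rank
    correlation is undefined); the caller decides how to treat them.
    """
    n = rel.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, rel.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    constant = rel.nunique(axis=1).to_numpy() <= 1
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1] = 0.0  # perfect monotone association
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = rel.index
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def build_network(
    rel: pd.DataFrame, rho_min: float = 0.8, p_max: float = 0.001
) -> nx.Graph:
    """Significant-positive-correlation network over MAG profiles.

    Every input MAG becomes a node (isolated nodes retained); an edge is
    added for each unordered pair with Spearman rho > ``rho_min`` (hence
    positive) and p < ``p_max``.  Constant-profile MAGs cannot form edges
    and are logged.
    """
    rho, p = spearman_matrix(rel)
    constant = rel.nunique(axis=1) <= 1
    if constant.any():
        logger.warning(
            "%d constant-abundance MAG(s) excluded from pairing", int(constant.sum())
        )
    g = nx.Graph(rho_min=rho_min, p_max=p_max)
    g.add_nodes_from(rel.index)
    ids = list(rel.index)
    rho_v, p_v = rho.to_numpy(), p.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    ok = (rho_v[iu, ju] > rho_min) & (p_v[iu, ju] < p_max)
    ok &= np.isfinite(rho_v[iu, ju])
    for i, j in zip(iu[ok], ju[ok]):
        g.add_edge(ids[i], ids[j], rho=float(rho_v[i, j]), p=float(p_v[i, j]))
    return g


def components(network: nx.Graph) -> list[set]:
    """Connected components, largest first (singletons = isolated nodes)."""
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


@dataclass
class Cohort:
    cohort_id: int
    members: list[str]
    median_rho: float
    fraction_uniform: bool | None = None
    do_uniform: bool | None = None


@dataclass
class CohortSet:
    cohorts: list[Cohort] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)

    def assignment(self) -> pd.Series:
        """MAG -> cohort id (NaN for unassigned)."""
        mapping = {m: c.cohort_id for c in self.cohorts for m in c.members}
        all_ids = list(mapping) + list(self.unassigned)
        return pd.Series({m: mapping.get(m, np.nan) for m in all_ids}, name="cohort_id")


def _median_pairwise_rho(rho: np.ndarray, idx: np.ndarray) -> float:
    sub = rho[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    return float(np.median(sub[iu, ju]))


def detect_cohorts(
    rel: pd.DataFrame, confirm_rho: float = 0.8, *, standardize: bool = True
) -> CohortSet:
    """Cohorts of co-varying MAGs via Ward clustering + Spearman confirmation.

    Profiles are standardized per MAG (z-score across samples) so that
    profile shape rather than magnitude drives the Euclidean/Ward
    dendrogram; ``standardize=False`` clusters raw profiles.  The tree is
    then split top-down until every multi-member cluster has median
    pairwise Spearman rho >= ``confirm_rho`` (computed on the raw
    profiles; rank correlation is unaffected by the standardization).
    Rows are ordered lexicographically by MAG id first so merge-order ties
    resolve deterministically.
    """
    if rel.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    rel = rel.loc[sorted(rel.index, key=str)]
    if rel.shape[0] < 2:
        return CohortSet(unassigned=list(rel.index))
    constant = rel.nunique(axis=1) <= 1
    active = rel.loc[~constant]
    unassigned = list(rel.index[constant])
    if active.shape[0] < 2:
        return CohortSet(unassigned=unassigned + list(active.index))

    data = active.to_numpy(dtype=float)
    if standardize:
        mean = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, ddof=1, keepdims=True)
        data = (data - mean) / sd
    z = linkage(data, method="ward")
    rho, _ = spearman_matrix(active)
    rho_v = np.nan_to_num(rho.to_numpy(), nan=-1.0)

    cohorts: list[Cohort] = []
    root = to_tree(z)
    stack = [root]
    while stack:
        node = stack.pop()
        leaves = np.array(node.pre_order(lambda leaf: leaf.id))
        if len(leaves) == 1:
            unassigned.append(active.index[leaves[0]])
            continue
        med = _median_pairwise_rho(rho_v, leaves)
        if med >= confirm_rho:
            members = sorted(active.index[leaves], key=str)
            cohorts.append(Cohort(cohort_id=0, members=members, median_rho=med))
        else:
            stack.append(node.get_left())
            stack.append(node.get_right())
    cohorts.sort(key=lambda c: (-len(c.members), c.members[0]))
    for i, c in enumerate(cohorts, start=1):
        c.cohort_id = i
    return CohortSet(cohorts=cohorts, unassigned=sorted(unassigned, key=str))


_SIDE = {
    "enriched-A": "A",
    "exclusive-A": "A",
    "enriched-B": "B",
    "exclusive-B": "B",
    "neutral": "neutral",
}


def _uniform(classes: list[str | None]) -> bool | None:
    if any(c is None or c == "absent" or (isinstance(c, float) and np.isnan(c)) for c in classes):
        return None  # indeterminate
    sides = {_SIDE.get(c, c) for c in classes}
    return len(sides) == 1


def cohort_consistency(
    cohort_set: CohortSet,
    fraction_enrichment: EnrichmentResult | pd.DataFrame,
    do_enrichment: EnrichmentResult | pd.DataFrame,
) -> tuple[int, int, pd.DataFrame]:
    """Count cohorts whose members share one enrichment preference.

    A cohort is uniform for a grouping when every member falls on the
    same side (enriched or exclusive both count toward their side).
    Members lacking a class leave the cohort indeterminate (flag None)
    for that grouping.  Returns (fraction-uniform count, DO-uniform
    count, per-cohort flag table); flags are also written back onto the
    cohort objects.
    """

    def _classes(res) -> pd.Series:
        table = res.table if isinstance(res, EnrichmentResult) else res
        return table["enrichment_class"]

    frac_cls = _classes(fraction_enrichment)
    do_cls = _classes(do_enrichment)
    rows = []
    for cohort in cohort_set.cohorts:
        fr = _uniform([frac_cls.get(m) for m in cohort.members])
        do = _uniform([do_cls.get(m) for m in cohort.members])
        cohort.fraction_uniform, cohort.do_uniform = fr, do
        rows.append(
            {
                "cohort_id": cohort.cohort_id,
                "n_members": len(cohort.members),
                "median_rho": cohort.median_rho,
                "fraction_uniform": fr,
                "do_uniform": do,
            }
        )
    flags = pd.DataFrame(rows)
    n_frac = int(sum(1 for r in rows if r["fraction_uniform"] is True))
    n_do = int(sum(1 for r in rows if r["do_uniform"] is True))
    return n_frac, n_do, flags


def network_to_edgelist(network: nx.Graph) -> pd.DataFrame:
    """Edge list table (mag_a, mag_b, rho, p), sorted for determinism."""
    rows = [
        {"mag_a": min(u, v, key=str), "mag_b": max(u, v, key=str),
         "rho": d["rho"], "p": d["p"]}
        for u, v, d in network.edges(data=True)
    ]
    out = pd.DataFrame(rows, columns=["mag_a", "mag_b", "rho", "p"])
    return out.sort_values(["mag_a", "mag_b"]).reset_index(drop=True)
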