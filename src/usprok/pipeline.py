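"""End-to-end pipeline: simulate (or load) inputs, run every stage, write TSVs.

Driven by a single :class:`PipelineConfig` (YAML-loadable); all
randomness flows from one seed.  Stage order: synthetic data (optional)
-> genome metrics -> abundance -> transcription -> AAI novelty ->
correlation screen -> co-occurrence.  Every stage writes tab-separated
outputs into the run directory and a ``manifest.json`` records the
config hash, seed, package version and per-output row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__, abundance, aai, cooccurrence, correlation, genome_metrics, transcription
from .synthetic import SimulationConfig, SyntheticData, simulate, write_outputs

logger = logging.getLogger(__name__)

ENV_PARAMETERS = (
    "DO", "DOC", "nitrate_n", "pH", "sulfate", "ORP", "temperature", "DRP", "conductivity",
)

STAGES = (
    "simulate", "genome_metrics", "abundance", "transcription",
    "aai", "correlation", "cooccurrence",
)


@dataclass
class PipelineConfig:
    """Run settings; defaults reproduce the reference synthetic study."""

    seed: int = 0
    outdir: str = "usprok-run"
    simulate: SimulationConfig | None = None
    input_dir: str | None = None  # pre-existing TSVs instead of simulation
    min_completeness: float = 0.5
    max_contamination: float = 0.05
    neutral_band: float = 1.05
    correlation_method: str = "spearman"
    alpha: float = 0.05
    rho_min: float = 0.8
    p_max: float = 0.001
    confirm_rho: float = 0.8

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            self.simulate = SimulationConfig(seed=self.seed)
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**{**self.simulate, "seed": self.seed})
        for name in ("alpha", "p_max"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not -1 <= self.rho_min <= 1 or not -1 <= self.confirm_rho <= 1:
            raise ValueError("correlation thresholds must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def content_hash(self) -> str:
        def _default(o):
            return asdict(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig) -> SyntheticData:
    """Read pre-existing pipeline inputs from ``input_dir``."""
    from .synthetic import GroundTruth, TranscriptData

    d = Path(config.input_dir)
    for required in ("samples.tsv", "mags.tsv", "coverage.tsv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"required input missing: {d / required}")
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample_id")
    mags = pd.read_csv(d / "mags.tsv", sep="\t", index_col="mag_id")
    scg_path = d / "scg.tsv"
    scg = pd.read_csv(scg_path, sep="\t") if scg_path.exists() else pd.DataFrame(
        columns=["mag_id", "marker_id", "copies", "scg_set"]
    )
    coverage = pd.read_csv(d / "coverage.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", index_col="gene_id")
    counts = pd.read_csv(d / "transcripts.tsv", sep="\t", index_col="gene_id")
    libs = pd.read_csv(d / "libsizes.tsv", sep="\t", index_col="sample_id")
    transcripts = TranscriptData(
        genes=genes,
        counts=counts,
        library_sizes=libs["library_size"],
        conditions=libs["condition"].to_dict(),
    )
    hits = pd.read_csv(d / "hits" / "hits.tsv", sep="\t")
    truth_path = d / "truth.tsv"
    truth = GroundTruth(
        mags=pd.read_csv(truth_path, sep="\t", index_col="mag_id")
        if truth_path.exists()
        else pd.DataFrame(),
        category_effects={},
    )
    sim = config.simulate or SimulationConfig(seed=config.seed)
    return SyntheticData(sim, samples, mags, scg, coverage, transcripts, hits, truth)


def _tsv(df: pd.DataFrame, path: Path, index_label=None) -> int:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)
    return len(df)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns the result bundle (in-memory objects).

    Outputs land in ``config.outdir``; any stage error aborts the run
    (downstream stages are skipped) with a non-empty exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "usprok_version": __version__,
        "stages": {},
        "outputs": {},
    }
    results: dict = {"manifest": manifest}

    t0 = time.perf_counter()
    if config.input_dir is not None:
        data = _load_inputs(config)
    else:
        data = simulate(config.simulate)
        if "simulate" in stages:
            write_outputs(data, outdir / "inputs")
    results["data"] = data
    manifest["stages"]["simulate"] = round(time.perf_counter() - t0, 3)
    manifest["n_metagenome_samples"] = len(data.samples)
    manifest["n_transcriptome_samples"] = len(data.transcripts.counts.columns)

    def _finalize() -> dict:
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", outdir)
        return results

    if "genome_metrics" not in stages:
        return _finalize()

    # --- genome metrics ---------------------------------------------------
    t0 = time.perf_counter()
    mags = genome_metrics.add_estimated_size(data.mags)
    tiers = genome_metrics.quality_tiers(mags)
    mags_out = pd.concat([mags, tiers], axis=1)
    manifest["outputs"]["mags_metrics.tsv"] = _tsv(mags_out, outdir / "mags_metrics.tsv", "mag_id")
    results["mags"] = mags_out
    manifest["stages"]["genome_metrics"] = round(time.perf_counter() - t0, 3)
    if "abundance" not in stages:
        return _finalize()

    # --- abundance --------------------------------------------------------
    t0 = time.perf_counter()
    normalized = abundance.normalize_counts(data.coverage)
    rel = abundance.relative_abundance(normalized)
    manifest["outputs"]["coverage.relab.tsv"] = _tsv(rel, outdir / "coverage.relab.tsv", "taxon_id")
    oxic = list(data.samples.index[data.samples["redox"] == "oxic"])
    nonoxic = list(data.samples.index[data.samples["redox"] != "oxic"])
    plank = list(data.samples.index[data.samples["fraction"] == "groundwater"])
    attached = list(data.samples.index[data.samples["fraction"] == "sediment-enriched"])
    enr_do = abundance.enrichment(
        rel, oxic, nonoxic, grouping="oxic-vs-dysoxic", neutral_band=config.neutral_band
    )
    enr_frac = abundance.enrichment(
        rel, plank, attached, grouping="planktonic-vs-attached", neutral_band=config.neutral_band
    )
    enr_out = pd.concat(
        {"oxic_vs_dysoxic": enr_do.table, "planktonic_vs_attached": enr_frac.table}, axis=1
    )
    manifest["outputs"]["enrichment.tsv"] = _tsv(enr_out, outdir / "enrichment.tsv", "taxon_id")
    bc = abundance.bray_curtis(rel)
    manifest["outputs"]["bray_curtis.tsv"] = _tsv(bc, outdir / "bray_curtis.tsv", "sample_id")
    ultrasmall = list(mags.index[mags["group"] != "other"])
    diversity = pd.DataFrame(
        {
            "richness": abundance.richness(data.coverage),
            "shannon": abundance.shannon(data.coverage),
            "ultrasmall_fraction": abundance.group_fraction(rel, ultrasmall),
        }
    )
    manifest["outputs"]["diversity.tsv"] = _tsv(diversity, outdir / "diversity.tsv", "sample_id")
    results.update(rel=rel, enrichment_do=enr_do, enrichment_fraction=enr_frac, diversity=diversity)
    manifest["stages"]["abundance"] = round(time.perf_counter() - t0, 3)
    if "transcription" not in stages:
        return _finalize()

    # --- transcription ----------------------------------------------------
    t0 = time.perf_counter()
    tx = data.transcripts
    tpm = transcription.modified_tpm_matrix(tx.counts, tx.genes["length"], tx.library_sizes)
    expr = transcription.mag_expression(tpm, tx.genes, mags, normalize_by_genome_size=True)
    manifest["outputs"]["mag_expression.tsv"] = _tsv(
        expr.total, outdir / "mag_expression.tsv", "mag_id"
    )
    props = transcription.category_condition_proportion(tpm, tx.genes, tx.conditions)
    manifest["outputs"]["category_proportions.tsv"] = _tsv(
        props, outdir / "category_proportions.tsv", "cog_category"
    )
    excl = transcription.exclusive_detection(tpm, tx.conditions)
    excl_out = pd.DataFrame(
        {
            "feature": list(excl.exclusive_a) + list(excl.exclusive_b),
            "exclusive_to": ["oxic"] * len(excl.exclusive_a) + ["dysoxic"] * len(excl.exclusive_b),
        }
    )
    manifest["outputs"]["exclusive_sets.tsv"] = len(excl_out)
    excl_out.to_csv(outdir / "exclusive_sets.tsv", sep="\t", index=False)
    unannot = transcription.annotated_fraction(tpm, tx.genes, ultrasmall_mags=ultrasmall)
    manifest["outputs"]["unannotated_fraction.tsv"] = _tsv(
        unannot, outdir / "unannotated_fraction.tsv", "mag_group"
    )
    results.update(tpm=tpm, mag_expression=expr, category_proportions=props, exclusive=excl)
    manifest["stages"]["transcription"] = round(time.perf_counter() - t0, 3)
    if "aai" not in stages:
        return _finalize()

    # --- AAI novelty ------------------------------------------------------
    t0 = time.perf_counter()
    queries = sorted(set(data.hits["query_genome"]) - set(data.hits["subject_genome"]) | {
        g for g in set(data.hits["query_genome"]) if not str(g).startswith("ref")
    })
    refs = sorted(g for g in set(data.hits["subject_genome"]) if str(g).startswith("ref"))
    novelty = aai.novelty_summary(queries, refs, data.hits)
    manifest["outputs"]["novelty_summary.tsv"] = _tsv(
        novelty, outdir / "novelty_summary.tsv", "query_genome"
    )
    results["novelty"] = novelty
    manifest["stages"]["aai"] = round(time.perf_counter() - t0, 3)
    if "correlation" not in stages:
        return _finalize()

    # --- correlation screen -----------------------------------------------
    t0 = time.perf_counter()
    env = data.samples[[p for p in ENV_PARAMETERS if p in data.samples.columns]]
    rel_us = rel.loc[[m for m in ultrasmall if m in rel.index]]
    screen = correlation.correlation_screen(
        rel_us, env, method=config.correlation_method, alpha=config.alpha
    )
    manifest["outputs"]["correlations.tsv"] = len(screen)
    screen.to_csv(outdir / "correlations.tsv", sep="\t", index=False, float_format="%.10g")
    counts = correlation.significant_counts(screen)
    manifest["outputs"]["correlation_counts.tsv"] = _tsv(
        counts, outdir / "correlation_counts.tsv", "parameter"
    )
    results["screen"] = screen
    manifest["stages"]["correlation"] = round(time.perf_counter() - t0, 3)
    if "cooccurrence" not in stages:
        return _finalize()

    # --- co-occurrence ----------------------------------------------------
    t0 = time.perf_counter()
    network = cooccurrence.build_network(rel_us, rho_min=config.rho_min, p_max=config.p_max)
    edges = cooccurrence.network_to_edgelist(network)
    manifest["outputs"]["network_edges.tsv"] = len(edges)
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False, float_format="%.10g")
    nx.write_graphml(network, outdir / "network.graphml")
    cohort_set = cooccurrence.detect_cohorts(rel_us, confirm_rho=config.confirm_rho)
    n_frac, n_do, flags = cooccurrence.cohort_consistency(cohort_set, enr_frac, enr_do)
    cohort_rows = [
        {
            "cohort_id": c.cohort_id, "mag_id": m, "median_rho": c.median_rho,
            "fraction_uniform": c.fraction_uniform, "do_uniform": c.do_uniform,
        }
        for c in cohort_set.cohorts
        for m in c.members
    ]
    cohorts_out = pd.DataFrame(
        cohort_rows, columns=["cohort_id", "mag_id", "median_rho", "fraction_uniform", "do_uniform"]
    )
    manifest["outputs"]["cohorts.tsv"] = len(cohorts_out)
    cohorts_out.to_csv(outdir / "cohorts.tsv", sep="\t", index=False, float_format="%.10g")
    manifest["network"] = {"nodes": network.number_of_nodes(), "edges": network.number_of_edges()}
    manifest["cohorts"] = {
        "n_cohorts": len(cohort_set.cohorts),
        "fraction_uniform": n_frac,
        "do_uniform": n_do,
    }
    results.update(network=network, cohort_set=cohort_set, cohort_flags=flags)
    manifest["stages"]["cooccurrence"] = round(time.perf_counter() - t0, 3)
    return _finalize()
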