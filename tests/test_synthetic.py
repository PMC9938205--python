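import numpy as np
import pandas as pd
import pytest

from usprok import abundance, cooccurrence, transcription
from usprok.genome_metrics import SCG_SET_SIZES
from usprok.synthetic import (
    ConstraintError,
    SimulationConfig,
    generate_coverage,
    generate_mags,
    generate_protein_hits,
    generate_samples,
    generate_transcripts,
    simulate,
    write_outputs,
)


class TestConfig:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConstraintError):
            SimulationConfig(cohort_size_range=(10, 2))
        with pytest.raises(ConstraintError):
            SimulationConfig(cohort_size_range=(1, 5))
        with pytest.raises(ConstraintError):
            SimulationConfig(abundance_noise_cv=-0.1)


class TestSamples:
    def test_design_counts(self):
        samples = generate_samples(SimulationConfig(seed=0))
        assert len(samples) == 16  # 4 sites x 2 wells x 2 fractions
        assert samples["site"].nunique() == 4
        assert (samples.groupby("site").size() == 4).all()

    def test_chemistry_within_ranges(self):
        cfg = SimulationConfig(seed=0)
        samples = generate_samples(cfg)
        for param, (lo, hi) in cfg.env_ranges.items():
            assert samples[param].between(lo, hi).all()

    def test_both_redox_classes_present(self):
        samples = generate_samples(SimulationConfig(seed=0))
        redox = set(samples["redox"])
        assert "oxic" in redox and redox - {"oxic"}

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=9)
        pd.testing.assert_frame_equal(generate_samples(cfg), generate_samples(cfg))

    def test_impossible_do_range_rejected(self):
        with pytest.raises(ConstraintError):
            generate_samples(SimulationConfig(env_ranges={**SimulationConfig().env_ranges, "DO": (0.1, 2.0)}))
        with pytest.raises(ConstraintError):
            generate_samples(SimulationConfig(env_ranges={**SimulationConfig().env_ranges, "DO": (4.0, 7.0)}))


class TestMags:
    def test_sizes_and_quality_bounds(self):
        cfg = SimulationConfig(seed=0)
        mags, scg, truth = generate_mags(cfg)
        us = mags[mags["group"] != "other"]
        assert (truth.mags.loc[us.index, "true_size"] >= 0.4e6).all()
        assert mags["completeness"].between(0.5, 1).all()
        assert mags["contamination"].between(0, 0.05).all()
        # bin size identity: true * completeness * (1 + contamination)
        expected = (
            truth.mags["true_size"] * mags["completeness"] * (1 + mags["contamination"])
        )
        assert np.allclose(mags["bin_size"], expected)

    def test_lineage_scg_sets(self):
        mags, scg, _ = generate_mags(SimulationConfig(seed=0))
        pates = mags[mags["group"] == "Patescibacteria"]
        assert (pates["scg_set"] == "bact43").all()
        assert (mags.loc[mags["group"] == "Dependentiae", "scg_set"] == "bact51").all()
        assert (
            mags.loc[mags["group"].str.startswith("DPANN"), "scg_set"] == "arch38"
        ).all()
        # SCG rows never exceed the marker-set size
        per_mag = scg.groupby("mag_id").size()
        sets = mags["scg_set"].reindex(per_mag.index).map(SCG_SET_SIZES)
        assert (per_mag <= sets).all()

    def test_cohort_sizes_within_range(self):
        cfg = SimulationConfig(seed=0)
        _, _, truth = generate_mags(cfg)
        sizes = truth.mags["cohort"].dropna().value_counts()
        lo, hi = cfg.cohort_size_range
        assert sizes.between(lo, hi).all()
        assert sizes.sum() <= cfg.n_ultrasmall_mags

    def test_every_ultrasmall_mag_has_label(self):
        mags, _, truth = generate_mags(SimulationConfig(seed=0))
        assert truth.mags["enrichment_label"].notna().all()


class TestCoverage:
    def _build(self, **kw):
        cfg = SimulationConfig(seed=4, n_ultrasmall_mags=30, n_background_mags=5,
                               n_cohorts=3, cohort_size_range=(4, 8), **kw)
        samples = generate_samples(cfg)
        mags, _, truth = generate_mags(cfg)
        return cfg, samples, mags, truth, generate_coverage(cfg, samples, mags, truth)

    def test_depth_conservation(self):
        cfg, samples, mags, truth, counts = self._build()
        totals = counts.sum(axis=0)
        lo, hi = cfg.depth_range
        assert totals.between(lo, hi).all()

    def test_zero_cv_gives_perfect_within_cohort_correlation(self):
        cfg, samples, mags, truth, counts = self._build(
            abundance_noise_cv=0.0, depth_range=(5_000_000, 5_000_000)
        )
        cohorts = truth.mags["cohort"].dropna()
        first = cohorts.unique()[0]
        members = cohorts.index[cohorts == first][:2]
        rho, _ = cooccurrence.spearman_matrix(counts.loc[members].astype(float))
        assert rho.iloc[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_cross_cohort_correlation_low(self):
        cfg, samples, mags, truth, counts = self._build()
        cohorts = truth.mags["cohort"].dropna()
        ids = cohorts.unique()
        # cohorts 1 and 2 have different dominant sites by round-robin design
        a = cohorts.index[cohorts == ids[0]][0]
        b = cohorts.index[cohorts == ids[1]][0]
        rel = abundance.relative_abundance(counts)
        rho, _ = cooccurrence.spearman_matrix(rel.loc[[a, b]])
        assert rho.iloc[0, 1] < 0.5

    def test_enrichment_effect_recovered(self):
        cfg = SimulationConfig(seed=8, n_ultrasmall_mags=40, n_background_mags=5,
                               site_effect=1.0, abundance_noise_cv=0.2)
        samples = generate_samples(cfg)
        mags, _, truth = generate_mags(cfg)
        counts = generate_coverage(cfg, samples, mags, truth)
        rel = abundance.relative_abundance(abundance.normalize_counts(counts))
        plank = list(samples.index[samples["fraction"] == "groundwater"])
        att = list(samples.index[samples["fraction"] == "sediment-enriched"])
        oxic = list(samples.index[samples["redox"] == "oxic"])
        nonoxic = list(samples.index[samples["redox"] != "oxic"])
        frac_res = abundance.enrichment(rel, plank, att).table
        do_res = abundance.enrichment(rel, oxic, nonoxic).table
        labels = truth.mags["enrichment_label"]
        checks = {
            "fraction-planktonic": (frac_res, cfg.enrichment_effect),
            "fraction-attached": (frac_res, 1 / cfg.enrichment_effect),
            "oxic": (do_res, cfg.enrichment_effect),
            "dysoxic": (do_res, 1 / cfg.enrichment_effect),
        }
        # relative abundance is compositional: every factor carries one
        # community-level bias, estimated by the neutral MAGs' median
        neutral = labels.index[~labels.isin(list(checks))]
        baselines = {
            id(frac_res): np.median(frac_res.loc[neutral, "factor"]),
            id(do_res): np.median(do_res.loc[neutral, "factor"]),
        }
        scored = 0
        for label, (table, target) in checks.items():
            members = labels.index[labels == label]
            if not len(members):
                continue
            scored += len(members)
            med = np.median(table.loc[members, "factor"]) / baselines[id(table)]
            assert med == pytest.approx(target, rel=0.35), label
        assert scored > 0


class TestTranscripts:
    def test_condition_design(self, small_config):
        mags, _, truth = generate_mags(small_config)
        tx = generate_transcripts(small_config, mags, truth)
        conditions = pd.Series(tx.conditions)
        assert (conditions == "oxic").sum() == 2
        assert (conditions == "dysoxic").sum() == 4
        assert (tx.library_sizes >= tx.counts.sum(axis=0)).all()

    def test_gene_counts_per_mag_in_range(self, small_config):
        mags, _, truth = generate_mags(small_config)
        tx = generate_transcripts(small_config, mags, truth)
        lo, hi = small_config.genes_per_mag_range
        per_mag = tx.genes.groupby("mag_id").size()
        assert per_mag.between(lo, hi).all()
        assert set(per_mag.index) == set(mags.index)

    def test_zero_in_oxic_gene_is_dysoxic_exclusive(self, small_config):
        mags, _, truth = generate_mags(small_config)
        tx = generate_transcripts(small_config, mags, truth)
        tpm = transcription.modified_tpm_matrix(
            tx.counts, tx.genes["length"], tx.library_sizes
        )
        res = transcription.exclusive_detection(tpm, tx.conditions)
        oxic = [s for s, c in tx.conditions.items() if c == "oxic"]
        dys = [s for s, c in tx.conditions.items() if c == "dysoxic"]
        zero_oxic = tx.counts.index[
            (tx.counts[oxic].sum(axis=1) == 0) & (tx.counts[dys].sum(axis=1) > 0)
        ]
        assert len(zero_oxic) > 0
        assert set(zero_oxic) <= set(res.exclusive_b)

    def test_neutral_effects_give_balanced_proportions(self):
        cfg = SimulationConfig(
            seed=3, n_ultrasmall_mags=30, n_background_mags=10,
            genes_per_mag_range=(200, 300), category_effects={},
            transcript_condition_effect=1.0,
        )
        mags, _, truth = generate_mags(cfg)
        tx = generate_transcripts(cfg, mags, truth)
        tpm = transcription.modified_tpm_matrix(
            tx.counts, tx.genes["length"], tx.library_sizes
        )
        props = transcription.category_condition_proportion(tpm, tx.genes, tx.conditions)
        assert props["pct_oxic"].median() == pytest.approx(50.0, abs=10.0)


class TestDeterminism:
    def test_full_simulation_byte_identical(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_outputs(simulate(small_config), d1)
        p2 = write_outputs(simulate(small_config), d2)
        assert [p.name for p in p1] == [p.name for p in p2]
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
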