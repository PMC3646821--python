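"""Filtering cascade: stage semantics, Table-layout counts, worklists."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pedexome.cascade import (
    STAGES,
    CascadeParams,
    coverage_gaps,
    filter_stage_exonic,
    rank_novel,
    run_cascade,
)
from pedexome.core import (
    FUNCTIONAL_CLASSES,
    GT_HET,
    GT_HOM_ALT,
    GenomicInterval,
    GenotypeCall,
    ValidationError,
    Variant,
)
from pedexome.io import Cohort
from pedexome.simulate import simulate_all
from tests.conftest import REFINED_INTERVAL


def brute_force_cascade(variants, genotypes, affected, params):
    """Independent re-implementation with plain per-sample sets."""
    def freq_ok(v):
        for f in (v.freq_panel_a, v.freq_panel_b):
            if f is not None and f > params.freq_threshold:
                return False
        return True

    per_sample = {}
    for s in affected:
        survivors = [
            v for v in variants
            if genotypes[(s, v.key_str)] in (GT_HET, GT_HOM_ALT)
        ]
        stages = {}
        survivors = [v for v in survivors if v.var_class != "other"]
        stages["exonic_splicing"] = set(v.key_str for v in survivors)
        survivors = [v for v in survivors if v.var_class in params.functional_classes_kept]
        stages["functional"] = set(v.key_str for v in survivors)
        survivors = [v for v in survivors if genotypes[(s, v.key_str)] == GT_HET]
        stages["heterozygous"] = set(v.key_str for v in survivors)
        survivors = [v for v in survivors if freq_ok(v)]
        stages["rare"] = set(v.key_str for v in survivors)
        survivors = [
            v for v in survivors if params.interval.contains(v.chrom, v.pos)
        ]
        stages["in_interval"] = set(v.key_str for v in survivors)
        survivors = [v for v in survivors if not v.in_catalog]
        stages["catalog_absent"] = set(v.key_str for v in survivors)
        per_sample[s] = stages
    shared = {
        stage: set.intersection(*(per_sample[s][stage] for s in affected))
        for stage in STAGES
    }
    return per_sample, shared


def _toy_cohort():
    iv = GenomicInterval("chr7", 100, 200)
    variants = [
        Variant("chr7", 150, "A", "T", "nonsynonymous_SNV", "G1",
                freq_panel_a=None, in_catalog=False),
        Variant("chr7", 160, "G", "C", "nonsynonymous_SNV", "G2",
                freq_panel_a=0.002, in_catalog=True, catalog_id="rs1"),
        Variant("chr7", 300, "T", "A", "stopgain", "G3", freq_panel_a=0.001),
        Variant("chr1", 50, "C", "G", "synonymous_SNV", "G4", freq_panel_a=0.2),
        Variant("chr1", 60, "C", "G", "other", "G5"),
    ]
    calls = [
        GenotypeCall(s, v.key, "het") for v in variants for s in ("P1", "P2")
    ]
    return Cohort.from_records(variants, calls), iv


class TestFilterStageExonic:
    def test_mixed_toy_set(self):
        variants = [
            Variant("chr1", 1, "A", "T", "nonsynonymous_SNV"),
            Variant("chr1", 2, "A", "T", "synonymous_SNV"),
            Variant("chr1", 3, "A", "T", "splicing"),
            Variant("chr1", 4, "A", "T", "other"),
            Variant("chr1", 5, "A", "T", "other"),
        ]
        assert len(filter_stage_exonic(variants)) == 3

    def test_empty_input(self):
        assert filter_stage_exonic([]) == []

    def test_matches_class_recount_on_simulated_sample(self, small_config):
        sim = simulate_all(small_config)
        variants = [sim.cohort.variant(k) for k in sim.cohort.variants.index[:500]]
        kept = filter_stage_exonic(variants)
        assert len(kept) == sum(1 for v in variants if v.var_class != "other")


class TestRankNovel:
    def test_novel_first(self):
        known = Variant("chr1", 1, "A", "T", "stopgain", in_catalog=True)
        novel = Variant("chr1", 2, "A", "T", "stoploss", in_catalog=False)
        ordered, n = rank_novel([known, novel])
        assert ordered == [novel, known] and n == 1

    def test_all_known_preserves_order(self):
        vs = [
            Variant("chr1", p, "A", "T", "stopgain", in_catalog=True)
            for p in (3, 1, 2)
        ]
        ordered, n = rank_novel(vs)
        assert ordered == vs and n == 0

    def test_matches_sort_oracle(self, small_config):
        sim = simulate_all(small_config)
        sample = [sim.cohort.variant(k) for k in sim.cohort.variants.index[:200]]
        ordered, _ = rank_novel(sample)
        oracle = [v for v in sample if not v.in_catalog] + [
            v for v in sample if v.in_catalog
        ]
        assert ordered == oracle


class TestRunCascade:
    def test_all_common_variants_leave_empty_rare_stage(self):
        variants = [
            Variant("chr1", p, "A", "T", "nonsynonymous_SNV", freq_panel_a=0.5)
            for p in range(1, 6)
        ]
        calls = [GenotypeCall("P1", v.key, "het") for v in variants]
        cohort = Cohort.from_records(variants, calls)
        params = CascadeParams(interval=GenomicInterval("chr1", 1, 10))
        result = run_cascade(cohort, ["P1"], params)
        assert result.stage_counts.loc["rare", "P1"] == 0

    def test_frequency_exactly_at_threshold_survives(self):
        v = Variant("chr1", 5, "A", "T", "nonsynonymous_SNV", freq_panel_a=0.01)
        cohort = Cohort.from_records([v], [GenotypeCall("P1", v.key, "het")])
        params = CascadeParams(interval=GenomicInterval("chr1", 1, 10))
        result = run_cascade(cohort, ["P1"], params)
        assert result.stage_counts.loc["rare", "P1"] == 1

    def test_above_threshold_in_either_panel_is_discarded(self):
        v = Variant("chr1", 5, "A", "T", "nonsynonymous_SNV",
                    freq_panel_a=0.001, freq_panel_b=0.05)
        cohort = Cohort.from_records([v], [GenotypeCall("P1", v.key, "het")])
        result = run_cascade(
            cohort, ["P1"], CascadeParams(interval=GenomicInterval("chr1", 1, 10))
        )
        assert result.stage_counts.loc["rare", "P1"] == 0

    def test_hom_alt_and_missing_fail_heterozygous_stage(self):
        variants = [
            Variant("chr1", p, "A", "T", "nonsynonymous_SNV") for p in (1, 2, 3)
        ]
        calls = [
            GenotypeCall("P1", variants[0].key, "het"),
            GenotypeCall("P1", variants[1].key, "hom_alt"),
            GenotypeCall("P1", variants[2].key, "missing"),
        ]
        cohort = Cohort.from_records(variants, calls)
        result = run_cascade(
            cohort, ["P1"], CascadeParams(interval=GenomicInterval("chr1", 1, 10))
        )
        assert result.stage_counts.loc["heterozygous", "P1"] == 1

    def test_class_composition_partitions_rare_stage(self, small_config):
        sim = simulate_all(small_config)
        params = CascadeParams(interval=REFINED_INTERVAL)
        result = run_cascade(sim.cohort, sim.truth.sequenced, params)
        assert sum(result.class_composition.values()) == result.stage_counts.loc[
            "rare", "shared_all"
        ]
        assert set(result.class_composition) <= FUNCTIONAL_CLASSES

    def test_agrees_with_brute_force_oracle(self, small_config):
        config = dataclasses.replace(small_config, n_common_sites=300, n_rare_sites=200)
        sim = simulate_all(config)
        affected = sim.truth.sequenced
        params = CascadeParams(interval=REFINED_INTERVAL)
        result = run_cascade(sim.cohort, affected, params)

        variants = [sim.cohort.variant(k) for k in sim.cohort.variants.index]
        genotypes = {
            (s, k): int(sim.cohort.genotypes.loc[k, s])
            for k in sim.cohort.variants.index
            for s in affected
        }
        per_sample, shared = brute_force_cascade(variants, genotypes, affected, params)
        for stage in STAGES:
            for s in affected:
                assert result.stage_counts.loc[stage, s] == len(per_sample[s][stage])
            assert result.stage_counts.loc[stage, "shared_all"] == len(shared[stage])
        assert {v.key_str for v in result.survivors} == shared["in_interval"]

    def test_monotone_stages_and_intersection_bounds(self, small_config):
        sim = simulate_all(small_config)
        params = CascadeParams(interval=REFINED_INTERVAL)
        result = run_cascade(
            sim.cohort, sim.truth.sequenced, params,
            subset_ids=sim.truth.sequenced[:3],
        )
        result.validate()  # raises on violation
        counts = result.stage_counts
        for col in counts.columns:
            assert (np.diff(counts[col].to_numpy()) <= 0).all()
        for stage in STAGES:
            member_min = counts.loc[stage, sim.truth.sequenced].min()
            assert counts.loc[stage, "shared_all"] <= counts.loc[stage, "shared_subset"]
            assert counts.loc[stage, "shared_subset"] <= member_min

    def test_adding_a_sample_never_raises_shared_counts(self, small_config):
        sim = simulate_all(small_config)
        params = CascadeParams(interval=REFINED_INTERVAL)
        three = run_cascade(sim.cohort, sim.truth.sequenced[:3], params)
        four = run_cascade(sim.cohort, sim.truth.sequenced, params)
        assert (
            four.stage_counts["shared_all"] <= three.stage_counts["shared_all"]
        ).all()

    def test_no_affected_samples_is_an_error(self, small_config):
        sim = simulate_all(small_config)
        with pytest.raises(ValidationError):
            run_cascade(sim.cohort, [], CascadeParams(interval=REFINED_INTERVAL))

    def test_unknown_sample_id_is_an_error(self, small_config):
        sim = simulate_all(small_config)
        with pytest.raises(ValidationError, match="NOSUCH"):
            run_cascade(
                sim.cohort, ["NOSUCH"], CascadeParams(interval=REFINED_INTERVAL)
            )

    def test_toy_two_sample_shared_columns(self):
        cohort, iv = _toy_cohort()
        result = run_cascade(cohort, ["P1", "P2"], CascadeParams(interval=iv))
        assert result.stage_counts.loc["exonic_splicing", "P1"] == 4
        assert result.stage_counts.loc["in_interval", "shared_all"] == 2
        assert result.stage_counts.loc["catalog_absent", "shared_all"] == 1
        assert result.survivors[0].gene == "G1"  # novel ranked first


class TestCoverageGaps:
    EXONS = pd.DataFrame(
        {
            "exon_id": ["e1", "e2", "e3"],
            "chrom": ["chr7", "chr7", "chr1"],
            "start": [110, 150, 5],
            "end": [120, 160, 9],
        }
    )

    def _params(self):
        return CascadeParams(interval=GenomicInterval("chr7", 100, 200))

    def test_low_coverage_exon_reported(self):
        cov = pd.DataFrame(
            {"sample": ["S1", "S1"], "exon_id": ["e1", "e2"], "mean_coverage": [25, 8]}
        )
        with pytest.warns(UserWarning, match="outside interval"):
            gaps = coverage_gaps(self.EXONS, cov, self._params())
        assert gaps == [("S1", "e2")]

    def test_everything_covered_gives_empty_worklist(self):
        cov = pd.DataFrame(
            {"sample": ["S1", "S1"], "exon_id": ["e1", "e2"], "mean_coverage": [25, 11]}
        )
        with pytest.warns(UserWarning):
            assert coverage_gaps(self.EXONS, cov, self._params()) == []

    def test_matches_threshold_scan_on_random_fixture(self):
        rng = np.random.default_rng(42)
        exons = pd.DataFrame(
            {
                "exon_id": [f"e{i}" for i in range(30)],
                "chrom": "chr7",
                "start": np.arange(30) * 3 + 100,
                "end": np.arange(30) * 3 + 101,
            }
        )
        cov = pd.DataFrame(
            {
                "sample": np.repeat(["A", "B"], 30),
                "exon_id": [f"e{i}" for i in range(30)] * 2,
                "mean_coverage": rng.uniform(0, 30, 60).round(1),
            }
        )
        gaps = coverage_gaps(exons, cov, self._params())
        oracle = sorted(
            (r.sample, r.exon_id)
            for r in cov.itertuples()
            if r.mean_coverage < 10
        )
        assert gaps == oracle

    def test_negative_coverage_rejected(self):
        cov = pd.DataFrame({"sample": ["S1"], "exon_id": ["e1"], "mean_coverage": [-1]})
        with pytest.raises(ValidationError):
            coverage_gaps(self.EXONS, cov, self._params())
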