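"""Filtering predicates against brute-force oracles; cascade composition."""

from __future__ import annotations

import numpy as np
import pytest

from pedvar.annotations import AnnotationRecord, annotation_map
from pedvar.filtering import (
    FilterConfig,
    exclude_gene_panel,
    filter_by_cadd,
    filter_by_maf,
    filter_consequence,
    run_cascade,
    shared_heterozygous,
)
from pedvar.pedigree import Individual, Pedigree, Status
from pedvar.segregation import segregation_filter
from pedvar.variants import Genotype, VariantRecord

from conftest import wgs_filter_config


def random_records(rng, n, samples):
    records = []
    for i in range(n):
        gts = {s: Genotype(int(rng.integers(-1, 3))) for s in samples}
        records.append(VariantRecord("1", i + 1, "G", "A", gts))
    return records


class TestSharedHeterozygous:
    def test_empty_collection(self):
        assert shared_heterozygous([], ["A"]) == frozenset()

    def test_all_het_retained(self):
        rec = VariantRecord("1", 1, "G", "A", {s: Genotype.HET for s in "ABCD"})
        assert shared_heterozygous([rec], list("ABCD")) == {rec.key}

    @pytest.mark.parametrize("spoiler", [Genotype.HOM_REF, Genotype.HOM_ALT, Genotype.MISSING])
    def test_any_non_het_excludes(self, spoiler):
        gts = {s: Genotype.HET for s in "ABCD"}
        gts["C"] = spoiler
        rec = VariantRecord("1", 1, "G", "A", gts)
        assert shared_heterozygous([rec], list("ABCD")) == frozenset()

    def test_missing_sample_is_an_input_error(self):
        rec = VariantRecord("1", 1, "G", "A", {"A": Genotype.HET})
        with pytest.raises(ValueError, match="absent"):
            shared_heterozygous([rec], ["A", "B"])

    def test_matches_brute_force_scan_on_random_records(self):
        rng = np.random.default_rng(5)
        samples = list("WXYZ")
        records = random_records(rng, 1000, samples)
        result = shared_heterozygous(records, samples)
        oracle = set()
        for rec in records:  # independent per-record scan
            ok = True
            for s in samples:
                if rec.genotypes[s] != Genotype.HET:
                    ok = False
            if ok:
                oracle.add(rec.key)
        assert result == oracle


def random_annotations(rng, n):
    records = []
    for i in range(n):
        records.append(
            AnnotationRecord(
                key=f"1:{i + 1}:G:A",
                gene=None if rng.random() < 0.2 else f"G{int(rng.integers(20)):02d}",
                consequence=str(
                    rng.choice(["exonic", "Exonic", "intronic", "UTR5", "splicing"])
                ),
                maf=None if rng.random() < 0.25 else float(rng.random() * 0.01),
                cadd=None if rng.random() < 0.25 else float(rng.random() * 40),
            )
        )
    return annotation_map(records)


class TestMafFilter:
    def test_novel_variant_with_zero_maf_is_retained(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", maf=0.0)])
        assert filter_by_maf({"1:1:G:A"}, anns, 0.001) == {"1:1:G:A"}

    def test_boundary_is_strict(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", maf=0.001)])
        assert filter_by_maf({"1:1:G:A"}, anns, 0.001) == frozenset()

    def test_absent_maf_policy(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", maf=None)])
        assert filter_by_maf({"1:1:G:A"}, anns, 0.001) == {"1:1:G:A"}
        assert (
            filter_by_maf({"1:1:G:A"}, anns, 0.001, missing_maf_policy="drop")
            == frozenset()
        )

    def test_matches_strict_comparison_oracle(self):
        rng = np.random.default_rng(8)
        anns = random_annotations(rng, 500)
        keys = set(anns) | {"9:9:G:A"}  # one key with no annotation row
        for policy in ("treat_as_zero", "drop"):
            result = filter_by_maf(keys, anns, 0.005, policy)
            oracle = set()
            for k in keys:
                if k not in anns:
                    continue
                maf = anns[k].maf
                if maf is None:
                    if policy == "treat_as_zero":
                        oracle.add(k)
                elif maf < 0.005:
                    oracle.add(k)
            assert result == oracle


class TestConsequenceFilter:
    def test_exonic_retained_intronic_excluded(self):
        anns = annotation_map(
            [
                AnnotationRecord(key="1:1:G:A", consequence="exonic"),
                AnnotationRecord(key="1:2:G:A", consequence="intronic"),
            ]
        )
        assert filter_consequence(set(anns), anns) == {"1:1:G:A"}

    def test_case_folding(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", consequence="Exonic")])
        assert filter_consequence({"1:1:G:A"}, anns, {"exonic"}) == {"1:1:G:A"}

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(9)
        anns = random_annotations(rng, 500)
        allowed = {"exonic", "splicing"}
        result = filter_consequence(set(anns), anns, allowed)
        oracle = {
            k for k, a in anns.items() if a.consequence.casefold() in allowed
        }
        assert result == oracle


class TestCaddFilter:
    def test_candidate_score_survives_10_but_not_15(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", cadd=13.71)])
        assert filter_by_cadd({"1:1:G:A"}, anns, 10.0) == {"1:1:G:A"}
        assert filter_by_cadd({"1:1:G:A"}, anns, 15.0) == frozenset()

    def test_boundary_is_strict(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", cadd=10.0)])
        assert filter_by_cadd({"1:1:G:A"}, anns, 10.0) == frozenset()

    def test_absent_cadd_policy(self):
        anns = annotation_map([AnnotationRecord(key="1:1:G:A", cadd=None)])
        assert filter_by_cadd({"1:1:G:A"}, anns, 10.0) == {"1:1:G:A"}
        assert (
            filter_by_cadd({"1:1:G:A"}, anns, 10.0, missing_cadd_policy="drop")
            == frozenset()
        )

    def test_matches_strict_comparison_oracle(self):
        rng = np.random.default_rng(10)
        anns = random_annotations(rng, 500)
        result = filter_by_cadd(set(anns), anns, 20.0)
        oracle = set()
        for k, a in anns.items():
            if a.cadd is None or a.cadd > 20.0:
                oracle.add(k)
        assert result == oracle


class TestPanelExclusion:
    def test_panel_gene_excluded_absent_gene_retained(self):
        anns = annotation_map(
            [
                AnnotationRecord(key="1:1:G:A", gene="DCN"),
                AnnotationRecord(key="1:2:G:A", gene=None),
            ]
        )
        assert exclude_gene_panel(set(anns), anns, {"dcn"}) == {"1:2:G:A"}

    def test_empty_panel_is_identity(self):
        anns = random_annotations(np.random.default_rng(1), 50)
        assert exclude_gene_panel(set(anns), anns, set()) == set(anns)

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(12)
        anns = random_annotations(rng, 500)
        panel = {f"G{i:02d}" for i in range(7)}
        result = exclude_gene_panel(set(anns), anns, panel)
        oracle = {
            k
            for k, a in anns.items()
            if a.gene is None or a.gene.casefold() not in {p.casefold() for p in panel}
        }
        assert result == oracle


class TestCascade:
    def test_empty_input_all_counts_zero(self, default_cohort):
        config = wgs_filter_config(default_cohort)
        result = run_cascade([], {}, default_cohort.pedigree, config)
        assert all(s.input_count == 0 and s.surviving_count == 0 for s in result.stages)
        assert result.final_candidates == frozenset()

    def test_lone_causal_variant_survives_every_stage(self, make_cohort):
        cohort = make_cohort(77, n_background_variants=0, n_markers=0)
        config = wgs_filter_config(cohort)
        result = run_cascade(
            cohort.variants,
            annotation_map(cohort.annotations),
            cohort.pedigree,
            config,
        )
        assert result.final_candidates == {cohort.truth.causal_key}
        assert [s.surviving_count for s in result.stages] == [1] * 6

    def test_stage_chaining_and_monotone_counts(self, default_cohort):
        config = wgs_filter_config(default_cohort)
        result = run_cascade(
            default_cohort.variants,
            annotation_map(default_cohort.annotations),
            default_cohort.pedigree,
            config,
        )
        stages = result.stages
        for prev, cur in zip(stages, stages[1:]):
            assert cur.input_count == prev.surviving_count
            assert cur.surviving_count <= cur.input_count
        drops = sum(s.input_count - s.surviving_count for s in stages)
        assert drops == stages[0].input_count - stages[-1].surviving_count
        assert result.final_candidates == stages[-1].surviving_keys

    def test_final_set_equals_sequential_standalone_application(self, make_cohort):
        for seed in range(20):
            cohort = make_cohort(300 + seed)
            config = wgs_filter_config(cohort)
            anns = annotation_map(cohort.annotations)
            result = run_cascade(cohort.variants, anns, cohort.pedigree, config)

            keys = exclude_gene_panel(
                {v.key for v in cohort.variants}, anns, config.panel_genes
            )
            by_key = {v.key: v for v in cohort.variants}
            keys &= shared_heterozygous(
                [by_key[k] for k in keys], config.affected_sample_ids
            )
            keys = filter_by_maf(keys, anns, config.maf_threshold)
            keys = filter_consequence(keys, anns, config.exonic_classes)
            keys = filter_by_cadd(keys, anns, config.cadd_threshold)
            keys = segregation_filter(
                keys, {k: by_key[k].genotypes for k in keys}, cohort.pedigree
            )
            assert result.final_candidates == keys

    def test_final_set_invariant_under_annotation_stage_order(self, default_cohort):
        """MAF / consequence / CADD are pure set predicates: their
        intersection commutes."""
        anns = annotation_map(default_cohort.annotations)
        config = wgs_filter_config(default_cohort)
        by_key = {v.key: v for v in default_cohort.variants}
        start = exclude_gene_panel(set(by_key), anns, config.panel_genes)
        start &= shared_heterozygous(
            [by_key[k] for k in start], config.affected_sample_ids
        )
        stages = {
            "maf": lambda ks: filter_by_maf(ks, anns, config.maf_threshold),
            "csq": lambda ks: filter_consequence(ks, anns, config.exonic_classes),
            "cadd": lambda ks: filter_by_cadd(ks, anns, config.cadd_threshold),
        }
        import itertools

        results = set()
        for order in itertools.permutations(stages.values()):
            keys = start
            for stage in order:
                keys = stage(keys)
            results.add(keys)
        assert len(results) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(affected_sample_ids=())
        with pytest.raises(ValueError):
            FilterConfig(affected_sample_ids=("A",), maf_threshold=0.0)
        with pytest.raises(ValueError):
            FilterConfig(affected_sample_ids=("A",), missing_maf_policy="bogus")
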