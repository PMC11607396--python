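"""Phasing rules, phase-set construction, assembly, and the sharing test."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from pedvar.haplotype import (
    ASSUMED,
    CERTAIN,
    IndividualPhasing,
    MarkerGenotypes,
    Origin,
    PhaseLink,
    PhasedHaplotypes,
    assemble_haplotypes,
    assess_sharing,
    phase_rule_parent_shared,
    phase_rule_read_links,
    phase_rule_sib_only,
)
from pedvar.intervals import GenomicInterval
from pedvar.pedigree import Individual, Pedigree, Sex
from pedvar.variants import Genotype


def make_markers(genotypes: dict[str, list[int]], interval=None) -> MarkerGenotypes:
    """Genotype lists as ints (-1 missing, 0/1/2)."""
    n = len(next(iter(genotypes.values())))
    interval = interval or GenomicInterval("12", 1, 10_000)
    keys = [f"12:{(i + 1) * 10}:G:A" for i in range(n)]
    return MarkerGenotypes(
        interval=interval,
        keys=keys,
        genotypes={iid: [Genotype(g) for g in row] for iid, row in genotypes.items()},
    )


def trio_pedigree():
    return Pedigree(
        [
            Individual("F", sex=Sex.MALE, genotyped=True),
            Individual("M", sex=Sex.FEMALE, genotyped=True),
            Individual("S1", father_id="F", mother_id="M", genotyped=True),
            Individual("S2", father_id="F", mother_id="M", genotyped=True),
        ]
    )


class TestParentSharedRule:
    def test_father_and_both_sons_het_labels_alt_paternal(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1], "M": [-1], "S1": [1], "S2": [1]})
        out = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"])
        assert {(a.individual_id, a.marker, a.origin) for a in out} == {
            ("S1", 0, Origin.PATERNAL),
            ("S2", 0, Origin.PATERNAL),
        }
        # untyped mother cannot exclude maternal descent: heuristic only
        assert all(a.confidence == ASSUMED for a in out)

    def test_father_hom_ref_rule_inapplicable(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [0], "M": [-1], "S1": [1], "S2": [1]})
        assert phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"]) == []

    def test_mother_hom_ref_makes_label_certain(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1], "M": [0], "S1": [1], "S2": [1]})
        out = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"])
        assert all(a.confidence == CERTAIN for a in out)

    def test_hom_parent_label_is_certain_but_flagged(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [2], "M": [-1], "S1": [1], "S2": [1]})
        out = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"])
        assert all(a.confidence == CERTAIN and a.parent_hom for a in out)

    def test_non_parent_raises(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1], "M": [1], "S1": [1], "S2": [1]})
        with pytest.raises(ValueError):
            phase_rule_parent_shared(ped, markers, "M", ["F"])

    def test_strict_mode_withholds_heuristic_labels(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1], "M": [1], "S1": [1], "S2": [1]})
        literal = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"])
        strict = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"], mode="strict")
        assert literal and not strict


class TestSibOnlyRule:
    def test_father_lacks_allele_labels_alt_maternal(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [0], "M": [-1], "S1": [1], "S2": [1]})
        out = phase_rule_sib_only(ped, markers, "F", ["S1", "S2"])
        assert {(a.individual_id, a.origin) for a in out} == {
            ("S1", Origin.MATERNAL),
            ("S2", Origin.MATERNAL),
        }
        assert all(a.confidence == CERTAIN for a in out)

    def test_single_carrier_brother_gives_no_assignment(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [0], "M": [-1], "S1": [1], "S2": [0]})
        assert phase_rule_sib_only(ped, markers, "F", ["S1", "S2"]) == []

    def test_carrier_excluded_parent_gives_no_assignment(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1], "M": [-1], "S1": [1], "S2": [1]})
        assert phase_rule_sib_only(ped, markers, "F", ["S1", "S2"]) == []


class TestReadLinks:
    def test_no_links_yields_singletons(self):
        markers = make_markers({"X": [1, 1, 1]})
        parts = phase_rule_read_links(markers, [])
        assert parts["X"].sets() == [[0], [1], [2]]

    def test_chain_transitivity(self):
        markers = make_markers({"X": [1, 1, 1]})
        links = [
            PhaseLink("X", 0, 1, 1, 1),  # alts cis
            PhaseLink("X", 1, 2, 1, 0),  # alt(1) cis ref(2)
        ]
        parts = phase_rule_read_links(markers, links)
        assert parts["X"].sets() == [[0, 1, 2]]
        comp = parts["X"].component
        rel = lambda a, b: comp[a][1] ^ comp[b][1]
        assert rel(0, 1) == 0 and rel(1, 2) == 1 and rel(0, 2) == 1

    def test_contradictory_link_marks_both_markers_conflict(self):
        markers = make_markers({"X": [1, 1]})
        links = [PhaseLink("X", 0, 1, 1, 1), PhaseLink("X", 0, 1, 1, 0)]
        parts = phase_rule_read_links(markers, links)
        assert parts["X"].conflicted == {0, 1}
        assert parts["X"].events

    def test_link_on_non_het_marker_is_ignored(self):
        markers = make_markers({"X": [1, 0]})
        parts = phase_rule_read_links(markers, [PhaseLink("X", 0, 1, 1, 0)])
        assert parts["X"].sets() == [[0]]
        assert parts["X"].conflicted == set()

    def test_random_links_match_graph_parity_oracle(self):
        """Union-find with parity versus a networkx BFS parity oracle on
        consistent random link sets over <= 8 markers."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            hap = rng.integers(0, 2, size=n)  # one true haplotype
            markers = make_markers({"X": [1] * n})
            links = []
            graph = nx.Graph()
            graph.add_nodes_from(range(n))
            for _ in range(int(rng.integers(0, 2 * n))):
                a, b = rng.choice(n, size=2, replace=False)
                links.append(
                    PhaseLink("X", int(a), int(b), int(hap[a]), int(hap[b]))
                )
                graph.add_edge(int(a), int(b))
            parts = phase_rule_read_links(markers, links)
            comp = parts["X"].component
            assert parts["X"].conflicted == set()
            oracle_sets = sorted(
                [sorted(c) for c in nx.connected_components(graph)], key=min
            )
            assert parts["X"].sets() == oracle_sets
            # parity between joined markers must mirror the true haplotype
            for a, b in itertools.combinations(range(n), 2):
                if comp[a][0] == comp[b][0] and nx.has_path(graph, a, b):
                    assert (comp[a][1] ^ comp[b][1]) == int(hap[a] ^ hap[b])


class TestAssembly:
    def test_labels_read_off_directly_without_links(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1, 0], "M": [0, 2], "S1": [1, 1], "S2": [1, 1]})
        assignments = phase_rule_parent_shared(
            ped, markers, "F", ["S1", "S2"]
        ) + phase_rule_sib_only(ped, markers, "F", ["S1", "S2"])
        haps = assemble_haplotypes(markers, assignments, None, ped)
        s1 = haps.phasing["S1"]
        assert (s1.hap1[0], s1.hap2[0]) == ("1", "0")  # paternal alt (certain)
        assert (s1.hap1[1], s1.hap2[1]) == ("0", "1")  # maternal alt (sib-only)
        assert s1.origin[0] is Origin.PATERNAL
        assert s1.origin[1] is Origin.MATERNAL

    def test_one_labelled_marker_phases_a_three_marker_set(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1, 1, 1], "M": [0, -1, -1], "S1": [1, 1, 1], "S2": [1, 1, 1]})
        # certain label only at marker 0 (mother hom-ref); links chain 0-1-2
        assignments = phase_rule_parent_shared(ped, markers, "F", ["S1", "S2"])
        links = [
            PhaseLink("S1", 0, 1, 1, 0),
            PhaseLink("S1", 1, 2, 1, 1),
        ]
        phase_sets = phase_rule_read_links(markers, links)
        haps = assemble_haplotypes(markers, assignments, phase_sets, ped)
        s1 = haps.phasing["S1"]
        assert s1.hap1 == "100"  # alt paternal at 0; alt(1) trans; alt(2) cis with alt(1)
        assert s1.hap2 == "011"
        assert [c for c in s1.confidence] == [CERTAIN] * 3

    def test_contradictory_certain_anchors_demote_whole_set(self):
        ped = trio_pedigree()
        markers = make_markers({"F": [1, 0], "M": [0, 2], "S1": [1, 1], "S2": [1, 1]})
        # marker 0: alt paternal (mother hom-ref); marker 1: alt maternal
        # (father hom-ref).  A cis link between the two alts contradicts that.
        assignments = phase_rule_parent_shared(
            ped, markers, "F", ["S1", "S2"]
        ) + phase_rule_sib_only(ped, markers, "F", ["S1", "S2"])
        phase_sets = phase_rule_read_links(markers, [PhaseLink("S1", 0, 1, 1, 1)])
        haps = assemble_haplotypes(markers, assignments, phase_sets, ped)
        s1 = haps.phasing["S1"]
        assert s1.origin[0] is Origin.CONFLICT and s1.origin[1] is Origin.CONFLICT
        assert s1.hap1 == "??"
        # S2 is unaffected by S1's conflict
        assert haps.phasing["S2"].hap1[0] == "1"

    def test_unanchored_individual_gets_relative_phase_for_largest_set(self):
        markers = make_markers({"Z": [1, 1, 1, 1]})
        links = [PhaseLink("Z", 0, 1, 1, 1), PhaseLink("Z", 1, 2, 1, 0)]
        haps = assemble_haplotypes(
            markers, [], phase_rule_read_links(markers, links), None
        )
        z = haps.phasing["Z"]
        assert z.hap1[:3] in ("110", "001") and z.hap2[:3] in ("001", "110")
        assert z.hap1[3] == "?"  # singleton set outside the largest set
        assert z.confidence[:3] == ["relative"] * 3

    def test_phasing_never_invents_alleles(self, make_cohort):
        """At every phased marker the two haplotype alleles are a permutation
        of the genotype's alleles."""
        from pedvar.pipeline import pedigree_phase_assignments

        cohort = make_cohort(88, n_background_variants=0)
        markers = cohort.marker_genotypes
        assignments = pedigree_phase_assignments(cohort.pedigree, markers)
        phase_sets = phase_rule_read_links(markers, cohort.links)
        haps = assemble_haplotypes(markers, assignments, phase_sets, cohort.pedigree)
        expected = {
            Genotype.HOM_REF: {"0"},
            Genotype.HET: {"0", "1"},
            Genotype.HOM_ALT: {"1"},
        }
        for iid, ph in haps.phasing.items():
            for m in range(markers.n_markers):
                alleles = {ph.hap1[m], ph.hap2[m]}
                if "?" in alleles:
                    continue
                assert alleles == expected[markers.genotype(iid, m)]


def make_phased(strings: dict[str, tuple[str, str]]) -> PhasedHaplotypes:
    n = len(next(iter(strings.values()))[0])
    markers = make_markers({iid: [1] * n for iid in strings})
    phasing = {
        iid: IndividualPhasing(
            hap1=h1,
            hap2=h2,
            origin=[Origin.UNPHASED] * n,
            confidence=[None] * n,
        )
        for iid, (h1, h2) in strings.items()
    }
    return PhasedHaplotypes(markers=markers, phasing=phasing, phase_sets={})


def sharing_oracle(strings, ids, min_informative):
    """Independent exhaustive enumeration of all haplotype assignments."""
    best_ok_informative = -1
    for choice in itertools.product([0, 1], repeat=len(ids)):
        chosen = [strings[iid][c] for iid, c in zip(ids, choice)]
        informative = conflicts = 0
        for col in zip(*chosen):
            if "?" in col:
                continue
            informative += 1
            if len(set(col)) > 1:
                conflicts += 1
        if conflicts == 0:
            best_ok_informative = max(best_ok_informative, informative)
    return best_ok_informative >= min_informative


class TestSharing:
    def test_identical_known_haplotypes_share(self):
        haps = make_phased({"A": ("0110", "1001"), "B": ("0110", "0000")})
        report = assess_sharing(haps, ["A", "B"], min_informative=3)
        assert report.shared and report.witness == "0110"
        assert report.informative_count == 4

    def test_all_pairings_differ_means_not_shared(self):
        haps = make_phased({"A": ("0000", "1111"), "B": ("0011", "1100")})
        report = assess_sharing(haps, ["A", "B"], min_informative=2)
        assert not report.shared
        assert report.conflicts

    def test_too_few_informative_markers_flags_invalid(self):
        haps = make_phased({"A": ("01??", "10??"), "B": ("01??", "0?1?")})
        report = assess_sharing(haps, ["A", "B"], min_informative=3)
        assert not report.valid and not report.shared

    def test_fewer_than_two_individuals_is_an_error(self):
        haps = make_phased({"A": ("01", "10")})
        with pytest.raises(ValueError):
            assess_sharing(haps, ["A"])

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(150):
            n_ind = int(rng.integers(2, 5))
            n_mark = int(rng.integers(1, 12))
            ids = [f"I{i}" for i in range(n_ind)]
            strings = {}
            for iid in ids:
                h1 = "".join(str(rng.choice(["0", "1", "?"], p=[0.4, 0.4, 0.2])) for _ in range(n_mark))
                h2 = "".join(str(rng.choice(["0", "1", "?"], p=[0.4, 0.4, 0.2])) for _ in range(n_mark))
                strings[iid] = (h1, h2)
            haps = make_phased(strings)
            report = assess_sharing(haps, ids, min_informative=2)
            assert report.shared == sharing_oracle(strings, ids, 2)

    def test_adding_markers_never_flips_false_to_true(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            n_mark = int(rng.integers(4, 10))
            ids = ["A", "B", "C"]
            strings = {
                iid: (
                    "".join(str(rng.integers(2)) for _ in range(n_mark)),
                    "".join(str(rng.integers(2)) for _ in range(n_mark)),
                )
                for iid in ids
            }
            prefix = {iid: (h1[:-1], h2[:-1]) for iid, (h1, h2) in strings.items()}
            short = assess_sharing(make_phased(prefix), ids, min_informative=2)
            long = assess_sharing(make_phased(strings), ids, min_informative=2)
            if short.valid and not short.shared:
                assert not long.shared
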