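"""Arrangement boundary, subset labelling, variant dedup and family tallies."""

import pytest

from zfsurvey.errors import ZfSurveyError
from zfsurvey.sequence_io import GeneLocus, GeneModel
from zfsurvey.subset_classify import (
    assign_subset,
    build_architecture,
    classify_arrangement,
    count_introns,
    dedupe_variants,
    percent,
    summarize_family,
)
from zfsurvey.synthetic_data import ProteinSpec, make_protein
from zfsurvey.zf_scan import scan_domains


def protein_with(types, gaps, pid="p.1", seed=0):
    record, truth, _ = make_protein(
        ProteinSpec(protein_id=pid, domain_types=tuple(types), gaps=tuple(gaps),
                    seed=seed)
    )
    return build_architecture(scan_domains(record))


class TestArchitecture:
    def test_gap_arithmetic(self):
        arch = protein_with(["Q", "Q"], [11])
        assert arch.gaps == (11,)

    def test_single_domain_no_gaps(self):
        arch = protein_with(["Q"], [])
        assert arch.gaps == ()

    def test_overlap_rejected(self):
        arch = protein_with(["Q"], [])
        with pytest.raises(ZfSurveyError):
            build_architecture(list(arch.domains) * 2)


class TestArrangementBoundary:
    def test_gap_11_is_tandem(self):
        arrangement, runs = classify_arrangement(protein_with(["Q", "Q"], [11]))
        assert arrangement == "tandem" and runs == [[0, 1]]

    def test_gap_12_is_isolated(self):
        arrangement, runs = classify_arrangement(protein_with(["Q", "Q"], [12]))
        assert arrangement == "isolated" and runs == [[0], [1]]

    def test_flipping_one_gap_changes_only_the_arrangement(self):
        a11 = assign_subset(protein_with(["M1", "M3"], [11]))
        a12 = assign_subset(protein_with(["M1", "M3"], [12]))
        assert a11.arrangement == "tandem" and a12.arrangement == "isolated"
        assert a11.n_domains == a12.n_domains == 2
        assert a11.type_string == a12.type_string == "M1;M3"

    def test_two_arrays_from_mixed_gaps(self):
        arrangement, runs = classify_arrangement(
            protein_with(["M1", "M2", "Z1", "Z2"], [5, 40, 5])
        )
        assert arrangement == "tandem"
        assert [len(r) for r in runs] == [2, 2]


class TestSubsets:
    @pytest.mark.parametrize(
        "types,gaps,subset",
        [
            (["Q"], [], "Ta-1i-Q-SF"),
            (["M3"], [], "Ta-1i-M-SF"),
            (["Z2"], [], "Ta-1i-Z-SF"),
            (["D"], [], "Ta-1i-D-SF"),
            (["Q", "Q"], [20], "Ta-2i-Q-SF"),
            (["M1", "M4"], [20], "Ta-2i-M-SF"),
            (["Q", "M2"], [20], "Ta-2i-Mix-SF"),
            (["M4", "Z1"], [40], "Ta-2i-Mix-SF"),
            (["D", "D"], [20], "Ta-2i-Mix-SF"),
            (["Q", "M1", "Z2"], [20, 20], "Ta-3i-SF"),
            (["Q", "M1", "Z1", "D"], [15, 15, 15], "Ta-4i-SF"),
            (["Q", "Q"], [5], "Ta-t1-SF"),
            (["M1", "M2", "Z1"], [5, 40], "Ta-t2-SF"),
            (["M1", "M2", "Z1", "Z2"], [5, 40, 5], "Ta-t2-SF"),
        ],
    )
    def test_subset_labels(self, types, gaps, subset):
        assignment = assign_subset(protein_with(types, gaps))
        assert assignment.subset == subset

    def test_five_or_more_dispersed_fingers_bin_into_4i(self):
        assignment = assign_subset(
            protein_with(["Q", "M1", "Z1", "Z2", "M2"], [15] * 4)
        )
        assert assignment.subset == "Ta-4i-SF" and assignment.n_domains == 5

    def test_subset_invariant_under_m_subclass_refinement(self):
        a = assign_subset(protein_with(["M1", "M1"], [20]))
        b = assign_subset(protein_with(["M3", "M4"], [20]))
        assert a.subset == b.subset == "Ta-2i-M-SF"

    def test_type_string_matches_detected_order(self):
        assignment = assign_subset(protein_with(["M3", "M4", "Z1"], [20, 20]))
        assert assignment.type_string == "M3;M4;Z1"


class TestVariants:
    def test_divergent_variant_series_flagged(self):
        full = assign_subset(protein_with(["M3", "M4", "M4", "M4", "Z1"],
                                          [15] * 4, pid="g.1"))
        reduced = assign_subset(protein_with(["M4", "Z1"], [40], pid="g.11"))
        gene_of = {"g.1": ("g", 1), "g.11": ("g", 11)}
        reps, report = dedupe_variants([full, reduced], gene_of)
        assert reps["g"].protein_id == "g.1"
        assert report.loc[0, "architecture_divergent"]

    def test_identical_variants_not_flagged(self):
        a = assign_subset(protein_with(["Q"], [], pid="g.1", seed=1))
        b = assign_subset(protein_with(["Q"], [], pid="g.2", seed=2))
        reps, report = dedupe_variants([a, b], {"g.1": ("g", 1), "g.2": ("g", 2)})
        assert reps["g"].protein_id == "g.1"
        assert not report.loc[0, "architecture_divergent"]

    def test_single_variant_gene_is_its_own_representative(self):
        a = assign_subset(protein_with(["Q"], [], pid="solo.1"))
        reps, _ = dedupe_variants([a], {"solo.1": ("solo", 1)})
        assert reps["solo"] is a


class TestIntronsAndSummary:
    @pytest.mark.parametrize("n_exons,expected", [(1, 0), (3, 2), (11, 10)])
    def test_intron_counts(self, n_exons, expected):
        exons = tuple((i * 200, i * 200 + 100) for i in range(n_exons))
        assert count_introns(GeneModel("g", "g.1", exons)) == expected

    def test_percent_half_up(self):
        assert percent(214, 457) == "46.8"
        assert percent(243, 457) == "53.2"
        assert percent(85, 204, 2) == "41.67"
        assert percent(115, 204, 2) == "56.37"
        assert percent(0, 457) == "0.0"

    def test_summary_tallies_and_percentages(self):
        assignments = [
            assign_subset(protein_with(["Q", "Q"], [5], pid=f"Traes_5BL_AB{i}.1"))
            for i in range(3)
        ] + [
            assign_subset(protein_with(["Q"], [], pid=f"Traes_2AS_CD{i}.1"))
            for i in range(2)
        ]
        loci = {f"Traes_5BL_AB{i}": GeneLocus(5, "B", "L", f"AB{i}") for i in range(3)}
        loci.update({f"Traes_2AS_CD{i}": GeneLocus(2, "A", "S", f"CD{i}")
                     for i in range(2)})
        models = [GeneModel(g, f"{g}.1", ((0, 100),)) for g in loci]
        summary = summarize_family(assignments, loci, models)
        assert summary.tandem_count == 3 and summary.isolated_count == 2
        assert summary.tandem_pct == "60.0" and summary.isolated_pct == "40.0"
        assert summary.chromosome_counts[5] == 3
        assert summary.subgenome_counts == {"A": 2, "B": 3, "D": 0}
        assert summary.subgenome_pct["B"] == "60.00"
        assert summary.intronless_genes == 5
        assert float(summary.tandem_pct) + float(summary.isolated_pct) == 100.0

    def test_unparsed_loci_are_skipped_with_count(self):
        assignments = [assign_subset(protein_with(["Q"], [], pid="foreign.1"))]
        summary = summarize_family(assignments, {"foreign": None}, None)
        assert summary.unparsed_locus_genes == 1
        assert sum(summary.chromosome_counts.values()) == 0
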