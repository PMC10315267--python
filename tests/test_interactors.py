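import numpy as np
import pandas as pd
import pytest

from zeitprot.interactors import (
    EvidenceThresholds,
    apply_evidence_filter,
    bait_max_spectra,
    call_all_interactors,
    call_interactors,
    classify_timepoints,
    cycling_fraction,
    group_by_parsimony,
    subtract_controls,
)
from zeitprot.io_tables import SpectralCountMatrix
from zeitprot.synthetic import ApmsSimConfig, simulate_apms


def make_matrix(counts: dict[str, list[int]], run_ids, unique=None):
    loci = list(counts)
    runs = {}
    for rid in run_ids:
        bait, zt, rep = rid.rsplit("_", 2)
        runs[rid] = {
            "bait": bait,
            "timepoint_zt": float(zt.removeprefix("ZT")),
            "replicate": int(rep),
            "is_control": bait == "none",
        }
    run_df = pd.DataFrame.from_dict(runs, orient="index")
    proteins = pd.DataFrame(
        {"name": loci, "mw_kda": 50.0, "cycling": [None] * len(loci)},
        index=pd.Index(loci, name="agi_locus"),
    )
    total = pd.DataFrame([counts[l] for l in loci], index=proteins.index, columns=run_ids)
    up = None
    if unique is not None:
        up = pd.DataFrame([unique[l] for l in loci], index=proteins.index, columns=run_ids)
    return SpectralCountMatrix(proteins=proteins, runs=run_df, total_spectra=total, unique_peptides=up)


RUNS_2REP = ["B_ZT5_1", "B_ZT5_2"]


class TestEvidenceFilter:
    @pytest.mark.parametrize(
        "unique,kept",
        [((2, 0), True), ((1, 0), False), ((1, 1), True), ((0, 0), False), ((3, 3), True)],
    )
    def test_two_peptide_rule_with_single_replicate_exception(self, unique, kept):
        m = make_matrix({"AT1G01010": [5, 5]}, RUNS_2REP, unique={"AT1G01010": list(unique)})
        out = apply_evidence_filter(m)
        assert ("AT1G01010" in out.proteins.index) is kept

    def test_without_evidence_matrix_is_a_noop(self, table1):
        out = apply_evidence_filter(table1)
        assert list(out.proteins.index) == list(table1.proteins.index)

    def test_monotone_in_min_unique_peptides(self, rng):
        m, _ = simulate_apms(ApmsSimConfig(seed=5))
        kept = [
            set(
                apply_evidence_filter(
                    m, EvidenceThresholds(min_unique_peptides=k)
                ).proteins.index
            )
            for k in (1, 2, 3, 4)
        ]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_peptide_table_thresholds(self):
        m = make_matrix({"AT1G01010": [5, 5], "AT1G01020": [4, 4]}, RUNS_2REP)
        peptides = pd.DataFrame(
            [
                # two confident peptides for the first locus in replicate 1
                ("B_ZT5_1", "PEPTIDEA", "AT1G01010", 0.99, 0.001),
                ("B_ZT5_1", "PEPTIDEB", "AT1G01010", 0.99, 0.001),
                # the second locus has peptides failing probability or FDR
                ("B_ZT5_1", "PEPTIDEC", "AT1G01020", 0.50, 0.001),
                ("B_ZT5_2", "PEPTIDED", "AT1G01020", 0.99, 0.200),
            ],
            columns=["run_id", "peptide", "agi_locus", "probability", "fdr"],
        )
        out = apply_evidence_filter(m, peptide_table=peptides)
        assert set(out.proteins.index) == {"AT1G01010"}

    def test_peptide_table_unknown_run_is_an_error(self):
        m = make_matrix({"AT1G01010": [5, 5]}, RUNS_2REP)
        peptides = pd.DataFrame(
            [("nope_1", "PEPTIDEA", "AT1G01010", 0.99, 0.001)],
            columns=["run_id", "peptide", "agi_locus", "probability", "fdr"],
        )
        with pytest.raises(ValueError, match="unknown runs"):
            apply_evidence_filter(m, peptide_table=peptides)


class TestControlSubtraction:
    RUNS = ["B_ZT5_1", "B_ZT5_2", "none_ZT5_1", "none_ZT5_2"]

    def test_any_control_spectrum_excludes(self):
        m = make_matrix(
            {"AT1G01010": [10, 12, 1, 0], "AT1G01020": [10, 12, 0, 0]}, self.RUNS
        )
        out = subtract_controls(m)
        assert set(out.proteins.index) == {"AT1G01020"}
        assert not out.runs["is_control"].any()

    def test_all_proteins_in_controls_gives_empty_list(self):
        m = make_matrix({"AT1G01010": [10, 0, 1, 0], "AT1G01020": [0, 3, 0, 2]}, self.RUNS)
        out = subtract_controls(m)
        assert out.n_proteins == 0 and out.n_runs == 2

    def test_idempotent(self):
        m = make_matrix(
            {"AT1G01010": [10, 12, 1, 0], "AT1G01020": [10, 12, 0, 0]}, self.RUNS
        )
        once = subtract_controls(m)
        twice = subtract_controls(once)
        pd.testing.assert_frame_equal(once.total_spectra, twice.total_spectra)

    def test_no_controls_is_a_noop(self, table1):
        out = subtract_controls(table1)
        assert list(out.proteins.index) == list(table1.proteins.index)


class TestParsimonyGrouping:
    def test_identical_sets_merge(self):
        clusters = group_by_parsimony({"p1": {"A", "B"}, "p2": {"A", "B"}})
        assert clusters == [[("A", "B")]]

    def test_strict_subset_absorbed(self):
        # A has peptides p1-p3, B only p1: one group explains both
        clusters = group_by_parsimony({"p1": {"A", "B"}, "p2": {"A"}, "p3": {"A"}})
        assert clusters == [[("A", "B")]]

    def test_partial_overlap_links_without_merging(self):
        # A: {p1, p2}, B: {p2, p3}: same cluster, two groups
        clusters = group_by_parsimony({"p1": {"A"}, "p2": {"A", "B"}, "p3": {"B"}})
        assert clusters == [[("A",), ("B",)]]

    def test_disjoint_proteins_make_separate_clusters(self):
        clusters = group_by_parsimony({"p1": {"A"}, "p2": {"B"}})
        assert clusters == [[("A",)], [("B",)]]

    def test_covers_each_protein_exactly_once(self, rng):
        # randomized instances against the covering invariant
        for _ in range(20):
            n_prot, n_pep = rng.integers(2, 7), rng.integers(2, 9)
            evidence = {}
            for j in range(n_pep):
                loci = {f"P{i}" for i in rng.choice(n_prot, size=rng.integers(1, n_prot + 1), replace=False)}
                evidence[f"pep{j}"] = loci
            clusters = group_by_parsimony(evidence)
            seen = [l for cl in clusters for grp in cl for l in grp]
            expected = {l for loci in evidence.values() for l in loci}
            assert sorted(seen) == sorted(expected)


class TestCallsAndClassification:
    def test_table2_rve8_zt9_includes_cor27_and_cop1(self, table2):
        call = call_interactors(table2, "RVE8-HFC", 9)
        assert call.per_replicate_counts["AT5G42900"] == [4, 7]  # COR27
        assert call.per_replicate_counts["AT2G32950"] == [3, 4]  # COP1

    def test_table1_rve8_zt5_excludes_cor27(self, table1):
        call = call_interactors(table1, "RVE8-HFC", 5)
        assert "AT5G42900" not in call.proteins

    def test_all_zero_group_gives_empty_set(self):
        m = make_matrix({"AT1G01010": [0, 0]}, RUNS_2REP)
        assert call_interactors(m, "B", 5).proteins == set()

    def test_unknown_group_lists_available(self, table1):
        with pytest.raises(KeyError, match="LNK1-HFC"):
            call_interactors(table1, "RVE8-HFC", 13)

    def test_ordering_by_descending_max_spectra(self, table1):
        call = call_interactors(table1, "LNK2-HFC", 5)
        maxima = [max(call.per_replicate_counts[l]) for l in call.ordered_loci()]
        assert maxima == sorted(maxima, reverse=True)

    def test_pooled_late_only_count_is_ten(self, pooled_classification):
        # brute-force locus set difference of the two curated tables
        assert pooled_classification.counts["late_only"] == 10

    def test_partition_sizes_sum_to_union(self, pooled_classification, table1, table2):
        union = set(table1.proteins.index) | set(table2.proteins.index)
        assert sum(pooled_classification.counts.values()) == len(union)

    def test_evening_specific_and_shared_examples(self, pooled_classification):
        labels = pooled_classification.labels
        for locus in ("AT5G42900", "AT4G33980", "AT2G32950", "AT2G46340"):
            assert labels[locus] == "late_only"  # COR27, COR28, COP1, SPA1
        for locus in ("AT3G55580", "AT3G53830"):
            assert labels[locus] == "shared"  # TCF1, RCC1L

    def test_per_bait_partition_present(self, pooled_classification):
        assert set(pooled_classification.per_bait) == {"LNK1-HFC", "LNK2-HFC", "RVE8-HFC"}
        # COR28 coprecipitated with all three baits at ZT9 only
        for bait in pooled_classification.per_bait:
            assert pooled_classification.per_bait[bait]["AT4G33980"] == "late_only"

    def test_equal_timepoints_is_an_error(self, table1):
        calls = call_all_interactors(table1)
        with pytest.raises(ValueError, match="differ"):
            classify_timepoints(calls, calls)


class TestBaitMaxSpectra:
    def test_lnk1_zt9_maximum(self, table2):
        assert bait_max_spectra(table2, "LNK1-HFC", 9, "AT5G64170") == 621

    def test_lnk2_zt5_maximum(self, table1):
        assert bait_max_spectra(table1, "LNK2-HFC", 5, "AT3G54500") == 497

    def test_zero_counts_give_zero(self, table1):
        # RVE5 has no spectra in the RVE8 purification at ZT5
        assert bait_max_spectra(table1, "RVE8-HFC", 5, "AT4G01280") == 0

    def test_absent_locus_is_an_error(self, table1):
        with pytest.raises(KeyError, match="AT9"):
            bait_max_spectra(table1, "RVE8-HFC", 5, "AT9G99999")


class TestCyclingFraction:
    def test_simple_arithmetic(self):
        n_cyc, n_ann, frac = cycling_fraction(
            {"A", "B", "C", "D"}, {"A": True, "B": True, "C": True, "D": False}
        )
        assert (n_cyc, n_ann, frac) == (3, 4, 0.75)

    def test_empty_set(self):
        assert cycling_fraction(set(), {"A": True}) == (0, 0, None)

    def test_unannotated_loci_excluded_from_denominator(self):
        n_cyc, n_ann, frac = cycling_fraction({"A", "B", "X"}, {"A": True, "B": False})
        assert (n_cyc, n_ann, frac) == (1, 2, 0.5)

    def test_table3_fraction_matches_footnote_flags(self, table3):
        n_cyc, n_ann, frac = cycling_fraction(set(table3.proteins.index), table3.cycling_map())
        assert n_ann == 21
        assert frac == pytest.approx(n_cyc / 21)
        assert n_cyc == 12  # count of cycling-flagged rows in the curated table
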