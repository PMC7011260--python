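"""Record model, TSV round-trips, fixtures, dedup and significance filter."""

import hashlib

import pytest

from metacred import assoc_io
from metacred.assoc_io import (
    InputSchemaError,
    MetaAnalysisRecord,
    RecordCatalog,
    RecordValidationError,
    deduplicate,
    filter_significant,
    load_fixture,
    read_catalog,
    write_catalog,
)

TABLE2_PRINTED_SHA256 = (
    "c73074cc6b461868bd402634ac209a8ea7b3ef3df0d49b4be692928a4d2250b9")


class TestRecordInvariants:
    def test_estimate_must_lie_inside_ci(self, make_record):
        with pytest.raises(RecordValidationError):
            make_record(odds_ratio=1.05, ci_lower=1.10, ci_upper=1.42)

    @pytest.mark.parametrize("field,value", [
        ("odds_ratio", -1.0), ("ci_lower", 0.0), ("maf", 1.5),
        ("p_value", 0.0), ("study_type", "cohort"), ("subtype", "mixed"),
        ("n_cases", -5),
    ])
    def test_out_of_range_fields_rejected(self, make_record, field, value):
        with pytest.raises(RecordValidationError):
            make_record(**{field: value})

    def test_protective_record_is_valid(self, make_record):
        rec = make_record(odds_ratio=0.8, ci_lower=0.7, ci_upper=0.92)
        assert rec.ci_excludes_null()


class TestReadWrite:
    def test_well_formed_tsv_round_trips_bit_identically(self, tmp_path,
                                                         make_record):
        catalog = RecordCatalog(records=(
            make_record(variant="rs1", maf=0.31,
                        printed_stats={"fprp_1.5_0.05": 0.04}),
            make_record(variant="rs2", p_value=None, odds_ratio=0.8,
                        ci_lower=0.7, ci_upper=0.92),
            make_record(variant="rs3", study_type="gwas", p_value=3.1e-9,
                        venice_grades="A + B + A"),
        ), provenance="synthetic")
        path = write_catalog(catalog, tmp_path / "cat.tsv")
        back = read_catalog(path)
        assert tuple(back) == tuple(catalog)

    def test_three_row_tsv_parses_to_three_records(self, tmp_path):
        path = tmp_path / "cat.tsv"
        header = ("author\tyear\tgene\tvariant\tcomparison\todds_ratio\t"
                  "ci_lower\tci_upper\tp_value\tstudy_type")
        rows = [
            "A\t2019\tG1\trs1\tT vs. C\t1.2\t1.1\t1.31\t0.01\tobservational",
            "B\t2018\tG2\trs2\tA vs. G\t0.8\t0.7\t0.91\t0.02\tobservational",
            "C\t2016\tG3\trs3\tC vs. T\t1.1\t1.05\t1.15\t1e-9\tgwas",
        ]
        path.write_text("\n".join([header] + rows) + "\n")
        catalog = read_catalog(path)
        assert len(catalog) == 3
        assert [r.variant for r in catalog] == ["rs1", "rs2", "rs3"]

    def test_missing_tokens_become_absent_values(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "author\tyear\tgene\tvariant\tcomparison\todds_ratio\t"
            "ci_lower\tci_upper\tp_value\tmaf\tstudy_type\tfprp_1.2_0.05\n"
            "A\t2019\tG1\trs1\tT vs. C\t1.2\t1.1\t1.31\tNA\t–\t"
            "observational\t-\n")
        rec = read_catalog(path)[0]
        assert rec.p_value is None
        assert rec.maf is None
        assert "fprp_1.2_0.05" not in rec.printed_stats

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("author\tyear\tgene\tvariant\tcomparison\n")
        with pytest.raises(InputSchemaError, match="odds_ratio"):
            read_catalog(path)

    def test_invalid_row_error_carries_row_index(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "author\tyear\tgene\tvariant\tcomparison\todds_ratio\t"
            "ci_lower\tci_upper\tstudy_type\n"
            "A\t2019\tG1\trs1\tT vs. C\t1.2\t1.1\t1.31\tobservational\n"
            "B\t2019\tG1\trs2\tT vs. C\t1.2\t1.25\t1.31\tobservational\n")
        with pytest.raises(RecordValidationError, match="row 1"):
            read_catalog(path)

    def test_scientific_notation_p_values_parse(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "author\tyear\tgene\tvariant\tcomparison\todds_ratio\t"
            "ci_lower\tci_upper\tp_value\tstudy_type\n"
            "A\t2016\tG\trs1\tC vs. T\t0.90\t0.89\t0.91\t5.6E-49\tgwas\n")
        assert read_catalog(path)[0].p_value == 5.6e-49


class TestFixtures:
    @pytest.mark.parametrize("name,n_rows,n_variants", [
        ("table1", 19, 8),
        ("table2", 47, 47),
        ("table3", 21, 8),
        ("table4", 20, 9),
        ("table5", 12, 10),
        ("table6", 36, 36),
    ])
    def test_fixture_shapes(self, name, n_rows, n_variants):
        catalog = load_fixture(name)
        assert len(catalog) == n_rows
        assert len(catalog.variants) == n_variants

    def test_unknown_fixture_name_raises(self):
        with pytest.raises(KeyError, match="table99"):
            load_fixture("table99")

    def test_table1_covers_five_genes(self, table1):
        assert len({r.gene for r in table1}) == 5

    def test_table2_covers_forty_genes(self, table2):
        # two variants share a gene printed with differing capitalisation
        assert len({r.gene.lower() for r in table2}) == 40

    def test_table2_printed_stats_integrity(self, table2):
        """Published FPRP/BFDP cells are frozen against a checksum; the
        nine rows whose FPRP was not computable carry no FPRP entries."""
        parts = []
        n_no_fprp = 0
        for rec in table2:
            if not any(k.startswith("fprp_") for k in rec.printed_stats):
                n_no_fprp += 1
            for key in sorted(rec.printed_stats):
                parts.append(f"{rec.gene}/{rec.variant}|{rec.comparison}|"
                             f"{key}={rec.printed_stats[key]!r}")
        blob = "\n".join(parts).encode()
        assert n_no_fprp == 9
        assert len(parts) == 246
        assert hashlib.sha256(blob).hexdigest() == TABLE2_PRINTED_SHA256

    def test_table6_records_all_carry_maf(self, table6):
        assert all(r.maf is not None for r in table6)
        assert all("par_percent" in r.printed_stats for r in table6)


class TestDeduplicate:
    def test_more_recent_meta_analysis_wins(self, make_record):
        old = make_record(year=2015, variant="rs1801133", comparison="T vs. C")
        new = make_record(year=2019, variant="rs1801133", comparison="T vs. C")
        out = deduplicate(RecordCatalog(records=(old, new)))
        assert len(out) == 1 and out[0].year == 2019

    def test_year_tie_broken_by_sample_size(self, make_record):
        small = make_record(n_cases=400, n_controls=600)
        large = make_record(n_cases=800, n_controls=1200)
        out = deduplicate(RecordCatalog(records=(small, large)))
        assert len(out) == 1 and out[0].sample_size == 2000

    def test_full_tie_keeps_first_seen_with_warning(self, make_record):
        a = make_record(author="First")
        b = make_record(author="Second")
        with pytest.warns(UserWarning, match="duplicate"):
            out = deduplicate(RecordCatalog(records=(a, b)))
        assert len(out) == 1 and out[0].author == "First"

    def test_single_record_unchanged_and_idempotent(self, make_record, table1):
        single = RecordCatalog(records=(make_record(),))
        assert tuple(deduplicate(single)) == tuple(single)
        once = deduplicate(table1)
        assert tuple(deduplicate(once)) == tuple(once)

    def test_distinct_subtypes_coexist(self, make_record):
        overall = make_record(subtype="overall")
        aura = make_record(subtype="MA")
        assert len(deduplicate(RecordCatalog(records=(overall, aura)))) == 2


class TestFilterSignificant:
    def test_gwas_threshold_is_strict(self, make_record):
        kept = make_record(study_type="gwas", p_value=3e-8)
        dropped = make_record(study_type="gwas", p_value=1e-7, variant="rs2")
        out = filter_significant(RecordCatalog(records=(kept, dropped)))
        assert [r.variant for r in out] == ["rs1"]

    def test_ci_including_one_is_dropped_despite_small_p(self, make_record):
        rec = make_record(odds_ratio=1.10, ci_lower=0.98, ci_upper=1.23,
                          p_value=0.04)
        assert len(filter_significant(RecordCatalog(records=(rec,)))) == 0

    def test_boundary_ci_bound_counts_as_excluding(self, make_record):
        # Printed bounds are rounded: "1.03 (1.00-1.06)" is significant.
        rec = make_record(odds_ratio=1.03, ci_lower=1.00, ci_upper=1.06,
                          study_type="gwas", p_value=2.5e-9)
        assert len(filter_significant(RecordCatalog(records=(rec,)))) == 1

    def test_missing_p_reconstructed_from_ci(self, make_record):
        strong = make_record(p_value=None)           # z ~ 3.9, p ~ 1e-4
        weak = make_record(p_value=None, odds_ratio=1.21, ci_lower=1.001,
                           ci_upper=1.46, variant="rs2")  # p ~ 0.049
        out = filter_significant(RecordCatalog(records=(strong, weak)))
        assert {r.variant for r in out} == {"rs1", "rs2"}

    def test_output_is_subset_and_idempotent(self, table1):
        once = filter_significant(table1)
        assert set(r.dedup_key for r in once) <= set(
            r.dedup_key for r in table1)
        assert tuple(filter_significant(once)) == tuple(once)
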