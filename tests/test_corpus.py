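"""Readers/writers for articles, curated tables, dictionaries, lexicons."""

import gzip

import pytest

from weakext.corpus import (Article, dump_dictionary, load_dictionary,
                            load_lexicon, normalize_text, read_article,
                            read_curated_table, write_article,
                            write_curated_table)
from weakext.errors import DictionaryConflictError, ParseError, SchemaError


def test_normalize_text_collapses_whitespace_and_typography():
    assert normalize_text("a\t b\n  c") == "a b c"
    assert normalize_text("“smart” — quotes’") == '"smart" - quotes\''


class TestArticleIO:
    def test_xml_roundtrip_preserves_fields_and_section_order(self, tmp_path):
        article = Article(
            doc_id="a1", title="X", abstract="An abstract.",
            sections=[("Intro", ["p1", "p2"]), ("Methods", ["p3"]),
                      ("Results", ["p4"])])
        path = tmp_path / "a1.xml"
        write_article(article, path)
        back = read_article(path, "structured_xml")
        assert back.title == "X"
        assert back.abstract == "An abstract."
        assert back.sections == article.sections
        assert back.doc_id == "a1"

    def test_plain_text_convention(self, tmp_path):
        path = tmp_path / "a2.txt"
        path.write_text("abc def")
        article = read_article(path, "plain_text")
        assert article.title == "" and article.abstract == ""
        assert article.sections == [("", ["abc def"])]
        assert article.source_format == "plain_text"

    def test_malformed_xml_reports_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<article><article-title>X</article>")
        with pytest.raises(ParseError, match="line"):
            read_article(path, "structured_xml")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("  \n")
        with pytest.raises(ParseError, match="empty"):
            read_article(path)

    def test_gzip_roundtrip(self, tmp_path):
        article = Article(doc_id="a3", title="T", sections=[("S", ["p"])])
        path = tmp_path / "a3.xml.gz"
        write_article(article, path)
        with gzip.open(path, "rt") as fh:
            assert "<article" in fh.read()
        assert read_article(path).title == "T"


class TestCuratedTable:
    def _write(self, tmp_path, text, name="table.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_rows_merge_per_document(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tDISEASETRAIT\n"
                                     "d1\tObesity\n"
                                     "d1\tBody mass index\n")
        records = read_curated_table(path, "phenotype")
        assert len(records) == 1
        assert records[0].phenotype_terms == ["Obesity", "Body mass index"]

    def test_stage_tuple_row(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                     "doc1\tinitial\tEuropean\n")
        records = read_curated_table(path, "stage_ethnicity")
        assert records[0].tuples == frozenset({("initial", "European")})

    def test_stage_value_normalized(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                     "doc1\tReplication \tEuropean\n")
        records = read_curated_table(path, "stage_ethnicity")
        assert records[0].tuples == frozenset({("replication", "European")})

    def test_invalid_stage_rejected(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                     "doc1\tpilot\tEuropean\n")
        with pytest.raises(SchemaError, match="STAGE"):
            read_curated_table(path, "stage_ethnicity")

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tTRAIT\nd1\tObesity\n")
        with pytest.raises(SchemaError, match="DISEASETRAIT"):
            read_curated_table(path, "phenotype")

    def test_blank_cell_skipped_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, "DOC_ID\tDISEASETRAIT\n"
                                     "d1\t\n"
                                     "d2\tAsthma\n")
        with caplog.at_level("WARNING"):
            records = read_curated_table(path, "phenotype")
        assert [r.doc_id for r in records] == ["d2"]
        assert "skipped" in caplog.text

    def test_row_permutation_gives_same_records(self, tmp_path):
        a = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                  "d1\tinitial\tEuropean\n"
                                  "d2\treplication\tEast Asian\n"
                                  "d1\treplication\tEuropean\n", "a.tsv")
        b = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                  "d1\treplication\tEuropean\n"
                                  "d2\treplication\tEast Asian\n"
                                  "d1\tinitial\tEuropean\n", "b.tsv")
        ra = read_curated_table(a, "stage_ethnicity")
        rb = read_curated_table(b, "stage_ethnicity")
        assert [(r.doc_id, r.tuples) for r in ra] == \
               [(r.doc_id, r.tuples) for r in rb]

    def test_ethnicity_alias_table_applied(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                     "d1\tinitial\tNorth African/Middle East\n")
        records = read_curated_table(
            path, "stage_ethnicity",
            ethnicity_aliases={"North African/Middle East":
                               "Middle East/North African"})
        assert records[0].tuples == frozenset(
            {("initial", "Middle East/North African")})

    def test_write_read_roundtrip(self, tmp_path):
        path = self._write(tmp_path, "DOC_ID\tSTAGE\tETHNICITY\n"
                                     "d1\tinitial\tEuropean\n"
                                     "d1\treplication\tEast Asian\n")
        records = read_curated_table(path, "stage_ethnicity")
        out = tmp_path / "out.tsv"
        write_curated_table(records, out)
        again = read_curated_table(out, "stage_ethnicity")
        assert [(r.doc_id, r.tuples) for r in again] == \
               [(r.doc_id, r.tuples) for r in records]


class TestDictionary:
    def _write(self, tmp_path, rows, name="dict.tsv"):
        path = tmp_path / name
        path.write_text("".join(f"{t}\t{e}\n" for t, e in rows))
        return path

    def test_adjectival_and_demonym_map_to_one_entity(self, tmp_path):
        path = self._write(tmp_path, [("German", "European"),
                                      ("Germans", "European")])
        d = load_dictionary(path)
        assert len(d.entries) == 2
        assert d.canonicals == frozenset({"European"})

    def test_casefold_collapses_duplicates(self, tmp_path):
        path = self._write(tmp_path, [("han", "East Asian"),
                                      ("Han", "East Asian")])
        assert len(load_dictionary(path).entries) == 1

    def test_conflicting_term_rejected(self, tmp_path):
        path = self._write(tmp_path, [("Indian", "South Asian"),
                                      ("indian", "Native American")])
        with pytest.raises(DictionaryConflictError, match="indian"):
            load_dictionary(path)

    def test_empty_dictionary_rejected(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            load_dictionary(path)

    def test_load_dump_load_fixed_point(self, tmp_path):
        path = self._write(tmp_path, [("German", "European"),
                                      ("Han", "East Asian")])
        d1 = load_dictionary(path)
        out = tmp_path / "dump.tsv"
        dump_dictionary(d1, out)
        d2 = load_dictionary(out)
        assert d1.entries == d2.entries


def test_lexicon_skips_blanks_and_comments(tmp_path):
    path = tmp_path / "lex.txt"
    path.write_text("cohort\n\n# comment\nStage\n")
    lex = load_lexicon(path, "sample_description")
    assert lex.terms == frozenset({"cohort", "stage"})
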