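"""gVCF / sites-VCF / eVCF / array-report parsing and serialization."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from evcfkit.errors import (
    ArrayReportError,
    InvalidRecordError,
    RecordOrderError,
    SerializationError,
    VcfParseError,
)
from evcfkit.vcf_io import (
    ArrayGenotype,
    DEFAULT_INFO_KEYS,
    EvcfHeaderMeta,
    EvcfRecord,
    GvcfRecord,
    RecordKind,
    export_annotation_table,
    parse_array_report,
    parse_evcf,
    parse_gvcf,
    parse_site_vcf,
    write_evcf,
    write_gvcf,
    write_site_vcf,
)

from conftest import make_site


class TestParseGvcf:
    def test_block_record_fields(self, gvcf_lines):
        records = parse_gvcf(gvcf_lines)
        block = records[0]
        assert block.kind is RecordKind.BLOCK
        assert (block.contig, block.pos, block.end) == ("chr1", 100, 199)
        assert block.gqx == 50 and block.min_dp == 30 and block.dp == 32
        assert block.filter == ("PASS",)
        assert block.alts == () and block.gt == (0, 0)

    def test_variant_record_fields(self, gvcf_lines):
        records = parse_gvcf(gvcf_lines)
        variant = records[2]
        assert variant.kind is RecordKind.VARIANT
        assert (variant.pos, variant.end) == (1500, 1500)
        assert variant.gt == (0, 1) and variant.alts == ("G",)
        assert variant.id == "rs1" and variant.qual == 120

    def test_every_line_maps_to_one_record(self, gvcf_lines):
        records = parse_gvcf(gvcf_lines)
        n_data = sum(1 for l in gvcf_lines if l and not l.startswith("#"))
        assert len(records) == n_data == 5

    def test_end_before_pos_rejected(self):
        lines = [
            "#CHROM POS ID REF ALT QUAL FILTER INFO FORMAT S",
            "chr1\t100\t.\tA\t.\t.\tPASS\tEND=99\tGT:GQX\t0/0:50",
        ]
        with pytest.raises(InvalidRecordError, match="END"):
            parse_gvcf(lines)

    def test_out_of_order_records_rejected(self):
        lines = [
            "#CHROM POS ID REF ALT QUAL FILTER INFO",
            "chr1\t200\t.\tA\t.\t.\tPASS\tEND=250",
            "chr1\t100\t.\tA\t.\t.\tPASS\tEND=150",
        ]
        with pytest.raises(RecordOrderError):
            parse_gvcf(lines)

    def test_malformed_line_carries_line_number(self):
        lines = [
            "#CHROM POS ID REF ALT QUAL FILTER INFO",
            "chr1\tnotanint\t.\tA\tG\t.\tPASS\t.",
        ]
        with pytest.raises(VcfParseError) as err:
            parse_gvcf(lines)
        assert err.value.line_number == 2

    def test_min_dp_accepted_from_info(self):
        # the block extension exists with MIN_DP/GQX in INFO as well as FORMAT
        lines = [
            "#CHROM POS ID REF ALT QUAL FILTER INFO",
            "chr1\t100\t.\tA\t.\t.\tPASS\tEND=150;MIN_DP=22;GQX=44",
        ]
        (rec,) = parse_gvcf(lines)
        assert rec.min_dp == 22 and rec.gqx == 44


class TestGvcfRoundTrip:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_write_then_parse_is_identity(self, data):
        n = data.draw(st.integers(1, 12))
        records = []
        pos = 1
        for _ in range(n):
            is_block = data.draw(st.booleans())
            ref = data.draw(st.sampled_from(["A", "C", "G", "T"]))
            if is_block:
                length = data.draw(st.integers(1, 500))
                records.append(
                    GvcfRecord(
                        contig="chr1", pos=pos, ref=ref, kind=RecordKind.BLOCK,
                        filter=("PASS",), end=pos + length - 1, gt=(0, 0),
                        gqx=float(data.draw(st.integers(0, 99))),
                        dp=data.draw(st.integers(0, 90)),
                        min_dp=data.draw(st.integers(0, 90)),
                    )
                )
                pos += length
            else:
                alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
                records.append(
                    GvcfRecord(
                        contig="chr1", pos=pos, ref=ref, kind=RecordKind.VARIANT,
                        alts=(alt,), qual=float(data.draw(st.integers(1, 500))),
                        filter=("PASS",),
                        gt=data.draw(st.sampled_from([(0, 1), (1, 1)])),
                        gqx=float(data.draw(st.integers(0, 99))),
                        dp=data.draw(st.integers(0, 90)),
                    )
                )
                pos += 1
        assert parse_gvcf(write_gvcf(records).splitlines()) == records


class TestParseSiteVcf:
    HEADER = "#CHROM POS ID REF ALT QUAL FILTER INFO"

    def test_caf_frequencies_mapped_per_alt(self):
        result = parse_site_vcf([self.HEADER, "chr1\t300\trs42\tA\tG\t.\t.\tCAF=0.8,0.2"])
        (site,) = result.records
        assert site.rsid == "rs42" and site.ref == "A" and site.alts == ("G",)
        assert site.alt_freqs == (0.2,)

    def test_multiallelic_kept_on_one_record(self):
        result = parse_site_vcf([self.HEADER, "chr1\t300\t.\tA\tG,T\t.\t.\t."])
        assert result.records[0].alts == ("G", "T")

    def test_alt_dot_skipped_and_tallied(self):
        result = parse_site_vcf(
            [self.HEADER, "chr1\t300\t.\tA\t.\t.\t.\t.", "chr1\t400\t.\tC\tT\t.\t.\t."]
        )
        assert result.n_skipped == 1 and len(result.records) == 1

    def test_duplicate_flagged_but_kept(self):
        result = parse_site_vcf(
            [self.HEADER, "chr1\t300\trs1\tA\tG\t.\t.\t.", "chr1\t300\trs1\tA\tG\t.\t.\t."]
        )
        assert [s.duplicate for s in result.records] == [False, True]

    def test_missing_ref_rejected(self):
        with pytest.raises(VcfParseError):
            parse_site_vcf([self.HEADER, "chr1\t300\t.\t.\tG\t.\t.\t."])

    def test_significance_labels_collected(self):
        result = parse_site_vcf(
            [self.HEADER, "chr1\t300\trs1\tA\tG\t.\t.\tCLNSIG=pathogenic,drug_response"]
        )
        assert result.significance[("chr1", 300, "A")] == {"pathogenic", "drug_response"}

    def test_site_vcf_round_trip(self):
        sites = [
            make_site(100, "A", ("G",), rsid="rs7", freqs=(0.3,)),
            make_site(250, "C", ("A", "T"), freqs=(0.1, 0.05)),
        ]
        text = write_site_vcf(sites)
        back = parse_site_vcf(text.splitlines()).records
        assert [(s.pos, s.ref, s.alts, s.alt_freqs) for s in back] == [
            (s.pos, s.ref, s.alts, s.alt_freqs) for s in sites
        ]


def _meta():
    return EvcfHeaderMeta(catalog_name="sites", catalog_version="v1")


def _homref_record(pos=300, ref="A", info=None):
    return EvcfRecord(
        contig="chr1", pos=pos, ref=ref, alts=(), filter=("PASS",),
        info=info if info is not None else {"known": True}, gt=(0, 0), gqx=50.0, dp=30,
    )


class TestWriteEvcf:
    def test_homref_serialization_rule(self):
        text = write_evcf([_homref_record()], _meta())
        line = [l for l in text.splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[4] == "." and fields[9].startswith("0/0")
        assert "known" in fields[7]

    def test_provenance_header_line(self):
        text = write_evcf([_homref_record()], _meta())
        assert "##siteCatalog=<name=sites,version=v1>" in text

    def test_missing_catalog_version_rejected(self):
        meta = EvcfHeaderMeta(catalog_name="sites", catalog_version="")
        with pytest.raises(SerializationError, match="version"):
            write_evcf([_homref_record()], meta)

    def test_undeclared_info_key_rejected(self):
        rec = _homref_record(info={"mystery": True})
        with pytest.raises(SerializationError, match="mystery"):
            write_evcf([rec], _meta())

    def test_unsorted_records_rejected(self):
        recs = [_homref_record(pos=500), _homref_record(pos=100)]
        with pytest.raises(RecordOrderError):
            write_evcf(recs, _meta())

    def test_round_trip_identity(self):
        records = [
            _homref_record(pos=100),
            EvcfRecord(
                contig="chr1", pos=200, ref="C", alts=("T",), id="rs9", qual=99.0,
                filter=("PASS",),
                info={"known": True, "gwascat_id": ("rs9",), "odds_ratio": (2.55,)},
                gt=(0, 1), gqx=80.0, dp=41,
            ),
            EvcfRecord(contig="chr1", pos=400, ref="G", alts=(), info={}, gt=None),
        ]
        meta = _meta()
        meta2, back = parse_evcf(write_evcf(records, meta).splitlines())
        assert back == records
        assert (meta2.catalog_name, meta2.catalog_version) == ("sites", "v1")

    def test_output_is_valid_vcf_for_independent_parser(self, tmp_path):
        """pysam, as an independent VCF implementation, accepts the output."""
        pysam = pytest.importorskip("pysam")
        records = [
            _homref_record(pos=100),
            EvcfRecord(
                contig="chr1", pos=200, ref="C", alts=("T",), qual=50.0,
                filter=("PASS",), info={"known": True}, gt=(0, 1), gqx=80.0, dp=40,
            ),
            EvcfRecord(contig="chr1", pos=400, ref="G", alts=(), info={}, gt=None),
        ]
        path = tmp_path / "out.evcf.vcf"
        with open(path, "w") as handle:
            write_evcf(records, _meta(), handle)
        with pysam.VariantFile(str(path)) as vf:
            parsed = list(vf)
        assert len(parsed) == 3
        assert parsed[0].alts is None  # hom-ref catalog record: ALT "."
        assert parsed[0].samples[0]["GT"] == (0, 0)
        assert parsed[2].samples[0]["GT"] == (None, None)


class TestParseArrayReport:
    HEADER = "marker_id\tcontig\tpos\tallele_a\tallele_b\n"

    def _expected(self):
        return {"rs42": make_site(300, "A", ("G",), rsid="rs42")}

    def test_plain_row(self):
        (ag,) = parse_array_report(
            io.StringIO(self.HEADER + "rs42\tchr1\t300\tA\tG\n"), self._expected()
        )
        assert (ag.marker_id, ag.pos, ag.allele_a, ag.allele_b) == ("rs42", 300, "A", "G")
        assert ag.matched

    def test_array_no_call_maps_to_missing(self):
        (ag,) = parse_array_report(
            io.StringIO(self.HEADER + "rs42\tchr1\t300\t-\t-\n"), self._expected()
        )
        assert ag.is_no_call and ag.allele_a is None and ag.allele_b is None

    def test_invalid_allele_rejected(self):
        with pytest.raises(ArrayReportError):
            parse_array_report(
                io.StringIO(self.HEADER + "rs42\tchr1\t300\tN\tG\n"), self._expected()
            )

    def test_unknown_marker_flagged_unmatched(self):
        (ag,) = parse_array_report(
            io.StringIO(self.HEADER + "rs999\tchr1\t300\tA\tG\n"), self._expected()
        )
        assert not ag.matched


class TestExportAnnotationTable:
    def test_het_snv_row(self):
        rec = EvcfRecord(contig="chr1", pos=100, ref="A", alts=("G",), gt=(0, 1))
        rows, _ = export_annotation_table([rec])
        assert rows == [("chr1", 100, 100, "A", "G")]

    def test_homref_row_repeats_reference(self):
        rows, _ = export_annotation_table([_homref_record(pos=300)])
        assert rows == [("chr1", 300, 300, "A", "A")]

    def test_deletion_left_anchor_trimmed(self):
        rec = EvcfRecord(contig="chr1", pos=100, ref="AG", alts=("A",), gt=(0, 1))
        rows, _ = export_annotation_table([rec])
        assert rows == [("chr1", 101, 101, "G", "-")]

    def test_insertion_anchored_at_shared_base(self):
        rec = EvcfRecord(contig="chr1", pos=100, ref="A", alts=("AG",), gt=(0, 1))
        rows, _ = export_annotation_table([rec])
        assert rows == [("chr1", 100, 100, "-", "G")]

    def test_het_alt_emits_both_alleles(self):
        rec = EvcfRecord(contig="chr1", pos=100, ref="A", alts=("C", "G"), gt=(1, 2))
        rows, _ = export_annotation_table([rec])
        assert {r.sample_observed for r in rows} == {"C", "G"}

    def test_nocall_skipped_with_tally(self):
        rec = EvcfRecord(contig="chr1", pos=100, ref="A", alts=(), gt=None)
        rows, n_skipped = export_annotation_table([rec])
        assert rows == [] and n_skipped == 1
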