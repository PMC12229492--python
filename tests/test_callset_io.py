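"""Dialect readers, coordinate conventions, filter counters, round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invkit.callset_io import (
    read_bed_inversions,
    read_dgv_table,
    read_tsv_callset,
    read_vcf_inversions,
    write_callset,
    write_provenance,
)
from invkit.model import Callset, InversionCall

from conftest import make_call, make_callset_from

VCF_HEADER = """##fileformat=VCFv4.2
##reference=GRCh38
##contig=<ID=chr1,length=248956422>
##contig=<ID=chr17,length=83257441>
##ALT=<ID=INV,Description="Inversion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=N_HOMALT,Number=1,Type=Integer,Description="Hom-alt count">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_text(tmp_path, body, name="test.vcf", header=VCF_HEADER):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestReadVcf:
    def test_splice_region_inversion_coordinates(self, tmp_path):
        """A 1-based POS/END pair converts to the half-open span whose length
        matches the 253-kb pathogenic inversion reported at this locus."""
        p = write_vcf_text(
            tmp_path,
            "chr17\t75576925\tINV_CHR17_66182818\tN\t<INV>\t.\tPASS\t"
            "SVTYPE=INV;END=75829482;AF=0.00006345\n",
        )
        cs = read_vcf_inversions(p, "gnomad")
        (call,) = cs.calls
        assert (call.chrom, call.start, call.end) == ("chr17", 75576924, 75829482)
        assert call.length == 252_558
        assert call.allele_frequency == pytest.approx(6.345e-5, rel=1e-4)

    def test_non_inversion_records_excluded(self, tmp_path):
        p = write_vcf_text(
            tmp_path,
            "chr1\t100\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
            "chr1\t300\tinv1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=400\n",
        )
        cs = read_vcf_inversions(p, "d")
        assert [c.id for c in cs.calls] == ["inv1"]
        assert cs.provenance["filter_counters"]["dropped_type"] == 1

    def test_empty_vcf_yields_empty_callset(self, tmp_path):
        cs = read_vcf_inversions(write_vcf_text(tmp_path, ""), "d")
        assert len(cs) == 0

    def test_filter_policy_drops_non_pass(self, tmp_path):
        p = write_vcf_text(
            tmp_path,
            "chr1\t100\ta\tN\t<INV>\t.\tLOW_QUAL\tSVTYPE=INV;END=200\n"
            "chr1\t300\tb\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=400\n",
        )
        cs = read_vcf_inversions(p, "d")
        assert [c.id for c in cs.calls] == ["b"]
        assert cs.provenance["filter_counters"]["dropped_filter"] == 1
        cs_all = read_vcf_inversions(p, "d", filter_policy=("PASS", ".", "LOW_QUAL"))
        assert len(cs_all) == 2

    def test_svlen_fallback_when_end_missing(self, tmp_path):
        p = write_vcf_text(
            tmp_path, "chr1\t101\ta\tN\t<INV>\t.\tPASS\tSVTYPE=INV;SVLEN=100\n"
        )
        (call,) = read_vcf_inversions(p, "d").calls
        assert (call.start, call.end) == (100, 200)

    def test_missing_end_and_svlen_is_hard_error(self, tmp_path):
        p = write_vcf_text(tmp_path, "chr1\t101\ta\tN\t<INV>\t.\tPASS\tSVTYPE=INV\n")
        with pytest.raises(ValueError, match="neither END nor SVLEN"):
            read_vcf_inversions(p, "d")

    def test_build_mismatch_is_hard_error(self, tmp_path):
        header = VCF_HEADER.replace("##reference=GRCh38", "##reference=hg19")
        p = write_vcf_text(tmp_path, "", header=header)
        with pytest.raises(ValueError, match="build"):
            read_vcf_inversions(p, "d")

    def test_pos_anchor_switch_shifts_start_by_one(self, tmp_path):
        p = write_vcf_text(
            tmp_path, "chr1\t101\ta\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=200\n"
        )
        first = read_vcf_inversions(p, "d", pos_anchor="first_base").calls[0]
        prec = read_vcf_inversions(p, "d", pos_anchor="preceding_base").calls[0]
        assert (first.start, prec.start) == (100, 101)
        assert first.end == prec.end == 200

    def test_exact_duplicates_collapsed_and_counted(self, tmp_path):
        p = write_vcf_text(
            tmp_path,
            "chr1\t100\ta\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=200\n"
            "chr1\t100\tb\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=200\n",
        )
        cs = read_vcf_inversions(p, "d")
        assert len(cs) == 1
        assert cs.provenance["filter_counters"]["dropped_duplicate"] == 1

    def test_counter_partition(self, tmp_path):
        p = write_vcf_text(
            tmp_path,
            "chr1\t100\ta\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=200\n"
            "chr1\t100\tb\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
            "chr1\t100\tc\tN\t<INV>\t.\tLOW\tSVTYPE=INV;END=200\n"
            "chr1\t500\td\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=600\n",
        )
        c = read_vcf_inversions(p, "d").provenance["filter_counters"]
        assert (
            c["kept"]
            + c["dropped_type"]
            + c["dropped_contig"]
            + c["dropped_filter"]
            + c["dropped_duplicate"]
            + c["malformed"]
            == c["total"]
            == 4
        )


class TestReadDgv:
    HEADER = "variantaccession\tchr\tstart\tend\tvarianttype\tvariantsubtype\n"

    def write(self, tmp_path, rows):
        p = tmp_path / "dgv.txt"
        p.write_text(self.HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_one_based_inclusive_conversion(self, tmp_path):
        p = self.write(tmp_path, [("v1", "17", 100, 200, "SV", "inversion")])
        (call,) = read_dgv_table(p, "dgv").calls
        assert (call.chrom, call.start, call.end) == ("chr17", 99, 200)

    def test_non_inversion_subtypes_excluded(self, tmp_path):
        p = self.write(
            tmp_path,
            [("v1", "1", 10, 20, "CNV", "duplication"),
             ("v2", "1", 30, 40, "SV", "Inversion")],
        )
        cs = read_dgv_table(p, "dgv")
        assert [c.id for c in cs.calls] == ["v2"]  # case-insensitive match

    def test_random_contigs_dropped_and_counted(self, tmp_path):
        p = self.write(tmp_path, [("v1", "chr17_random", 10, 20, "SV", "inversion")])
        cs = read_dgv_table(p, "dgv")
        assert len(cs) == 0
        assert cs.provenance["filter_counters"]["dropped_contig"] == 1

    def test_unparseable_coordinate_skipped_with_counter(self, tmp_path):
        p = self.write(
            tmp_path,
            [("v1", "1", "oops", 20, "SV", "inversion"),
             ("v2", "1", 30, 40, "SV", "inversion")],
        )
        with pytest.warns(UserWarning):
            cs = read_dgv_table(p, "dgv")
        assert len(cs) == 1
        assert cs.provenance["filter_counters"]["malformed"] == 1

    def test_missing_required_column_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("chr\tstart\n1\t10\n")
        with pytest.raises(ValueError, match="missing required"):
            read_dgv_table(p, "dgv")


class TestReadBed:
    def test_verbatim_ingestion_and_sorting(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t10\t50\tb\nchr1\t0\t100\ta\nchr1\t5\t30\tc\n")
        cs = read_bed_inversions(p, "bed")
        assert [(c.chrom, c.start, c.end, c.id) for c in cs.calls] == [
            ("chr1", 0, 100, "a"),
            ("chr1", 5, 30, "c"),
            ("chr2", 10, 50, "b"),
        ]

    def test_zero_length_row_rejected(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.warns(UserWarning):
            cs = read_bed_inversions(p, "bed")
        assert len(cs) == 0
        assert cs.provenance["filter_counters"]["malformed"] == 1


class TestWriteAndRoundTrip:
    def test_coordinate_conventions_on_output(self, tmp_path):
        cs = make_callset_from([("chr17", 75576924, 75829482)], dataset="gnomad")
        bed = write_callset(cs, tmp_path / "x.bed", "bed")
        assert bed.read_text().startswith("chr17\t75576924\t75829482")
        tsv = write_callset(cs, tmp_path / "x.tsv", "tsv")
        row = tsv.read_text().splitlines()[1].split("\t")
        assert (row[2], row[3]) == ("75576925", "75829482")  # 1-based display

    def test_empty_callset_writes_header_only(self, tmp_path):
        cs = Callset(dataset="d", calls=[])
        tsv = write_callset(cs, tmp_path / "x.tsv", "tsv")
        assert len(tsv.read_text().splitlines()) == 1
        assert len(read_tsv_callset(tsv)) == 0

    def test_provenance_sidecar(self, tmp_path):
        import json

        cs = make_callset_from([("chr1", 0, 10)])
        cs.provenance["filter_counters"] = {"total": 1, "kept": 1}
        side = write_provenance(cs, tmp_path / "x.json")
        payload = json.loads(side.read_text())
        assert payload["n_calls"] == 1 and "filter_counters" in payload

    @settings(max_examples=25, deadline=None)
    @given(
        coords=st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
            ),
            min_size=0,
            max_size=30,
        ),
        fmt=st.sampled_from(["bed", "tsv"]),
    )
    def test_roundtrip_identity(self, tmp_path_factory, coords, fmt):
        """write -> read is the identity on (chrom, start, end, id) in both formats."""
        tmp = tmp_path_factory.mktemp("rt")
        seen = set()
        calls = []
        for i, (chrom, start, ln) in enumerate(coords):
            if (chrom, start, start + ln) in seen:
                continue
            seen.add((chrom, start, start + ln))
            calls.append(make_call(chrom, start, start + ln, id=f"c{i}", af=0.01))
        cs = Callset(
            dataset="test", calls=sorted(calls, key=InversionCall.sort_key)
        )
        path = write_callset(cs, tmp / f"x.{fmt}", fmt)
        reader = read_bed_inversions if fmt == "bed" else read_tsv_callset
        back = reader(path, "test") if fmt == "bed" else read_tsv_callset(path)
        key = lambda cs: [(c.chrom, c.start, c.end, c.id) for c in cs.calls]
        assert key(back) == key(cs)
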