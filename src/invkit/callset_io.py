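"""Readers and writers for the three inversion-callset dialects.

Supported inputs:

* population SV VCFs with symbolic ``<INV>`` alleles (gnomAD-SV / 1KGP style),
  via cyvcf2; INFO keys for allele frequency and homozygote counts are
  configurable because producers disagree on their names,
* DGV-style tab-delimited variant tables (1-based inclusive coordinates,
  ``variantsubtype`` column),
* generic BED3+ (already 0-based half-open),
* the package's own TSV output (1-based inclusive display coordinates).

All readers emit the same harmonized :class:`~invkit.model.Callset`:
0-based half-open coordinates, 24 accepted contigs, exact duplicates
collapsed, calls sorted, and a filter-counter partition of the input rows
(kept + dropped-by-type + dropped-by-contig + dropped-by-filter +
dropped-by-duplicate + malformed = total).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .model import Callset, InversionCall, harmonize_calls, normalize_contig

__all__ = [
    "read_vcf_inversions",
    "read_dgv_table",
    "read_bed_inversions",
    "read_tsv_callset",
    "write_callset",
    "write_provenance",
]

TSV_COLUMNS = [
    "id",
    "chrom",
    "start_1based",
    "end_1based",
    "length",
    "dataset",
    "allele_frequency",
    "n_homalt",
    "svtype_raw",
]

_OTHER_BUILD_TOKENS = {
    "GRCh38": ("grch37", "hg19", "hg18", "grch36"),
    "GRCh37": ("grch38", "hg38",),
}


def _new_counters() -> dict:
    return {
        "total": 0,
        "dropped_type": 0,
        "dropped_contig": 0,
        "dropped_filter": 0,
        "malformed": 0,
    }


def _check_build(header_text: str, expected_build: str, path) -> None:
    low = header_text.lower()
    for tok in _OTHER_BUILD_TOKENS.get(expected_build, ()):
        if tok in low:
            raise ValueError(
                f"{path}: header declares genome build {tok!r} but "
                f"{expected_build} was expected"
            )


def read_vcf_inversions(
    path,
    dataset_label: str,
    *,
    af_key: str = "AF",
    homalt_key: str = "N_HOMALT",
    filter_policy: tuple[str, ...] = ("PASS", "."),
    pos_anchor: str = "first_base",
    expected_build: str = "GRCh38",
) -> Callset:
    """Extract SVTYPE=INV records from a (possibly bgzipped) SV VCF.

    ``pos_anchor`` handles the producer ambiguity of whether POS is the
    first inverted base (default: ``start = POS - 1`` in 0-based terms) or
    the base preceding the event (``preceding_base``: ``start = POS``).
    INFO/END (1-based inclusive) maps directly to the half-open ``end``;
    when END is absent, SVLEN is used; when both are absent the record is a
    hard error. FILTER values outside ``filter_policy`` are dropped and
    counted (the VCF parser reports PASS and '.' identically, so the
    default policy treats them as one class).
    """
    if pos_anchor not in ("first_base", "preceding_base"):
        raise ValueError(f"unknown pos_anchor {pos_anchor!r}")
    counters = _new_counters()
    calls: list[InversionCall] = []
    vcf = VCF(str(path))
    try:
        if expected_build:
            _check_build(vcf.raw_header, expected_build, path)
        for i, rec in enumerate(vcf):
            counters["total"] += 1
            svtype = rec.INFO.get("SVTYPE")
            if svtype is None:
                warnings.warn(f"{path}: record {rec.ID or i} lacks SVTYPE; skipped")
                counters["malformed"] += 1
                continue
            if str(svtype) != "INV":
                counters["dropped_type"] += 1
                continue
            # cyvcf2 reports FILTER None for both PASS and '.'
            filt = rec.FILTER.split(";") if rec.FILTER else ["PASS", "."]
            if not any(f in filter_policy for f in filt):
                counters["dropped_filter"] += 1
                continue
            chrom = normalize_contig(rec.CHROM)
            if chrom is None:
                counters["dropped_contig"] += 1
                continue
            start = rec.POS - 1 if pos_anchor == "first_base" else rec.POS
            end = rec.INFO.get("END")
            if end is None:
                svlen = rec.INFO.get("SVLEN")
                if svlen is None:
                    raise ValueError(
                        f"{path}: INV record {rec.ID or rec.POS} carries neither END nor SVLEN"
                    )
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                end = start + abs(int(svlen))
            af = rec.INFO.get(af_key)
            if isinstance(af, (tuple, list)):
                af = af[0]
            nh = rec.INFO.get(homalt_key)
            if isinstance(nh, (tuple, list)):
                nh = nh[0]
            try:
                calls.append(
                    InversionCall(
                        id=rec.ID or f"{dataset_label}_{i}",
                        chrom=chrom,
                        start=start,
                        end=int(end),
                        dataset=dataset_label,
                        allele_frequency=float(af) if af is not None else None,
                        n_homalt=int(nh) if nh is not None else None,
                        svtype_raw=str(svtype),
                    )
                )
            except ValueError as exc:
                warnings.warn(f"{path}: {exc}; record skipped")
                counters["malformed"] += 1
    finally:
        vcf.close()
    return harmonize_calls(
        dataset_label,
        calls,
        counters,
        provenance={"source": str(path), "dialect": "vcf", "pos_anchor": pos_anchor},
    )


def read_dgv_table(
    path,
    dataset_label: str,
    *,
    inversion_synonyms: tuple[str, ...] = ("inversion",),
) -> Callset:
    """Extract inversion rows from a DGV-style tab-delimited variant table.

    Rows whose ``variantsubtype`` (fallback ``varianttype``) matches the
    synonym list case-insensitively are retained; DGV's 1-based inclusive
    coordinates become half-open as (start-1, end).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    try:
        chr_col = lower.get("chr") or lower["chromosome"]
        start_col = lower["start"]
        end_col = lower["end"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing required DGV column {exc}") from exc
    type_col = lower.get("variantsubtype") or lower.get("varianttype")
    if type_col is None:
        raise ValueError(f"{path}: missing required DGV column variantsubtype/varianttype")
    id_col = lower.get("variantaccession") or lower.get("id")
    synonyms = {s.lower() for s in inversion_synonyms}

    counters = _new_counters()
    calls: list[InversionCall] = []
    for i, row in enumerate(df.itertuples(index=False)):
        counters["total"] += 1
        rec = dict(zip(df.columns, row))
        subtype = str(rec[type_col]).strip().lower()
        if subtype not in synonyms:
            counters["dropped_type"] += 1
            continue
        chrom = normalize_contig(str(rec[chr_col]))
        if chrom is None:
            counters["dropped_contig"] += 1
            continue
        try:
            start1 = int(rec[start_col])
            end1 = int(rec[end_col])
            calls.append(
                InversionCall(
                    id=str(rec[id_col]) if id_col else f"{dataset_label}_{i}",
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    dataset=dataset_label,
                    svtype_raw=str(rec[type_col]),
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path}: row {i}: {exc}; row skipped")
            counters["malformed"] += 1
    return harmonize_calls(
        dataset_label,
        calls,
        counters,
        provenance={"source": str(path), "dialect": "dgv"},
    )


def read_bed_inversions(path, dataset_label: str) -> Callset:
    """Ingest a BED3+ file of inversion coordinates (already half-open).

    An optional 4th column provides record ids; rows with start >= end are
    rejected and counted as malformed.
    """
    counters = _new_counters()
    calls: list[InversionCall] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            counters["total"] += 1
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}: line {i + 1} has fewer than 3 columns; skipped")
                counters["malformed"] += 1
                continue
            chrom = normalize_contig(fields[0])
            if chrom is None:
                counters["dropped_contig"] += 1
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                if end <= start:
                    raise ValueError(f"start {start} >= end {end}")
                calls.append(
                    InversionCall(
                        id=fields[3] if len(fields) > 3 and fields[3] else f"{dataset_label}_{i}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        dataset=dataset_label,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"{path}: line {i + 1}: {exc}; row rejected")
                counters["malformed"] += 1
    return harmonize_calls(
        dataset_label,
        calls,
        counters,
        provenance={"source": str(path), "dialect": "bed"},
    )


def read_tsv_callset(path, dataset_label: str | None = None) -> Callset:
    """Read back the package's own TSV output (inverse of ``write_callset``)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    counters = _new_counters()
    calls: list[InversionCall] = []
    for row in df.itertuples(index=False):
        counters["total"] += 1
        rec = dict(zip(df.columns, row))
        af = rec.get("allele_frequency")
        nh = rec.get("n_homalt")
        calls.append(
            InversionCall(
                id=str(rec["id"]),
                chrom=str(rec["chrom"]),
                start=int(rec["start_1based"]) - 1,
                end=int(rec["end_1based"]),
                dataset=dataset_label or str(rec.get("dataset", "callset")),
                allele_frequency=None if pd.isna(af) else float(af),
                n_homalt=None if nh is None or pd.isna(nh) else int(nh),
                svtype_raw=str(rec.get("svtype_raw", "INV")),
            )
        )
    return harmonize_calls(
        calls[0].dataset if calls else (dataset_label or "callset"),
        calls,
        counters,
        provenance={"source": str(path), "dialect": "tsv"},
    )


def write_callset(cs: Callset, path, format: str = "tsv") -> Path:
    """Write a harmonized callset as BED (half-open) or TSV (1-based display).

    Either output round-trips through the matching reader with identical
    (chrom, start, end, id); the TSV additionally preserves the population
    fields.
    """
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            for c in cs.calls:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\n")
    elif format == "tsv":
        df = pd.DataFrame(
            [
                {
                    "id": c.id,
                    "chrom": c.chrom,
                    "start_1based": c.start + 1,
                    "end_1based": c.end,
                    "length": c.length,
                    "dataset": c.dataset,
                    "allele_frequency": c.allele_frequency,
                    "n_homalt": c.n_homalt,
                    "svtype_raw": c.svtype_raw,
                }
                for c in cs.calls
            ],
            columns=TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown callset format {format!r}")
    return path


def write_provenance(cs: Callset, path) -> Path:
    """Write the JSON provenance sidecar (source, dialect, filter counters)."""
    path = Path(path)
    payload = {
        "dataset": cs.dataset,
        "genome_build": cs.genome_build,
        "n_calls": len(cs),
        **cs.provenance,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
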