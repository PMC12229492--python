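"""Canonical-transcript gene models and disease annotations.

The gene table is expected to carry exactly one (canonical) transcript per
gene, as produced by a UCSC-style extraction of protein-coding transcripts.
Exon blocks use absolute half-open coordinates; introns are derived as the
complement of the exons within the gene span, so ``exons + introns`` tile the
span exactly and ``n_introns == n_exons - 1``.

Disease annotations follow the OMIM genemap shape: a gene is
``phenotype_linked`` when it has at least one phenotype row,
``cataloged_no_phenotype`` when present without phenotypes, and
``not_in_omim`` otherwise. Free-text inheritance strings are normalized to
{AR, AD, XLR, XLD, other} via a documented synonym map; a gene with several
phenotypes of different modes carries the union of their modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .model import normalize_contig

__all__ = [
    "GeneModel",
    "GeneAnnotation",
    "MODE_SYNONYMS",
    "normalize_inheritance",
    "read_gene_table",
    "join_annotations",
    "inheritance_background",
]

OMIM_STATUSES = ("phenotype_linked", "cataloged_no_phenotype", "not_in_omim")
INHERITANCE_MODES = ("AR", "AD", "XLR", "XLD", "other")


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene with its canonical transcript's exon blocks."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: degenerate exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping/unsorted exon blocks")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(
                f"gene {self.gene_id}: exon blocks do not tile the gene span "
                f"[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Complement of the exons within the gene span (5'->3' in + orientation)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:  # zero-length gaps cannot occur after validation
                out.append((e1, s2))
        return tuple(out)

    def intron_ordinal(self, geometric_index: int) -> int:
        """1-based intron number in transcription orientation.

        Intron 1 is the intron nearest the transcription start site, so on
        the minus strand geometric order is reversed.
        """
        n = len(self.introns)
        if not (0 <= geometric_index < n):
            raise IndexError(geometric_index)
        return geometric_index + 1 if self.strand == "+" else n - geometric_index


@dataclass(frozen=True)
class GeneAnnotation:
    """Disease linkage of one gene (OMIM status, inheritance modes, Orphanet)."""

    gene_id: str
    omim_status: str = "not_in_omim"
    inheritance_modes: frozenset[str] = frozenset()
    orphanet_linked: bool = False

    def __post_init__(self) -> None:
        if self.omim_status not in OMIM_STATUSES:
            raise ValueError(f"bad omim_status {self.omim_status!r}")
        if self.inheritance_modes and self.omim_status != "phenotype_linked":
            raise ValueError(
                f"gene {self.gene_id}: inheritance modes require phenotype linkage"
            )
        bad = set(self.inheritance_modes) - set(INHERITANCE_MODES)
        if bad:
            raise ValueError(f"gene {self.gene_id}: unknown inheritance modes {bad}")


MODE_SYNONYMS = {
    "autosomal recessive": "AR",
    "ar": "AR",
    "autosomal dominant": "AD",
    "ad": "AD",
    "x-linked recessive": "XLR",
    "xlr": "XLR",
    "x-linked dominant": "XLD",
    "xld": "XLD",
}


def normalize_inheritance(text: str | float | None) -> frozenset[str]:
    """Map a free-text inheritance string onto {AR, AD, XLR, XLD, other}.

    Multiple modes may be separated by ';', ',' or '/'. Unrecognized
    non-empty tokens map to 'other'; empty input maps to the empty set.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return frozenset()
    s = str(text).strip()
    if not s:
        return frozenset()
    for sep in (";", ",", "/"):
        s = s.replace(sep, "|")
    modes = set()
    for tok in s.split("|"):
        tok = tok.strip()
        if not tok:
            continue
        modes.add(MODE_SYNONYMS.get(tok.lower(), "other"))
    return frozenset(modes)


def _required_column(df: pd.DataFrame, names: tuple[str, ...], path) -> str:
    lower = {c.lower(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    raise ValueError(f"{path}: missing required column (one of {names})")


def read_gene_table(path) -> list[GeneModel]:
    """Load a genePred-style TSV of canonical protein-coding transcripts.

    Required columns (case-insensitive): gene_id, symbol, chrom, strand,
    start, end, exon_starts, exon_ends, biotype. Coordinates are half-open
    0-based; exon_starts/exon_ends are comma-separated absolute positions.
    Non-protein-coding rows and rows on non-accepted contigs are dropped;
    a gene_id appearing twice (two transcripts) is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {
        k: _required_column(df, names, path)
        for k, names in {
            "gene_id": ("gene_id", "geneid", "name2"),
            "symbol": ("symbol", "gene_symbol", "genesymbol"),
            "chrom": ("chrom", "chr", "chromosome"),
            "strand": ("strand",),
            "start": ("start", "txstart"),
            "end": ("end", "txend"),
            "exon_starts": ("exon_starts", "exonstarts"),
            "exon_ends": ("exon_ends", "exonends"),
            "biotype": ("biotype", "transcript_type", "gene_type"),
        }.items()
    }
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        if str(rec[cols["biotype"]]).strip().lower() != "protein_coding":
            continue
        chrom = normalize_contig(str(rec[cols["chrom"]]))
        if chrom is None:
            continue
        gid = str(rec[cols["gene_id"]]).strip()
        if gid in seen:
            raise ValueError(f"{path}: gene {gid} has more than one transcript row")
        seen.add(gid)
        starts = [int(x) for x in str(rec[cols["exon_starts"]]).rstrip(",").split(",")]
        ends = [int(x) for x in str(rec[cols["exon_ends"]]).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"{path}: gene {gid}: exon block lists differ in length")
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=str(rec[cols["symbol"]]).strip(),
                chrom=chrom,
                start=int(rec[cols["start"]]),
                end=int(rec[cols["end"]]),
                strand=str(rec[cols["strand"]]).strip(),
                exons=tuple(zip(starts, ends)),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def _gene_key_map(genes: list[GeneModel]) -> dict[str, str]:
    """symbol -> gene_id map; ambiguous symbols resolve first-by-id with a warning."""
    by_symbol: dict[str, list[str]] = {}
    for g in genes:
        by_symbol.setdefault(g.symbol, []).append(g.gene_id)
    out = {}
    for sym, ids in by_symbol.items():
        if len(ids) > 1:
            warnings.warn(
                f"symbol {sym!r} maps to {len(ids)} gene ids; using {min(ids)}",
                stacklevel=3,
            )
        out[sym] = min(ids)
    return out


def join_annotations(
    genes: list[GeneModel],
    omim_table,
    orphanet_table=None,
) -> dict[str, GeneAnnotation]:
    """Join OMIM genemap-style and Orphanet tables onto the gene universe.

    The OMIM table needs a key column (gene_id or symbol) and may carry
    ``phenotype`` and ``inheritance`` columns; a row with a non-empty
    phenotype marks the gene phenotype-linked and contributes its
    (normalized) inheritance modes. Every gene in ``genes`` receives an
    annotation; genes absent from the OMIM table are ``not_in_omim``.
    """
    sym2id = _gene_key_map(genes)
    known_ids = {g.gene_id for g in genes}

    def resolve(rec: dict, id_col, sym_col) -> str | None:
        if id_col is not None:
            gid = str(rec[id_col]).strip()
            if gid in known_ids:
                return gid
        if sym_col is not None:
            return sym2id.get(str(rec[sym_col]).strip())
        return None

    omim = pd.read_csv(omim_table, sep="\t", dtype=str, comment="#")
    lower = {c.lower(): c for c in omim.columns}
    id_col = lower.get("gene_id")
    sym_col = lower.get("symbol") or lower.get("gene_symbol") or lower.get("approved_symbol")
    if id_col is None and sym_col is None:
        raise ValueError(f"{omim_table}: OMIM table needs a gene_id or symbol column")
    phen_col = lower.get("phenotype") or lower.get("phenotypes")
    inh_col = lower.get("inheritance") or lower.get("inheritance_mode")

    status: dict[str, str] = {}
    modes: dict[str, set[str]] = {}
    for row in omim.itertuples(index=False):
        rec = dict(zip(omim.columns, row))
        gid = resolve(rec, id_col, sym_col)
        if gid is None:
            continue
        phen = rec.get(phen_col) if phen_col else None
        has_phen = phen is not None and not (isinstance(phen, float) and pd.isna(phen)) and str(phen).strip() != ""
        if has_phen:
            status[gid] = "phenotype_linked"
            modes.setdefault(gid, set()).update(
                normalize_inheritance(rec.get(inh_col) if inh_col else None)
            )
        else:
            status.setdefault(gid, "cataloged_no_phenotype")

    orpha_ids: set[str] = set()
    if orphanet_table is not None:
        orpha = pd.read_csv(orphanet_table, sep="\t", dtype=str, comment="#")
        olower = {c.lower(): c for c in orpha.columns}
        oid = olower.get("gene_id")
        osym = olower.get("symbol") or olower.get("gene_symbol")
        if oid is None and osym is None:
            raise ValueError(f"{orphanet_table}: Orphanet table needs a gene_id or symbol column")
        for row in orpha.itertuples(index=False):
            rec = dict(zip(orpha.columns, row))
            gid = resolve(rec, oid, osym)
            if gid is not None:
                orpha_ids.add(gid)

    out: dict[str, GeneAnnotation] = {}
    for g in genes:
        st = status.get(g.gene_id, "not_in_omim")
        out[g.gene_id] = GeneAnnotation(
            gene_id=g.gene_id,
            omim_status=st,
            inheritance_modes=frozenset(modes.get(g.gene_id, set()))
            if st == "phenotype_linked"
            else frozenset(),
            orphanet_linked=g.gene_id in orpha_ids,
        )
    return out


def inheritance_background(annotations: dict[str, GeneAnnotation]) -> pd.DataFrame:
    """Per-mode gene counts/proportions over the phenotype-linked gene universe.

    A gene with k modes contributes to k mode counts; the denominator is the
    number of phenotype-linked genes, so proportions can sum to more than 1.
    """
    linked = [a for a in annotations.values() if a.omim_status == "phenotype_linked"]
    if not linked:
        raise ValueError("no phenotype-linked genes in the annotation universe")
    counts = {m: 0 for m in INHERITANCE_MODES}
    for a in linked:
        for m in a.inheritance_modes:
            counts[m] += 1
    n = len(linked)
    return pd.DataFrame(
        {
            "mode": list(counts),
            "n_genes": list(counts.values()),
            "proportion": [c / n for c in counts.values()],
        }
    ).set_index("mode")
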