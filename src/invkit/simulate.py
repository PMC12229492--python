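"""Synthetic genomes, gene models, annotations and inversion callsets.

The generator produces inputs with the same shape and statistical structure
as the public callsets the pipeline targets, with known per-call ground
truth, so the whole analysis is exercisable and checkable without any
download:

* inversion lengths are drawn by inverse transform through a monotone
  cubic interpolation (in log space) of a dataset's five-number length
  summary (min, Q1, median, Q3, max), so empirical quantiles converge to
  the published ones as n grows — the
  real quartiles are not log-symmetric, so no two-parameter log-normal can
  match all three at once; a log-normal fallback calibrated by quantile
  matching (``mu = ln(median)``, ``sigma = (ln q3 - ln q1) / (2 * 0.6745)``)
  remains available for profiles specified only by quartiles,
* allele frequencies come from a rare/common mixture (defaults emulate the
  observed ~99% rare fraction),
* a configurable share of category-planted calls is placed by construction
  (e.g. both breakpoints inside one intron for single-intron intragenic
  events), and the planted labels are recorded for recovery testing.

Everything is driven by a single numpy Generator per call, so a fixed seed
reproduces outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .gene_model import GeneAnnotation, GeneModel
from .model import Callset, InversionCall, harmonize_calls

__all__ = [
    "Genome",
    "DatasetProfile",
    "PlantedCall",
    "builtin_profile",
    "BUILTIN_PROFILES",
    "make_genome",
    "make_genes",
    "make_callset",
    "write_gene_table",
    "write_annotation_tables",
    "write_vcf",
]

_Z_QUARTILE = 0.6745  # 75th percentile of the standard normal

PLANT_KINDS = (
    "gene_spanning",
    "gene_disrupting",
    "intragenic_single_intron",
    "intragenic_multi",
    "intergenic",
)


@dataclass(frozen=True)
class Genome:
    """A toy reference: contig names mapped to lengths (bp)."""

    chroms: tuple[tuple[str, int], ...]

    def __iter__(self):
        return iter(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)


@dataclass(frozen=True)
class DatasetProfile:
    """Parameters emulating one source dataset's callset statistics.

    ``length_mu``/``length_sigma`` parameterize a log-normal on bp;
    ``prop_rare`` is the share of calls in the rare allele-frequency
    stratum; ``prop_homalt_zero`` the share never seen homozygous.
    """

    label: str
    n_calls: int
    length_mu: float
    length_sigma: float
    #: optional quantile anchors ((prob, bp), ...); when set they define the
    #: length distribution and the log-normal fields are reference values
    length_quantiles: tuple[tuple[float, float], ...] | None = None
    prop_rare: float = 0.989
    rare_af_range: tuple[float, float] = (1e-5, 0.05)
    common_af_range: tuple[float, float] = (0.05, 0.5)
    prop_homalt_zero: float = 0.9
    with_af: bool = True

    def __post_init__(self) -> None:
        if self.length_sigma <= 0:
            raise ValueError("length_sigma must be positive")
        for p in (self.prop_rare, self.prop_homalt_zero):
            if not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0,1]")
        if self.length_quantiles is not None:
            probs = [p for p, _ in self.length_quantiles]
            vals = [v for _, v in self.length_quantiles]
            if probs != sorted(probs) or vals != sorted(vals) or min(vals) <= 0:
                raise ValueError("length quantile anchors must be monotone and positive")

    @classmethod
    def from_quartiles(
        cls, label: str, n_calls: int, q1_kb: float, median_kb: float, q3_kb: float, **kw
    ) -> "DatasetProfile":
        """Calibrate the two-parameter log-normal from target quartiles (kb)."""
        mu = float(np.log(median_kb * 1000.0))
        sigma = float((np.log(q3_kb * 1000.0) - np.log(q1_kb * 1000.0)) / (2 * _Z_QUARTILE))
        return cls(label=label, n_calls=n_calls, length_mu=mu, length_sigma=sigma, **kw)

    @classmethod
    def from_five_number(
        cls,
        label: str,
        n_calls: int,
        min_kb: float,
        q1_kb: float,
        median_kb: float,
        q3_kb: float,
        max_kb: float,
        **kw,
    ) -> "DatasetProfile":
        """Anchor the length quantile function at a five-number summary (kb)."""
        prof = cls.from_quartiles(label, n_calls, q1_kb, median_kb, q3_kb, **kw)
        anchors = tuple(
            (p, kb * 1000.0)
            for p, kb in zip((0.0, 0.25, 0.5, 0.75, 1.0),
                             (min_kb, q1_kb, median_kb, q3_kb, max_kb))
        )
        return replace(prof, length_quantiles=anchors)

    def draw_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n inversion lengths (bp) from the profile's length model.

        The anchored quantile function is interpolated with a monotone cubic
        (PCHIP) in log space: it passes exactly through the anchors while
        keeping the slope continuous, which avoids the slope discontinuity a
        piecewise-linear quantile function would put right at the quartiles.
        """
        if self.length_quantiles is not None:
            probs = np.array([p for p, _ in self.length_quantiles])
            logv = np.log([v for _, v in self.length_quantiles])
            qf = PchipInterpolator(probs, logv)
            lengths = np.exp(qf(rng.uniform(0, 1, n)))
        else:
            lengths = rng.lognormal(self.length_mu, self.length_sigma, n)
        return np.maximum(1, lengths.round().astype(np.int64))


#: profiles anchored to the published per-dataset five-number length summaries
BUILTIN_PROFILES: dict[str, DatasetProfile] = {
    "gnomad": DatasetProfile.from_five_number(
        "gnomad", 2185, 0.052, 0.896, 7.12, 23.63, 118_667.16
    ),
    "dgv": DatasetProfile.from_five_number(
        "dgv", 3468, 0.035, 0.395, 2.67, 24.3, 9734.0, with_af=False
    ),
    "onekgp": DatasetProfile.from_five_number(
        "onekgp", 920, 0.052, 0.238, 0.831, 6.16, 98.73
    ),
    "ebert": DatasetProfile.from_five_number(
        "ebert", 414, 0.3, 8.13, 23.94, 87.63, 57_207.41, with_af=False
    ),
    "porubsky": DatasetProfile.from_five_number(
        "porubsky", 399, 0.236, 4.67, 20.73, 114.28, 23_268.23, with_af=False
    ),
}


def builtin_profile(name: str, n_calls: int | None = None) -> DatasetProfile:
    try:
        prof = BUILTIN_PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {sorted(BUILTIN_PROFILES)}"
        ) from None
    return prof if n_calls is None else replace(prof, n_calls=n_calls)


@dataclass(frozen=True)
class PlantedCall:
    """Ground truth for one quota-planted inversion."""

    inversion_id: str
    kind: str
    gene_id: str | None
    category: str | None  # expected category against gene_id; None for intergenic
    single_intron: bool | None
    stratum: str


def make_genome(n_chroms: int = 2, chrom_length: int = 10_000_000, seed: int = 0) -> Genome:
    """A deterministic toy genome of equal-length contigs named chr1..chrN."""
    if n_chroms < 1 or n_chroms > 24 or chrom_length < 1:
        raise ValueError("need 1..24 contigs of positive length")
    names = [f"chr{i}" for i in range(1, min(n_chroms, 22) + 1)]
    if n_chroms >= 23:
        names.append("chrX")
    if n_chroms == 24:
        names.append("chrY")
    return Genome(chroms=tuple((n, chrom_length) for n in names))


_DEFAULT_STATUS_MIX = {  # synthetic defaults, freely configurable
    "phenotype_linked": 0.25,
    "cataloged_no_phenotype": 0.57,
    "not_in_omim": 0.18,
}
_DEFAULT_INHERITANCE_MIX = {"AR": 0.45, "AD": 0.35, "XLR": 0.05, "XLD": 0.03, "other": 0.12}


def make_genes(
    genome: Genome,
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 10),
    exon_length_range: tuple[int, int] = (80, 300),
    intron_length_model: tuple[float, float] = (7.5, 0.8),  # log-normal on bp
    intergenic_gap_range: tuple[int, int] = (20_000, 60_000),
    status_mix: dict[str, float] | None = None,
    inheritance_mix: dict[str, float] | None = None,
    orphanet_rate: float = 0.3,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, GeneAnnotation]]:
    """Lay out non-overlapping multi-exon genes and draw disease annotations.

    Genes are placed left to right with random intergenic gaps; exon counts,
    exon lengths and (log-normal) intron lengths are drawn per gene. OMIM
    status and inheritance modes are drawn from configurable mixes whose
    defaults are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    status_mix = status_mix or _DEFAULT_STATUS_MIX
    inheritance_mix = inheritance_mix or _DEFAULT_INHERITANCE_MIX
    statuses = list(status_mix)
    status_p = np.array([status_mix[s] for s in statuses], dtype=float)
    status_p /= status_p.sum()
    modes = list(inheritance_mix)
    mode_p = np.array([inheritance_mix[m] for m in modes], dtype=float)
    mode_p /= mode_p.sum()

    genes: list[GeneModel] = []
    annotations: dict[str, GeneAnnotation] = {}
    chrom_iter = iter(genome.chroms)
    chrom, chrom_len = next(chrom_iter)
    cursor = int(rng.integers(*intergenic_gap_range))
    for i in range(n_genes):
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = rng.integers(exon_length_range[0], exon_length_range[1] + 1, n_exons)
        intron_lens = np.maximum(
            50, rng.lognormal(*intron_length_model, max(n_exons - 1, 0)).astype(int)
        )
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        while cursor + gene_len > chrom_len:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ValueError(
                    f"cannot fit {n_genes} genes into the genome (placed {i})"
                )
            chrom, chrom_len = nxt
            cursor = int(rng.integers(*intergenic_gap_range))
        start = cursor
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        gid = f"SYNG{i:05d}"
        gene = GeneModel(
            gene_id=gid,
            symbol=f"SYM{i:05d}",
            chrom=chrom,
            start=start,
            end=pos,
            strand="+" if rng.random() < 0.5 else "-",
            exons=tuple(exons),
        )
        genes.append(gene)
        cursor = pos + int(rng.integers(*intergenic_gap_range))

        status = statuses[int(rng.choice(len(statuses), p=status_p))]
        gene_modes: frozenset[str] = frozenset()
        if status == "phenotype_linked":
            k = 1 + int(rng.random() < 0.15)  # a minority of genes carry two modes
            k = min(k, int((mode_p > 0).sum()))
            gene_modes = frozenset(
                rng.choice(modes, size=k, replace=False, p=mode_p).tolist()
            )
        annotations[gid] = GeneAnnotation(
            gene_id=gid,
            omim_status=status,
            inheritance_modes=gene_modes,
            orphanet_linked=bool(
                status == "phenotype_linked" and rng.random() < orphanet_rate
            ),
        )
    return genes, annotations


def _free_gaps(genome: Genome, genes: list[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    """Intergenic half-open gaps per contig (complement of the gene spans)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in genome.chroms:
        cursor = 0
        out = []
        for g in sorted(by_chrom.get(chrom, []), key=lambda g: g.start):
            if g.start > cursor:
                out.append((cursor, g.start))
            cursor = max(cursor, g.end)
        if cursor < length:
            out.append((cursor, length))
        gaps[chrom] = out
    return gaps


def _plant_one(
    kind: str,
    genes: list[GeneModel],
    gaps: dict[str, list[tuple[int, int]]],
    neighbors: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[str, int, int, str | None, str | None, bool | None]:
    """Construct coordinates realizing one planted kind; returns
    (chrom, start, end, gene_id, category, single_intron)."""
    for _ in range(200):  # rejection sampling over eligible genes/gaps
        if kind == "intergenic":
            chrom = rng.choice(list(gaps))
            cands = [g for g in gaps[chrom] if g[1] - g[0] >= 100]
            if not cands:
                continue
            lo, hi = cands[int(rng.integers(len(cands)))]
            start = int(rng.integers(lo, hi - 10))
            end = int(rng.integers(start + 1, min(hi, start + 5000) + 1))
            return chrom, start, end, None, None, None

        g = genes[int(rng.integers(len(genes)))]
        left, right = neighbors[g.gene_id]
        if kind == "intragenic_single_intron":
            introns = [iv for iv in g.introns if iv[1] - iv[0] >= 20]
            if not introns:
                continue
            s, e = introns[int(rng.integers(len(introns)))]
            start = int(rng.integers(s, e - 2))
            end = int(rng.integers(start + 2, e + 1))
            return g.chrom, start, end, g.gene_id, "intragenic", True
        if kind == "intragenic_multi":
            if len(g.introns) < 2:
                continue
            i = int(rng.integers(len(g.introns) - 1))
            (s1, e1), (s2, e2) = g.introns[i], g.introns[i + 1]
            start = int(rng.integers(s1, e1))
            end = int(rng.integers(s2 + 1, e2 + 1))
            return g.chrom, start, end, g.gene_id, "intragenic", False
        if kind == "gene_disrupting":
            room = right - g.end  # free run after the gene before the next one
            if room < 2:
                continue
            start = int(rng.integers(g.start, g.end))  # breakpoint inside gene
            end = int(rng.integers(g.end + 1, g.end + min(room, 50_000) + 1))
            return g.chrom, start, end, g.gene_id, "gene_disrupting", None
        if kind == "gene_spanning":
            room_l, room_r = g.start - left, right - g.end
            if room_l < 2 or room_r < 2:
                continue
            start = int(rng.integers(max(left, g.start - 50_000), g.start))
            end = int(rng.integers(g.end + 1, g.end + min(room_r, 50_000) + 1))
            return g.chrom, start, end, g.gene_id, "gene_spanning", None
        raise ValueError(f"unknown planted kind {kind!r}")
    raise ValueError(f"quota for {kind!r} is infeasible with this gene architecture")


def make_callset(
    profile: DatasetProfile,
    genes: list[GeneModel] | None = None,
    planted: dict[str, int] | None = None,
    seed: int = 0,
    genome: Genome | None = None,
) -> tuple[Callset, list[PlantedCall]]:
    """Draw a synthetic inversion callset, optionally planting labelled events.

    ``planted`` maps kinds (``gene_spanning``, ``gene_disrupting``,
    ``intragenic_single_intron``, ``intragenic_multi``, ``intergenic``) to
    quotas realized by construction against the gene architecture; any
    remaining calls up to ``profile.n_calls`` are background draws from the
    calibrated log-normal length model placed uniformly on the genome.
    Planted calls retain their intended labels for recovery testing.
    """
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    bad = set(planted) - set(PLANT_KINDS)
    if bad:
        raise ValueError(f"unknown planted kinds {sorted(bad)}")
    n_planted = sum(planted.values())
    if n_planted > profile.n_calls:
        raise ValueError(
            f"planted quota ({n_planted}) exceeds profile n_calls ({profile.n_calls})"
        )
    if n_planted and not genes:
        raise ValueError("planting categories requires a gene architecture")
    if genome is None:
        if genes:
            chroms = sorted({g.chrom for g in genes})
            genome = Genome(
                chroms=tuple(
                    (c, max(g.end for g in genes if g.chrom == c) + 1_000_000)
                    for c in chroms
                )
            )
        else:
            genome = make_genome(2, 10_000_000)
    genes = genes or []
    gaps = _free_gaps(genome, genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    neighbors: dict[str, tuple[int, int]] = {}
    for chrom, length in genome.chroms:
        row = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        for i, g in enumerate(row):
            left = row[i - 1].end if i > 0 else 0
            right = row[i + 1].start if i + 1 < len(row) else length
            neighbors[g.gene_id] = (left, right)

    calls: list[InversionCall] = []
    truth: list[PlantedCall] = []
    counters = {"total": 0, "dropped_type": 0, "dropped_contig": 0,
                "dropped_filter": 0, "malformed": 0}
    idx = 0

    def draw_af() -> tuple[float | None, int | None, str]:
        if not profile.with_af:
            return None, None, "unknown"
        if rng.random() < profile.prop_rare:
            lo, hi = profile.rare_af_range
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            af = min(af, np.nextafter(hi, 0))
            stratum = "rare"
        else:
            lo, hi = profile.common_af_range
            af = float(rng.uniform(lo, hi))
            stratum = "common"
        nh = 0 if rng.random() < profile.prop_homalt_zero else int(rng.integers(1, 5))
        return af, nh, stratum

    for kind in PLANT_KINDS:
        for _ in range(planted.get(kind, 0)):
            chrom, start, end, gid, category, single = _plant_one(
                kind, genes, gaps, neighbors, rng
            )
            af, nh, stratum = draw_af()
            call_id = f"{profile.label}_INV_{idx:05d}"
            idx += 1
            counters["total"] += 1
            calls.append(
                InversionCall(call_id, chrom, start, end, profile.label,
                              allele_frequency=af, n_homalt=nh)
            )
            truth.append(PlantedCall(call_id, kind, gid, category, single, stratum))

    chrom_names = [c for c, _ in genome.chroms]
    chrom_lens = np.array([l for _, l in genome.chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    n_background = profile.n_calls - n_planted
    bg_lengths = profile.draw_lengths(n_background, rng)
    for length in bg_lengths:
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        chrom, clen = chrom_names[ci], int(chrom_lens[ci])
        length = int(length)
        # events longer than the contig cannot exist on it: truncate the
        # length distribution by redrawing rather than clamping (a clamp
        # would pile identical whole-contig calls up as duplicates)
        while length >= clen:
            length = int(profile.draw_lengths(1, rng)[0])
        start = int(rng.integers(0, clen - length))
        af, nh, _ = draw_af()
        call_id = f"{profile.label}_INV_{idx:05d}"
        idx += 1
        counters["total"] += 1
        calls.append(
            InversionCall(call_id, chrom, start, start + length, profile.label,
                          allele_frequency=af, n_homalt=nh)
        )

    cs = harmonize_calls(
        profile.label,
        calls,
        counters,
        provenance={"source": "synthetic", "dialect": "simulated", "seed": seed,
                    "profile": profile.label},
    )
    planted_ids = {t.inversion_id for t in truth}
    kept_ids = {c.id for c in cs.calls}
    truth = [t for t in truth if t.inversion_id in kept_ids and t.inversion_id in planted_ids]
    return cs, truth


def write_gene_table(genes: list[GeneModel], annotations, path) -> Path:
    """Emit the genePred-style TSV consumed by ``gene_model.read_gene_table``."""
    path = Path(path)
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "biotype": "protein_coding",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_annotation_tables(
    annotations: dict[str, GeneAnnotation], omim_path, orphanet_path
) -> tuple[Path, Path]:
    """Emit OMIM genemap-style and Orphanet TSVs matching the join readers."""
    mode_names = {"AR": "Autosomal recessive", "AD": "Autosomal dominant",
                  "XLR": "X-linked recessive", "XLD": "X-linked dominant",
                  "other": "Other"}
    omim_rows, orpha_rows = [], []
    for gid in sorted(annotations):
        a = annotations[gid]
        if a.omim_status == "not_in_omim":
            continue
        if a.omim_status == "cataloged_no_phenotype":
            omim_rows.append({"gene_id": gid, "phenotype": "", "inheritance": ""})
        else:
            omim_rows.append(
                {
                    "gene_id": gid,
                    "phenotype": f"Synthetic phenotype of {gid}",
                    "inheritance": "; ".join(
                        mode_names[m] for m in sorted(a.inheritance_modes)
                    ),
                }
            )
        if a.orphanet_linked:
            orpha_rows.append({"gene_id": gid})
    pd.DataFrame(omim_rows, columns=["gene_id", "phenotype", "inheritance"]).to_csv(
        omim_path, sep="\t", index=False
    )
    pd.DataFrame(orpha_rows, columns=["gene_id"]).to_csv(
        orphanet_path, sep="\t", index=False
    )
    return Path(omim_path), Path(orphanet_path)


def write_vcf(cs: Callset, path, genome: Genome | None = None) -> Path:
    """Emit a symbolic-allele SV VCF re-readable by ``read_vcf_inversions``.

    POS anchors the first inverted base (1-based), END the last; AF and
    N_HOMALT go into INFO when present.
    """
    path = Path(path)
    contigs = (
        list(genome.chroms)
        if genome is not None
        else [(c, max((x.end for x in cs.calls if x.chrom == c), default=1))
              for c in sorted({x.chrom for x in cs.calls})]
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh38\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=N_HOMALT,Number=1,Type=Integer,Description="Hom-alt count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in cs.calls:
            info = [f"SVTYPE=INV", f"END={c.end}", f"SVLEN={c.length}"]
            if c.allele_frequency is not None:
                info.append(f"AF={c.allele_frequency:.10g}")
            if c.n_homalt is not None:
                info.append(f"N_HOMALT={c.n_homalt}")
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t{c.id}\tN\t<INV>\t.\tPASS\t{';'.join(info)}\n"
            )
    return path
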