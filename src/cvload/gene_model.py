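"""Disease-gene region sets from a GTF plus curated gene lists.

Genes implicated in common, Mendelian and congenital forms of a disease are
looked up by symbol in a GENCODE-dialect GTF, extended by a promoter flank
(default 2000 bp on each side), and used both to subset variants and to label
variant positions with a genic region (exonic/UTR/upstream/downstream/
intronic/intergenic).

Coordinates are 1-based inclusive throughout (the GTF/VCF convention);
conversion to 0-based half-open happens only in the BED exporter.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from gffutils.feature import feature_from_line

CATEGORIES = ("common", "mendelian", "congenital")

#: Region labels in decreasing precedence; a position matching several
#: feature classes gets the first one. "intergenic" means outside the
#: flank-extended region.
REGION_PRECEDENCE = ("exonic", "UTR5", "UTR3", "upstream", "downstream", "intronic")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, line: str, why: str = "malformed GTF line"):
        self.lineno = lineno
        super().__init__(f"{why} at line {lineno}: {line[:120]!r}")


class NoGenesError(ValueError):
    """No gene from the supplied lists was found in the GTF."""


@dataclass
class GeneRegion:
    """A disease-annotated gene with its coding/UTR sub-structure.

    ``exons`` holds the coding (CDS) intervals when the GTF provides CDS
    features, otherwise the plain exon intervals; ``utr5``/``utr3`` hold the
    untranslated intervals. All intervals are 1-based inclusive and lie
    within [start, end].
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    categories: frozenset[str] = frozenset()
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start {self.start} > end {self.end}")
        for name in ("exons", "utr5", "utr3"):
            for lo, hi in getattr(self, name):
                if not (self.start <= lo <= hi <= self.end):
                    raise ValueError(
                        f"gene {self.symbol}: {name} interval ({lo},{hi}) "
                        f"outside gene body ({self.start},{self.end})"
                    )


@dataclass(frozen=True)
class AnalysisRegion:
    """A gene body extended by ``flank`` bp each side, clipped at position 1."""

    gene_id: str
    symbol: str
    chrom: str
    start_ext: int
    end_ext: int
    flank: int


@dataclass
class GeneModel:
    """Result of matching gene lists against a GTF."""

    genes: list[GeneRegion]
    #: per category, the list symbols not found in the GTF (reported, never fabricated)
    missing: dict[str, list[str]]

    def __iter__(self):
        return iter(self.genes)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so GENCODE ('chr1') and VCF ('1') naming agree."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


_UTR5_TYPES = {"five_prime_utr", "5utr"}
_UTR3_TYPES = {"three_prime_utr", "3utr"}


def parse_gene_model(
    gtf_source,
    gene_lists: Mapping[str, set[str]],
    aliases: Mapping[str, str] | None = None,
) -> GeneModel:
    """Build :class:`GeneRegion` objects for every listed gene found in the GTF.

    Parameters
    ----------
    gtf_source
        Path, GTF text, open handle, or iterable of GTF lines (GENCODE dialect).
    gene_lists
        Mapping category -> set of gene symbols. A gene on several lists gets
        the union of category labels and appears once.
    aliases
        Optional symbol alias table (alias -> canonical symbol) applied to GTF
        symbols before matching.
    """
    for cat in gene_lists:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown gene-list category {cat!r}; expected {CATEGORIES}")
    if not gene_lists or all(not s for s in gene_lists.values()):
        raise ValueError("gene lists are empty")
    aliases = aliases or {}
    wanted: dict[str, set[str]] = {}
    for cat, symbols in gene_lists.items():
        for sym in symbols:
            wanted.setdefault(sym, set()).add(cat)

    # first pass: collect per-symbol gene span and sub-features
    spans: dict[str, dict] = {}
    for lineno, raw in enumerate(_iter_lines(gtf_source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise GtfParseError(lineno, line, "expected 9 tab-separated columns")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise GtfParseError(lineno, line, str(exc)) from exc
        attrs = feat.attributes
        symbol = (attrs.get("gene_name") or attrs.get("gene_id") or [None])[0]
        if symbol is None:
            raise GtfParseError(lineno, line, "no gene_name/gene_id attribute")
        symbol = aliases.get(symbol, symbol)
        if symbol not in wanted:
            continue
        entry = spans.setdefault(
            symbol,
            {
                "gene_id": (attrs.get("gene_id") or [symbol])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "gene_span": None,
                "exon": [],
                "cds": [],
                "utr": [],
                "utr5": [],
                "utr3": [],
                "lo": feat.start,
                "hi": feat.end,
            },
        )
        entry["lo"] = min(entry["lo"], feat.start)
        entry["hi"] = max(entry["hi"], feat.end)
        ftype = feat.featuretype.lower()
        iv = (feat.start, feat.end)
        if ftype == "gene":
            entry["gene_span"] = iv
            entry["gene_id"] = (attrs.get("gene_id") or [entry["gene_id"]])[0]
        elif ftype == "exon":
            entry["exon"].append(iv)
        elif ftype == "cds":
            entry["cds"].append(iv)
        elif ftype == "utr":
            entry["utr"].append(iv)
        elif ftype in _UTR5_TYPES:
            entry["utr5"].append(iv)
        elif ftype in _UTR3_TYPES:
            entry["utr3"].append(iv)

    genes: list[GeneRegion] = []
    for symbol, entry in spans.items():
        start, end = entry["gene_span"] or (entry["lo"], entry["hi"])
        coding = sorted(set(entry["cds"]))
        exons = coding if coding else sorted(set(entry["exon"]))
        utr5 = sorted(set(entry["utr5"]))
        utr3 = sorted(set(entry["utr3"]))
        # generic GENCODE "UTR" features: orient against the CDS span
        if entry["utr"] and coding:
            cds_lo = min(lo for lo, _ in coding)
            cds_hi = max(hi for _, hi in coding)
            for lo, hi in sorted(set(entry["utr"])):
                if hi < cds_lo:
                    (utr5 if entry["strand"] == "+" else utr3).append((lo, hi))
                elif lo > cds_hi:
                    (utr3 if entry["strand"] == "+" else utr5).append((lo, hi))
        genes.append(
            GeneRegion(
                gene_id=entry["gene_id"],
                symbol=symbol,
                chrom=entry["chrom"],
                start=start,
                end=end,
                strand=entry["strand"],
                categories=frozenset(wanted[symbol]),
                exons=exons,
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    genes.sort(key=lambda g: (normalize_chrom(g.chrom), g.start, g.symbol))

    found = {g.symbol for g in genes}
    missing = {
        cat: sorted(s for s in symbols if s not in found)
        for cat, symbols in gene_lists.items()
    }
    if not genes:
        raise NoGenesError(
            "no genes from the supplied lists were found in the GTF "
            f"(missing: {sum(len(v) for v in missing.values())} symbols)"
        )
    return GeneModel(genes=genes, missing=missing)


def extend_regions(genes: Sequence[GeneRegion], flank: int = 2000) -> list[AnalysisRegion]:
    """Extend each gene body by ``flank`` bp per side (promoter capture).

    Overlapping extended regions are intentionally NOT merged: a variant
    falling in two genes' regions is attributed to both genes.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    return [
        AnalysisRegion(
            gene_id=g.gene_id,
            symbol=g.symbol,
            chrom=g.chrom,
            start_ext=max(1, g.start - flank),
            end_ext=g.end + flank,
            flank=flank,
        )
        for g in genes
    ]


def classify_region(pos: int, gene: GeneRegion, flank: int = 2000) -> str:
    """Label a position relative to one gene.

    Precedence when feature intervals overlap:
    exonic (CDS) > UTR5 > UTR3 > upstream > downstream > intronic.
    Upstream/downstream are the flank windows on the strand-appropriate side;
    anything outside the extended region is intergenic. Total function.
    """
    start_ext = max(1, gene.start - flank)
    end_ext = gene.end + flank
    if pos < start_ext or pos > end_ext:
        return "intergenic"
    if any(lo <= pos <= hi for lo, hi in gene.exons):
        return "exonic"
    if any(lo <= pos <= hi for lo, hi in gene.utr5):
        return "UTR5"
    if any(lo <= pos <= hi for lo, hi in gene.utr3):
        return "UTR3"
    before = pos < gene.start  # in the low-coordinate flank window
    after = pos > gene.end
    if before or after:
        if gene.strand == "-":
            return "upstream" if after else "downstream"
        return "upstream" if before else "downstream"
    return "intronic"


def classify_variants(
    positions: Iterable[tuple[str, int]],
    genes: Sequence[GeneRegion],
    flank: int = 2000,
) -> dict[tuple[str, int], str]:
    """Best (highest-precedence) region label per (chrom, pos) across all genes.

    Variant-level counts deduplicate by variant, so a position in two genes'
    regions contributes one label: the most specific one any gene assigns.
    """
    rank = {label: i for i, label in enumerate(REGION_PRECEDENCE)}
    rank["intergenic"] = len(rank)
    by_chrom: dict[str, list[GeneRegion]] = {}
    for g in genes:
        by_chrom.setdefault(normalize_chrom(g.chrom), []).append(g)
    out: dict[tuple[str, int], str] = {}
    for chrom, pos in positions:
        best = "intergenic"
        for g in by_chrom.get(normalize_chrom(chrom), []):
            label = classify_region(pos, g, flank)
            if rank[label] < rank[best]:
                best = label
        out[(chrom, pos)] = best
    return out


def count_gene_overlaps(genes: Sequence[GeneRegion]) -> dict[str, int]:
    """Seven-part Venn counts of gene membership over the three disease lists.

    The regions are disjoint and sum to the number of distinct genes with a
    non-empty category set.
    """
    keys = {
        frozenset({"common"}): "common_only",
        frozenset({"mendelian"}): "mendelian_only",
        frozenset({"congenital"}): "congenital_only",
        frozenset({"common", "mendelian"}): "common_mendelian",
        frozenset({"common", "congenital"}): "common_congenital",
        frozenset({"mendelian", "congenital"}): "mendelian_congenital",
        frozenset(CATEGORIES): "common_mendelian_congenital",
    }
    counts = {name: 0 for name in keys.values()}
    for g in genes:
        cats = frozenset(g.categories)
        if not cats:
            continue
        counts[keys[cats]] += 1
    return counts


_HEADER_RE = re.compile(r"^#\s*category\s*[:=]\s*(\w+)", re.IGNORECASE)


def read_gene_list(source) -> tuple[str, set[str]]:
    """Read a one-symbol-per-line gene list with a ``# category: NAME`` header."""
    category = None
    symbols: set[str] = set()
    for line in _iter_lines(source):
        line = line.strip()
        if not line:
            continue
        m = _HEADER_RE.match(line)
        if m:
            category = m.group(1).lower()
            continue
        if line.startswith("#"):
            continue
        symbols.add(line.split()[0])
    if category is None:
        raise ValueError("gene list lacks a '# category: NAME' header")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    return category, symbols


def read_gene_lists(sources: Iterable) -> dict[str, set[str]]:
    lists: dict[str, set[str]] = {}
    for src in sources:
        cat, symbols = read_gene_list(src)
        lists.setdefault(cat, set()).update(symbols)
    return lists


def regions_to_bed(regions: Sequence[AnalysisRegion], out: TextIO) -> None:
    """Export as BED (0-based half-open; the only place coordinates convert)."""
    for r in regions:
        out.write(f"{r.chrom}\t{r.start_ext - 1}\t{r.end_ext}\t{r.symbol}\n")


def regions_to_tsv(regions: Sequence[AnalysisRegion], genes: Sequence[GeneRegion], out: TextIO) -> None:
    cats = {g.gene_id: ",".join(sorted(g.categories)) for g in genes}
    out.write("gene_id\tsymbol\tchrom\tstart_ext\tend_ext\tcategories\n")
    for r in regions:
        out.write(
            f"{r.gene_id}\t{r.symbol}\t{r.chrom}\t{r.start_ext}\t{r.end_ext}\t{cats.get(r.gene_id, '')}\n"
        )
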