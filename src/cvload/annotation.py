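"""Predictor scores, consequence terms and ClinVar significance for variants.

The deleteriousness consensus follows the three-tool convention: a missense
SNV is "combinedly predicted deleterious" (a dSNV) when SIFT < 0.05 (strict),
PolyPhen-2 HDIV > 0.957 (strict) and CADD phred >= 15 (inclusive) all hold.
A missing score never supports a call: the conjunction fails on absent
evidence.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_model import normalize_chrom
from .variant_store import GenotypeMatrix, VariantKey

log = logging.getLogger(__name__)

#: Loss-of-function consequence classes (Sequence Ontology terms). The list
#: is exhaustive: splice_region_variant, for instance, is not LoF.
LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: ANNOVAR-style labels translated to Sequence Ontology terms.
CONSEQUENCE_ALIASES: dict[str, str] = {
    "nonsynonymous snv": "missense_variant",
    "nonsynonymous_snv": "missense_variant",
    "synonymous snv": "synonymous_variant",
    "synonymous_snv": "synonymous_variant",
    "stopgain": "stop_gained",
    "stoploss": "stop_lost",
    "startloss": "start_lost",
    "frameshift substitution": "frameshift_variant",
    "frameshift change": "frameshift_variant",
    "splicing": "splice_acceptor_variant",
}


def normalize_consequence(term: str | None, extra: Mapping[str, str] | None = None) -> str | None:
    if term is None:
        return None
    key = term.strip().lower()
    if extra and key in {k.lower(): v for k, v in extra.items()}:
        return {k.lower(): v for k, v in extra.items()}[key]
    return CONSEQUENCE_ALIASES.get(key, key)


@dataclass(frozen=True)
class Thresholds:
    """Consensus cutoffs: SIFT strict below, PolyPhen strict above, CADD inclusive."""

    sift_max: float = 0.05
    polyphen_min: float = 0.957
    cadd_min: float = 15.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class AnnotationRecord:
    key: VariantKey
    sift: float | None = None
    polyphen_hdiv: float | None = None
    cadd_phred: float | None = None
    consequence: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score out of [0,1]: {self.sift}")
        if self.polyphen_hdiv is not None and not 0.0 <= self.polyphen_hdiv <= 1.0:
            raise ValueError(f"PolyPhen HDIV score out of [0,1]: {self.polyphen_hdiv}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD phred score negative: {self.cadd_phred}")


@dataclass
class DeleteriousnessVerdict:
    key: VariantKey
    sift_call: bool
    polyphen_call: bool
    cadd_call: bool
    combined: bool
    is_lof: bool
    consequence: str | None = None


@dataclass
class ClinVarRecord:
    key: VariantKey
    significances: list[str]
    diseases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.significances:
            raise ValueError(f"ClinVar record {self.key} has no significance terms")


class DuplicateAnnotationError(ValueError):
    """The annotation table repeats a variant key with conflicting scores."""


def _read_table(source, columns: Sequence[str]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, Path)) and "\n" in str(source):
        df = pd.read_csv(io.StringIO(str(source)), sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    return df


def read_annotation_table(source) -> pd.DataFrame:
    """TSV with header chrom, pos, ref, alt, sift, polyphen_hdiv, cadd_phred,
    consequence, gene_id; empty fields mean "score absent"."""
    return _read_table(
        source,
        ["chrom", "pos", "ref", "alt", "sift", "polyphen_hdiv", "cadd_phred", "consequence"],
    )


def _variant_keys(variants) -> list[VariantKey]:
    if isinstance(variants, GenotypeMatrix):
        return list(variants.variants)
    return list(variants)


def join_annotations(
    variants,
    annotations,
    consequence_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Left-join predictor scores onto variants by exact (chrom, pos, ref, alt).

    The join is strict on alleles: a table row with REF/ALT swapped relative
    to the VCF does not match. Unannotated variants are kept with all scores
    absent; join statistics are logged.
    """
    keys = _variant_keys(variants)
    df = read_annotation_table(annotations)

    def score(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    table: dict[tuple, tuple] = {}
    dupes: list[tuple] = []
    for row in df.itertuples(index=False):
        k = (row.chrom, int(row.pos), str(row.ref), str(row.alt))
        payload = (
            score(row.sift),
            score(row.polyphen_hdiv),
            score(row.cadd_phred),
            normalize_consequence(None if pd.isna(row.consequence) else str(row.consequence), consequence_map),
            getattr(row, "gene_id", None),
        )
        if k in table and table[k][:4] != payload[:4]:
            dupes.append(k)
        table[k] = payload
    if dupes:
        raise DuplicateAnnotationError(
            f"conflicting duplicate annotation keys: {sorted(set(dupes))[:10]}"
        )

    records: list[AnnotationRecord] = []
    matched = 0
    for key in keys:
        hit = table.get((normalize_chrom(key.chrom), key.pos, key.ref, key.alt))
        if hit is None:
            records.append(AnnotationRecord(key=key))
        else:
            matched += 1
            sift, poly, cadd, cons, gene = hit
            gene = None if gene is None or (isinstance(gene, float) and math.isnan(gene)) else str(gene)
            records.append(
                AnnotationRecord(
                    key=key, sift=sift, polyphen_hdiv=poly, cadd_phred=cadd,
                    consequence=cons, gene_id=gene,
                )
            )
    log.info(
        "join_annotations: %d/%d variants annotated (%d unmatched)",
        matched, len(keys), len(keys) - matched,
    )
    return records


def classify_deleterious(
    record: AnnotationRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> DeleteriousnessVerdict:
    """Apply the three per-tool cutoffs and the consensus conjunction.

    ``combined`` additionally requires a missense consequence — SIFT and
    PolyPhen only score amino-acid substitutions, so the consensus is only
    defined there.
    """
    sift_call = record.sift is not None and record.sift < thresholds.sift_max
    polyphen_call = (
        record.polyphen_hdiv is not None and record.polyphen_hdiv > thresholds.polyphen_min
    )
    cadd_call = record.cadd_phred is not None and record.cadd_phred >= thresholds.cadd_min
    consequence = normalize_consequence(record.consequence)
    combined = (
        sift_call and polyphen_call and cadd_call and consequence == "missense_variant"
    )
    return DeleteriousnessVerdict(
        key=record.key,
        sift_call=sift_call,
        polyphen_call=polyphen_call,
        cadd_call=cadd_call,
        combined=combined,
        is_lof=consequence in LOF_CONSEQUENCES,
        consequence=consequence,
    )


def predictor_venn(verdicts: Iterable[DeleteriousnessVerdict]) -> dict[str, int]:
    """Seven-part Venn of per-tool deleterious calls.

    CADD scores every variant (including non-coding ones), so CADD-only
    regions are expected to dominate; SIFT/PolyPhen call only where scored.
    Regions are disjoint and sum to the number of variants with >= 1 call.
    """
    counts = {
        "sift_only": 0,
        "polyphen_only": 0,
        "cadd_only": 0,
        "sift_polyphen": 0,
        "sift_cadd": 0,
        "polyphen_cadd": 0,
        "all_three": 0,
    }
    names = {
        frozenset({"s"}): "sift_only",
        frozenset({"p"}): "polyphen_only",
        frozenset({"c"}): "cadd_only",
        frozenset({"s", "p"}): "sift_polyphen",
        frozenset({"s", "c"}): "sift_cadd",
        frozenset({"p", "c"}): "polyphen_cadd",
        frozenset({"s", "p", "c"}): "all_three",
    }
    for v in verdicts:
        calls = frozenset(
            t for t, on in (("s", v.sift_call), ("p", v.polyphen_call), ("c", v.cadd_call)) if on
        )
        if calls:
            counts[names[calls]] += 1
    return counts


def classify_lof(record: AnnotationRecord | str | None) -> bool:
    """True iff the consequence is one of the loss-of-function classes."""
    term = record.consequence if isinstance(record, AnnotationRecord) else record
    return normalize_consequence(term) in LOF_CONSEQUENCES


_SIG_SPLIT = re.compile(r"[|/;,]")


def canonical_significance(term: str) -> str:
    """Canonical ClinVar significance: lower-case, spaces -> underscores."""
    return re.sub(r"\s+", "_", term.strip().lower())


def parse_significance(text: str) -> list[str]:
    """Split a multi-significance string on | / ; , and canonicalize terms."""
    return [canonical_significance(t) for t in _SIG_SPLIT.split(text) if t.strip()]


def read_clinvar_table(source) -> list[ClinVarRecord]:
    """TSV with chrom, pos, ref, alt, clnsig, disease."""
    df = _read_table(source, ["chrom", "pos", "ref", "alt", "clnsig"])
    records = []
    for row in df.itertuples(index=False):
        diseases = []
        raw = getattr(row, "disease", None)
        if raw is not None and not pd.isna(raw):
            diseases = [d.strip() for d in _SIG_SPLIT.split(str(raw)) if d.strip()]
        records.append(
            ClinVarRecord(
                key=VariantKey(normalize_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt)),
                significances=parse_significance(str(row.clnsig)),
                diseases=diseases,
            )
        )
    return records


def clinvar_filter(
    records: Iterable[ClinVarRecord],
    keep: Iterable[str] = ("Pathogenic", "Likely_pathogenic"),
) -> list[ClinVarRecord]:
    """Keep records with ANY significance in ``keep`` (case-insensitive).

    A record with multiple significances passes once; all its diseases stay
    attached so multi-disease hits remain reportable.
    """
    wanted = {canonical_significance(t) for t in keep}
    return [r for r in records if wanted.intersection(parse_significance("|".join(r.significances)))]
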