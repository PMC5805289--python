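"""Ancestral/derived polarization and derived allele frequencies (DAF).

The ancestral state (e.g. from a human-chimpanzee ancestor alignment) is
consumed as a table keyed by chrom/pos/ref/alt. When the ancestral base
equals REF the derived allele is ALT and DAF is the alt frequency; when it
equals ALT the orientation flips (DAF = 1 - alt AF). Sites whose ancestral
base is unknown or matches neither allele are kept but carry no DAF and are
tallied in an exclusion report.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .gene_model import normalize_chrom
from .variant_store import AlleleCounts, VariantKey

_BASES = frozenset("ACGT")

#: DAF bin edges: rare below 0.5%, low for 0.5%..5% inclusive, common above 5%.
RARE_MAX = 0.005
COMMON_MIN = 0.05


@dataclass
class PolarizedVariant:
    """A variant with derived-allele orientation and per-population DAF.

    ``daf`` is None for populations with no called chromosomes and for the
    whole variant when polarization failed (``status`` != "ok"). Counts obey
    derived + ancestral = called chromosomes in every population.
    """

    key: VariantKey
    ancestral: str | None
    derived: str | None
    status: str  # ok | unknown_ancestral | mismatch
    daf: dict[str, float | None] = field(default_factory=dict)
    derived_count: dict[str, int] = field(default_factory=dict)
    called: dict[str, int] = field(default_factory=dict)
    hom_derived: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class PolarizationResult:
    variants: list[PolarizedVariant]
    exclusions: Counter

    def defined(self) -> list[PolarizedVariant]:
        return [v for v in self.variants if v.ok]

    def __iter__(self):
        return iter(self.variants)


def read_ancestral_table(source) -> dict[tuple[str, int, str, str], str]:
    """TSV with chrom, pos, ref, alt, ancestral_base."""
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)) and "\n" in str(source):
        df = pd.read_csv(io.StringIO(str(source)), sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        out[(normalize_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt))] = str(
            row.ancestral_base
        )
    return out


def _clean_base(base: str | None) -> str | None:
    """Upper-case; anything outside ACGT (N, -, ambiguity codes) -> unknown."""
    if base is None:
        return None
    base = str(base).strip().upper()
    return base if base in _BASES else None


def polarize(
    counts: AlleleCounts,
    ancestral: Mapping[tuple[str, int, str, str], str] | Mapping[VariantKey, str],
) -> PolarizationResult:
    """Orient every variant to its derived allele and compute per-population DAF."""
    table: dict[tuple[str, int, str, str], str | None] = {}
    for k, v in ancestral.items():
        if isinstance(k, VariantKey):
            k = (normalize_chrom(k.chrom), k.pos, k.ref, k.alt)
        else:
            k = (normalize_chrom(k[0]), int(k[1]), k[2], k[3])
        table[k] = v

    out: list[PolarizedVariant] = []
    exclusions: Counter = Counter()
    af = counts.af
    for i, key in enumerate(counts.variants):
        anc = _clean_base(table.get((normalize_chrom(key.chrom), key.pos, key.ref, key.alt)))
        if anc is None:
            status, derived = "unknown_ancestral", None
        elif anc == key.ref:
            status, derived = "ok", key.alt
        elif anc == key.alt:
            status, derived = "ok", key.ref
        else:
            status, derived = "mismatch", None
        pv = PolarizedVariant(key=key, ancestral=anc, derived=derived, status=status)
        for pi, pop in enumerate(counts.populations):
            an = int(counts.an[i, pi])
            n_called = an // 2
            pv.called[pop] = an
            if status != "ok":
                pv.daf[pop] = None
                continue
            if an == 0:
                pv.daf[pop] = None
                pv.derived_count[pop] = 0
                pv.hom_derived[pop] = 0
                continue
            if derived == key.alt:
                dc = int(counts.alt_count[i, pi])
                hom = int(counts.hom_alt[i, pi])
            else:
                dc = an - int(counts.alt_count[i, pi])
                hom = n_called - int(counts.hom_alt[i, pi]) - int(counts.het[i, pi])
            pv.derived_count[pop] = dc
            pv.hom_derived[pop] = hom
            pv.daf[pop] = dc / an
        if status != "ok":
            exclusions[status] += 1
        out.append(pv)
    return PolarizationResult(variants=out, exclusions=exclusions)


def daf_bin(daf: float) -> str:
    """Assign a DAF to the rare (<0.5%), low (0.5%..5%) or common (>5%) bin."""
    if not 0.0 <= daf <= 1.0:
        raise ValueError(f"DAF out of [0,1]: {daf}")
    if daf < RARE_MAX:
        return "rare"
    if daf <= COMMON_MIN:
        return "low"
    return "common"


def polarized_to_tsv(result: PolarizationResult, populations: list[str], out) -> None:
    cols = "\t".join(f"daf_{p}" for p in populations)
    out.write(f"chrom\tpos\tref\talt\tancestral\tderived\tstatus\t{cols}\n")
    for v in result.variants:
        dafs = "\t".join(
            "." if v.daf.get(p) is None else f"{v.daf[p]:.6g}" for p in populations
        )
        out.write(
            f"{v.key.chrom}\t{v.key.pos}\t{v.key.ref}\t{v.key.alt}\t"
            f"{v.ancestral or '.'}\t{v.derived or '.'}\t{v.status}\t{dafs}\n"
        )
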