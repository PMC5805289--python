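"""Multi-sample VCF access: region subsetting, SNV filtering, allele counts.

Records are decomposed to one biallelic record per ALT allele before any
filtering, genotypes become alt-allele dosages in {0, 1, 2} with -1 for
missing (half-calls such as ./1 count as missing), and per-population allele
counts are tallied over called chromosomes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .gene_model import AnalysisRegion, normalize_chrom

log = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")


class MissingGenotypesError(ValueError):
    """The VCF carries no GT FORMAT field."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a decomposed variant record; rsID does not affect equality."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = field(default=".", compare=False)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != self.alt
            and self.ref in _BASES
            and self.alt in _BASES
        )


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages, variants x samples, int8 with -1 = missing."""

    variants: list[VariantKey]
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,-1}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def select_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            [self.variants[i] for i in idx], list(self.samples), self.dosages[idx]
        )

    def select_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in samples]
        return GenotypeMatrix(list(self.variants), list(samples), self.dosages[:, idx])


@dataclass
class PopulationPanel:
    """Sample -> population assignment with a declared population order."""

    assignments: dict[str, str]
    populations: list[str]

    @classmethod
    def from_mapping(cls, assignments: Mapping[str, str], populations: Sequence[str] | None = None):
        pops = list(populations) if populations else sorted(set(assignments.values()))
        extra = set(assignments.values()) - set(pops)
        if extra:
            raise ValueError(f"samples assigned to undeclared populations: {sorted(extra)}")
        return cls(dict(assignments), pops)

    @classmethod
    def from_tsv(cls, path, populations: Sequence[str] | None = None):
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("sample\t"):
                    continue
                sample, pop = line.split("\t")[:2]
                if sample in assignments:
                    raise ValueError(f"sample {sample} listed twice in panel")
                assignments[sample] = pop
        return cls.from_mapping(assignments, populations)

    def samples_for(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments


def _region_trees(regions: Sequence[AnalysisRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # IntervalTree is half-open; +1 keeps end_ext inclusive
        trees.setdefault(normalize_chrom(r.chrom), IntervalTree()).addi(
            r.start_ext, r.end_ext + 1, r.gene_id
        )
    return trees


def subset_vcf(
    vcf_source,
    regions: Sequence[AnalysisRegion],
    panel: PopulationPanel | None = None,
) -> GenotypeMatrix:
    """Load records whose POS falls inside at least one analysis region.

    Multiallelic records are split into one biallelic record per ALT before
    any downstream filter; samples are restricted to the panel when given.
    Bounds are inclusive on both ends.
    """
    trees = _region_trees(regions)
    with pysam.VariantFile(str(vcf_source)) as vcf:
        if "GT" not in vcf.header.formats:
            raise MissingGenotypesError(f"{vcf_source}: VCF has no GT FORMAT field")
        vcf_samples = list(vcf.header.samples)
        if panel is not None:
            samples = [s for s in vcf_samples if s in panel]
            dropped = len(vcf_samples) - len(samples)
            if dropped:
                log.info("subset_vcf: %d VCF samples not in panel dropped", dropped)
        else:
            samples = vcf_samples
        sample_idx = [vcf_samples.index(s) for s in samples]

        keys: list[VariantKey] = []
        rows: list[np.ndarray] = []
        seen_chroms: set[str] = set()
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            seen_chroms.add(chrom)
            tree = trees.get(chrom)
            if tree is None or not tree.overlaps(rec.pos):
                continue
            gts = [rec.samples[vcf_samples[i]].get("GT") for i in sample_idx]
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                row = np.full(len(samples), MISSING, dtype=np.int8)
                for j, gt in enumerate(gts):
                    if gt is None or any(a is None for a in gt):
                        continue  # half-calls and ./. are missing
                    row[j] = sum(1 for a in gt if a == ai)
                keys.append(
                    VariantKey(
                        chrom=chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        id=rec.id or ".",
                    )
                )
                rows.append(row)
    missing_chroms = set(trees) - seen_chroms
    for chrom in sorted(missing_chroms):
        log.warning("subset_vcf: region chromosome %s absent from VCF (zero records)", chrom)
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(keys, samples, dosages)


def filter_snv(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep biallelic single-base substitutions; log the removed count."""
    mask = np.array([k.is_snv for k in matrix.variants], dtype=bool)
    removed = int((~mask).sum())
    if removed:
        log.info("filter_snv: removed %d non-SNV records (indels/MNVs)", removed)
    return matrix.select_variants(mask)


@dataclass
class AlleleCounts:
    """Per (variant, population) allele and genotype tallies.

    Arrays are variants x populations. ``an`` counts called chromosomes
    (missing genotypes excluded); ``af`` is NaN wherever a population has no
    called chromosomes at a site — never a 0/0.
    """

    variants: list[VariantKey]
    populations: list[str]
    alt_count: np.ndarray
    an: np.ndarray
    hom_alt: np.ndarray
    het: np.ndarray
    pop_sizes: dict[str, int]

    @property
    def af(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.an > 0, self.alt_count / np.maximum(self.an, 1), np.nan)

    @property
    def n_called(self) -> np.ndarray:
        """Called diploid samples per (variant, population)."""
        return self.an // 2

    @property
    def hom_ref(self) -> np.ndarray:
        return self.n_called - self.hom_alt - self.het

    @property
    def monomorphic(self) -> np.ndarray:
        """True where the cohort shows no variation at all (cohort AF 0 or 1)."""
        total_alt = self.alt_count.sum(axis=1)
        total_an = self.an.sum(axis=1)
        return (total_alt == 0) | (total_alt == total_an)

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)


def allele_counts(matrix: GenotypeMatrix, panel: PopulationPanel) -> AlleleCounts:
    """Tally alt alleles, called chromosomes, and genotype classes per population."""
    unassigned = [s for s in matrix.samples if s not in panel]
    if unassigned:
        raise KeyError(f"samples not covered by panel: {unassigned[:5]}")
    pops = panel.populations
    nv = matrix.n_variants
    alt = np.zeros((nv, len(pops)), dtype=np.int64)
    an = np.zeros_like(alt)
    hom = np.zeros_like(alt)
    het = np.zeros_like(alt)
    sizes: dict[str, int] = {}
    for pi, pop in enumerate(pops):
        cols = [i for i, s in enumerate(matrix.samples) if panel.assignments[s] == pop]
        sizes[pop] = len(cols)
        if not cols:
            continue
        d = matrix.dosages[:, cols]
        called = d != MISSING
        alt[:, pi] = np.where(called, d, 0).sum(axis=1)
        an[:, pi] = 2 * called.sum(axis=1)
        hom[:, pi] = (d == 2).sum(axis=1)
        het[:, pi] = (d == 1).sum(axis=1)
    return AlleleCounts(
        variants=list(matrix.variants),
        populations=list(pops),
        alt_count=alt,
        an=an,
        hom_alt=hom,
        het=het,
        pop_sizes=sizes,
    )


def matrix_to_tsv(matrix: GenotypeMatrix, out) -> None:
    """Dosage matrix as TSV (variants as rows); '.' marks missing."""
    out.write("chrom\tpos\tref\talt\tid\t" + "\t".join(matrix.samples) + "\n")
    for key, row in zip(matrix.variants, matrix.dosages):
        vals = "\t".join("." if v == MISSING else str(int(v)) for v in row)
        out.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{key.id}\t{vals}\n")


def matrix_to_vcf(matrix: GenotypeMatrix, out) -> None:
    """Minimal VCF 4.2 round-trip export (GT-only FORMAT, unphased)."""
    out.write("##fileformat=VCFv4.2\n")
    for chrom in dict.fromkeys(k.chrom for k in matrix.variants):
        out.write(f"##contig=<ID={chrom}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
        + "\n"
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for key, row in zip(matrix.variants, matrix.dosages):
        gts = "\t".join(gt_map[int(v)] for v in row)
        out.write(
            f"{key.chrom}\t{key.pos}\t{key.id}\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gts}\n"
        )
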