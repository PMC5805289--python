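"""Self-contained multi-population synthetic cohorts with known ground truth.

Population allele frequencies follow the Balding-Nichols drift model: around
an ancestral frequency p, each population draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p and whose expected pairwise
Weir-Cockerham theta is F. Diploid genotypes are then binomial draws from the
population frequency. The generator emits a complete input bundle — VCF,
sample panel, predictor-score table, ancestral-allele table, ClinVar-style
table, GTF and gene lists — all cross-referenced by chrom/pos/ref/alt, plus
a ground-truth table for exact-recovery tests.

Every file kind draws from its own RNG stream derived from the master seed,
so e.g. changing ClinVar planting never perturbs genotypes. A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .gene_model import GeneRegion, classify_region

_BASES = np.array(list("ACGT"))

_LOF_TERMS = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "frameshift_variant",
)

_NONCODING_TERM = {
    "UTR5": "5_prime_UTR_variant",
    "UTR3": "3_prime_UTR_variant",
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
    "intronic": "intron_variant",
    "intergenic": "intergenic_variant",
}

_DISEASES = (
    "synthetic_dilated_cardiomyopathy",
    "synthetic_long_QT_syndrome",
    "synthetic_atrioventricular_septal_defect",
    "synthetic_hypertrophic_cardiomyopathy",
)

# RNG stream ids (master seed + id -> independent stream per file kind)
_STREAM_LAYOUT = 0
_STREAM_FREQ = 1
_STREAM_GENO = 2
_STREAM_ANNOT = 3
_STREAM_CLINVAR = 4


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_individuals: int
    fst: float  # Balding-Nichols drift parameter F

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"drift F must lie in (0,1), got {self.fst}")
        if self.n_individuals < 1:
            raise ValueError("population needs at least one individual")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults describe the reference conditions used throughout the test
    suite: two populations of 50 diploids drifted at F = 0.1 over 5000 sites
    in six disease genes, 10% of sites consensus-deleterious, 2% LoF, 2% of
    sites private per population, five pathogenic/likely-pathogenic ClinVar
    plants.
    """

    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("POP1", 50, 0.1),
        PopulationSpec("POP2", 50, 0.1),
    )
    n_sites: int = 5000
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    deleterious_fraction: float = 0.1
    lof_fraction: float = 0.02
    clinvar_pathogenic_count: int = 5
    private_site_fraction: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("deleterious_fraction", "lof_fraction", "private_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if len({p.label for p in self.populations}) != len(self.populations):
            raise ValueError("population labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]


class SimulatedFrequencies(NamedTuple):
    ancestral: np.ndarray  # (n_sites,)
    by_population: np.ndarray  # (n_sites, n_pops)


def simulate_frequencies(spec: CohortSpec) -> SimulatedFrequencies:
    """Draw ancestral and per-population allele frequencies under drift.

    E[population frequency] = ancestral p; Var = p(1-p)F, so the F -> 0
    limit concentrates at p and the expected pairwise theta is F.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_FREQ])
    p = rng.uniform(spec.ancestral_freq_low, spec.ancestral_freq_high, size=spec.n_sites)
    cols = []
    for pop in spec.populations:
        f = pop.fst
        cols.append(rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f))
    return SimulatedFrequencies(ancestral=p, by_population=np.column_stack(cols))


# ---------------------------------------------------------------------------
# synthetic gene model

_GENE_DEFS = (
    # symbol, chrom, start, strand, categories
    ("GENE1", "1", 10001, "+", ("common",)),
    ("GENE2", "1", 40001, "-", ("mendelian",)),
    ("GENE3", "1", 70001, "+", ("congenital",)),
    ("GENE4", "2", 10001, "+", ("common", "mendelian")),
    ("GENE5", "2", 40001, "-", ("common",)),
    ("GENE6", "2", 70001, "+", ("mendelian", "congenital")),
)

_GENE_LEN = 9400  # bp of gene body in the fixed template below
FLANK = 2000


def _gene_structure(start: int):
    """Template: UTR(200) | CDS(1800) | intron | CDS(2000) | intron | CDS(3000) | UTR(400)."""
    s = start
    exons = [(s, s + 1999), (s + 3000, s + 4999), (s + 6000, s + 9399)]
    cds = [(s + 200, s + 1999), (s + 3000, s + 4999), (s + 6000, s + 8999)]
    utr_low = (s, s + 199)
    utr_high = (s + 9000, s + 9399)
    return exons, cds, utr_low, utr_high


def synthetic_genes() -> list[GeneRegion]:
    """The six fixed genes of the synthetic model, as GeneRegion objects."""
    genes = []
    for i, (symbol, chrom, start, strand, cats) in enumerate(_GENE_DEFS, start=1):
        exons, cds, utr_low, utr_high = _gene_structure(start)
        utr5, utr3 = ((utr_low,), (utr_high,)) if strand == "+" else ((utr_high,), (utr_low,))
        genes.append(
            GeneRegion(
                gene_id=f"ENSGSYN{i:06d}",
                symbol=symbol,
                chrom=f"chr{chrom}",
                start=start,
                end=start + _GENE_LEN - 1,
                strand=strand,
                categories=frozenset(cats),
                exons=list(cds),
                utr5=list(utr5),
                utr3=list(utr3),
            )
        )
    return genes


def synthetic_gtf() -> str:
    """GENCODE-dialect GTF text for the six synthetic genes."""
    lines = []
    for i, (symbol, chrom, start, strand, _cats) in enumerate(_GENE_DEFS, start=1):
        gid, tid = f"ENSGSYN{i:06d}", f"ENSTSYN{i:06d}"
        attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{symbol}";'
        end = start + _GENE_LEN - 1
        exons, cds, utr_low, utr_high = _gene_structure(start)

        def row(ftype, lo, hi):
            lines.append(
                f"chr{chrom}\tSYNTH\t{ftype}\t{lo}\t{hi}\t.\t{strand}\t.\t{attrs}"
            )

        row("gene", start, end)
        row("transcript", start, end)
        for lo, hi in exons:
            row("exon", lo, hi)
        for lo, hi in cds:
            row("CDS", lo, hi)
        row("UTR", *utr_low)
        row("UTR", *utr_high)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cohort emission


@dataclass
class CohortBundle:
    """Paths of an emitted cohort plus the in-memory ground truth."""

    out_dir: Path
    vcf: Path
    panel: Path
    annotations: Path
    ancestral: Path
    clinvar: Path
    gtf: Path
    gene_lists: dict[str, Path]
    ground_truth_path: Path
    ground_truth: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)


def _layout_sites(spec: CohortSpec, rng: np.random.Generator):
    """Place sites uniformly in the extended gene regions (flank included),
    so every region class — exonic, UTR, upstream, downstream, intronic —
    is populated. Returns sorted (chrom, pos, gene) records."""
    genes = synthetic_genes()
    n_genes = len(genes)
    per_gene = [spec.n_sites // n_genes] * n_genes
    for i in range(spec.n_sites - sum(per_gene)):
        per_gene[i] += 1
    records = []
    for g, n_g in zip(genes, per_gene):
        lo, hi = max(1, g.start - FLANK), g.end + FLANK
        span = hi - lo + 1
        if n_g > span:
            raise ValueError(f"gene {g.symbol}: cannot place {n_g} unique sites in {span} bp")
        offsets = np.sort(rng.choice(span, size=n_g, replace=False))
        for off in offsets:
            pos = int(lo + off)
            records.append((g.chrom[3:], pos, g, classify_region(pos, g, FLANK)))
    records.sort(key=lambda r: (r[0], r[1]))
    return records


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def emit_cohort(
    spec: CohortSpec,
    out_dir,
    frequencies: SimulatedFrequencies | None = None,
) -> CohortBundle:
    """Write the full input bundle for one synthetic cohort.

    Deleterious-flagged sites receive scores that pass the consensus
    thresholds and a missense consequence; every non-flagged site fails at
    least one leg of the conjunction. The ancestral base equals REF for half
    the sites and ALT for the rest, so polarization is exercised both ways.
    Planted private sites carry zero derived alleles outside their home
    population (and at least one inside it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = spec.n_sites
    pops = spec.populations
    rng_layout = np.random.default_rng([spec.seed, _STREAM_LAYOUT])
    rng_geno = np.random.default_rng([spec.seed, _STREAM_GENO])
    rng_annot = np.random.default_rng([spec.seed, _STREAM_ANNOT])
    rng_clinvar = np.random.default_rng([spec.seed, _STREAM_CLINVAR])

    sites = _layout_sites(spec, rng_layout)
    chroms = [s[0] for s in sites]
    positions = [s[1] for s in sites]
    site_genes = [s[2] for s in sites]
    regions = [s[3] for s in sites]

    ref_idx = rng_layout.integers(0, 4, size=n)
    alt_shift = rng_layout.integers(1, 4, size=n)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    if frequencies is None:
        frequencies = simulate_frequencies(spec)
    freqs = frequencies.by_population.copy()  # alt-allele frequency per population

    # ancestral orientation: REF for the first half of a random permutation
    perm = rng_annot.permutation(n)
    anc_is_ref = np.zeros(n, dtype=bool)
    anc_is_ref[perm[: n // 2]] = True
    ancestral = np.where(anc_is_ref, refs, alts)

    # --- consequence / score planting -------------------------------------
    exonic = np.flatnonzero(np.array(regions) == "exonic")
    n_del = round(spec.deleterious_fraction * n)
    n_lof = round(spec.lof_fraction * n)
    if n_del + n_lof > exonic.size:
        raise ValueError(
            f"cannot place {n_del} deleterious + {n_lof} LoF sites in "
            f"{exonic.size} coding positions; enlarge the cohort or lower the fractions"
        )
    chosen = rng_annot.choice(exonic, size=n_del + n_lof, replace=False)
    del_idx = np.sort(chosen[:n_del])
    lof_idx = np.sort(chosen[n_del:])
    deleterious = np.zeros(n, dtype=bool)
    deleterious[del_idx] = True
    is_lof = np.zeros(n, dtype=bool)
    is_lof[lof_idx] = True

    consequences = [""] * n
    sift = np.full(n, np.nan)
    poly = np.full(n, np.nan)
    cadd = rng_annot.uniform(0.0, 35.0, size=n)  # CADD scores every variant
    lof_terms = rng_annot.choice(len(_LOF_TERMS), size=n)
    coin = rng_annot.uniform(size=n)
    # failing-pattern picker for non-deleterious missense: any proper subset
    # of {sift, polyphen, cadd} may pass, never all three
    patterns = ((False, False, False), (True, False, False), (False, True, False),
                (False, False, True), (True, True, False), (True, False, True),
                (False, True, True))
    pattern_pick = rng_annot.integers(0, len(patterns), size=n)
    u_sift = rng_annot.uniform(size=n)
    u_poly = rng_annot.uniform(size=n)
    u_cadd = rng_annot.uniform(size=n)

    for i, region in enumerate(regions):
        if deleterious[i]:
            consequences[i] = "missense_variant"
            sift[i] = 0.049 * u_sift[i]
            poly[i] = 0.958 + 0.042 * u_poly[i]
            cadd[i] = 15.0 + 25.0 * u_cadd[i]
        elif is_lof[i]:
            consequences[i] = _LOF_TERMS[lof_terms[i]]
        elif region == "exonic":
            if coin[i] < 0.5:
                consequences[i] = "missense_variant"
                s_pass, p_pass, c_pass = patterns[pattern_pick[i]]
                sift[i] = 0.049 * u_sift[i] if s_pass else 0.05 + 0.95 * u_sift[i]
                poly[i] = 0.958 + 0.042 * u_poly[i] if p_pass else 0.957 * u_poly[i]
                cadd[i] = 15.0 + 25.0 * u_cadd[i] if c_pass else 14.99 * u_cadd[i]
            else:
                consequences[i] = "synonymous_variant"
        else:
            consequences[i] = _NONCODING_TERM[region]

    # --- private-site planting --------------------------------------------
    private_to = np.array([""] * n, dtype=object)
    n_priv = round(spec.private_site_fraction * n)
    if n_priv * len(pops):
        candidates = rng_geno.permutation(n)
        taken = 0
        for pop_i, pop in enumerate(pops):
            grabbed = 0
            while grabbed < n_priv and taken < n:
                i = candidates[taken]
                taken += 1
                if private_to[i]:
                    continue
                private_to[i] = pop.label
                derived_freq = rng_geno.uniform(0.01, 0.1)
                for pj in range(len(pops)):
                    if pj == pop_i:
                        freqs[i, pj] = derived_freq if anc_is_ref[i] else 1 - derived_freq
                    else:
                        freqs[i, pj] = 0.0 if anc_is_ref[i] else 1.0
                grabbed += 1

    # --- genotypes ----------------------------------------------------------
    dosages = []
    sample_names: list[str] = []
    for pj, pop in enumerate(pops):
        sample_names += [f"{pop.label}_{k:04d}" for k in range(1, pop.n_individuals + 1)]
        dosages.append(rng_geno.binomial(2, freqs[:, pj][:, None], size=(n, pop.n_individuals)))
    dosage = np.concatenate(dosages, axis=1).astype(np.int8)

    # guarantee each planted private site carries its derived allele at home
    pop_cols: dict[str, slice] = {}
    off = 0
    for pop in pops:
        pop_cols[pop.label] = slice(off, off + pop.n_individuals)
        off += pop.n_individuals
    for i in np.flatnonzero(private_to != ""):
        cols = pop_cols[str(private_to[i])]
        home = dosage[i, cols]
        derived_dosage = home if anc_is_ref[i] else 2 - home
        if derived_dosage.sum() == 0:
            dosage[i, cols.start] = 1

    # --- ClinVar planting ---------------------------------------------------
    n_cv = spec.clinvar_pathogenic_count
    cv_order = rng_clinvar.permutation(n)
    cv_idx = np.sort(cv_order[:n_cv])
    decoy_idx = np.sort(cv_order[n_cv : 2 * n_cv])
    clinvar_sig = np.array([""] * n, dtype=object)
    for j, i in enumerate(cv_idx):
        sig = "Pathogenic" if j % 2 == 0 else "Likely_pathogenic"
        if j == n_cv - 1 and n_cv > 2:
            sig += "|risk_factor"  # exercise multi-significance parsing
        clinvar_sig[i] = sig
    for j, i in enumerate(decoy_idx):
        clinvar_sig[i] = "Benign" if j % 2 == 0 else "Uncertain_significance"

    # --- file emission ------------------------------------------------------
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "panel": out_dir / "panel.tsv",
        "annotations": out_dir / "annotations.tsv",
        "ancestral": out_dir / "ancestral.tsv",
        "clinvar": out_dir / "clinvar.tsv",
        "gtf": out_dir / "genes.gtf",
        "truth": out_dir / "ground_truth.tsv",
    }

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=cvload-synthetic\n")
        for chrom in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(n):
            row = "\t".join(gt[int(v)] for v in dosage[i])
            fh.write(
                f"{chroms[i]}\t{positions[i]}\trssyn{i + 1}\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{row}\n"
            )

    with open(paths["panel"], "w") as fh:
        fh.write("sample\tpopulation\n")
        for pop in pops:
            for k in range(1, pop.n_individuals + 1):
                fh.write(f"{pop.label}_{k:04d}\t{pop.label}\n")

    with open(paths["annotations"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsift\tpolyphen_hdiv\tcadd_phred\tconsequence\tgene_id\n")
        for i in range(n):
            s = "" if np.isnan(sift[i]) else _fmt(sift[i])
            p = "" if np.isnan(poly[i]) else _fmt(poly[i])
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t{refs[i]}\t{alts[i]}\t{s}\t{p}\t"
                f"{_fmt(cadd[i])}\t{consequences[i]}\t{site_genes[i].gene_id}\n"
            )

    with open(paths["ancestral"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tancestral_base\n")
        for i in range(n):
            fh.write(f"{chroms[i]}\t{positions[i]}\t{refs[i]}\t{alts[i]}\t{ancestral[i]}\n")

    with open(paths["clinvar"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclnsig\tdisease\n")
        for i in range(n):
            if not clinvar_sig[i]:
                continue
            disease = _DISEASES[i % len(_DISEASES)]
            fh.write(f"{chroms[i]}\t{positions[i]}\t{refs[i]}\t{alts[i]}\t{clinvar_sig[i]}\t{disease}\n")

    paths["gtf"].write_text(synthetic_gtf())

    gene_list_paths: dict[str, Path] = {}
    for cat in ("common", "mendelian", "congenital"):
        p = out_dir / f"genes_{cat}.txt"
        symbols = [g[0] for g in _GENE_DEFS if cat in g[4]]
        p.write_text(f"# category: {cat}\n" + "\n".join(symbols) + "\n")
        gene_list_paths[cat] = p

    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "gene": [g.symbol for g in site_genes],
            "region": regions,
            "consequence": consequences,
            "deleterious": deleterious,
            "lof": is_lof,
            "ancestral_base": ancestral,
            "clinvar": clinvar_sig,
            "private_to": private_to,
        }
    )
    for pj, pop in enumerate(pops):
        truth[f"alt_freq_{pop.label}"] = np.round(freqs[:, pj], 6)
    truth.to_csv(paths["truth"], sep="\t", index=False)

    return CohortBundle(
        out_dir=out_dir,
        vcf=paths["vcf"],
        panel=paths["panel"],
        annotations=paths["annotations"],
        ancestral=paths["ancestral"],
        clinvar=paths["clinvar"],
        gtf=paths["gtf"],
        gene_lists=gene_list_paths,
        ground_truth_path=paths["truth"],
        ground_truth=truth,
        spec=spec,
    )
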