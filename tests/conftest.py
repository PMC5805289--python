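import numpy as np
import pytest

from cvload.synthetic import CohortSpec, PopulationSpec, emit_cohort
from cvload import variant_store as vs
from cvload import polarization as pol
from cvload import annotation as ann
from cvload.gene_model import extend_regions, parse_gene_model, read_gene_lists

#: reference cohort used by most integration-level tests: small enough to be
#: fast, large enough that every region class and planted feature appears
SMALL_SPEC = CohortSpec(
    populations=(PopulationSpec("POP1", 20, 0.1), PopulationSpec("POP2", 20, 0.1)),
    n_sites=800,
    clinvar_pathogenic_count=5,
    seed=11,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return emit_cohort(SMALL_SPEC, out)


@pytest.fixture(scope="session")
def cohort(bundle):
    """Bundle loaded through the pipeline building blocks."""
    lists = read_gene_lists(bundle.gene_lists.values())
    model = parse_gene_model(bundle.gtf, lists)
    regions = extend_regions(model.genes, 2000)
    panel = vs.PopulationPanel.from_tsv(bundle.panel)
    matrix = vs.filter_snv(vs.subset_vcf(bundle.vcf, regions, panel))
    counts = vs.allele_counts(matrix, panel)
    records = ann.join_annotations(matrix, bundle.annotations)
    verdicts = [ann.classify_deleterious(r) for r in records]
    polarized = pol.polarize(counts, pol.read_ancestral_table(bundle.ancestral))
    return {
        "bundle": bundle,
        "model": model,
        "regions": regions,
        "panel": panel,
        "matrix": matrix,
        "counts": counts,
        "records": records,
        "verdicts": verdicts,
        "polarized": polarized,
    }


TOY_GTF = """\
chr1\tTEST\tgene\t1000\t5000\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\texon\t1000\t2000\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\tCDS\t1200\t2000\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\tUTR\t1000\t1199\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\texon\t4000\t5000\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\tCDS\t4000\t4500\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr1\tTEST\tUTR\t4501\t5000\t.\t+\t.\tgene_id "G1"; gene_name "GENEA";
chr2\tTEST\tgene\t10000\t20000\t.\t-\t.\tgene_id "G2"; gene_name "GENEB";
chr2\tTEST\tgene\t30000\t31000\t.\t+\t.\tgene_id "G3"; gene_name "GENEC";
chr2\tTEST\tgene\t40000\t41000\t.\t+\t.\tgene_id "G4"; gene_name "GENED";
chr3\tTEST\tgene\t500\t900\t.\t+\t.\tgene_id "G5"; gene_name "GENEE";
"""


@pytest.fixture()
def toy_gtf():
    return TOY_GTF


def write_vcf(path, variants, samples, dosages):
    """Plain-text VCF writer for fixtures; dosage -1 means missing."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v[0] for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), row in zip(variants, dosages):
            gts = "\t".join(gt[int(v)] for v in row)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def make_matrix(variants, dosages, samples=None):
    keys = [vs.VariantKey(*v) for v in variants]
    samples = samples or [f"S{i}" for i in range(np.asarray(dosages).shape[1])]
    return vs.GenotypeMatrix(keys, samples, np.asarray(dosages, dtype=np.int8))
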