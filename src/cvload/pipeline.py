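"""End-to-end orchestration of the mutational-load analysis.

Stage order: region construction -> variant subsetting -> SNV filter ->
annotation join -> consensus classification -> polarization -> load metrics /
sharing / FST / PCA / ClinVar filtering. Every number in the human-readable
report tables also appears in the machine-readable summary, and a fixed seed
makes reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import annotation as ann
from . import gene_model as gm
from . import load_metrics as lm
from . import polarization as pol
from . import popstruct as ps
from . import sharing as sh
from . import variant_store as vs

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Inputs, thresholds and knobs of one analysis run."""

    vcf: str
    panel: str
    gtf: str
    gene_lists: dict[str, str]
    annotations: str
    ancestral: str
    clinvar: str | None = None
    focal: str = ""
    populations: list[str] = field(default_factory=list)
    sift_max: float = 0.05
    polyphen_min: float = 0.957
    cadd_min: float = 15.0
    flank: int = 2000
    pca_k: int = 10
    hist_bin_width: float = 0.05
    downsample_n: int | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sift_max <= 0 or self.polyphen_min < 0 or self.cadd_min < 0:
            raise ValueError("thresholds must be positive")

    @property
    def thresholds(self) -> ann.Thresholds:
        return ann.Thresholds(self.sift_max, self.polyphen_min, self.cadd_min)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_paths(self) -> None:
        paths = [self.vcf, self.panel, self.gtf, self.annotations, self.ancestral]
        paths += list(self.gene_lists.values())
        if self.clinvar:
            paths.append(self.clinvar)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``out_dir``.

    Returns the machine-readable summary (also persisted as summary.json).
    Completed stage outputs are persisted before any later stage can fail.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate_paths()
    config.to_yaml(out_dir / "effective_config.yaml")
    summary: dict[str, Any] = {"seed": config.seed}

    # --- gene model --------------------------------------------------------
    @_stage("gene_model")
    def stage_genes():
        lists = gm.read_gene_lists(config.gene_lists.values())
        model = gm.parse_gene_model(config.gtf, lists)
        regions = gm.extend_regions(model.genes, config.flank)
        with open(out_dir / "regions.tsv", "w") as fh:
            gm.regions_to_tsv(regions, model.genes, fh)
        return model, regions

    model, regions = stage_genes()
    summary["n_genes"] = len(model.genes)
    summary["n_missing_genes"] = sum(len(v) for v in model.missing.values())
    summary.update({f"venn_genes_{k}": v for k, v in gm.count_gene_overlaps(model.genes).items()})

    # --- variants ----------------------------------------------------------
    @_stage("variant_store")
    def stage_variants():
        panel = vs.PopulationPanel.from_tsv(config.panel, config.populations or None)
        raw = vs.subset_vcf(config.vcf, regions, panel)
        snvs = vs.filter_snv(raw)
        counts = vs.allele_counts(snvs, panel)
        return panel, raw, snvs, counts

    panel, raw, snvs, counts = stage_variants()
    focal = config.focal or panel.populations[0]
    others = [p for p in panel.populations if p != focal]
    summary["n_variants_in_regions"] = raw.n_variants
    summary["n_snvs"] = snvs.n_variants
    summary["n_samples_focal"] = len(panel.samples_for(focal))

    # --- annotation & consensus classification ----------------------------
    @_stage("annotation")
    def stage_annotation():
        records = ann.join_annotations(snvs, config.annotations)
        verdicts = [ann.classify_deleterious(r, config.thresholds) for r in records]
        return records, verdicts

    records, verdicts = stage_annotation()
    venn = ann.predictor_venn(verdicts)
    summary.update({f"venn_predictor_{k}": v for k, v in venn.items()})
    dsnv_keys = [v.key for v in verdicts if v.combined]
    summary["n_dsnv"] = len(dsnv_keys)

    # --- polarization ------------------------------------------------------
    @_stage("polarization")
    def stage_polarize():
        table = pol.read_ancestral_table(config.ancestral)
        result = pol.polarize(counts, table)
        with open(out_dir / "polarized.tsv", "w") as fh:
            pol.polarized_to_tsv(result, counts.populations, fh)
        return result

    polarized = stage_polarize()
    summary["n_polarization_excluded"] = int(sum(polarized.exclusions.values()))

    # --- load metrics ------------------------------------------------------
    @_stage("load_metrics")
    def stage_load():
        labels = gm.classify_variants(
            ((k.chrom, k.pos) for k in snvs.variants), model.genes, config.flank
        )
        load = lm.summarize_load(
            verdicts, labels, polarized, len(panel.samples_for(focal)), population=focal
        )
        load.to_frame().to_csv(out_dir / "table1_load.tsv", sep="\t", index=False)
        spec_table = lm.spectrum(polarized, focal, dsnv_keys, config.hist_bin_width)
        spec_table.to_frame().to_csv(out_dir / "spectrum.tsv", sep="\t", index=False)
        return load, spec_table

    load, spec_table = stage_load()
    summary["per_person_dsnv"] = load.per_person_dsnv
    for k, v in load.counts.items():
        summary[f"count_{k}"] = v
    for k, v in load.proportions.items():
        summary[f"prop_{k}"] = v
    for b in ("rare", "low", "common"):
        summary[f"spectrum_all_{b}"] = spec_table.bins_all[b]
        summary[f"spectrum_dsnv_{b}"] = spec_table.bins_deleterious[b]
    summary["singletons_focal"] = spec_table.singletons

    # --- sharing -----------------------------------------------------------
    @_stage("sharing")
    def stage_sharing():
        dsnv_polarized = [v for v in polarized.variants if v.key in set(dsnv_keys)]
        result = sh.sharing_analysis(dsnv_polarized, focal, others)
        result.to_frame().to_csv(out_dir / "table3_sharing.tsv", sep="\t", index=False)
        return result

    sharing = stage_sharing()
    summary["sharing_total_dsnv"] = sharing.total_dsnv
    summary["sharing_private"] = sharing.private
    summary["prop_private"] = sharing.proportion_private
    for pair in sharing.pairs:
        summary[f"sharing_{pair.other}_shared"] = pair.shared
        summary[f"sharing_{pair.other}_prop_shared"] = pair.proportion_shared
        summary[f"sharing_{pair.other}_higher"] = pair.higher
        summary[f"sharing_{pair.other}_lower"] = pair.lower
        summary[f"sharing_{pair.other}_prop_higher"] = pair.proportion_higher
        summary[f"sharing_{pair.other}_max_fold"] = pair.max_fold

    # --- FST ---------------------------------------------------------------
    @_stage("fst")
    def stage_fst():
        sites = ps.fst_from_counts(counts, panel.populations)
        sites["differentiation"] = [
            ps.classify_differentiation(None if np.isnan(t) else t) for t in sites["theta"]
        ]
        dsnv_set = set(dsnv_keys)
        sites["deleterious"] = [k in dsnv_set for k in counts.variants]
        sites.to_csv(out_dir / "fst_sites.tsv", sep="\t", index=False)
        all_sum = ps.fst_summary(sites)
        del_rows = sites[sites["deleterious"]]
        del_sum = ps.fst_summary(del_rows) if del_rows["theta"].notna().any() else None
        return sites, all_sum, del_sum

    fst_sites, fst_all, fst_del = stage_fst()
    summary["fst_mean_all"] = fst_all.mean_theta
    summary["fst_weighted_all"] = fst_all.weighted_theta
    summary["fst_n_sites"] = fst_all.n_sites_used
    if fst_del is not None:
        summary["fst_mean_dsnv"] = fst_del.mean_theta
        summary["fst_weighted_dsnv"] = fst_del.weighted_theta
        summary["fst_enrichment"] = ps.fst_enrichment(fst_del, fst_all)
    for lbl in ("less", "moderate", "high", "severe"):
        summary[f"fst_bin_{lbl}"] = int((fst_sites["differentiation"] == lbl).sum())
    with open(out_dir / "fst_summary.tsv", "w") as fh:
        fh.write("set\tmean_theta\tweighted_theta\tn_sites\n")
        fh.write(f"all\t{fst_all.mean_theta:.6g}\t{fst_all.weighted_theta:.6g}\t{fst_all.n_sites_used}\n")
        if fst_del is not None:
            fh.write(
                f"deleterious\t{fst_del.mean_theta:.6g}\t{fst_del.weighted_theta:.6g}\t{fst_del.n_sites_used}\n"
            )

    # --- PCA ---------------------------------------------------------------
    @_stage("pca")
    def stage_pca():
        result = ps.pca(snvs, config.pca_k)
        result.to_frame().to_csv(out_dir / "pca_coords.tsv", sep="\t", index=False)
        np.savetxt(out_dir / "pca_eigenvalues.tsv", result.eigenvalues, fmt="%.6g")
        return result

    pca_res = stage_pca()
    summary["pca_eigenvalue_1"] = float(pca_res.eigenvalues[0]) if pca_res.eigenvalues.size else None
    summary["pca_k"] = int(pca_res.coords.shape[1])

    # --- ClinVar -----------------------------------------------------------
    if config.clinvar:
        @_stage("clinvar")
        def stage_clinvar():
            recs = ann.read_clinvar_table(config.clinvar)
            hits = ann.clinvar_filter(recs)
            with open(out_dir / "clinvar_hits.tsv", "w") as fh:
                fh.write("chrom\tpos\tref\talt\tsignificances\tdiseases\n")
                for r in hits:
                    fh.write(
                        f"{r.key.chrom}\t{r.key.pos}\t{r.key.ref}\t{r.key.alt}\t"
                        f"{'|'.join(r.significances)}\t{'|'.join(r.diseases)}\n"
                    )
            return recs, hits

        clin_recs, clin_hits = stage_clinvar()
        summary["n_clinvar_records"] = len(clin_recs)
        summary["n_clinvar_pathogenic"] = len(clin_hits)

    # --- downsampled comparison -------------------------------------------
    n_target = config.downsample_n or min(
        len(panel.samples_for(p)) for p in panel.populations
    )
    @_stage("downsample")
    def stage_downsample():
        df = lm.downsample_compare(
            snvs, panel, polarized, dsnv_keys, n_target, seed=config.seed
        )
        df.to_csv(out_dir / "downsample.tsv", sep="\t", index=False)
        return df

    downsampled = stage_downsample()
    for row in downsampled.itertuples(index=False):
        summary[f"downsample_{row.population}_singletons"] = int(row.singletons)
        summary[f"downsample_{row.population}_homozygous_pct"] = (
            None if np.isnan(row.homozygous_pct) else float(row.homozygous_pct)
        )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d summary statistics", len(summary))
    return summary
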