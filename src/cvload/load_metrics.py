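"""Cohort mutational-load summaries, allele-frequency spectra, downsampling.

The headline statistic is the per-person deleterious load: the number of
consensus-deleterious SNVs (dSNVs) found in the cohort divided by the sample
size. Companion proportions (nonsynonymous/exonic, deleterious/nonsynonymous,
homozygous/deleterious, synonymous/exonic) summarize where the burden sits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import DeleteriousnessVerdict
from .polarization import PolarizationResult, PolarizedVariant, daf_bin
from .variant_store import MISSING, GenotypeMatrix, PopulationPanel, VariantKey

log = logging.getLogger(__name__)

COUNT_KEYS = (
    "total",
    "exonic",
    "upstream",
    "downstream",
    "utr5",
    "utr3",
    "nonsynonymous",
    "synonymous",
    "dsnv",
    "homozygous_dsnv",
    "lof_in_dsnv",
    "lof_total",
)

_REGION_TO_KEY = {
    "exonic": "exonic",
    "upstream": "upstream",
    "downstream": "downstream",
    "UTR5": "utr5",
    "UTR3": "utr3",
}


@dataclass
class LoadSummary:
    """Counts, proportions and the per-person dSNV load for one cohort."""

    n_samples: int
    counts: dict[str, int]
    proportions: dict[str, float | None] = field(default_factory=dict)
    per_person_dsnv: float = 0.0

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], n_samples: int) -> "LoadSummary":
        """Derive the proportions and per-person load from raw counts.

        Zero denominators yield None ("undefined"), never a division error.
        """
        if n_samples <= 0:
            raise ValueError("n_samples must be positive")
        c = {k: int(counts.get(k, 0)) for k in COUNT_KEYS}

        def ratio(num: int, den: int) -> float | None:
            return num / den if den else None

        props = {
            "nonsyn_over_exonic": ratio(c["nonsynonymous"], c["exonic"]),
            "syn_over_exonic": ratio(c["synonymous"], c["exonic"]),
            "del_over_nonsyn": ratio(c["dsnv"], c["nonsynonymous"]),
            "homo_over_del": ratio(c["homozygous_dsnv"], c["dsnv"]),
        }
        return cls(
            n_samples=n_samples,
            counts=c,
            proportions=props,
            per_person_dsnv=c["dsnv"] / n_samples,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample_size", self.n_samples)]
        rows += [(k, v) for k, v in self.counts.items()]
        rows += [
            (k, "" if v is None else round(v, 4)) for k, v in self.proportions.items()
        ]
        rows.append(("per_person_dsnv", round(self.per_person_dsnv, 4)))
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_load(
    verdicts: Sequence[DeleteriousnessVerdict],
    region_labels: Mapping[tuple[str, int], str],
    polarized: PolarizationResult | None,
    n_samples: int,
    population: str | None = None,
) -> LoadSummary:
    """Tally the load table for one cohort (or one focal population of it).

    A dSNV counts as homozygous when at least one sample carries a homozygous
    derived genotype; where polarization is undefined the alt allele stands in
    for the derived allele (flagged in the log). With ``population`` given,
    homozygosity is evaluated within that population only.
    """
    counts = {k: 0 for k in COUNT_KEYS}
    counts["total"] = len(verdicts)
    hom_lookup: dict[VariantKey, int] = {}
    fallback = 0
    if polarized is not None:
        for pv in polarized.variants:
            pops = [population] if population else list(pv.hom_derived or pv.called)
            if pv.ok:
                hom_lookup[pv.key] = sum(pv.hom_derived.get(p, 0) for p in pops)
            else:
                hom_lookup[pv.key] = -1  # signal: fall back to alt-allele homozygosity
    for v in verdicts:
        label = region_labels.get((v.key.chrom, v.key.pos))
        key = _REGION_TO_KEY.get(label or "")
        if key:
            counts[key] += 1
        if v.consequence == "missense_variant":
            counts["nonsynonymous"] += 1
        elif v.consequence == "synonymous_variant":
            counts["synonymous"] += 1
        if v.is_lof:
            counts["lof_total"] += 1
        if v.combined:
            counts["dsnv"] += 1
            if v.is_lof:
                counts["lof_in_dsnv"] += 1
            hom = hom_lookup.get(v.key, 0)
            if hom == -1:
                fallback += 1
                hom = 0
            if hom > 0:
                counts["homozygous_dsnv"] += 1
    if fallback:
        log.info("summarize_load: %d dSNVs lacked polarization; alt-homozygosity used", fallback)
    return LoadSummary.from_counts(counts, n_samples)


@dataclass
class SpectrumTable:
    """DAF spectrum for one population: 3-bin summary plus a fine histogram."""

    population: str
    bins_all: dict[str, int]
    bins_deleterious: dict[str, int]
    hist_edges: np.ndarray
    hist_all: np.ndarray
    hist_deleterious: np.ndarray
    singletons: int
    n_defined: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.hist_edges[:-1],
                "bin_end": self.hist_edges[1:],
                "count_all": self.hist_all,
                "count_deleterious": self.hist_deleterious,
            }
        )


def spectrum(
    polarized: PolarizationResult | Iterable[PolarizedVariant],
    population: str,
    deleterious_keys: Iterable[VariantKey] = (),
    bin_width: float = 0.05,
) -> SpectrumTable:
    """DAF spectrum over variants with a defined DAF in ``population``.

    The deleterious spectrum is computed over the same variant universe, so
    its bin counts are bounded by the all-SNV counts bin by bin.
    """
    variants = polarized.variants if isinstance(polarized, PolarizationResult) else list(polarized)
    dset = set(deleterious_keys)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    edges[-1] = 1.0
    bins_all = {"rare": 0, "low": 0, "common": 0}
    bins_del = {"rare": 0, "low": 0, "common": 0}
    dafs_all, dafs_del = [], []
    singletons = 0
    for pv in variants:
        d = pv.daf.get(population)
        if d is None:
            continue
        bins_all[daf_bin(d)] += 1
        dafs_all.append(d)
        if pv.derived_count.get(population) == 1:
            singletons += 1
        if pv.key in dset:
            bins_del[daf_bin(d)] += 1
            dafs_del.append(d)
    hist_all, _ = np.histogram(dafs_all, bins=edges)
    hist_del, _ = np.histogram(dafs_del, bins=edges)
    return SpectrumTable(
        population=population,
        bins_all=bins_all,
        bins_deleterious=bins_del,
        hist_edges=edges,
        hist_all=hist_all,
        hist_deleterious=hist_del,
        singletons=singletons,
        n_defined=len(dafs_all),
    )


def downsample_compare(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    polarized: PolarizationResult,
    deleterious_keys: Iterable[VariantKey],
    n_target: int,
    seed: int = 1,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Equal-sample-size comparison of deleterious singletons and homozygosity.

    For each population, ``n_target`` individuals are drawn uniformly without
    replacement (one RNG, populations processed in declared order) and, over
    the dSNVs segregating for the derived allele in the subsample: the number
    with derived allele count exactly 1 (singletons) and the percentage with
    at least one homozygous-derived individual.
    """
    pops = list(populations) if populations else list(panel.populations)
    rng = np.random.default_rng(seed)
    dset = set(deleterious_keys)
    orient = {pv.key: pv.derived for pv in polarized.variants if pv.ok}
    rows_idx = [i for i, k in enumerate(matrix.variants) if k in dset and k in orient]
    flip = np.array([orient[matrix.variants[i]] == matrix.variants[i].ref for i in rows_idx])

    out = []
    for pop in pops:
        members = [s for s in panel.samples_for(pop) if s in set(matrix.samples)]
        if len(members) < n_target:
            raise ValueError(
                f"population {pop} has {len(members)} samples < n_target {n_target}"
            )
        chosen = sorted(rng.choice(len(members), size=n_target, replace=False))
        sub = matrix.select_samples([members[i] for i in chosen])
        d = sub.dosages[rows_idx].astype(np.int64)
        called = d != MISSING
        derived = np.where(called, d, 0)
        derived[flip] = np.where(called[flip], 2 - d[flip], 0)
        dc = derived.sum(axis=1)
        segregating = dc > 0
        singles = int((dc == 1).sum())
        hom_any = ((derived == 2) & called).any(axis=1)
        n_seg = int(segregating.sum())
        pct_hom = 100.0 * int((hom_any & segregating).sum()) / n_seg if n_seg else np.nan
        out.append(
            {
                "population": pop,
                "n_individuals": n_target,
                "n_dsnv_segregating": n_seg,
                "singletons": singles,
                "homozygous_pct": pct_hom,
            }
        )
    return pd.DataFrame(out)
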