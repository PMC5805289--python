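"""Private vs shared deleterious variants across populations.

A dSNV carried by the focal population is *shared with X* when its derived
allele is also observed in population X, and *private* when no other
population of the compared set carries it. On each shared set the module
counts variants whose focal DAF exceeds, equals, or falls below the other
population's DAF, and summarizes fold differences and medians. Exact DAF
ties are reported separately rather than folded into either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .polarization import PolarizationResult, PolarizedVariant

log = logging.getLogger(__name__)


def fold_difference(daf_focal: float, daf_other: float) -> float:
    """Ratio of derived allele frequencies; both must be positive."""
    if daf_focal <= 0 or daf_other <= 0:
        raise ValueError("fold_difference requires strictly positive DAFs")
    return daf_focal / daf_other


@dataclass
class PairSharing:
    """Sharing statistics of the focal population against one other population."""

    other: str
    shared: int
    higher: int
    lower: int
    ties: int
    total_shared: int
    max_fold: float | None = None
    median_focal_daf: float | None = None
    median_other_daf: float | None = None
    n_dropped: int = 0

    @property
    def proportion_shared(self) -> float | None:
        """shared-with-this-population / total shared dSNVs."""
        return self.shared / self.total_shared if self.total_shared else None

    @property
    def proportion_higher(self) -> float | None:
        """higher-DAF variants / variants shared with this population."""
        return self.higher / self.shared if self.shared else None


@dataclass
class SharingSummary:
    focal: str
    total_dsnv: int
    private: int
    total_shared: int
    pairs: list[PairSharing]

    @property
    def proportion_private(self) -> float | None:
        return self.private / self.total_dsnv if self.total_dsnv else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "focal": self.focal,
                    "total_dsnv": self.total_dsnv,
                    "private_dsnv": self.private,
                    "shared_with": p.other,
                    "shared": p.shared,
                    "proportion_shared": None if p.proportion_shared is None else round(p.proportion_shared, 3),
                    "higher_daf": p.higher,
                    "lower_daf": p.lower,
                    "ties": p.ties,
                    "proportion_higher": None if p.proportion_higher is None else round(p.proportion_higher, 3),
                    "max_fold_difference": None if p.max_fold is None else round(p.max_fold, 2),
                    "median_focal_daf": p.median_focal_daf,
                    "median_other_daf": p.median_other_daf,
                }
            )
        return pd.DataFrame(rows)


def sharing_analysis(
    polarized: PolarizationResult | Iterable[PolarizedVariant],
    focal: str,
    others: Sequence[str],
) -> SharingSummary:
    """Decompose the focal population's dSNVs into private and shared sets.

    Only variants with a defined DAF and at least one derived allele in the
    focal population enter the analysis. A site where some other population
    has zero called chromosomes is dropped from that pairwise comparison
    (logged) but still counts toward privacy against the remaining
    populations.
    """
    variants = polarized.variants if isinstance(polarized, PolarizationResult) else list(polarized)
    if focal in others:
        raise ValueError(f"focal population {focal!r} also listed in others")
    carried = [
        v
        for v in variants
        if v.ok and v.daf.get(focal) is not None and v.derived_count.get(focal, 0) > 0
    ]
    total = len(carried)
    private = 0
    shared_any = 0
    for v in carried:
        present = [
            o for o in others if v.called.get(o, 0) > 0 and v.derived_count.get(o, 0) > 0
        ]
        if present:
            shared_any += 1
        else:
            private += 1
    total_shared = shared_any

    pairs: list[PairSharing] = []
    for other in others:
        higher = lower = ties = shared = dropped = 0
        folds: list[float] = []
        f_dafs: list[float] = []
        o_dafs: list[float] = []
        for v in carried:
            if v.called.get(other, 0) == 0:
                dropped += 1
                continue
            if v.derived_count.get(other, 0) <= 0:
                continue
            shared += 1
            df, do = v.daf[focal], v.daf[other]
            f_dafs.append(df)
            o_dafs.append(do)
            if df > do:
                higher += 1
            elif df < do:
                lower += 1
            else:
                ties += 1
            if df > 0 and do > 0:
                folds.append(fold_difference(df, do))
        if dropped:
            log.info(
                "sharing_analysis: %d sites dropped from %s/%s pair (no called chromosomes)",
                dropped, focal, other,
            )
        pairs.append(
            PairSharing(
                other=other,
                shared=shared,
                higher=higher,
                lower=lower,
                ties=ties,
                total_shared=total_shared,
                max_fold=max(folds) if folds else None,
                median_focal_daf=median(f_dafs) if f_dafs else None,
                median_other_daf=median(o_dafs) if o_dafs else None,
                n_dropped=dropped,
            )
        )
    return SharingSummary(
        focal=focal,
        total_dsnv=total,
        private=private,
        total_shared=total_shared,
        pairs=pairs,
    )
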