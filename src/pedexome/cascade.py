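"""The dominant-model exome filtering cascade.

Candidate variants for a dominant Mendelian disease segregating in a family
are prioritized by a fixed sequence of per-sample filters followed by an
intersection across affected relatives at every stage:

1. ``exonic_splicing``  - keep exonic and splice-site calls;
2. ``functional``       - keep protein-relevant classes (drop synonymous);
3. ``heterozygous``     - dominant model: keep heterozygous calls only;
4. ``rare``             - drop variants above the population-frequency
   threshold in any panel where they are reported (absent-from-panel is
   treated as rare: a private mutation has no catalog frequency);
5. ``in_interval``      - restrict to the linkage interval;
6. ``catalog_absent``   - novelty: not in the known-variant catalog.

A variant above the threshold in *either* frequency panel is discarded;
a frequency exactly at the threshold survives (only "higher than" the
threshold is discarded).  Stage counts are reported per sample plus
"shared" columns (identity-key intersection across samples), which is the
layout of a total-and-shared variant count table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    FUNCTIONAL_CLASSES,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    GenomicInterval,
    ValidationError,
    Variant,
)
from .io import Cohort, _row_to_variant

logger = logging.getLogger(__name__)

STAGES = (
    "exonic_splicing",
    "functional",
    "heterozygous",
    "rare",
    "in_interval",
    "catalog_absent",
)


@dataclass
class CascadeParams:
    """Tunable parameters of the filtering cascade."""

    interval: GenomicInterval
    freq_threshold: float = 0.01
    functional_classes_kept: frozenset[str] = FUNCTIONAL_CLASSES
    genotype_model: str = "dominant_het"
    coverage_threshold: int = 10
    #: treat missing calls as unknown rather than absent at the heterozygous
    #: stage (off by default: low-coverage sites are resequenced, not rescued)
    rescue_missing: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_threshold <= 1.0):
            raise ValidationError(f"freq_threshold {self.freq_threshold} outside (0, 1]")
        if self.genotype_model != "dominant_het":
            raise ValidationError(f"unsupported genotype model {self.genotype_model!r}")


@dataclass
class CascadeResult:
    """Stage-by-stage counts plus the surviving candidate variants.

    ``stage_counts`` has one row per stage and one column per sample, plus
    ``shared_subset`` (if a platform subset was given) and ``shared_all``.
    ``class_composition`` breaks the shared count at the ``rare`` stage down
    by functional class.  ``survivors`` are the variants shared by all
    affected samples inside the interval, catalog-absent first; ``n_novel``
    of them are catalog-absent.
    """

    stage_counts: pd.DataFrame
    class_composition: dict[str, int]
    survivors: list[Variant]
    n_novel: int
    params: CascadeParams
    sample_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Assert the structural invariants of a cascade table."""
        counts = self.stage_counts
        for col in counts.columns:
            col_vals = counts[col].to_numpy()
            if (np.diff(col_vals) > 0).any():
                raise ValidationError(f"stage counts increase down column {col!r}")
        shared_cols = [c for c in counts.columns if c.startswith("shared")]
        for stage in counts.index:
            member_min = counts.loc[stage, self.sample_ids].min()
            for col in shared_cols:
                if counts.loc[stage, col] > member_min:
                    raise ValidationError(
                        f"shared count exceeds member minimum at stage {stage!r}"
                    )
        if "shared_all" in counts.columns:
            if sum(self.class_composition.values()) != counts.loc["rare", "shared_all"]:
                raise ValidationError("class composition does not sum to rare-stage count")


def filter_stage_exonic(variants: Sequence[Variant]) -> list[Variant]:
    """Keep exonic/splicing variants (everything except class ``other``)."""
    kept = [v for v in variants if v.var_class != "other"]
    n_dropped = len(variants) - len(kept)
    if n_dropped:
        logger.info("exonic_splicing stage dropped %d non-exonic variants", n_dropped)
    return kept


def rank_novel(survivors: Sequence[Variant]) -> tuple[list[Variant], int]:
    """Stable-sort survivors with catalog-absent variants first.

    Returns the reordered list and the number of catalog-absent variants.
    """
    ordered = sorted(survivors, key=lambda v: v.in_catalog)  # False < True, stable
    n_novel = sum(1 for v in ordered if not v.in_catalog)
    return ordered, n_novel


def _variant_masks(cohort: Cohort, params: CascadeParams) -> dict[str, np.ndarray]:
    vdf = cohort.variants
    exonic = (vdf["var_class"] != "other").to_numpy()
    functional = vdf["var_class"].isin(params.functional_classes_kept).to_numpy()
    thr = params.freq_threshold
    fa = vdf["freq_a"].to_numpy(dtype=float)
    fb = vdf["freq_b"].to_numpy(dtype=float)
    common_a = ~np.isnan(fa) & (fa > thr)
    common_b = ~np.isnan(fb) & (fb > thr)
    rare = ~(common_a | common_b)
    iv = params.interval
    in_interval = (
        (vdf["chrom"] == iv.chrom)
        & (vdf["pos"] >= iv.start)
        & (vdf["pos"] <= iv.end)
    ).to_numpy()
    novel = (~vdf["in_catalog"].astype(bool)).to_numpy()
    return {
        "exonic_splicing": exonic,
        "functional": functional,
        "rare": rare,
        "in_interval": in_interval,
        "catalog_absent": novel,
    }


def run_cascade(
    cohort: Cohort,
    affected_ids: Sequence[str],
    params: CascadeParams,
    subset_ids: Optional[Sequence[str]] = None,
) -> CascadeResult:
    """Run the full cascade over the affected samples of a cohort.

    *subset_ids*, when given, adds a ``shared_subset`` column (e.g. the
    samples sequenced on one platform) between the per-sample columns and
    ``shared_all``.
    """
    affected_ids = list(affected_ids)
    if not affected_ids:
        raise ValidationError("cascade requires at least one affected sequenced sample")
    missing = [s for s in affected_ids if s not in cohort.genotypes.columns]
    if missing:
        raise ValidationError(f"samples absent from genotype data: {missing}")
    if subset_ids is not None:
        bad = [s for s in subset_ids if s not in affected_ids]
        if bad:
            raise ValidationError(f"subset ids not among affected samples: {bad}")

    vmask = _variant_masks(cohort, params)
    gt = cohort.genotypes[affected_ids].to_numpy()

    # per-sample cumulative masks, staged
    called_nonref = (gt == GT_HET) | (gt == GT_HOM_ALT)
    if params.rescue_missing:
        called_nonref |= gt == GT_MISSING
    het = gt == GT_HET
    if params.rescue_missing:
        het |= gt == GT_MISSING

    per_stage_sample_masks: dict[str, np.ndarray] = {}
    cur = called_nonref & vmask["exonic_splicing"][:, None]
    per_stage_sample_masks["exonic_splicing"] = cur
    cur = cur & vmask["functional"][:, None]
    per_stage_sample_masks["functional"] = cur
    cur = cur & het
    per_stage_sample_masks["heterozygous"] = cur
    cur = cur & vmask["rare"][:, None]
    per_stage_sample_masks["rare"] = cur
    cur = cur & vmask["in_interval"][:, None]
    per_stage_sample_masks["in_interval"] = cur
    cur = cur & vmask["catalog_absent"][:, None]
    per_stage_sample_masks["catalog_absent"] = cur

    columns = list(affected_ids)
    if subset_ids is not None:
        columns.append("shared_subset")
    columns.append("shared_all")

    counts = pd.DataFrame(0, index=list(STAGES), columns=columns, dtype=int)
    shared_all_masks: dict[str, np.ndarray] = {}
    subset_idx = (
        [affected_ids.index(s) for s in subset_ids] if subset_ids is not None else None
    )
    for stage in STAGES:
        m = per_stage_sample_masks[stage]
        counts.loc[stage, affected_ids] = m.sum(axis=0)
        if subset_idx is not None:
            counts.loc[stage, "shared_subset"] = int(m[:, subset_idx].all(axis=1).sum())
        shared = m.all(axis=1)
        shared_all_masks[stage] = shared
        counts.loc[stage, "shared_all"] = int(shared.sum())
        logger.info(
            "stage %-16s per-sample %s shared %d",
            stage,
            m.sum(axis=0).tolist(),
            int(shared.sum()),
        )

    rare_shared = cohort.variants.loc[shared_all_masks["rare"]]
    class_composition = rare_shared["var_class"].value_counts().to_dict()

    surv_df = cohort.variants.loc[shared_all_masks["in_interval"]]
    survivors = [_row_to_variant(row) for _, row in surv_df.iterrows()]
    survivors, n_novel = rank_novel(survivors)

    result = CascadeResult(
        stage_counts=counts,
        class_composition={k: int(v) for k, v in class_composition.items()},
        survivors=survivors,
        n_novel=n_novel,
        params=params,
        sample_ids=list(affected_ids),
    )
    result.validate()
    return result


def coverage_gaps(
    exon_table: pd.DataFrame,
    coverage: pd.DataFrame,
    params: CascadeParams,
) -> list[tuple[str, str]]:
    """Sanger follow-up worklist: (sample, exon) pairs with low coverage.

    *exon_table* has columns ``exon_id, chrom, start, end``; *coverage* is
    long-format with columns ``sample, exon_id, mean_coverage``.  Exons lying
    outside the linkage interval are excluded with a warning; every retained
    (sample, exon) whose mean coverage is below the coverage threshold is
    reported.
    """
    if (coverage["mean_coverage"] < 0).any():
        raise ValidationError("negative coverage values")
    iv = params.interval
    inside = exon_table.apply(
        lambda r: iv.contains(str(r["chrom"]), int(r["start"]))
        and iv.contains(str(r["chrom"]), int(r["end"])),
        axis=1,
    )
    outside = exon_table.loc[~inside, "exon_id"].tolist()
    if outside:
        warnings.warn(
            f"{len(outside)} exons outside interval {iv} excluded from coverage scan",
            stacklevel=2,
        )
    keep = set(exon_table.loc[inside, "exon_id"])
    hits = coverage[
        coverage["exon_id"].isin(keep)
        & (coverage["mean_coverage"] < params.coverage_threshold)
    ]
    return sorted(zip(hits["sample"], hits["exon_id"]))
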