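"""Co-segregation analysis, penetrance estimation, interval refinement.

Under an autosomal-dominant model a candidate variant co-segregates with the
disease when every typed affected individual carries it; unaffected carriers
are counted as non-penetrant rather than as contradictions.  Penetrance is
estimated as the fraction of typed carriers that are affected.  The linkage
interval is refined by markers whose presence/absence pattern among affected
relatives is discordant: a marker not shared by all affecteds cannot lie on
the common disease haplotype, so it bounds the shared region on whichever
side of the candidate position it falls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    GT_CODES,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    Affection,
    GenomicInterval,
    Pedigree,
    ValidationError,
)

CARRIER_STATES = (
    "affected_carrier",
    "nonpenetrant_carrier",
    "unaffected_noncarrier",
    "affected_noncarrier",
    "untyped",
)


@dataclass
class SegregationReport:
    """Per-individual carrier/phenotype classification for one variant."""

    status: dict[str, str] = field(default_factory=dict)
    verdict: str = "complete_cosegregation"  # or "incompatible"
    n_affected_carriers: int = 0
    n_nonpenetrant: int = 0

    def counts(self) -> dict[str, int]:
        out = {state: 0 for state in CARRIER_STATES}
        for s in self.status.values():
            out[s] += 1
        return out

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "n_affected_carriers": self.n_affected_carriers,
            "n_nonpenetrant": self.n_nonpenetrant,
            "counts": self.counts(),
            "status": dict(sorted(self.status.items())),
        }


@dataclass(frozen=True)
class MarkerObservation:
    """Presence/absence pattern of an informative marker among relatives."""

    marker_id: str
    chrom: str
    pos: int
    present_in: frozenset[str]
    absent_in: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.present_in & self.absent_in
        if overlap:
            raise ValidationError(
                f"marker {self.marker_id}: ids both present and absent: {sorted(overlap)}"
            )


def classify_segregation(
    pedigree: Pedigree, genotypes: Mapping[str, int | str]
) -> SegregationReport:
    """Classify every pedigree member against one variant's genotypes.

    *genotypes* maps sample id to a genotype (integer code or name); members
    without an entry, or with a missing call, are "untyped".  The verdict is
    ``complete_cosegregation`` iff no typed affected individual lacks the
    variant.
    """
    if not genotypes:
        raise ValidationError("no genotypes supplied")
    unknown = [s for s in genotypes if s not in pedigree]
    if unknown:
        raise ValidationError(f"typed individuals absent from pedigree: {sorted(unknown)}")

    report = SegregationReport()
    for ind in pedigree.members():
        gt = genotypes.get(ind.id)
        if isinstance(gt, str):
            gt = GT_CODES[gt]
        if gt is None or gt == GT_MISSING:
            report.status[ind.id] = "untyped"
            continue
        carrier = gt in (GT_HET, GT_HOM_ALT)
        if carrier and ind.affected is Affection.AFFECTED:
            report.status[ind.id] = "affected_carrier"
            report.n_affected_carriers += 1
        elif carrier:
            # unknown phenotype carriers are conservatively non-penetrant only
            # when explicitly unaffected
            if ind.affected is Affection.UNAFFECTED:
                report.status[ind.id] = "nonpenetrant_carrier"
                report.n_nonpenetrant += 1
            else:
                report.status[ind.id] = "untyped"
        elif ind.affected is Affection.AFFECTED:
            report.status[ind.id] = "affected_noncarrier"
        else:
            report.status[ind.id] = "unaffected_noncarrier"

    incompatible = any(s == "affected_noncarrier" for s in report.status.values())
    report.verdict = "incompatible" if incompatible else "complete_cosegregation"
    return report


def estimate_penetrance(report: SegregationReport) -> tuple[float, str]:
    """Penetrance among typed carriers: affected / (affected + non-penetrant).

    Returns the raw fraction and the value rounded to the nearest percent as
    a display string (e.g. 64 affected carriers and 5 non-penetrant carriers
    give 64/69 = 0.9275..., reported as "93%").
    """
    total = report.n_affected_carriers + report.n_nonpenetrant
    if total == 0:
        raise ValidationError("cannot estimate penetrance with zero typed carriers")
    raw = report.n_affected_carriers / total
    return raw, f"{round(raw * 100):d}%"


def refine_interval(
    interval: GenomicInterval,
    causal_pos: int,
    markers: Sequence[MarkerObservation],
    affected_ids: Iterable[str],
) -> GenomicInterval:
    """Shrink a linkage interval using discordant marker patterns.

    A marker inside the interval that is *not* present in every affected
    individual cannot be part of the haplotype shared by all patients, so the
    shared region cannot extend past it: a discordant marker distal to the
    candidate position pulls the end in, a proximal one pushes the start up.
    The new boundary is placed at the marker position itself, the convention
    under which the printed refinement chr7:...-129,964,025 -> ...-128,845,555
    is reproduced.  Markers present in all affecteds leave the interval
    unchanged.  A discordant marker at the candidate position itself would
    exclude the candidate and raises an error.
    """
    if not interval.contains(interval.chrom, causal_pos):
        raise ValidationError(
            f"candidate position {causal_pos} outside interval {interval}"
        )
    affected = set(affected_ids)
    start, end = interval.start, interval.end
    for marker in markers:
        if marker.chrom != interval.chrom:
            continue
        if not (interval.start <= marker.pos <= interval.end):
            continue
        shared_by_all = affected <= marker.present_in
        if shared_by_all or not (marker.present_in & affected):
            # uninformative: on the shared haplotype, or absent from it entirely
            continue
        if marker.pos == causal_pos:
            raise ValidationError(
                f"discordant marker {marker.marker_id} coincides with the "
                f"candidate position {causal_pos}"
            )
        if marker.pos > causal_pos:
            end = min(end, marker.pos)
        else:
            start = max(start, marker.pos)
    refined = GenomicInterval(interval.chrom, start, end)
    if not refined.contains(interval.chrom, causal_pos):  # pragma: no cover
        raise ValidationError("refinement excluded the candidate position")
    return refined


# ---------------------------------------------------------------------------
# marker table I/O (marker_id, chrom, pos, present_in, absent_in; id lists
# comma-separated)
# ---------------------------------------------------------------------------

def read_markers(path: str | os.PathLike) -> list[MarkerObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples():
        out.append(
            MarkerObservation(
                marker_id=row.marker_id,
                chrom=row.chrom,
                pos=int(row.pos),
                present_in=_id_set(row.present_in),
                absent_in=_id_set(row.absent_in),
            )
        )
    return out


def write_markers(markers: Sequence[MarkerObservation], path: str | os.PathLike) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "present_in": ",".join(sorted(m.present_in)) or ".",
            "absent_in": ",".join(sorted(m.absent_in)) or ".",
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _id_set(cell: Optional[str]) -> frozenset[str]:
    if cell is None or cell in (".", "", "nan") or (isinstance(cell, float)):
        return frozenset()
    return frozenset(x for x in str(cell).split(",") if x)
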