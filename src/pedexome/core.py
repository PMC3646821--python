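"""Domain types and coordinate conventions.

Coordinates are 1-based throughout, matching VCF POS and GRCh37 positions as
printed in the genetics literature.  Genomic intervals are closed on both
ends (``start <= pos <= end`` is inside).

Two length conventions coexist in linkage genetics and both are provided:

* :meth:`GenomicInterval.length` is ``end - start``, the *marker distance*
  between the two boundary positions.  This is the convention under which
  the LGMD1F critical interval chr7:126,287,140-129,964,025 is the familiar
  "3.68 Mb" region and its refinement to 128,845,555 is a "1.1 Mb" reduction.
* :meth:`GenomicInterval.n_bases` is ``end - start + 1``, the number of
  bases covered, used wherever sequence content is summed (exon spans).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

#: functional classes used by the annotation tables and the filter cascade
VAR_CLASSES = (
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "stopgain",
    "stoploss",
    "frameshift_del",
    "frameshift_ins",
    "nonframeshift_indel",
    "splicing",
    "other",
)

#: classes regarded as protein-relevant under a dominant Mendelian model
#: (everything exonic/splicing except synonymous changes)
FUNCTIONAL_CLASSES = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift_del",
        "frameshift_ins",
        "nonframeshift_indel",
        "splicing",
    }
)

# integer genotype codes used in genotype matrices
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

GT_NAMES = {
    GT_HOM_REF: "hom_ref",
    GT_HET: "het",
    GT_HOM_ALT: "hom_alt",
    GT_MISSING: "missing",
}
GT_CODES = {v: k for k, v in GT_NAMES.items()}


class PedexomeError(Exception):
    """Base class for all package errors."""


class ParseError(PedexomeError):
    """A standard-format file could not be parsed; carries the line number."""


class ValidationError(PedexomeError):
    """Input violated a documented precondition."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, closed chromosomal span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise ValidationError(f"positions must be positive: {self}")
        if self.start > self.end:
            raise ValidationError(f"start > end in interval {self}")

    def length(self) -> int:
        """Marker distance ``end - start`` in bp (see module docstring)."""
        return self.end - self.start

    def n_bases(self) -> int:
        """Number of bases covered, ``end - start + 1``."""
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff (chrom, pos) falls inside this closed interval."""
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # chr7:126287140-129964025
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"cannot parse interval {text!r}") from exc

    def to_bed_fields(self) -> tuple[str, int, int]:
        """Convert to BED's 0-based half-open convention."""
        return (self.chrom, self.start - 1, self.end)

    @classmethod
    def from_bed_fields(cls, chrom: str, bed_start: int, bed_end: int) -> "GenomicInterval":
        """Build from BED's 0-based half-open coordinates."""
        return cls(chrom, bed_start + 1, bed_end)


def interval_length(interval: GenomicInterval) -> int:
    """Marker distance of *interval* in bp (``end - start``)."""
    return interval.length()


def contains(interval: GenomicInterval, chrom: str, pos: int) -> bool:
    """True iff (chrom, pos) lies inside the closed *interval*."""
    return interval.contains(chrom, pos)


def normalize_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-shifted representation of a ref/alt pair.

    Trims shared trailing bases, then shared leading bases (always keeping at
    least one base on each side), adjusting ``pos`` for trimmed leading bases.
    Without flanking reference sequence a full left-alignment is not possible;
    this minimal representation is sufficient to make identity keys comparable
    across callers that pad indels differently.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class Variant:
    """One called sequence change with annotation.

    ``freq_panel_a`` / ``freq_panel_b`` are population allele frequencies in
    two independent panels (an exome-server-like and a 1000-genomes-like
    catalog); ``None`` means the variant is absent from that panel, which is
    distinct from an observed frequency of 0.0.  ``in_catalog`` is membership
    in a dbSNP-like catalog of known variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str = "other"
    gene: str = ""
    freq_panel_a: Optional[float] = None
    freq_panel_b: Optional[float] = None
    in_catalog: bool = False
    catalog_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise ValidationError(f"unknown variant class {self.var_class!r}")
        for f in (self.freq_panel_a, self.freq_panel_b):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValidationError(f"frequency {f} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key (chrom, pos, ref, alt) after minimal normalization."""
        pos, ref, alt = normalize_allele_pair(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)

    @property
    def key_str(self) -> str:
        c, p, r, a = self.key
        return f"{c}:{p}:{r}:{a}"


@dataclass(frozen=True)
class GenotypeCall:
    """Genotype of one sample at one variant."""

    sample_id: str
    variant_key: tuple[str, int, str, str]
    gt: str  # hom_ref | het | hom_alt | missing

    def __post_init__(self) -> None:
        if self.gt not in GT_CODES:
            raise ValidationError(f"unknown genotype {self.gt!r}")


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class Individual:
    """A pedigree member."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    sampled: bool = True


@dataclass
class Pedigree:
    """A family graph: individuals keyed by id, with validated parentage."""

    family_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise ValidationError(f"duplicate individual id {ind.id!r}")
        self.individuals[ind.id] = ind

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def members(self) -> Iterable[Individual]:
        return self.individuals.values()

    def affected_ids(self) -> list[str]:
        return [i.id for i in self.members() if i.affected is Affection.AFFECTED]

    def founders(self) -> list[str]:
        return [
            i.id
            for i in self.members()
            if i.father_id is None and i.mother_id is None
        ]

    def children_of(self, ind_id: str) -> list[str]:
        return [
            i.id
            for i in self.members()
            if ind_id in (i.father_id, i.mother_id)
        ]

    def validate(self) -> None:
        """Check parent references resolve and parentage is acyclic."""
        bad = []
        for ind in self.members():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self.individuals:
                    bad.append((ind.id, parent))
        if bad:
            rows = ", ".join(f"{c} -> missing parent {p}" for c, p in bad)
            raise ValidationError(f"dangling parent references: {rows}")
        # cycle check via DFS over parent edges
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            ind = self.individuals[node]
            for parent in (ind.father_id, ind.mother_id):
                if parent is None:
                    continue
                if state.get(parent) == 1:
                    raise ValidationError(f"parentage cycle involving {parent!r}")
                if parent not in state:
                    visit(parent)
            state[node] = 2

        for ind_id in self.individuals:
            if ind_id not in state:
                visit(ind_id)

    def generation_order(self) -> list[str]:
        """Ids ordered so every parent precedes their children."""
        order: list[str] = []
        placed: set[str] = set()
        pending = dict(self.individuals)
        while pending:
            progressed = False
            for ind_id, ind in list(pending.items()):
                parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
                if all(p in placed for p in parents):
                    order.append(ind_id)
                    placed.add(ind_id)
                    del pending[ind_id]
                    progressed = True
            if not progressed:  # pragma: no cover - validate() rejects cycles
                raise ValidationError("pedigree contains a parentage cycle")
        return order
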