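"""Transcript-level interpretation of coding variants.

Covers codon-level substitution effects, stop-loss read-through translation
on alternative splice forms, in-silico restriction (RFLP) digestion, and
global protein identity.

Coding math happens in cDNA (c.) coordinates, 1-based from the first base of
the start codon; genomic positions map through the exon structure.  A
stop-loss event is read through in the frame of the *mutated* transcript
until the first downstream in-frame termination codon of that splice form,
which is why two isoforms sharing a coding sequence can acquire C-terminal
extensions of different lengths.  Only the standard nuclear genetic code is
used (no selenocysteine read-through).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import ceil
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .core import GenomicInterval, ParseError, ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def translate(seq: str, to_stop: bool = True) -> str:
    """Translate a nucleotide string with the standard code."""
    coding = seq[: len(seq) - len(seq) % 3]
    return str(Seq(coding).translate(to_stop=to_stop))


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """Exon structure plus spliced cDNA with CDS bounds.

    ``cds_start``/``cds_end`` are 1-based positions in the spliced cDNA;
    exons are ordered 5'->3' along the transcript (descending genomic
    coordinates on the minus strand).
    """

    id: str
    gene: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    cdna: str

    def __post_init__(self) -> None:
        self.cdna = self.cdna.upper()
        if self.strand not in "+-":
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        span = sum(e.n_bases() for e in self.exons)
        if span != len(self.cdna):
            raise ValidationError(
                f"{self.id}: exon span {span} != cDNA length {len(self.cdna)}"
            )
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3 != 0:
            raise ValidationError(f"{self.id}: CDS length {cds_len} not divisible by 3")
        if translate(self.cds_seq()[-3:], to_stop=False) != "*":
            raise ValidationError(f"{self.id}: reference CDS does not end in a stop codon")

    def cds_seq(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]

    def protein(self) -> str:
        """Reference protein (stop codon not included)."""
        return translate(self.cds_seq(), to_stop=True)

    def c_to_cdna(self, c_pos: int) -> int:
        """c. coordinate (1 = first base of start codon) -> cDNA position."""
        pos = self.cds_start + c_pos - 1
        if not (1 <= pos <= len(self.cdna)):
            raise ValidationError(f"c.{c_pos} outside cDNA of {self.id}")
        return pos

    def cdna_to_genomic(self, cdna_pos: int) -> tuple[str, int]:
        if not (1 <= cdna_pos <= len(self.cdna)):
            raise ValidationError(f"cDNA position {cdna_pos} outside {self.id}")
        offset = cdna_pos - 1
        for exon in self.exons:
            if offset < exon.n_bases():
                if self.strand == "+":
                    return exon.chrom, exon.start + offset
                return exon.chrom, exon.end - offset
            offset -= exon.n_bases()
        raise AssertionError("unreachable")  # pragma: no cover

    def genomic_to_cdna(self, chrom: str, pos: int) -> int:
        offset = 0
        for exon in self.exons:
            if exon.contains(chrom, pos):
                within = pos - exon.start if self.strand == "+" else exon.end - pos
                return offset + within + 1
            offset += exon.n_bases()
        raise ValidationError(f"{chrom}:{pos} not exonic in transcript {self.id}")


# ---------------------------------------------------------------------------
# cDNA-level variants
# ---------------------------------------------------------------------------

_HGVS_RE = re.compile(
    r"^(?:c\.)?(?P<start>\d+)(?:_(?P<end>\d+))?"
    r"(?:(?P<sub>(?P<ref>[ACGT])>(?P<alt>[ACGT]))|(?P<del>del(?P<dseq>[ACGT]*))|(?P<ins>ins(?P<iseq>[ACGT]+)))$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class CdnaVariant:
    """A substitution, deletion or insertion in transcript coordinates.

    ``start``/``end`` are inclusive c. positions (for insertions, the two
    flanking positions).  Parsed from HGVS-like strings such as
    ``c.2453G>A``, ``c.2771del``, ``c.2771delA`` or ``c.100_101insTGC``.
    """

    kind: str  # sub | del | ins
    start: int
    end: int
    ref: str = ""
    alt: str = ""

    @classmethod
    def parse(cls, text: str) -> "CdnaVariant":
        m = _HGVS_RE.match(text.strip())
        if m is None:
            raise ParseError(f"cannot parse variant {text!r}")
        start = int(m.group("start"))
        end = int(m.group("end") or start)
        if end < start:
            raise ParseError(f"inverted position range in {text!r}")
        if m.group("sub"):
            if end != start:
                raise ParseError(f"substitution with a range: {text!r}")
            return cls("sub", start, start, m.group("ref").upper(), m.group("alt").upper())
        if m.group("del"):
            dseq = (m.group("dseq") or "").upper()
            if dseq and len(dseq) != end - start + 1:
                raise ParseError(f"deleted bases disagree with range in {text!r}")
            return cls("del", start, end, dseq, "")
        iseq = m.group("iseq").upper()
        if end != start + 1:
            raise ParseError(f"insertion positions must flank: {text!r}")
        return cls("ins", start, end, "", iseq)

    def __str__(self) -> str:
        if self.kind == "sub":
            return f"c.{self.start}{self.ref}>{self.alt}"
        if self.kind == "del":
            span = f"{self.start}" if self.start == self.end else f"{self.start}_{self.end}"
            return f"c.{span}del{self.ref}"
        return f"c.{self.start}_{self.end}ins{self.alt}"

    @property
    def length_change(self) -> int:
        if self.kind == "sub":
            return 0
        if self.kind == "del":
            return -(self.end - self.start + 1)
        return len(self.alt)


def apply_cdna_variant(seq: str, var: CdnaVariant, offset: int = 0) -> str:
    """Apply *var* to *seq*; positions are 1-based after subtracting *offset*.

    For transcript application, *offset* is ``cds_start - 1`` so that c.1
    lands on the first base of the start codon.
    """
    s = var.start + offset - 1
    e = var.end + offset - 1
    if not (0 <= s < len(seq)) or not (0 <= e < len(seq)):
        raise ValidationError(f"variant {var} outside sequence of length {len(seq)}")
    if var.kind == "sub":
        if var.ref and seq[s] != var.ref:
            raise ValidationError(
                f"reference mismatch at position {var.start}: expected "
                f"{var.ref}, sequence has {seq[s]}"
            )
        return seq[:s] + var.alt + seq[s + 1 :]
    if var.kind == "del":
        if var.ref and seq[s : e + 1] != var.ref:
            raise ValidationError(
                f"reference mismatch for {var}: sequence has {seq[s:e + 1]}"
            )
        return seq[:s] + seq[e + 1 :]
    return seq[: s + 1] + var.alt + seq[s + 1 :]


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

@dataclass
class CodingEffect:
    """Predicted protein-level consequence of a cDNA variant."""

    kind: str  # synonymous | missense | stopgain | stoploss | frameshift | inframe_indel
    codon_index: int
    ref_aa: str
    alt_aa: str
    extension_peptide: str = ""
    extension_length: int = 0
    nonstop_runthrough: bool = False

    @property
    def hgvs_p(self) -> str:
        if self.kind == "stoploss":
            return f"p.X{self.codon_index}{self.alt_aa}"
        if self.kind == "synonymous":
            return f"p.{self.ref_aa}{self.codon_index}="
        return f"p.{self.ref_aa}{self.codon_index}{self.alt_aa}"


def _stop_codon_indices(tx: Transcript) -> range:
    return range(tx.cds_end - 2, tx.cds_end + 1)  # cdna positions of the stop


def classify_coding_effect(tx: Transcript, var: CdnaVariant) -> CodingEffect:
    """Classify a cDNA variant against one transcript.

    Substitutions are translated with the standard code; length changes not
    divisible by three are frameshifts; any event that abolishes the
    reference termination codon is a stop-loss, with the read-through
    extension computed on this transcript's own 3' sequence.
    """
    cdna_start = tx.c_to_cdna(var.start)
    cdna_end = tx.c_to_cdna(var.end)
    stop_positions = _stop_codon_indices(tx)

    touches_stop = not (cdna_end < stop_positions.start or cdna_start > stop_positions.stop - 1)
    if touches_stop and _abolishes_stop(tx, var):
        return stoploss_extension(tx, var)

    if cdna_start < tx.cds_start or cdna_end > tx.cds_end:
        raise ValidationError(
            f"{var} lies outside the CDS of {tx.id}; only coding variants are classified"
        )

    if var.kind == "sub":
        codon_index = ceil(var.start / 3)
        codon_lo = tx.cds_start + (codon_index - 1) * 3 - 1
        ref_codon = tx.cdna[codon_lo : codon_lo + 3]
        within = (var.start - 1) % 3
        if var.ref and ref_codon[within] != var.ref:
            raise ValidationError(
                f"reference mismatch: codon {codon_index} is {ref_codon}, "
                f"position {within + 1} is not {var.ref}"
            )
        alt_codon = ref_codon[:within] + var.alt + ref_codon[within + 1 :]
        ref_aa = translate(ref_codon, to_stop=False)
        alt_aa = translate(alt_codon, to_stop=False)
        if alt_aa == ref_aa:
            kind = "synonymous"
        elif alt_aa == "*":
            kind = "stopgain"
        else:
            kind = "missense"
        return CodingEffect(kind, codon_index, ref_aa, alt_aa)

    codon_index = ceil(var.start / 3)
    if var.length_change % 3 != 0:
        return CodingEffect("frameshift", codon_index, "", "")
    return CodingEffect("inframe_indel", codon_index, "", "")


def _abolishes_stop(tx: Transcript, var: CdnaVariant) -> bool:
    mutant = apply_cdna_variant(tx.cdna, var, offset=tx.cds_start - 1)
    new_stop = mutant[tx.cds_end - 3 : tx.cds_end]
    return translate(new_stop, to_stop=False) != "*"


def stoploss_extension(tx: Transcript, var: CdnaVariant) -> CodingEffect:
    """Read-through translation after loss of the termination codon.

    Translates the mutated transcript from the start codon until the first
    in-frame stop in this splice form's 3' sequence.  The extension peptide
    is everything beyond the reference protein length (its first residue is
    the one replacing the former stop).  If no downstream stop exists before
    the transcript end, the effect is flagged ``nonstop_runthrough``.
    """
    if not _abolishes_stop(tx, var):
        raise ValidationError(f"{var} does not abolish the stop codon of {tx.id}")
    mutant = apply_cdna_variant(tx.cdna, var, offset=tx.cds_start - 1)
    tail = mutant[tx.cds_start - 1 :]
    full = translate(tail, to_stop=False)
    stop_at = full.find("*")
    nonstop = stop_at < 0
    protein = full if nonstop else full[:stop_at]
    n_ref = len(tx.protein())
    extension = protein[n_ref:]
    return CodingEffect(
        kind="stoploss",
        codon_index=n_ref + 1,
        ref_aa="*",
        alt_aa=extension[:1],
        extension_peptide=extension,
        extension_length=len(extension),
        nonstop_runthrough=nonstop,
    )


# ---------------------------------------------------------------------------
# restriction digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestrictionEnzyme:
    """Name, IUPAC recognition sequence and cut offset within the site."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = [b for b in self.recognition.upper() if b not in IUPAC_DNA]
        if bad:
            raise ValidationError(f"invalid IUPAC symbols in recognition site: {bad}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValidationError("cut offset outside recognition site")

    def regex(self) -> re.Pattern:
        pattern = "".join(f"[{IUPAC_DNA[b]}]" for b in self.recognition.upper())
        return re.compile(f"(?=({pattern}))")


#: AluI: blunt cutter AG^CT, palindromic, the classic RFLP workhorse
ALU_I = RestrictionEnzyme("AluI", "AGCT", 2)

ENZYMES = {"AluI": ALU_I}


@dataclass
class DigestResult:
    """Comparison of restriction maps of a reference and mutant amplicon."""

    enzyme: RestrictionEnzyme
    sites_ref: list[int]
    sites_mut: list[int]
    lost: list[int]
    gained: list[int]
    fragments_ref: list[int]
    fragments_mut: list[int]


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of recognition sites (forward strand;
    palindromic recognition makes the reverse strand redundant)."""
    if not seq:
        raise ValidationError("empty sequence")
    return [m.start() + 1 for m in enzyme.regex().finditer(seq.upper())]


def _fragments(seq_len: int, sites: Sequence[int], cut_offset: int) -> list[int]:
    cuts = sorted({s - 1 + cut_offset for s in sites} - {0, seq_len})
    bounds = [0] + list(cuts) + [seq_len]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def digest_compare(
    amplicon_ref: str, variant: CdnaVariant, enzyme: RestrictionEnzyme
) -> DigestResult:
    """Restriction maps of an amplicon before and after one variant.

    Site loss/gain is decided by projecting reference site coordinates onto
    the mutant (positions right of a deletion/insertion shift by the length
    change; positions inside a deleted span have no image): a reference site
    is *lost* if no mutant site starts at its projected coordinate, and a
    mutant site is *gained* if it is not the image of a surviving reference
    site.  Fragment lengths always partition the amplicon length.
    """
    amplicon_ref = amplicon_ref.upper()
    mutant = apply_cdna_variant(amplicon_ref, variant)
    sites_ref = find_sites(amplicon_ref, enzyme)
    sites_mut = find_sites(mutant, enzyme) if mutant else []

    delta = variant.length_change

    def project(pos: int) -> Optional[int]:
        if variant.kind == "sub":
            return pos
        if variant.kind == "del":
            if pos < variant.start:
                return pos
            if pos <= variant.end:
                return None
            return pos + delta
        return pos if pos <= variant.start else pos + delta

    mut_set = set(sites_mut)
    surviving_images = set()
    lost = []
    for s in sites_ref:
        image = project(s)
        if image is not None and image in mut_set:
            surviving_images.add(image)
        else:
            lost.append(s)
    gained = [m for m in sites_mut if m not in surviving_images]

    return DigestResult(
        enzyme=enzyme,
        sites_ref=sites_ref,
        sites_mut=sites_mut,
        lost=lost,
        gained=gained,
        fragments_ref=_fragments(len(amplicon_ref), sites_ref, enzyme.cut_offset),
        fragments_mut=_fragments(len(mutant), sites_mut, enzyme.cut_offset),
    )


# ---------------------------------------------------------------------------
# protein identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring for percent-identity reports."""

    match: float = 1.0
    mismatch: float = 0.0
    open_gap: float = -5.0
    extend_gap: float = -0.5


def global_identity(
    protein_a: str, protein_b: str, params: AlignmentParams = AlignmentParams()
) -> tuple[int, int, int]:
    """Global alignment identity of two proteins.

    Returns ``(matches, denominator, percent)`` where the denominator is the
    length of *protein_a* (the reference/query convention) and percent is
    rounded to the nearest integer.
    """
    for name, seq in (("protein_a", protein_a), ("protein_b", protein_b)):
        if not seq:
            raise ValidationError(f"{name} is empty")
        bad = sorted(set(seq.upper()) - STANDARD_AA)
        if bad:
            raise ValidationError(f"invalid residue symbols in {name}: {bad}")
    a, b = protein_a.upper(), protein_b.upper()
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    alignment = aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    denominator = len(a)
    percent = round(matches / denominator * 100)
    return matches, denominator, int(percent)
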