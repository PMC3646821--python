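"""Synthetic TNPO3-like transcript and protein fixtures.

Everything here is constructed in code: the sequences are *synthetic
stand-ins*, not RefSeq records, built so that the documented molecular
anatomy of the TNPO3 stop-loss disease allele is reproduced exactly:

* a 923-residue reference protein translated from a 2,772-nt CDS ending in
  a TAG termination codon (c.2770-2772);
* two muscle splice forms sharing the whole CDS: form A splices exon 22 to
  a non-coding exon 23, form B terminates within an extended exon 22;
* deleting the A of the stop codon (c.2771del; deleted base at
  chr7:128,597,310 on the synthetic exon layout) turns codon 924 into TGC,
  i.e. p.X924C, and the read-through runs into splice-form-specific 3'
  sequence: 15 extra residues (CSHSCSVPVTQECLF) on form A and 95 extra
  residues on form B;
* the reference allele carries an AluI site (AGCT) spanning c.2771-2774
  that the deletion destroys, enabling an RFLP assay;
* codon 818 is AGA (arginine) so that c.2453 is its second base, the site
  of the independent missense allele c.2453G>A;
* a zebrafish-like ortholog stand-in differs from the human stand-in at 131
  of 923 positions, i.e. 792/923 (86%) global identity.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, ParseError
from .consequence import ALU_I, CdnaVariant, RestrictionEnzyme, Transcript

PROTEIN_LENGTH = 923
UTR5_LENGTH = 100
CDS_START = UTR5_LENGTH + 1                  # cDNA position of the start codon
CDS_END = UTR5_LENGTH + PROTEIN_LENGTH * 3 + 3  # last base of the stop codon
GENE_START = 128_588_140                     # synthetic plus-strand layout, chr7
INTRON_LENGTH = 300
DELETED_BASE_GENOMIC = 128_597_310           # genomic position of the stop codon's A

_FIXTURE_SEED = 20_070_032  # fixed; fixture sequences are part of the API

# one sense codon per amino acid (arbitrary fixed choice)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"

# read-through anatomy (mutant frame = "TG" + 3'UTR after the delA):
# codon 924 = TGC (Cys), then the form-specific extension
_FORM_A_EXT_CODONS = [
    "TGC", "TCT", "CAT", "TCT", "TGC", "TCT", "GTT", "CCT",
    "GTT", "ACT", "CAA", "GAA", "TGC", "CTT", "TTT", "TAA",
]
_SHARED_UTR = "".join(_FORM_A_EXT_CODONS)[2:14]  # exon-22 part, both forms


def human_tnpo3_protein() -> str:
    """Synthetic 923-aa stand-in for the long human TNPO3 isoform."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    residues = list(rng.choice(list(_AA), size=PROTEIN_LENGTH))
    residues[0] = "M"
    residues[817] = "R"  # codon 818, the missense-allele position
    return "".join(residues)


def zebrafish_tnpo3_protein() -> str:
    """Synthetic zebrafish-like ortholog: 131/923 positions substituted."""
    human = human_tnpo3_protein()
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    positions = rng.choice(np.arange(1, PROTEIN_LENGTH), size=131, replace=False)
    residues = list(human)
    for p in positions:
        old = residues[p]
        choices = [a for a in _AA if a != old]
        residues[p] = choices[int(rng.integers(len(choices)))]
    return "".join(residues)


def _cds() -> str:
    protein = human_tnpo3_protein()
    codons = [_CODON[a] for a in protein]
    codons[817] = "AGA"  # arginine codon whose 2nd base is c.2453 G
    return "".join(codons) + "TAG"


def _utr5() -> str:
    rng = np.random.default_rng(_FIXTURE_SEED + 2)
    return "".join(rng.choice(list("ACGT"), size=UTR5_LENGTH))


def _form_b_utr() -> str:
    """Extended-exon-22 3'UTR giving a 95-residue read-through extension."""
    rng = np.random.default_rng(_FIXTURE_SEED + 3)
    sense_codons = [c for c in _CODON.values() if c not in ("TAA", "TAG", "TGA")]
    # shared exon-22 segment (extension residues 1-4 plus the TG of codon 5)
    utr = [_SHARED_UTR, "T"]  # codon 924+4 = TG|T -> Cys
    for _ in range(90):  # extension residues 6..95
        utr.append(sense_codons[int(rng.integers(len(sense_codons)))])
    utr.append("TAA")
    utr.append("".join(rng.choice(list("ACGT"), size=30)))
    return "".join(utr)


def _form_a_utr() -> str:
    rng = np.random.default_rng(_FIXTURE_SEED + 4)
    ext = "".join(_FORM_A_EXT_CODONS)[2:]  # 46 nt incl. the new stop
    return ext + "".join(rng.choice(list("ACGT"), size=40))


def _exon_layout(cdna_len: int, n_exons: int) -> list[GenomicInterval]:
    """Plus-strand synthetic exon layout: 20 x 125 nt, exon 21 of 200 nt,
    exon 22 to the shared-UTR boundary, optional non-coding exon 23."""
    bounds = [125 * i for i in range(1, 21)] + [2700]
    shared_end = CDS_END + len(_SHARED_UTR)  # cDNA end of exon 22's shared part
    if n_exons == 23:
        bounds += [shared_end, cdna_len]
    else:
        bounds += [cdna_len]
    exons = []
    prev = 0
    for k, b in enumerate(bounds):
        g_start = GENE_START + prev + INTRON_LENGTH * k
        exons.append(GenomicInterval("chr7", g_start, g_start + (b - prev) - 1))
        prev = b
    return exons


def _build_form(form: str) -> Transcript:
    cds = _cds()
    if form == "A":
        cdna = _utr5() + cds + _form_a_utr()
        exons = _exon_layout(len(cdna), 23)
        tx_id = "TNPO3-FORM-A"
    else:
        cdna = _utr5() + cds + _form_b_utr()
        exons = _exon_layout(len(cdna), 22)
        tx_id = "TNPO3-FORM-B"
    return Transcript(
        id=tx_id, gene="TNPO3", strand="+", exons=exons,
        cds_start=CDS_START, cds_end=CDS_END, cdna=cdna,
    )


def tnpo3_form_a() -> Transcript:
    """Splice form A: exon 22 joined to the non-coding exon 23."""
    return _build_form("A")


def tnpo3_form_b() -> Transcript:
    """Splice form B: terminates within an extended exon 22."""
    return _build_form("B")


def tnpo3_delA() -> CdnaVariant:
    """The stop-loss allele: deletion of the A of the TAG stop codon."""
    return CdnaVariant.parse("c.2771delA")


def tnpo3_missense() -> CdnaVariant:
    """The independent missense allele in exon 21, c.2453G>A."""
    return CdnaVariant.parse("c.2453G>A")


def exon22_amplicon() -> tuple[str, CdnaVariant, RestrictionEnzyme]:
    """A short amplicon over the stop codon for the AluI RFLP assay.

    Returns the reference amplicon, the delA variant in amplicon
    coordinates, and the AluI enzyme.
    """
    tx = tnpo3_form_a()
    lo = CDS_END - 32  # 0-based slice start; stop codon near the middle
    amplicon = tx.cdna[lo : lo + 70]
    del_pos = (UTR5_LENGTH + 2771) - lo  # 1-based within amplicon
    return amplicon, CdnaVariant("del", del_pos, del_pos, "A", ""), ALU_I


# ---------------------------------------------------------------------------
# transcript FASTA + exon-table round trip (for the CLI surface)
# ---------------------------------------------------------------------------

def write_transcript(tx: Transcript, fasta_path, exons_path) -> None:
    """Write the spliced cDNA as FASTA and the exon structure as TSV."""
    rec = SeqRecord(
        Seq(tx.cdna),
        id=tx.id,
        description=f"gene={tx.gene} strand={tx.strand} cds={tx.cds_start}-{tx.cds_end}",
    )
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(exons_path, "w") as fh:
        fh.write("transcript_id\texon_rank\tchrom\tstart\tend\n")
        for rank, exon in enumerate(tx.exons, start=1):
            fh.write(f"{tx.id}\t{rank}\t{exon.chrom}\t{exon.start}\t{exon.end}\n")


def read_transcript(fasta_path, exons_path, transcript_id: Optional[str] = None) -> Transcript:
    """Read a transcript back from FASTA (+ header tokens) and exon TSV."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if transcript_id is not None:
        records = [r for r in records if r.id == transcript_id]
    if not records:
        raise ParseError(f"no matching transcript in {fasta_path}")
    rec = records[0]
    tokens = dict(
        t.split("=", 1) for t in rec.description.split() if "=" in t
    )
    try:
        cds_lo, cds_hi = tokens["cds"].split("-")
    except KeyError as exc:
        raise ParseError(f"FASTA header of {rec.id} lacks a cds=START-END token") from exc
    exons = []
    with open(exons_path) as fh:
        header = fh.readline().split()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = dict(zip(header, line.split()))
            if fields["transcript_id"] != rec.id:
                continue
            exons.append(
                (int(fields["exon_rank"]),
                 GenomicInterval(fields["chrom"], int(fields["start"]), int(fields["end"])))
            )
    exons.sort()
    return Transcript(
        id=rec.id,
        gene=tokens.get("gene", ""),
        strand=tokens.get("strand", "+"),
        exons=[e for _, e in exons],
        cds_start=int(cds_lo),
        cds_end=int(cds_hi),
        cdna=str(rec.seq),
    )


def write_protein_fasta(sequences: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
        str(path),
        "fasta",
    )


def read_protein_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
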