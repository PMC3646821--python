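"""Transcript consequences: coding effects, read-through, RFLP, identity."""

import numpy as np
import pytest
from Bio.Restriction import AluI
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from pedexome import datasets
from pedexome.consequence import (
    ALU_I,
    AlignmentParams,
    CdnaVariant,
    RestrictionEnzyme,
    Transcript,
    apply_cdna_variant,
    classify_coding_effect,
    digest_compare,
    find_sites,
    global_identity,
    stoploss_extension,
    translate,
)
from pedexome.core import GenomicInterval, ParseError, ValidationError

CODON_TABLE = {}  # filled lazily by the brute-force oracle


def naive_codon_walk(cdna, cds_start):
    """Independent translation oracle: walk codons until a stop."""
    protein = []
    for i in range(cds_start - 1, len(cdna) - 2, 3):
        aa = str(Seq(cdna[i : i + 3]).translate())
        if aa == "*":
            return "".join(protein)
        protein.append(aa)
    return "".join(protein)


def toy_transcript(cdna, cds_start, cds_end, tx_id="TOY"):
    n = len(cdna)
    return Transcript(
        id=tx_id, gene="TOY", strand="+",
        exons=[GenomicInterval("chr1", 1000, 1000 + n - 1)],
        cds_start=cds_start, cds_end=cds_end, cdna=cdna,
    )


class TestCdnaVariantParsing:
    @pytest.mark.parametrize(
        "text,kind,start,end",
        [
            ("c.2453G>A", "sub", 2453, 2453),
            ("c.2771del", "del", 2771, 2771),
            ("c.2771delA", "del", 2771, 2771),
            ("c.100_102del", "del", 100, 102),
            ("c.100_101insTGC", "ins", 100, 101),
            ("2770delA", "del", 2770, 2770),
        ],
    )
    def test_accepted_forms(self, text, kind, start, end):
        var = CdnaVariant.parse(text)
        assert (var.kind, var.start, var.end) == (kind, start, end)

    @pytest.mark.parametrize("text", ["c.12", "c.5G>", "c.1_3insX", "c.100_99del", "c.100_102insA"])
    def test_rejected_forms(self, text):
        with pytest.raises(ParseError):
            CdnaVariant.parse(text)

    def test_deletion_reference_mismatch_detected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            apply_cdna_variant("AAAA", CdnaVariant("del", 2, 2, "G", ""))


class TestTranscriptModel:
    def test_fixture_protein_is_923_residues(self):
        for tx in (datasets.tnpo3_form_a(), datasets.tnpo3_form_b()):
            assert len(tx.protein()) == 923
            assert tx.protein() == naive_codon_walk(tx.cdna, tx.cds_start)

    def test_exon_span_must_match_cdna(self):
        with pytest.raises(ValidationError, match="exon span"):
            toy_transcript("ATGAAATAA", 1, 9).exons  # 9 nt ok ...
            Transcript(
                id="BAD", gene="X", strand="+",
                exons=[GenomicInterval("chr1", 1, 5)],
                cds_start=1, cds_end=9, cdna="ATGAAATAA",
            )

    def test_cds_must_end_in_stop(self):
        with pytest.raises(ValidationError, match="stop"):
            toy_transcript("ATGAAAAAA", 1, 9)

    def test_genomic_mapping_round_trip(self):
        tx = datasets.tnpo3_form_a()
        for cdna_pos in (1, 100, 2871, len(tx.cdna)):
            chrom, g = tx.cdna_to_genomic(cdna_pos)
            assert tx.genomic_to_cdna(chrom, g) == cdna_pos

    def test_stop_codon_deletion_site_maps_to_printed_position(self):
        tx = datasets.tnpo3_form_a()
        assert tx.cdna_to_genomic(tx.c_to_cdna(2771)) == ("chr7", 128_597_310)

    def test_intronic_position_rejected(self):
        tx = datasets.tnpo3_form_a()
        with pytest.raises(ValidationError, match="not exonic"):
            tx.genomic_to_cdna("chr7", datasets.GENE_START + 130)  # inside intron 1

    def test_fasta_exon_table_round_trip(self, tmp_path):
        tx = datasets.tnpo3_form_b()
        fasta, exons = tmp_path / "b.fa", tmp_path / "b.tsv"
        datasets.write_transcript(tx, fasta, exons)
        back = datasets.read_transcript(fasta, exons)
        assert back == tx


class TestClassifyCodingEffect:
    def test_stop_codon_deletion_is_stoploss_at_codon_924(self):
        effect = classify_coding_effect(datasets.tnpo3_form_a(), datasets.tnpo3_delA())
        assert effect.kind == "stoploss"
        assert effect.codon_index == 924
        assert effect.hgvs_p == "p.X924C"

    def test_exon21_missense_follows_the_genetic_code(self):
        # c.2453 is position 2 of codon 818 (AGA, arginine); G>A gives AAA,
        # lysine -- the code admits no G>A substitution turning Arg into Pro
        effect = classify_coding_effect(datasets.tnpo3_form_a(), datasets.tnpo3_missense())
        assert effect.kind == "missense"
        assert effect.codon_index == 818
        assert (effect.ref_aa, effect.alt_aa) == ("R", "K")

    def test_synonymous_substitution(self):
        tx = toy_transcript("ATGCTTAAATAA", 1, 12)  # M L K *
        effect = classify_coding_effect(tx, CdnaVariant.parse("c.6T>G"))  # CTT->CTG = L
        assert effect.kind == "synonymous"

    def test_stopgain_substitution(self):
        tx = toy_transcript("ATGCTTAAATAA", 1, 12)
        effect = classify_coding_effect(tx, CdnaVariant.parse("c.4C>T"))  # CTT->TTT? F
        assert effect.kind == "missense"
        effect = classify_coding_effect(tx, CdnaVariant.parse("c.7A>T"))  # AAA->TAA *
        assert effect.kind == "stopgain"

    def test_frameshift_deletion_mid_cds(self):
        tx = toy_transcript("ATGCTTAAATAA", 1, 12)
        effect = classify_coding_effect(tx, CdnaVariant.parse("c.4del"))
        assert effect.kind == "frameshift"

    def test_position_outside_cdna_is_an_error(self):
        tx = toy_transcript("ATGCTTAAATAA", 1, 12)
        with pytest.raises(ValidationError):
            classify_coding_effect(tx, CdnaVariant.parse("c.999G>A"))


class TestStoplossExtension:
    def test_form_a_gains_the_15_residue_peptide(self):
        effect = stoploss_extension(datasets.tnpo3_form_a(), datasets.tnpo3_delA())
        assert effect.extension_peptide == "CSHSCSVPVTQECLF"
        assert effect.extension_length == 15
        assert not effect.nonstop_runthrough

    def test_form_b_gains_95_residues(self):
        effect = stoploss_extension(datasets.tnpo3_form_b(), datasets.tnpo3_delA())
        assert effect.extension_length == 95
        assert effect.extension_peptide[:4] == "CSHS"  # shared exon-22 segment

    def test_non_stop_disrupting_variant_is_an_error(self):
        with pytest.raises(ValidationError, match="abolish"):
            stoploss_extension(datasets.tnpo3_form_a(), CdnaVariant.parse("c.3G>A"))

    def test_runthrough_without_downstream_stop_is_flagged(self):
        tx = toy_transcript("ATGAAATAACGGGGGGG", 1, 9)
        effect = stoploss_extension(tx, CdnaVariant.parse("c.8del"))
        assert effect.nonstop_runthrough

    def test_toy_example_matches_codon_walk(self):
        tx = toy_transcript("ATGAAATAATGATTTTAA", 1, 9)  # M K * | readthrough
        effect = stoploss_extension(tx, CdnaVariant.parse("c.8delA"))
        mutant = tx.cdna[:7] + tx.cdna[8:]
        assert effect.extension_peptide == naive_codon_walk(mutant, 1)[2:]

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_toy_transcripts_match_codon_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(3, 30))
        sense = [c for c in
                 ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                 if str(Seq(c).translate()) != "*"]
        body = "".join(rng.choice(sense) for _ in range(n_codons))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
        cdna = "ATG" + body + "TGA" + utr3
        cds_end = 3 + len(body) + 3
        tx = toy_transcript(cdna, 1, cds_end)
        var = CdnaVariant("del", cds_end - 1, cds_end - 1, "G", "")
        mutant = apply_cdna_variant(cdna, var)
        oracle_protein = naive_codon_walk(mutant, 1)
        if len(oracle_protein) == len(tx.protein()):
            return  # deletion created another in-frame stop immediately
        effect = stoploss_extension(tx, var)
        assert effect.extension_peptide == oracle_protein[len(tx.protein()):]


def brute_force_sites(seq, recognition):
    """Sliding-window IUPAC match enumeration."""
    from pedexome.consequence import IUPAC_DNA

    hits = []
    k = len(recognition)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in IUPAC_DNA[recognition[j]] for j in range(k)):
            hits.append(i + 1)
    return hits


class TestDigestCompare:
    def test_constructed_site_loss(self):
        ref = "TTAGCTTT"  # AluI AGCT at position 3
        result = digest_compare(ref, CdnaVariant("del", 3, 3, "A", ""), ALU_I)
        assert result.sites_ref == [3]
        assert result.lost == [3] and result.gained == []

    def test_fixture_amplicon_loses_an_alu_site(self):
        amplicon, variant, enzyme = datasets.exon22_amplicon()
        result = digest_compare(amplicon, variant, enzyme)
        assert len(result.lost) >= 1
        assert sum(result.fragments_ref) == len(amplicon)
        assert sum(result.fragments_mut) == len(amplicon) - 1

    def test_site_gain_reported(self):
        ref = "TTAACTTT"
        result = digest_compare(ref, CdnaVariant("sub", 4, 4, "A", "G"), ALU_I)
        assert result.gained == [3] and result.lost == []

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValidationError):
            find_sites("", ALU_I)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_sequences_match_enumeration_and_biopython(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        sites = find_sites(seq, ALU_I)
        assert sites == brute_force_sites(seq, "AGCT")
        # independent cross-check: Biopython reports 1-based cut positions
        assert [s + ALU_I.cut_offset for s in sites] == AluI.search(Seq(seq))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fragment_lengths_partition_the_amplicon(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 300))))
        pos = int(rng.integers(1, len(seq) + 1))
        kind = ["sub", "del", "ins"][int(rng.integers(3))]
        if kind == "sub":
            var = CdnaVariant("sub", pos, pos, "", "ACGT"[int(rng.integers(4))])
        elif kind == "del":
            var = CdnaVariant("del", pos, pos, "", "")
        else:
            pos = min(pos, len(seq) - 1)
            var = CdnaVariant("ins", pos, pos + 1, "", "ACGT"[int(rng.integers(4))])
        result = digest_compare(seq, var, ALU_I)
        assert sum(result.fragments_ref) == len(seq)
        assert sum(result.fragments_mut) == len(seq) + var.length_change


class TestGlobalIdentity:
    def test_identical_sequences(self):
        seq = "M" + "ACDEFGHIKL" * 5
        m, d, pct = global_identity(seq[:50], seq[:50])
        assert (m, d, pct) == (50, 50, 100)

    def test_single_substitution_in_ten(self):
        m, d, pct = global_identity("ACDEFGHIKL", "ACDEFGHIKV")
        assert (m, d, pct) == (9, 10, 90)

    def test_match_count_symmetric_denominator_is_not(self):
        a, b = "ACDEFGHIKL", "ACDEFGHIKLMNP"
        m_ab, d_ab, _ = global_identity(a, b)
        m_ba, d_ba, _ = global_identity(b, a)
        assert m_ab == m_ba
        assert (d_ab, d_ba) == (len(a), len(b))

    def test_human_vs_zebrafish_synthetic_orthologs(self):
        m, d, pct = global_identity(
            datasets.human_tnpo3_protein(), datasets.zebrafish_tnpo3_protein()
        )
        assert (m, d, pct) == (792, 923, 86)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValidationError, match="invalid residue"):
            global_identity("ACDX1", "ACDEF")
        with pytest.raises(ValidationError, match="empty"):
            global_identity("", "ACDEF")

    def test_gap_parameters_are_reported_in_config(self):
        params = AlignmentParams()
        assert params.match == 1.0 and params.mismatch == 0.0


class TestEnzymeModel:
    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValidationError):
            RestrictionEnzyme("Bad", "AGXT", 2)

    def test_overlapping_sites_found(self):
        # lookahead scanning must report overlapping matches
        enz = RestrictionEnzyme("Toy", "AN", 1)
        assert find_sites("AAAT", enz) == [1, 2, 3]
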