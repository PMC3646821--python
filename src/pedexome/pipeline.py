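"""End-to-end discovery pipeline: cascade -> segregation -> refinement ->
molecular consequence, with a rendered count table and JSON reports.

Every output file is deterministic for a fixed configuration and seed; all
progress logging goes to stderr so the report bundle is byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cascade import CascadeParams, CascadeResult, run_cascade
from .consequence import (
    ALU_I,
    CdnaVariant,
    Transcript,
    classify_coding_effect,
    digest_compare,
)
from .core import (
    Affection,
    GenomicInterval,
    ParseError,
    PedexomeError,
    ValidationError,
    Variant,
)
from .io import Cohort, read_annotation, read_pedigree, read_vcf_cohort, write_bed, write_vcf
from .segregation import (
    classify_segregation,
    estimate_penetrance,
    read_markers,
    refine_interval,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative inputs of one pipeline run (CLI overrides file values)."""

    vcf: str
    ped: str
    interval: GenomicInterval
    out_dir: str
    annotation: Optional[str] = None
    markers: Optional[str] = None
    sanger: Optional[str] = None  # family-wide genotypes of the top candidate
    transcripts: Optional[list[tuple[str, str]]] = None  # (fasta, exon tsv) pairs
    affected_ids: Optional[list[str]] = None
    subset_ids: Optional[list[str]] = None
    freq_threshold: float = 0.01
    coverage_threshold: int = 10
    seed: int = 17
    log_level: str = "INFO"

    def validate(self) -> None:
        for label, path in (
            ("vcf", self.vcf),
            ("ped", self.ped),
            ("annotation", self.annotation),
            ("markers", self.markers),
            ("sanger", self.sanger),
        ):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{label} path does not exist: {path}")
        for pair in self.transcripts or []:
            for path in pair:
                if not Path(path).exists():
                    raise ValidationError(f"transcript file does not exist: {path}")


def render_table1(result: CascadeResult) -> str:
    """Render stage counts as TSV: rows = stages, columns = samples + shared.

    Cells are exactly the ``CascadeResult.stage_counts`` values; nothing is
    recomputed at render time.
    """
    df = result.stage_counts.copy()
    df.index.name = "stage"
    return df.to_csv(sep="\t")


def parse_table1(text: str) -> pd.DataFrame:
    """Parse a rendered count table back into a stage-by-sample matrix."""
    from io import StringIO

    return pd.read_csv(StringIO(text), sep="\t", index_col="stage")


def genomic_to_cdna_variant(tx: Transcript, variant: Variant) -> CdnaVariant:
    """Map a genomic VCF-style variant onto transcript (c.) coordinates.

    Handles substitutions and anchored deletions/insertions on plus-strand
    transcripts; raises if the affected bases are not exonic.
    """
    if tx.strand != "+":
        raise ValidationError("genomic mapping implemented for plus-strand transcripts")
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        c = tx.genomic_to_cdna(variant.chrom, variant.pos) - (tx.cds_start - 1)
        return CdnaVariant("sub", c, c, ref, alt)
    if len(ref) > len(alt) and ref.startswith(alt):
        # anchored deletion: deleted bases follow the anchor
        first = variant.pos + len(alt)
        last = variant.pos + len(ref) - 1
        c1 = tx.genomic_to_cdna(variant.chrom, first) - (tx.cds_start - 1)
        c2 = tx.genomic_to_cdna(variant.chrom, last) - (tx.cds_start - 1)
        return CdnaVariant("del", min(c1, c2), max(c1, c2), ref[len(alt):], "")
    if len(alt) > len(ref) and alt.startswith(ref):
        anchor = variant.pos + len(ref) - 1
        c = tx.genomic_to_cdna(variant.chrom, anchor) - (tx.cds_start - 1)
        return CdnaVariant("ins", c, c + 1, "", alt[len(ref):])
    raise ValidationError(f"unsupported allele pair {ref}>{alt} for transcript mapping")


def _consequence_report(
    variant: Variant, transcripts: Sequence[Transcript]
) -> dict:
    """Classify one candidate on every supplied splice form, plus RFLP."""
    report: dict = {"variant": variant.key_str, "gene": variant.gene, "forms": {}}
    for tx in transcripts:
        try:
            cvar = genomic_to_cdna_variant(tx, variant)
        except ValidationError as exc:
            report["forms"][tx.id] = {"skipped": str(exc)}
            continue
        effect = classify_coding_effect(tx, cvar)
        entry = {
            "cdna_variant": str(cvar),
            "kind": effect.kind,
            "hgvs_p": effect.hgvs_p,
            "codon_index": effect.codon_index,
            "extension_length": effect.extension_length,
            "extension_peptide": effect.extension_peptide,
        }
        # RFLP: AluI map of a 70-bp window centred on the variant
        cdna_pos = tx.c_to_cdna(cvar.start)
        lo = max(cdna_pos - 35, 0)
        amplicon = tx.cdna[lo : lo + 70]
        local = dataclasses.replace(
            cvar, start=cdna_pos - lo, end=cvar.end - cvar.start + cdna_pos - lo
        )
        digest = digest_compare(amplicon, local, ALU_I)
        entry["rflp"] = {
            "enzyme": ALU_I.name,
            "sites_lost": len(digest.lost),
            "sites_gained": len(digest.gained),
            "fragments_ref": digest.fragments_ref,
            "fragments_mut": digest.fragments_mut,
        }
        report["forms"][tx.id] = entry
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full discovery pipeline and write the report bundle.

    Stages: filtering cascade over the affected sequenced samples ->
    novelty ranking -> co-segregation classification of every survivor ->
    interval refinement from marker observations -> molecular consequence of
    the top-ranked candidate.  Returns a dict with the bundle paths and the
    key in-memory results.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("load")
        cohort = read_vcf_cohort(config.vcf)
        pedigree = read_pedigree(config.ped)
        if config.annotation:
            ann = read_annotation(config.annotation)
            keep = cohort.variants.index.intersection(ann.index)
            merged = cohort.variants.copy()
            merged.loc[keep, ann.columns] = ann.loc[keep]
            cohort = Cohort(merged, cohort.genotypes)
    except (ParseError, ValidationError) as exc:
        raise PedexomeError(f"stage load failed: {exc}") from exc

    affected = config.affected_ids or [
        s
        for s in cohort.sample_ids
        if s in pedigree and pedigree[s].affected is Affection.AFFECTED
    ]

    _stage("cascade")
    params = CascadeParams(
        interval=config.interval,
        freq_threshold=config.freq_threshold,
        coverage_threshold=config.coverage_threshold,
    )
    result = run_cascade(cohort, affected, params, subset_ids=config.subset_ids)
    table1_path = out / "table1.tsv"
    table1_path.write_text(render_table1(result))

    _stage("survivors")
    surv_keys = [v.key_str for v in result.survivors]
    surv_cohort = Cohort(
        cohort.variants.loc[surv_keys].copy(), cohort.genotypes.loc[surv_keys].copy()
    )
    survivors_path = out / "survivors.vcf"
    write_vcf(surv_cohort, survivors_path)

    _stage("segregation")
    segregation_report = {}
    sanger: dict[str, int] = {}
    if config.sanger:
        table = pd.read_csv(config.sanger, sep="\t", dtype={"sample": str})
        sanger = dict(zip(table["sample"], table["gt_code"].astype(int)))
    for rank, v in enumerate(result.survivors):
        genotypes = {
            s: int(cohort.genotypes.loc[v.key_str, s])
            for s in cohort.sample_ids
            if s in pedigree
        }
        if rank == 0 and sanger:  # family-wide recheck of the top candidate
            genotypes = {**genotypes, **sanger}
        report = classify_segregation(pedigree, genotypes)
        entry = report.to_dict()
        try:
            raw, pct = estimate_penetrance(report)
            entry["penetrance"] = {"raw": round(raw, 4), "rounded": pct}
        except ValidationError:
            entry["penetrance"] = None
        segregation_report[v.key_str] = entry
    segregation_path = out / "segregation.json"
    segregation_path.write_text(
        json.dumps(segregation_report, indent=1, sort_keys=True) + "\n"
    )

    _stage("refine")
    refined = config.interval
    top: Optional[Variant] = result.survivors[0] if result.survivors else None
    if config.markers and top is not None:
        markers = read_markers(config.markers)
        all_affected = pedigree.affected_ids()
        refined = refine_interval(config.interval, top.pos, markers, all_affected)
    refined_bed = out / "refined_interval.bed"
    write_bed([refined], refined_bed)
    (out / "refined_interval.txt").write_text(str(refined) + "\n")

    _stage("consequence")
    transcripts: list[Transcript] = []
    if config.transcripts:
        from .datasets import read_transcript

        for fasta, exons in config.transcripts:
            transcripts.append(read_transcript(fasta, exons))
    else:
        from .datasets import tnpo3_form_a, tnpo3_form_b

        transcripts = [tnpo3_form_a(), tnpo3_form_b()]
    consequence = None
    if top is not None:
        try:
            consequence = _consequence_report(top, transcripts)
        except (ValidationError, ParseError) as exc:
            raise PedexomeError(f"stage consequence failed on {top.key_str}: {exc}") from exc
    consequence_path = out / "consequence.json"
    consequence_path.write_text(
        json.dumps(consequence, indent=1, sort_keys=True) + "\n"
    )

    logger.info(
        "pipeline done: %d survivors, %d catalog-absent, refined interval %s",
        len(result.survivors), result.n_novel, refined,
    )
    return {
        "cascade": result,
        "segregation": segregation_report,
        "refined_interval": refined,
        "consequence": consequence,
        "paths": {
            "table1": str(table1_path),
            "survivors_vcf": str(survivors_path),
            "segregation": str(segregation_path),
            "refined_bed": str(refined_bed),
            "consequence": str(consequence_path),
        },
    }
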