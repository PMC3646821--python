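"""Readers and writers for the standard interchange formats.

VCF handling goes through :mod:`pysam`; only the small slice of VCF v4.x the
pipeline needs is supported (GT genotypes plus the annotation INFO keys
``GENE``, ``VC``, ``AF_A``, ``AF_B``, ``DBSNP``).  Multiallelic records are
split into one variant per ALT allele on read.  Tables (annotation, markers,
coverage) are plain TSV via pandas.  BED import/export converts explicitly
between BED's 0-based half-open coordinates and the package's 1-based closed
:class:`~pedexome.core.GenomicInterval`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    GT_CODES,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GT_NAMES,
    Affection,
    GenomicInterval,
    GenotypeCall,
    Individual,
    ParseError,
    Pedigree,
    Sex,
    ValidationError,
    Variant,
)

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_class",
    "gene",
    "freq_a",
    "freq_b",
    "in_catalog",
    "catalog_id",
]


@dataclass
class Cohort:
    """Variants plus a genotype matrix for a set of sequenced samples.

    ``variants`` is indexed by the ``chrom:pos:ref:alt`` identity key;
    ``genotypes`` shares that index, one int8 column per sample with codes
    0 = hom_ref, 1 = het, 2 = hom_alt, -1 = missing.
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.genotypes.index):
            raise ValidationError("variants and genotypes indices differ")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def variant(self, key_str: str) -> Variant:
        row = self.variants.loc[key_str]
        return _row_to_variant(row)

    @classmethod
    def from_records(
        cls, variants: Sequence[Variant], calls: Sequence[GenotypeCall]
    ) -> "Cohort":
        vdf = variants_to_frame(variants)
        samples = sorted({c.sample_id for c in calls})
        gt = pd.DataFrame(
            np.full((len(vdf), len(samples)), GT_MISSING, dtype=np.int8),
            index=vdf.index,
            columns=samples,
        )
        key_of = {tuple(v.key): v.key_str for v in variants}
        for call in calls:
            key = key_of.get(tuple(call.variant_key))
            if key is None:
                raise ValidationError(f"call references unknown variant {call.variant_key}")
            gt.loc[key, call.sample_id] = GT_CODES[call.gt]
        return cls(vdf, gt)

    def to_records(self) -> tuple[list[Variant], list[GenotypeCall]]:
        variants = [_row_to_variant(row) for _, row in self.variants.iterrows()]
        calls = []
        for v in variants:
            for sample in self.sample_ids:
                code = int(self.genotypes.loc[v.key_str, sample])
                calls.append(GenotypeCall(sample, v.key, GT_NAMES[code]))
        return variants, calls


def _row_to_variant(row: pd.Series) -> Variant:
    def _freq(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return None
        return float(x)

    cid = row["catalog_id"]
    if cid is None or (isinstance(cid, float) and math.isnan(cid)) or cid == "":
        cid = None
    return Variant(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        var_class=str(row["var_class"]),
        gene=str(row["gene"]),
        freq_panel_a=_freq(row["freq_a"]),
        freq_panel_b=_freq(row["freq_b"]),
        in_catalog=bool(row["in_catalog"]),
        catalog_id=cid,
    )


def variants_to_frame(variants: Sequence[Variant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "var_class": v.var_class,
                "gene": v.gene,
                "freq_a": np.nan if v.freq_panel_a is None else v.freq_panel_a,
                "freq_b": np.nan if v.freq_panel_b is None else v.freq_panel_b,
                "in_catalog": v.in_catalog,
                "catalog_id": v.catalog_id,
            }
        )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.index = pd.Index([v.key_str for v in variants], name="key")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate variant identity keys: {dups[:5]}")
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def write_vcf(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write a cohort as a minimal, sorted, single-ALT-per-record VCF."""
    header = pysam.VariantHeader()
    header.add_line('##source=pedexome')
    for chrom in sorted(cohort.variants["chrom"].unique(), key=_chrom_sort_key):
        header.contigs.add(str(chrom))
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("VC", 1, "String", "Functional variant class")
    header.info.add("AF_A", 1, "Float", "Population frequency, panel A")
    header.info.add("AF_B", 1, "Float", "Population frequency, panel B")
    header.info.add("DBSNP", 1, "String", "Known-variant catalog id")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in cohort.sample_ids:
        header.add_sample(sample)

    order = cohort.variants.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
    ).index
    gt_map = {
        GT_HOM_REF: (0, 0),
        GT_HET: (0, 1),
        GT_HOM_ALT: (1, 1),
        GT_MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in order:
            row = cohort.variants.loc[key]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,  # pysam is 0-based internally
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.info["GENE"] = str(row["gene"]) or "."
            rec.info["VC"] = str(row["var_class"])
            if not _isnan(row["freq_a"]):
                rec.info["AF_A"] = float(row["freq_a"])
            if not _isnan(row["freq_b"]):
                rec.info["AF_B"] = float(row["freq_b"])
            if row["in_catalog"]:
                rec.info["DBSNP"] = str(row["catalog_id"] or "known")
            for sample in cohort.sample_ids:
                rec.samples[sample]["GT"] = gt_map[int(cohort.genotypes.loc[key, sample])]
            out.write(rec)


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _info_get(info, key):
    # pysam raises ValueError for INFO keys never declared in the header
    try:
        return info[key]
    except (KeyError, ValueError):
        return None


def read_vcf_cohort(path: str | os.PathLike) -> Cohort:
    """Read a VCF into a :class:`Cohort`, splitting multiallelic records."""
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    variants: list[Variant] = []
    gt_rows: list[list[int]] = []
    lineno = len(str(vcf.header).splitlines())
    try:
        for rec in vcf:
            lineno += 1
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                info = rec.info
                freq_a = _info_get(info, "AF_A")
                freq_b = _info_get(info, "AF_B")
                catalog_id = _info_get(info, "DBSNP")
                gene = _info_get(info, "GENE") or ""
                if gene == ".":
                    gene = ""
                variants.append(
                    Variant(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        var_class=_info_get(info, "VC") or "other",
                        gene=str(gene),
                        freq_panel_a=None if freq_a is None else float(freq_a),
                        freq_panel_b=None if freq_b is None else float(freq_b),
                        in_catalog=catalog_id is not None,
                        catalog_id=None if catalog_id is None else str(catalog_id),
                    )
                )
                row = []
                for sample in samples:
                    alleles = rec.samples[sample].get("GT")
                    if alleles is None or any(a is None for a in alleles):
                        row.append(GT_MISSING)
                    else:
                        n_alt = sum(1 for a in alleles if a == alt_index)
                        row.append((GT_HOM_REF, GT_HET, GT_HOM_ALT)[n_alt])
                gt_rows.append(row)
    except (ValueError, OSError) as exc:
        raise ParseError(f"malformed VCF record near line {lineno + 1} of {path}: {exc}") from exc
    finally:
        vcf.close()
    vdf = variants_to_frame(variants)
    gdf = pd.DataFrame(
        np.asarray(gt_rows, dtype=np.int8).reshape(len(variants), len(samples)),
        index=vdf.index,
        columns=samples,
    )
    return Cohort(vdf, gdf)


def read_vcf(path: str | os.PathLike) -> tuple[list[Variant], list[GenotypeCall]]:
    """Read a VCF into variant and genotype-call records."""
    cohort = read_vcf_cohort(path)
    return cohort.to_records()


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_FROM_PED = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}
_PHENO_TO_PED = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Phenotype coding: 2 affected, 1 unaffected, 0/-9 unknown.  Parent id "0"
    means founder.  Dangling parent references raise a validation error.
    """
    ped: Optional[Pedigree] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path} line {lineno}: expected 6 PED columns, got {len(fields)}"
                )
            fam, ind_id, father, mother, sex, pheno = fields[:6]
            if ped is None:
                ped = Pedigree(family_id=fam)
            ped.add(
                Individual(
                    id=ind_id,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_FROM_PED.get(sex, Sex.UNKNOWN),
                    affected=_PHENO_FROM_PED.get(pheno, Affection.UNKNOWN),
                )
            )
    if ped is None:
        raise ParseError(f"{path}: empty PED file")
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind in ped.members():
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_PED[ind.sex],
                        _PHENO_TO_PED[ind.affected],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

def write_annotation(variants_frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the annotation table (chrom, pos, ref, alt, gene, var_class,
    freq_a, freq_b, catalog_id); absent frequencies/ids become "."."""
    df = variants_frame.reset_index(drop=True)[
        ["chrom", "pos", "ref", "alt", "gene", "var_class", "freq_a", "freq_b", "catalog_id"]
    ].copy()
    df["catalog_id"] = df["catalog_id"].fillna(".")
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read an annotation TSV back into the variants-frame layout."""
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    df["in_catalog"] = df["catalog_id"].notna()
    df["catalog_id"] = df["catalog_id"].where(df["catalog_id"].notna(), None)
    df["gene"] = df["gene"].fillna("")
    keys = [
        Variant(r.chrom, int(r.pos), r.ref, r.alt).key_str
        for r in df.itertuples()
    ]
    df.index = pd.Index(keys, name="key")
    return df[VARIANT_COLUMNS]


# ---------------------------------------------------------------------------
# BED / interval text
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, lo, hi = iv.to_bed_fields()
            fh.write(f"{chrom}\t{lo}\t{hi}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected >= 3 BED columns")
            out.append(
                GenomicInterval.from_bed_fields(fields[0], int(fields[1]), int(fields[2]))
            )
    return out
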