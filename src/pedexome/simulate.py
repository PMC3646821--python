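"""Synthetic family cohorts for exercising the discovery pipeline.

The generator emulates the study design of a large autosomal-dominant
muscular-dystrophy kindred: a multi-generation pedigree descending from one
carrier founder, ~93% penetrance, per-individual exomes of roughly 20,000
exonic variants drawn from a two-part population frequency spectrum (common
catalog-known sites plus rare, mostly catalog-absent sites), one planted
rare heterozygous causal variant inside the linkage interval co-transmitted
with the disease haplotype together with a small number of benign companion
variants, and platform-dependent exon-level coverage dropout.

Founder genotypes are drawn under Hardy-Weinberg equilibrium from each
site's population allele frequency; descendants receive alleles by Mendelian
transmission.  All randomness flows from a single integer seed through named
substreams, so every product (pedigree, site list, genotypes) is
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    GT_HET,
    GT_MISSING,
    Affection,
    GenomicInterval,
    PedexomeError,
    Pedigree,
    Individual,
    Sex,
    ValidationError,
    Variant,
)
from .io import Cohort, variants_to_frame, write_annotation, write_pedigree, write_vcf
from .segregation import MarkerObservation, write_markers

# default linkage interval: the 3.68-Mb dominant-LGMD critical region on 7q32
DEFAULT_INTERVAL = GenomicInterval("chr7", 126_287_140, 129_964_025)

# functional-class mix of an annotated exome call set (exonic + splicing,
# with a small "other" fraction exercising the first cascade stage)
CLASS_PROBS = {
    "synonymous_SNV": 0.44,
    "nonsynonymous_SNV": 0.46,
    "splicing": 0.05,
    "other": 0.02,
    "stopgain": 0.005,
    "stoploss": 0.001,
    "frameshift_del": 0.005,
    "frameshift_ins": 0.005,
    "nonframeshift_indel": 0.014,
}

# approximate GRCh37 autosome lengths (bp), for scattering positions
CHROM_SIZES = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}

_ROMAN = ("", "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV")


def _roman(n: int) -> str:
    return _ROMAN[n] if n < len(_ROMAN) else f"G{n}"


@dataclass(frozen=True)
class CausalSpec:
    """Specification of the planted causal variant.

    The default is a single-base deletion that removes the termination codon
    of the TNPO3-like transcript fixture: the deleted base sits at
    chr7:128,597,310 and the record is left-anchored on the preceding base,
    VCF style.  It is heterozygous in exactly the disease-haplotype carriers,
    absent from the known-variant catalog and from both frequency panels.
    """

    chrom: str = "chr7"
    pos: int = 128_597_309
    ref: str = "TA"
    alt: str = "T"
    var_class: str = "stoploss"
    gene: str = "TNPO3"

    def as_variant(self) -> Variant:
        return Variant(
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=self.alt,
            var_class=self.var_class, gene=self.gene,
            freq_panel_a=None, freq_panel_b=None,
            in_catalog=False, catalog_id=None,
        )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    seed: int = 17
    n_generations: int = 7
    mean_sibship: float = 3.0
    penetrance: float = 0.93
    phenocopy_rate: float = 0.0
    de_novo_rate: float = 0.0
    #: probability that a non-carrier descendant founds a sibship; carrier
    #: branches always continue (the kindred is ascertained through them)
    noncarrier_reproduce_p: float = 0.3

    n_common_sites: int = 42_000
    n_rare_sites: int = 30_000
    rare_freq_max: float = 0.01
    common_freq_range: tuple[float, float] = (0.05, 0.5)
    #: fraction of rare sites present in the dbSNP-like catalog
    rare_catalog_p: float = 0.2

    interval: GenomicInterval = DEFAULT_INTERVAL
    #: sites deliberately placed inside the linkage interval (the stated
    #: interval density); genome-wide scatter avoids the interval
    interval_common_sites: int = 40
    interval_rare_sites: int = 8

    causal: CausalSpec = field(default_factory=CausalSpec)
    n_haplotype_companions: int = 1
    #: a common marker planted at the distal recombination boundary, whose
    #: realized sharing pattern among affecteds drives interval refinement
    boundary_marker_pos: int = 128_845_555
    boundary_marker_freq: float = 0.30

    n_affected_sequenced: int = 4
    platforms: tuple[str, ...] = ("solid", "solid", "solid", "illumina")
    dropout_rates: dict[str, float] = field(
        default_factory=lambda: {"solid": 0.03, "illumina": 0.01}
    )
    exon_bin_size: int = 5_000

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValidationError(f"penetrance {self.penetrance} outside (0, 1]")
        if self.rare_freq_max > 0.01 + 1e-12:
            raise ValidationError("rare_freq_max must be <= 0.01")
        if not self.interval.contains(self.causal.chrom, self.causal.pos):
            raise ValidationError("causal position outside the linkage interval")
        if self.n_generations < 2:
            raise ValidationError("need at least 2 generations")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    causal_key: str = ""
    carriers: dict[str, bool] = field(default_factory=dict)
    affection: dict[str, str] = field(default_factory=dict)
    phenocopies: list[str] = field(default_factory=list)
    companion_keys: list[str] = field(default_factory=list)
    sequenced: list[str] = field(default_factory=list)
    #: interval exons masked to missing, per sequenced sample
    dropped_exons: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for ind, aff in self.affection.items():
            if aff == "affected" and not self.carriers.get(ind, False):
                if ind not in self.phenocopies:
                    raise ValidationError(f"affected non-carrier {ind} not a phenocopy")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, CohortTruth]:
    """Grow a multi-generation pedigree from one carrier founder.

    Each carrier transmits the disease haplotype to each child with
    probability 1/2 and is affected with probability ``penetrance``;
    non-carriers are unaffected (phenocopies optional).  Drawing is retried
    on deterministic sub-seeds until the family contains at least
    ``n_affected_sequenced`` affected members, so downstream sampling is
    always possible.
    """
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0, attempt]))
        ped, truth = _grow_pedigree(config, rng)
        n_affected = sum(1 for a in truth.affection.values() if a == "affected")
        if n_affected >= max(config.n_affected_sequenced, 1):
            return ped, truth
    raise PedexomeError(
        "could not grow a pedigree with enough affected members; "
        "increase n_generations or mean_sibship"
    )


def _grow_pedigree(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Pedigree, CohortTruth]:
    ped = Pedigree(family_id="FAM1")
    truth = CohortTruth()
    counters = {g: 0 for g in range(1, config.n_generations + 1)}

    def new_id(gen: int) -> str:
        counters[gen] += 1
        return f"{_roman(gen)}-{counters[gen]}"

    def add(gen, father, mother, sex, carrier) -> str:
        ind_id = new_id(gen)
        if carrier:
            affected = bool(rng.random() < config.penetrance)
        else:
            affected = bool(rng.random() < config.phenocopy_rate)
            if affected:
                truth.phenocopies.append(ind_id)
        ped.add(
            Individual(
                id=ind_id, father_id=father, mother_id=mother, sex=sex,
                affected=Affection.AFFECTED if affected else Affection.UNAFFECTED,
            )
        )
        truth.carriers[ind_id] = bool(carrier)
        truth.affection[ind_id] = "affected" if affected else "unaffected"
        return ind_id

    founder = add(1, None, None, Sex.MALE, carrier=True)
    spouse = add(1, None, None, Sex.FEMALE, carrier=False)
    couples = [(founder, spouse, True)]  # (father, mother, carrier couple)

    for gen in range(2, config.n_generations + 1):
        next_couples = []
        for father, mother, carrier_couple in couples:
            n_children = int(rng.poisson(config.mean_sibship))
            if carrier_couple:
                n_children = max(n_children, 1)
            for _ in range(n_children):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                if carrier_couple:
                    carrier = bool(rng.random() < 0.5)
                else:
                    carrier = bool(rng.random() < config.de_novo_rate)
                child = add(gen, father, mother, sex, carrier)
                if gen < config.n_generations and (
                    carrier or rng.random() < config.noncarrier_reproduce_p
                ):
                    partner_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                    partner = add(gen, None, None, partner_sex, carrier=False)
                    if sex is Sex.MALE:
                        next_couples.append((child, partner, carrier))
                    else:
                        next_couples.append((partner, child, carrier))
        couples = next_couples
    ped.validate()
    truth.validate()
    return ped, truth


def pedigree_distance(ped: Pedigree, a: str, b: str) -> int:
    """Meiotic path length between two members (BFS over parent-child edges)."""
    if a == b:
        return 0
    adj: dict[str, set[str]] = {i: set() for i in ped.individuals}
    for ind in ped.members():
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None:
                adj[ind.id].add(parent)
                adj[parent].add(ind.id)
    seen = {a: 0}
    queue = deque([a])
    while queue:
        node = queue.popleft()
        for nxt in adj[node]:
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                if nxt == b:
                    return seen[nxt]
                queue.append(nxt)
    return -1  # disconnected


def select_sequenced(
    ped: Pedigree, truth: CohortTruth, n: int
) -> list[str]:
    """Pick *n* affected members, maximally separated by meioses.

    Greedy: start from the deepest affected individual, then repeatedly add
    the affected member with the largest minimum distance to those already
    chosen (deterministic tie-break by id).  Mirrors selecting patients
    "separated by the largest number of meioses" for informative sequencing.
    """
    affected = sorted(
        i for i, a in truth.affection.items() if a == "affected"
    )
    if len(affected) < n:
        raise ValidationError(f"only {len(affected)} affected members, need {n}")

    def gen_of(ind_id: str) -> int:
        return _ROMAN.index(ind_id.split("-")[0]) if ind_id.split("-")[0] in _ROMAN else 0

    chosen = [max(affected, key=lambda i: (gen_of(i), i))]
    while len(chosen) < n:
        best = max(
            (i for i in affected if i not in chosen),
            key=lambda i: (min(pedigree_distance(ped, i, c) for c in chosen), i),
        )
        chosen.append(best)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# population sites
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _sites_frame(config: SimulationConfig) -> pd.DataFrame:
    """Vectorized construction of the population site table.

    Adds a ``true_freq`` column (the generative allele frequency) used for
    Hardy-Weinberg founder draws; panel columns ``freq_a``/``freq_b`` carry
    the *observed* frequencies, missing where a site is absent from a panel.
    """
    rng = _rng(config, 1)
    n_c, n_r = config.n_common_sites, config.n_rare_sites
    n = n_c + n_r
    lo, hi = config.common_freq_range
    true_freq = np.concatenate([
        rng.uniform(lo, hi, n_c),
        rng.uniform(5e-4, config.rare_freq_max, n_r),
    ])
    is_rare = np.zeros(n, dtype=bool)
    is_rare[n_c:] = True

    # positions: a stated number of sites inside the interval, the rest
    # scattered genome-wide avoiding the interval
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    iv = config.interval
    n_iv_c = min(config.interval_common_sites, n_c)
    n_iv_r = min(config.interval_rare_sites, n_r)
    iv_idx = np.concatenate([np.arange(n_iv_c), n_c + np.arange(n_iv_r)])
    out_idx = np.setdiff1d(np.arange(n), iv_idx)
    chroms[iv_idx] = iv.chrom
    pos[iv_idx] = rng.integers(iv.start, iv.end + 1, size=iv_idx.size)

    names = list(CHROM_SIZES)
    sizes = np.array([CHROM_SIZES[c] for c in names], dtype=float)
    picks = rng.choice(len(names), size=out_idx.size, p=sizes / sizes.sum())
    chroms[out_idx] = np.array(names, dtype=object)[picks]
    iv_len = iv.end - iv.start + 1
    raw = rng.integers(1, sizes[picks].astype(np.int64) - iv_len, size=out_idx.size)
    # on the interval chromosome, fold positions past the interval start
    on_iv_chrom = np.array(names)[picks] == iv.chrom
    shift = on_iv_chrom & (raw >= iv.start)
    raw[shift] += iv_len
    pos[out_idx] = raw

    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)

    classes = rng.choice(
        np.array(list(CLASS_PROBS), dtype=object), size=n, p=list(CLASS_PROBS.values())
    )
    # indel classes get indel-shaped alleles (small fraction; plain loop)
    for i in np.flatnonzero(np.isin(classes, ["frameshift_del", "nonframeshift_indel"])):
        width = 1 if classes[i] == "frameshift_del" else 3
        tail = "".join(rng.choice(_BASES, size=width))
        ref[i] = alt[i] + tail
        alt[i] = str(alt[i])
    for i in np.flatnonzero(classes == "frameshift_ins"):
        alt[i] = str(ref[i]) + "".join(rng.choice(_BASES, size=1))

    in_catalog = np.ones(n, dtype=bool)
    in_catalog[n_c:] = rng.random(n_r) < config.rare_catalog_p
    rs_num = rng.integers(10_000_000, 99_999_999, size=n)
    catalog_id = np.where(in_catalog, np.char.add("rs", rs_num.astype(str)), None)

    # observed panel frequencies: catalog members are seen in each panel with
    # high probability; novel sites have no panel frequency at all
    jitter = lambda f: np.clip(f * rng.normal(1.0, 0.05, size=n), 0.0, 1.0)
    seen_a = in_catalog & (rng.random(n) < 0.95)
    seen_b = in_catalog & (rng.random(n) < 0.95)
    freq_a = np.where(seen_a, jitter(true_freq), np.nan)
    freq_b = np.where(seen_b, jitter(true_freq), np.nan)

    gene = np.char.add(
        np.char.add(np.array([c.removeprefix("chr") for c in chroms]), "G"),
        (pos // 200_000).astype(str),
    )

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": [str(x) for x in ref],
            "alt": [str(x) for x in alt],
            "var_class": classes,
            "gene": gene,
            "freq_a": freq_a,
            "freq_b": freq_b,
            "in_catalog": in_catalog,
            "catalog_id": catalog_id,
            "true_freq": true_freq,
            "is_rare": is_rare,
        }
    )
    df.index = pd.Index(
        df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"],
        name="key",
    )
    df = df[~df.index.duplicated(keep="first")]
    return df


def simulate_population_sites(config: SimulationConfig) -> list[Variant]:
    """Population site list as variant records (see :func:`_sites_frame`)."""
    df = _sites_frame(config)
    out = []
    for row in df.itertuples():
        out.append(
            Variant(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                var_class=row.var_class, gene=row.gene,
                freq_panel_a=None if np.isnan(row.freq_a) else float(row.freq_a),
                freq_panel_b=None if np.isnan(row.freq_b) else float(row.freq_b),
                in_catalog=bool(row.in_catalog),
                catalog_id=row.catalog_id,
            )
        )
    return out


def expected_exonic_variants(sites: pd.DataFrame) -> float:
    """Expected non-reference exonic calls per individual, Sum(1-(1-f)^2)."""
    f = sites["true_freq"].to_numpy()
    mask = (sites["var_class"] != "other").to_numpy()
    return float((1.0 - (1.0 - f[mask]) ** 2).sum())


# ---------------------------------------------------------------------------
# cohort genotypes
# ---------------------------------------------------------------------------

def mendelian_possible(father: int, mother: int, child: int) -> bool:
    """Brute-force transmission check on allele dosages (0/1/2)."""
    trans = {0: {0}, 1: {0, 1}, 2: {1}}
    return any(
        tf + tm == child for tf in trans[father] for tm in trans[mother]
    )


def _draw_dosages(
    ped: Pedigree, freqs: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Allele dosage per individual per site: Hardy-Weinberg founders,
    Mendelian transmission for descendants (parents drawn before children)."""
    n = freqs.size
    dosage: dict[str, np.ndarray] = {}
    for ind_id in ped.generation_order():
        ind = ped[ind_id]
        if ind.father_id is None and ind.mother_id is None:
            d = rng.binomial(1, freqs, size=n) + rng.binomial(1, freqs, size=n)
        else:
            df_ = dosage[ind.father_id]
            dm = dosage[ind.mother_id]
            tf = rng.random(n) < df_ / 2.0
            tm = rng.random(n) < dm / 2.0
            d = tf.astype(np.int8) + tm.astype(np.int8)
        dosage[ind_id] = d.astype(np.int8)
    return dosage


@dataclass
class SimulatedCohort:
    """In-memory product of one cohort simulation."""

    cohort: Cohort
    pedigree: Pedigree
    truth: CohortTruth
    coverage: pd.DataFrame          # long: sample, exon_id, mean_coverage
    exon_table: pd.DataFrame        # exon_id, chrom, start, end (interval exons)
    markers: list[MarkerObservation]
    #: causal-variant genotype for every family member (Sanger-style recheck)
    causal_genotypes: dict[str, int]


def simulate_cohort(
    pedigree: Pedigree,
    sites: Union[pd.DataFrame, Sequence[Variant]],
    config: SimulationConfig,
    truth: CohortTruth,
) -> SimulatedCohort:
    """Draw genotypes for the pedigree and assemble the sequenced cohort.

    The causal variant and its haplotype companions are heterozygous in
    exactly the truth carriers.  Coverage dropout masks genotypes of whole
    exon bins to missing, at a per-platform rate, except at the planted
    haplotype sites (the discovery scenario conditions on the causal variant
    being callable in the sequenced patients; surrounding low-coverage exons
    form the resequencing worklist instead).
    """
    if not isinstance(sites, pd.DataFrame):
        sites = variants_to_frame(list(sites))
        sites = sites.assign(
            true_freq=sites[["freq_a", "freq_b"]].mean(axis=1).fillna(0.001),
            is_rare=lambda d: d["true_freq"] <= config.rare_freq_max,
        )
    if len(sites) == 0:
        raise ValidationError("empty site table")
    missing_members = [i for i in truth.carriers if i not in pedigree]
    if missing_members:
        raise ValidationError(f"truth references unknown individuals: {missing_members}")

    rng = _rng(config, 2)
    sequenced = truth.sequenced or select_sequenced(
        pedigree, truth, config.n_affected_sequenced
    )
    truth.sequenced = list(sequenced)

    freqs = sites["true_freq"].to_numpy(dtype=float)
    dosage = _draw_dosages(pedigree, freqs, rng)

    gt = pd.DataFrame(
        {s: dosage[s] for s in sequenced}, index=sites.index, dtype=np.int8
    )

    # planted haplotype: causal + companions, heterozygous in carriers
    causal_v = config.causal.as_variant()
    truth.causal_key = causal_v.key_str
    companions = []
    iv = config.interval
    for k in range(config.n_haplotype_companions):
        cpos = int(rng.integers(iv.start, iv.end + 1))
        ref_i = int(rng.integers(0, 4))
        companions.append(
            Variant(
                chrom=iv.chrom, pos=cpos,
                ref=str(_BASES[ref_i]), alt=str(_BASES[(ref_i + 1) % 4]),
                var_class="nonsynonymous_SNV", gene="IRF5",
                freq_panel_a=0.002, freq_panel_b=None,
                in_catalog=True, catalog_id=f"rs9{k}{cpos % 1_000_000}",
            )
        )
    truth.companion_keys = [c.key_str for c in companions]

    planted = [causal_v] + companions
    planted_df = variants_to_frame(planted).assign(true_freq=0.0, is_rare=True)
    carrier_row = np.array(
        [GT_HET if truth.carriers.get(s, False) else 0 for s in sequenced],
        dtype=np.int8,
    )
    planted_gt = pd.DataFrame(
        np.tile(carrier_row, (len(planted), 1)),
        index=planted_df.index, columns=sequenced, dtype=np.int8,
    )

    # boundary marker: an ordinary common site at the distal recombination
    # boundary; its realized sharing pattern among affecteds is reported as a
    # marker observation for interval refinement
    marker_v = Variant(
        chrom=iv.chrom, pos=config.boundary_marker_pos, ref="G", alt="A",
        var_class="synonymous_SNV", gene="SMO",
        freq_panel_a=config.boundary_marker_freq,
        freq_panel_b=config.boundary_marker_freq,
        in_catalog=True, catalog_id="rsBOUNDARY",
    )
    marker_df = variants_to_frame([marker_v]).assign(
        true_freq=config.boundary_marker_freq, is_rare=False
    )
    # the boundary marker must be *informative*: carried by some but not all
    # affected members, the configuration that reveals a recombination
    # boundary; redraw (bounded, deterministic) until that holds
    affected_members = [i for i, a in truth.affection.items() if a == "affected"]
    for _ in range(100):
        marker_dosage = _draw_dosages(
            pedigree, np.array([config.boundary_marker_freq]), rng
        )
        n_carrying = sum(1 for i in affected_members if marker_dosage[i][0] > 0)
        if 0 < n_carrying < len(affected_members):
            break
    marker_gt = pd.DataFrame(
        {s: marker_dosage[s] for s in sequenced}, index=marker_df.index, dtype=np.int8
    )

    all_sites = pd.concat([sites, planted_df, marker_df])
    all_sites = all_sites[~all_sites.index.duplicated(keep="last")]
    gt = pd.concat([gt, planted_gt, marker_gt]).loc[all_sites.index]

    # exon-level coverage dropout per platform
    exon_ids = (
        all_sites["chrom"].astype(str)
        + ":e"
        + (all_sites["pos"] // config.exon_bin_size).astype(str)
    )
    protected = set(planted_df.index)
    iv_exon_mask = (
        (all_sites["chrom"] == iv.chrom)
        & (all_sites["pos"] >= iv.start)
        & (all_sites["pos"] <= iv.end)
    )
    iv_exons = sorted(exon_ids[iv_exon_mask].unique())
    uniq_exons = exon_ids.unique()
    exon_index = pd.Series(np.arange(len(uniq_exons)), index=uniq_exons)
    site_exon_idx = exon_index[exon_ids].to_numpy()

    coverage_rows = []
    for i, sample in enumerate(sequenced):
        platform = config.platforms[i % len(config.platforms)]
        rate = config.dropout_rates.get(platform, 0.0)
        dropped = rng.random(len(uniq_exons)) < rate
        mask = dropped[site_exon_idx]
        mask &= ~all_sites.index.isin(protected)
        col = gt[sample].to_numpy(copy=True)
        col[mask] = GT_MISSING
        gt[sample] = col
        dropped_iv = [e for e in iv_exons if dropped[exon_index[e]]]
        truth.dropped_exons[sample] = dropped_iv
        cov = rng.gamma(8.0, 2.5, size=len(iv_exons))
        for j, exon in enumerate(iv_exons):
            mean_cov = float(rng.uniform(2.0, 9.5)) if exon in dropped_iv else float(
                max(cov[j], 10.0)
            )
            coverage_rows.append(
                {"sample": sample, "exon_id": exon, "mean_coverage": round(mean_cov, 1)}
            )

    coverage = pd.DataFrame(coverage_rows, columns=["sample", "exon_id", "mean_coverage"])
    exon_table = pd.DataFrame(
        [
            {
                "exon_id": e,
                "chrom": e.split(":")[0],
                "start": max(int(e.split(":e")[1]) * config.exon_bin_size, iv.start),
                "end": min(
                    (int(e.split(":e")[1]) + 1) * config.exon_bin_size - 1, iv.end
                ),
            }
            for e in iv_exons
        ]
    )

    # marker observation over ALL affected members (Sanger-typed), from dosage
    affected_all = [
        i for i, a in truth.affection.items() if a == "affected"
    ]
    marker_carriers = {
        i for i in pedigree.individuals if marker_dosage[i][0] > 0
    }
    markers = [
        MarkerObservation(
            marker_id="rsBOUNDARY",
            chrom=iv.chrom,
            pos=config.boundary_marker_pos,
            present_in=frozenset(i for i in affected_all if i in marker_carriers),
            absent_in=frozenset(i for i in pedigree.individuals if i not in marker_carriers),
        )
    ]

    causal_genotypes = {
        i: (GT_HET if truth.carriers.get(i, False) else 0) for i in pedigree.individuals
    }

    cohort = Cohort(
        all_sites[
            [
                "chrom", "pos", "ref", "alt", "var_class", "gene",
                "freq_a", "freq_b", "in_catalog", "catalog_id",
            ]
        ].copy(),
        gt,
    )
    truth.validate()
    return SimulatedCohort(
        cohort=cohort,
        pedigree=pedigree,
        truth=truth,
        coverage=coverage,
        exon_table=exon_table,
        markers=markers,
        causal_genotypes=causal_genotypes,
    )


def simulate_cohort_exomes(
    pedigree: Pedigree,
    sites: Union[pd.DataFrame, Sequence[Variant]],
    config: SimulationConfig,
    truth: CohortTruth,
    out_dir: str | Path,
) -> dict[str, str]:
    """Simulate a cohort and write the standard files.

    Writes ``cohort.vcf``, ``cohort.ped``, ``annotation.tsv``,
    ``coverage.tsv``, ``exons.tsv``, ``markers.tsv``, ``sanger_causal.tsv``
    (causal genotype for every family member) and ``truth.json``; returns a
    name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(pedigree, sites, config, truth)
    paths = {
        "vcf": str(out / "cohort.vcf"),
        "ped": str(out / "cohort.ped"),
        "annotation": str(out / "annotation.tsv"),
        "coverage": str(out / "coverage.tsv"),
        "exons": str(out / "exons.tsv"),
        "markers": str(out / "markers.tsv"),
        "sanger": str(out / "sanger_causal.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_vcf(sim.cohort, paths["vcf"])
    write_pedigree(pedigree, paths["ped"])
    write_annotation(sim.cohort.variants, paths["annotation"])
    sim.coverage.to_csv(paths["coverage"], sep="\t", index=False)
    sim.exon_table.to_csv(paths["exons"], sep="\t", index=False)
    write_markers(sim.markers, paths["markers"])
    pd.DataFrame(
        sorted(sim.causal_genotypes.items()), columns=["sample", "gt_code"]
    ).to_csv(paths["sanger"], sep="\t", index=False)
    sim.truth.to_json(paths["truth"])
    return paths


def simulate_all(config: SimulationConfig) -> SimulatedCohort:
    """Convenience: pedigree + sites + cohort in one call, in memory."""
    ped, truth = simulate_pedigree(config)
    sites = _sites_frame(config)
    return simulate_cohort(ped, sites, config, truth)
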