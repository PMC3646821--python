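# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and length conventions

All positions are 1-based; intervals are closed on both ends, matching VCF
POS and the way linkage boundaries are printed in the genetics literature.
Two length conventions coexist deliberately:

* `GenomicInterval.length() = end − start` — the marker distance between
  the boundary positions. This is the convention under which
  chr7:126,287,140–129,964,025 spans 3.68 Mb, its refinement to
  128,845,555 spans 2.6 Mb, and the reduction is 1.1 Mb.
* `GenomicInterval.n_bases() = end − start + 1` — bases covered, used
  wherever sequence content is summed (exon spans, cDNA lengths).

Variant identity is `(chrom, pos, ref, alt)` after a minimal
normalization (shared trailing then leading bases trimmed, keeping one
base each side). Without flanking reference sequence a full left-alignment
is impossible; the minimal representation is sufficient to reconcile
callers that pad indels differently, and cross-platform intersection is by
exact normalized key — no fuzzy matching.

A population frequency of `None` means *absent from that panel* and is
deliberately distinct from 0.0: a private mutation has no catalog
frequency, and the rare-stage filter treats unknown as rare while
discarding anything *above* the threshold in any panel where it is
reported (exactly-at-threshold survives; only "higher than" is discarded).

## Filtering cascade

Stage order is fixed: exonic/splicing → functional class → heterozygous →
rare → interval → catalog novelty. Counts are reported per sample plus
identity-key intersections across the affected samples (optionally also
across a platform subset), which yields the monotone total-and-shared
matrix. The heterozygous stage drops hom-alt and missing calls; a rescue
mode (`rescue_missing=True`) that treats missing calls as unknown rather
than absent exists but is off by default — the modeled workflow resequences
low-coverage exons (the `coverage_gaps` worklist, threshold 10×) instead of
rescuing calls. Class composition is tabulated at the rare stage over the
shared set and always partitions its count.

## Segregation and penetrance

Classification is per individual from genotype × phenotype under a
dominant model. Affected individuals with missing genotypes are *untyped*
and are never evidence in either direction. Carriers with unknown
phenotype are also not counted as non-penetrant; only explicitly
unaffected carriers are. Obligate-carrier inference through pedigree
topology is out of scope for the default path (a deliberate design
choice: it requires assumptions about untyped connecting ancestors that
the genotype data can make unnecessary).

Penetrance = affected carriers / (affected + non-penetrant carriers),
reported raw and rounded to the nearest percent.

## Interval refinement

For each marker observation inside the interval: if it is present in every
affected member it is consistent with the shared haplotype and changes
nothing; if it is present in some affected members and absent in others it
is discordant, and the boundary on its side of the candidate position
moves to the marker position. Markers absent from *all* affected are
treated as uninformative about the shared haplotype. The new boundary is
placed **at** the marker position, not one base beyond: the true exclusion
is strictly beyond the marker, but this convention reproduces printed
refined intervals whose ends are the marker positions themselves. The
operation is idempotent and order-independent (each boundary is a min/max
over marker positions), and a discordant marker coinciding with the
candidate position raises an error rather than silently excluding it.

## Transcript consequences

Coding math is done in c. coordinates (1 = first base of the start codon)
with the standard nuclear genetic code only (no selenocysteine
read-through). Length changes not divisible by three are frameshifts;
in-frame indels are labelled `inframe_indel` and not further interpreted.
Any event that abolishes the reference termination codon is a stop-loss:
the mutated transcript is re-translated from the start codon until the
first in-frame stop of *that splice form's* 3' sequence, and the extension
peptide is everything beyond the reference protein length. If no stop
exists before the transcript end the effect is flagged
`nonstop_runthrough`.

Restriction scanning is IUPAC-aware with overlapping (lookahead) matches,
on the given strand only; for palindromic enzymes such as AluI (AG^CT) the
reverse strand is redundant. Site loss/gain is decided by projecting
reference site coordinates through the variant (positions right of an
indel shift by the length change; positions inside a deleted span have no
image). Fragment lengths are cut-position differences and always partition
the amplicon length.

Protein identity uses Biopython global alignment with match 1, mismatch 0,
gap open −5, gap extend −0.5 (parameters carried in `AlignmentParams` and
reported with results). The denominator is the query (first) protein's
length, the convention under which 792 matching positions over a 923-aa
query is 86%.

### The bundled fixtures are synthetic

`pedexome.datasets` constructs all transcript and protein fixtures in code
rather than bundling database records. The stand-ins are engineered to
reproduce the documented anatomy of the TNPO3 stop-loss disease allele: a
923-residue protein; TAG termination codon at c.2770–2772 whose A sits at
chr7:128,597,310 on the synthetic plus-strand exon layout; deleting that A
creates codon 924 = TGC (p.X924C) and destroys an AluI AGCT site spanning
c.2771–2774; splice form A (exon 22 → non-coding exon 23) reads through
into a 15-residue extension CSHSCSVPVTQECLF while form B (extended exon
22) gains 95 residues, the first four (CSHS) shared between the forms; and
a zebrafish-like ortholog differs at 131/923 positions (86% identity).
Everything *besides* this engineered anatomy (residue composition, UTR
content, intron sizes, the real gene's minus-strand orientation) is
arbitrary and carries no information.

One documented discrepancy: the missense allele c.2453G>A falls on the
second base of codon 818, which the fixture sets to AGA (arginine). No
G>A substitution at codon position 2 of any arginine codon can encode
proline; the genetic code gives lysine (AGA→AAA), and the package reports
what the code dictates (`p.R818K` on the fixture) rather than the
reported amino-acid pair. The position, codon index and reference residue
are reproduced exactly.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Pedigree.** One carrier founder couple; each carrier transmits the
haplotype to each child with probability 1/2 and is affected with
probability = penetrance (default 0.93); non-carriers are unaffected
(phenocopy and de-novo rates exist, default 0.0). Seven generations with
mean sibship 3 (Poisson); carrier branches always continue (at least one
child, always a reproducing partner) while non-carrier descendants found a
sibship with probability 0.3 — an ascertainment-style pruning reflecting
that collected kindreds track their affected branches. Drawing is retried
on deterministic sub-seeds until the family has at least as many affected
members as exomes to be sequenced. Sequenced patients are chosen greedily
to maximize pairwise meiotic separation, the informative-sampling rule for
dominant families.

**Sites.** 42,000 common sites (frequency Uniform(0.05, 0.5),
catalog-known) and 30,000 rare sites (Uniform(0.0005, 0.01), 20%
catalog-known), giving an expectation of ≈19,500 non-reference exonic
calls per individual — the ~20,000-per-exome scale of a captured exome.
The exome-wide frequency spectrum of a real cohort is not inferred from
data; these are parameterized, stated defaults. A stated number of sites
(40 common + 8 rare) is placed uniformly inside the linkage interval and
the genome-wide scatter avoids it, so interval density is controlled.
Catalog members carry panel frequencies with probability 0.95 per panel
(jittered ×N(1, 0.05)); catalog-absent sites have no panel frequencies.

**Genotypes.** Founders (including married-in spouses) are Hardy–Weinberg
draws at each site's generative frequency; descendants receive alleles by
per-parent Bernoulli(dosage/2) transmission, which the test suite verifies
against brute-force enumeration of possible transmissions. The causal
variant and its haplotype companions (default: one catalog-known benign
companion, emulating a second interval variant riding the disease
haplotype) are heterozygous in exactly the truth carriers.

**Coverage dropout.** Whole exon bins (5 kb) drop to missing at a
per-platform rate (0.03 for the three SOLiD-like samples, 0.01 for the
Illumina-like fourth). Planted haplotype sites are exempt: the discovery
scenario conditions on the causal variant being callable in the sequenced
patients, and what dropout models is the surrounding low-coverage exons
that generate the Sanger resequencing worklist (interval exons with
simulated mean coverage < 10× are recorded in the truth object and in the
coverage table).

**Boundary marker.** A common site planted at chr7:128,845,555 whose
family-wide realized genotypes are reported as a marker observation. The
draw is conditioned (bounded deterministic redraws) on the marker being
*informative* — carried by some but not all affected members — because the
modeled scenario is exactly that an informative recombinant marker was
found at the boundary.

All randomness flows from a single integer seed through named substreams
(pedigree / sites / cohort), so every product is reproducible
bit-for-bit; repeated runs are byte-identical including all report files.

**What the generator does not emulate:** read-level data, recombination
maps and LD structure beyond the single co-transmitted haplotype,
platform-specific error profiles, population stratification, or phenocopy
structure (off by default). Passing the recovery tests therefore shows the
*pipeline logic* is sound under the stated statistical structure, not that
it is robust to every artifact of real capture sequencing.

## Problem sizes used in validation

The acceptance checks run the cascade on full study-scale cohorts
(72,000 sites, four sequenced exomes) across 50 seeded replicates; the
planted causal survives the cascade in all replicates and is the sole
catalog-absent in-interval survivor in ≥49/50 (the rare exception is a
genuine rare catalog-absent interval site shared by chance transmission).
Penetrance recovery pools carriers over 200 four-generation pedigrees and
checks the affected fraction against 0.93 within 3 binomial SE (plus a
0.01 allowance for the ascertainment bias introduced by requiring ≥1
affected member per family). Unit and property tests use scaled cohorts
(2,000–3,500 sites, five generations) for speed; nothing in the scaled
runs changes the semantics being tested. `scripts/acceptance.py` reports
the cascade survivor count as the median over 15 replicate cohorts seeded
from `--seed`.

## Known limitations

* VCF support is deliberately minimal: GT genotypes, split multiallelics,
  the annotation INFO keys; no phasing, breakends or symbolic alleles.
  INFO frequencies are 32-bit floats on disk, so round-trips agree to
  float32 precision, not bit-exactly.
* A single genome assembly is assumed throughout; no liftover.
* Genomic↔transcript mapping of indels assumes anchored VCF-style alleles
  and is implemented for plus-strand transcripts (the synthetic fixtures
  are laid out on the plus strand).
* The interval-refinement boundary convention (boundary = marker position)
  slightly overstates the refined interval relative to the strict
  exclusion semantics; this is documented above and consistent throughout.
* `simulate_cohort_exomes` takes the truth object produced by
  `simulate_pedigree` explicitly — carrier status is ground truth, not a
  property of the pedigree structure.
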