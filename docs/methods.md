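# Methods

This note records the models, defaults, and design choices behind
varmend, and what the synthetic fixtures do and do not establish.

## Variant model and normalization

Variant keys are left-aligned, parsimonious `(chrom, pos, ref, alt)`
tuples: shared trailing bases are trimmed first, then shared leading
bases (advancing the position), always leaving one base per allele. This
is the usual trimming convention of VCF normalizers operating without a
reference sequence; reference-context left-shifting of homopolymer
indels is out of scope, so two representations compare equal iff their
trimmed forms match. Normalization is idempotent and edit-preserving
(property-tested by splicing both representations into random context
sequences).

Multiallelic rows are decomposed into one biallelic record per alternate
allele; in each sub-record the focal alternate maps to allele index 1
and everything else to 0, so the multiset of per-sample alternate
alleles is preserved across the decomposition.

Genotypes carry a confidence status. Calls with depth < 10 or GQ < 20
(both configurable) are demoted to LOW_CONFIDENCE and are never treated
as called by trio observation encoding or star-allele phasing. These
cutoffs are conventional short-read values, not estimates from data.

Annotation lookups are exact on normalized keys and return an explicit
ABSENT marker on a miss. ABSENT is deliberately distinct from zero: a
variant missing from every population survey is *novel* (and therefore
rare), not observed-at-frequency-0.

## Tiering semantics

Boundary conventions follow the printed definitions of the thresholds:

- rarity: MAF ≤ threshold (default 0.01) in **all** sources with data
  ("no greater than"); the alternative reading (rare in ≥ 1 source) is
  vacuous because most variants are absent from at least one survey;
- conservation: strict `GERP++ > 2` and `PhyloP > 0.95`; an ABSENT score
  fails (no evidence is not evidence);
- pathogenicity consensus: ≥ 3 damaging votes among SIFT ("Damaging"),
  LRT ("Deleterious"), PolyPhen2 ("Probably"/"Possibly damaging"),
  MutationTaster ("Disease causing (automatic)"); unknown vocabulary is
  a warned non-vote;
- "large" in-frame coding indels count as LOF at ≥ 50 bp (configurable;
  no canonical size exists);
- local-cohort filter: remove at local AF ≥ 0.25 (i.e. < 25% retained),
  ABSENT retained.

Tiers are evaluated 1 → 4 with first-match-wins inside each track; this
is the only order consistent with tier 4 being defined by exhaustion.
The novel track requires membership in a monogenic-disease gene set; the
reported track relies on catalog membership alone and does not re-check
the gene set. Each assignment carries the list of predicates that fired,
for audit.

Gene-level effect class is the most severe per-transcript class under a
fixed total severity order (splice-dinucleotide > nonsense > nonstop >
frameshift > large coding indel > non-frameshift indel > missense >
synonymous > UTR > intronic > intergenic), making it invariant to
transcript enumeration order.

## Trio HMM

Observation symbols are assigned with precedence MIA > ALLHET >
CONSISTENT; sites with any uncalled or low-confidence member are
skipped. The three-symbol alphabet exists because reference-compression
regions manifest as excess universal heterozygosity, which a two-symbol
(error/no-error) alphabet cannot separate from inheritance-error tracts.

Default parameters (all exposed via YAML config):

| state       | P(CONSISTENT) | P(MIA) | P(ALLHET) | tract length L | π    |
|-------------|---------------|--------|-----------|----------------|------|
| GOOD        | 0.989         | 0.001  | 0.010     | 10 Mb          | 0.98 |
| COMPRESSION | 0.40          | 0.10   | 0.50      | 100 kb         | 0.01 |
| MIA_RICH    | 0.55          | 0.40   | 0.05      | 100 kb         | 0.01 |

Rationale: the MIA rate in clean data is of the order of the genotyping
error rate (true de novo events are orders of magnitude rarer), artifact
tracts are short relative to chromosomes, and nearly all of the genome
is clean. Transitions scale with inter-marker distance as
`stay(s) = exp(−d/L_s)`, the leave mass split between the other two
states in proportion to their stationary weights; at d = 0 this is the
identity and as d → ∞ each row tends to the renormalized stationary
weights — both covered by exact tests.

Decoding is Viterbi in log space (the single best path is what region
exclusion needs); per-site posteriors are not required for filtering and
are omitted. Ties break toward GOOD, then the lower state index, which
keeps soft-filtering conservative. Segment boundaries fall at midpoints
between adjacent observed sites; chromosome ends extend only to the
first/last observation, so unobserved flanks are never labeled. Region
labels are appended to the FILTER field of overlapping records; records
are never dropped. Observations default to SNVs only (indel MIA rates
are caller-dependent); X is treated as autosomal for female children and
X/Y sites are excluded for male children, since hemizygous genotype
conventions vary by caller.

## Candidate modes

Modes 1–4 (de novo, compound het, rare homozygous, hemizygous) are
restricted to GOOD segments. De novo requires both parents CALLED
hom-ref in strict mode (default); a lenient flag admits low-confidence
hom-ref parents. Compound-het pairs are all unordered pairs of
child-heterozygous variants in one gene with ≥ 1 rare member; phasing
from parental carriage yields TRANS_CONFIRMED when the two alternates
can only have come from different parents, excludes pairs provably in
cis (both only from the same parent), and reports everything else
PHASE_UNKNOWN rather than dropping it. Hemizygosity requires an
explicit overlapping deletion interval (from `<DEL>` records or a BED);
without structural-variant support the genotype pattern stays in the MIA
channel. The dominant-reduced-penetrance mode reports rare child-carried
variants in a supplied disease-gene list without a segregation
requirement — under reduced penetrance an unaffected carrier parent is
expected, so inherited variants are kept alongside de novo ones.

## Star-allele calling

Definitions are long-form TSV (`gene allele chrom pos ref alt`) listing
only non-reference positions; `*1` is implicit all-reference. The
skeleton uses any CALLED homozygous genotype (reference or alternate) as
phase-free evidence; heterozygous sites are expanded into
`max(1, 2^(h−1))` unordered complementary pairs (the first het site is
pinned to one haplotype to cancel mirror images). More than 12 het
defining sites aborts with an explicit error: the tool is built to make
only high-confidence calls and leaves such cases to a curator.
Matching is perfect-match only; UNKNOWN positions widen the candidate
set monotonically (masking can never remove a candidate). Copy-number
star alleles (e.g. CYP2D6 duplications) are an acknowledged limitation.
Single-variant drug-response annotation filters knowledge-base rows by
an ordered clinical evidence scale (1A strongest … 4) and only matches
carried genotypes.

## Synthetic fixtures

The trio simulator draws per-site symbols from the planted segment's
emission row and realizes them as genotype patterns; artifact segments
realize MIA symbols as de-novo-mimicking patterns (recorded in the
manifest) so candidate modes can be shown to emit nothing from flagged
regions, while clean-region background MIAs use a pattern matching no
candidate mode. Gene blocks hosting planted events are kept free of
background heterozygosity, which makes the truth manifest *sufficient*:
expected candidate output is exactly the planted event list. Default
conditions: two chromosomes, runs of 60–150 sites per state (artifact
tracts 60 sites), inter-site gaps uniform on 200–600 bp, background MAF
0.30, planted rare alleles at 0.001, DP 40 / GQ 99 throughout. Each
generator draws from its own named stream of the user seed, so outputs
are byte-reproducible and adding a generator never perturbs another.

What passing on these fixtures does **not** show: robustness to linkage
disequilibrium, to depth- and mapping-driven genotype error that
correlates across family members, to multi-caller VCF idiosyncrasies, or
to realistic site-frequency spectra — none of which the generator
models.

## Problem sizes and numerical choices

Acceptance-style checks run at desk scale, chosen to exercise each
property well past its decision boundary: 200 random instances of ≤ 8
observations against exhaustive 3^n enumeration (agreement asserted on
log-probability, robust to ties); 100 seeded simulations of 400 sites
with planted tracts of ≥ 50 sites for ≥ 95% per-site recovery (observed
≈ 99%, residual errors concentrated at segment boundaries, whose
midpoint placement is only resolvable to the inter-site gap); 10,000
random annotated variants against an independently coded tiering
decision table; 500 random star fixtures for truth-in-set. All
floating-point closed-form checks (identity at d = 0, 1/e at d = L, row
stochasticity) are asserted at 1e-12.
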