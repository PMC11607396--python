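# Methods

## Scope and model

`pedvar` operationalizes the discovery analysis for a fully penetrant
autosomal dominant disorder in a single extended pedigree.  The genetic
model is deliberately minimal: one causal heterozygous allele entering
through a single founder, no phenocopies, no de novo events, and complete
penetrance among individuals whose disease status is known.  Individuals
with unknown status (a late-onset disease leaves the youngest generation
undiagnosable) and missing genotypes impose no constraint anywhere.
X-linked, recessive, and de novo models are out of scope, as are structural
and copy-number variants.

Upstream steps — alignment, variant calling, annotation, in-silico score
computation — are consumed as inputs, never recomputed.

## Filtering cascade

Order: panel exclusion → shared heterozygosity → MAF → consequence → CADD →
segregation.  Panel exclusion runs first because candidate discovery in a
new gene only makes sense once known disease genes are exhausted.  Both
numeric filters are strict inequalities (`MAF < 0.001`, `CADD > 10`),
matching how such thresholds are conventionally quoted; the boundary cases
(`MAF = 0.001`, `CADD = 10`) are excluded and covered by tests.

Missing-value semantics are explicit configuration rather than I/O-level
coercion:

* **absent MAF → frequency 0** (default): a variant absent from the
  population database is novel and must survive a rarity filter.
  `missing_maf_policy="drop"` inverts this for conservative reanalysis.
* **absent CADD → retained, flagged** (default): scores are undefined for
  some indels, and a stringent threshold can silently discard a true
  candidate — a moderately scored missense variant (CADD ≈ 13.7) survives a
  >10 filter but would be lost at >15, which is exactly the cautionary case
  the threshold tests pin down.
* **no annotation row at all → dropped and counted** by each of the three
  annotation filters.  Treating all three identically keeps the final
  candidate set invariant under reordering of the MAF/consequence/CADD
  stages (they are then pure set predicates whose intersection commutes,
  asserted by test).  Panel exclusion retains unannotated keys, since panel
  membership cannot be established for them.

The `hom_alt` genotype in an affected counts as carrying (a dominant model
requires ≥1 allele) but is flagged, because a het-only family makes a
homozygous carrier suspect.  A `max_violations` tolerance exists for reuse
on imperfect data; it defaults to 0 and tolerated violations flip nothing
silently — the verdict simply reports no violations when within tolerance.

## Phasing and the sharing verdict

Three rules generate origin labels for the alternate allele at
heterozygous markers:

1. **parent-shared**: the parent carries the allele and every listed child
   carries it → label the allele with that parent's side in each child;
2. **sib-only**: every listed sib carries the allele and one genotyped
   parent does not → label it with the other parent's side;
3. **read links**: a read spanning two heterozygous sites fixes their
   relative phase; links close transitively into phase sets via union-find
   with a parity bit, and a contradicting link marks both endpoints as
   conflicted.

Rule 1 is a heuristic: an allele shared by parent and children can in
principle descend from the *other* parent.  Every label therefore carries a
confidence class.  A label is **certain** when forced by Mendelian logic —
the parent is homozygous (its transmitted allele is determined), the child
is homozygous, or the other parent's genotype excludes alternative descent
(e.g. child het, other parent hom-ref).  Otherwise it is **assumed**.  The
`strict` mode withholds assumed labels entirely; the default `literal` mode
emits them, faithful to how the rule is stated.

Assembly integrates labels and phase sets with a deliberate asymmetry:
only certain labels orient phase sets and enter the haplotype strings.  A
single wrong heuristic label propagated through a read-backed chain would
corrupt an entire phase set, so assumed labels are reported per marker but
never asserted in the strings.  Contradictions are arbitrated
hierarchically: certain beats assumed (logged); assumed-vs-assumed at one
marker (e.g. both parents carry the allele) is treated as *no information*
rather than a conflict, so read links can still phase the marker; and
disagreement between certain anchors — impossible on error-free data —
demotes the whole phase set to conflict rather than picking a side.  An
individual with no certain label anywhere (e.g. a cousin with untyped
parents) still gets allele strings for their largest read-backed phase set,
in an arbitrary but deterministic orientation (`relative` confidence):
relative phase is exactly what read evidence proves, and the sharing test
chooses per-individual orientations anyway.

The sharing test is identity-by-state consistency used as
identity-by-descent evidence, not probabilistic IBD: it searches for one
haplotype per individual such that the choices agree at every marker known
in all of them.  Unknown alleles — unphased, heuristic-only, or conflicted
markers — act as wildcards, so exclusion rests only on confidently phased
evidence.  A verdict is only `valid` when supported by at least
`min_informative` markers (default 3, guarding against vacuous verdicts on
sparse phasing; a real analysis of ~11 markers comfortably exceeds it).
The implementation enumerates assignments (2^n for n individuals, capped at
16); tests check it against an independently written exhaustive oracle.
`shared` can flip true→false as markers are added but never the reverse on
valid instances (monotonicity, asserted by test).

## TPM

`TPM_g = 10^6 · (c_g/ℓ_g) / Σ_h (c_h/ℓ_h)` per sample column.  Gene length
is a user-supplied effective length in base pairs; whether union-exon or
transcript length is appropriate is the caller's contract.  All-zero
columns produce zeros with a warning rather than an error (robustness for
sparse fixtures).  Column sums are conserved to 1e-9 relative tolerance;
ranking ties are broken lexicographically by tissue label and flagged.

## Synthetic cohorts

The simulator emulates the data-generating process the analysis assumes:

* **Pedigree template**: four generations, eight affected members
  descending from an affected founder grandmother; five affected and four
  unaffected members genotyped; an affected proband with two affected sons
  and an affected first cousin; youngest generation status-unknown.  The
  sequenced-affected set is the proband, his two sons, and the cousin.
* **Markers**: 11 SNPs (default) at random positions in a ~385 kb interval,
  founder haplotypes drawn at allele frequency 0.5, dropped down the
  pedigree with at most one crossover per meiosis (recombination
  probability default 0 — a ~385 kb interval is ≈0.4 cM, so zero
  recombination is the realistic default, with an explicit knob).
* **Scenarios**: `random` (unconstrained transmission; the interval is a
  *non-causal* locus on a different chromosome from the causal variant),
  `shared` (every affected inherits one designated founder haplotype —
  transmission along the affected lineage is forced), and `distinct`
  (founder haplotypes pairwise distinct and the affected sib pair receives
  complementary haplotypes from both parents, which provably leaves no
  haplotype common to the sequenced affecteds).
* **Causal variant**: one novel exonic SNV (MAF 0, CADD drawn in (10, 15]),
  heterozygous in every genotyped affected and absent in every genotyped
  unaffected.
* **Background**: variants drawn independently (not gene-dropped), with a
  MAF spectrum of a point mass at 0 (novel) inside a rare fraction
  (default 0.5) plus log-uniform tails, Hardy–Weinberg genotypes at the
  population frequency conditioned on ≥1 cohort carrier (site
  ascertainment), uniform CADD on [0, 40] with a small absent fraction,
  a consequence-class mixture dominated by intronic/intergenic classes,
  and a small fraction of panel-gene and unannotated variants so every
  cascade policy is exercised.
* **Read links**: emitted between adjacent heterozygous markers with
  probability 0.8 per pair, always consistent with the true haplotypes
  (no chimeric reads).

What the simulator does *not* emulate: within-family sharing of background
variants (relatives share far more rare variants than independent draws
produce, which is why the real analysis counts thousands of shared rare
variants while simulated cohorts retain only a handful past the sharing
stage), linkage disequilibrium between markers, genotyping error, sequencing
depth, and read-level artifacts.  Passing tests therefore demonstrate the
correctness of the *logic* on Mendelian-consistent data, not robustness to
call errors — the confidence machinery and the `max_violations` /
`genotype_missing_rate` knobs exist for exploring the latter.

Default cohort size is 1,000 background variants: large enough that every
cascade stage drops variants, small enough that hundreds of seeded cohorts
simulate in seconds.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere internally (VCF convention);
  BED input is converted from 0-based half-open on read.
* Chromosome dialects (`chr12` vs `12`) are normalized (default: strip the
  prefix) so VCF/BED/annotation joins are robust.
* Multi-allelic records are decomposed at load into one biallelic record
  per alternate allele; any missing allele in a genotype makes the whole
  call missing.  Indels are matched by exact key; left-normalization is not
  performed (documented limitation).
* Pedigree validation returns violations as data (all at once), not
  exceptions; cycle detection is an iterative three-colour DFS checked
  against a graph-library oracle.
* Empty variant sets, header-only VCFs, zero-marker intervals, and all-zero
  count columns are all defined, tested degenerate cases.

## Known limitations

* Deterministic co-segregation only — no LOD-score linkage.
* Sharing is IBS consistency; with few or uninformative markers it cannot
  distinguish IBD sharing from chance identity (the `min_informative`
  guard and the reported informative/consistent counts expose this).
* The parent-shared heuristic's assumed labels are reported but cannot be
  independently validated without the other parent's genotype.
* No population phasing (EM/HMM), no recombination mapping within the
  interval beyond the single-crossover simulator model.
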