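# pedvar

Family-based rare-variant discovery for autosomal dominant disorders.

`pedvar` implements the desk analysis used to find a causal variant in a
single extended pedigree when genome-wide sequencing is available for a few
affected relatives: a shared-heterozygote filtering cascade, deterministic
dominant co-segregation testing, pedigree- and read-backed haplotype phasing
with an identical-haplotype-sharing test for locus exclusion, and TPM-based
tissue expression ranking for candidate prioritization.  A gene-dropping
simulator generates complete synthetic cohorts (VCF, PED, annotations,
marker genotypes, read links, and ground truth) so every stage is testable
without patient data.

It is written for statistical geneticists and rare-disease researchers who
want the classical family-filtering workflow as a reproducible, scriptable
library rather than a one-off spreadsheet analysis.

## The analysis

Given genotypes $G_{v,i}$ for variants $v$ and family members $i$, a set
$A$ of sequenced affected relatives, population allele frequencies
$\mathrm{MAF}(v)$ and deleteriousness scores $\mathrm{CADD}(v)$, candidates
are the variants that pass, in order:

1. **panel exclusion** — $\mathrm{gene}(v)$ not in the established
   disease-gene panel;
2. **shared heterozygosity** — $G_{v,i} = \text{het}$ for every $i \in A$
   (a dominant allele entering through one founder is expected heterozygous
   in every affected);
3. **rarity** — $\mathrm{MAF}(v) < 0.001$ (strict; a variant absent from the
   population database counts as frequency 0);
4. **consequence** — exonic;
5. **deleteriousness** — $\mathrm{CADD}(v) > 10$ (strict);
6. **co-segregation** — under full penetrance, every genotyped affected
   carries the allele and no genotyped unaffected does.

Every stage is a pure set predicate and the result is a ledger of
input/surviving counts, so each dropped variant is attributable to exactly
one stage.

For locus exclusion, SNP markers across a candidate interval are phased by
three rules — alleles shared between a parent and all listed children are
attributed to that parent's haplotype; alleles present in the sibs but
absent from a genotyped parent are attributed to the other parent;
sequencing reads spanning two heterozygous sites fix their relative phase
(union-find with a parity bit) — and the sharing test asks whether one
haplotype per affected can be chosen that agrees at every jointly-phased
marker.  If not, the interval cannot carry a dominant allele shared by
descent and the locus is excluded.  Labels are graded by confidence:
exclusion rests only on phase assignments forced by Mendelian logic, while
heuristic labels are reported but treated as wildcards.

Expression ranking uses transcripts per million,
$\mathrm{TPM}_g = 10^6 \cdot (c_g/\ell_g) / \sum_h (c_h/\ell_h)$,
with counts $c$ and effective gene lengths $\ell$ in kilobases; every
sample column sums to $10^6$.

## Worked example

Simulate a cohort (nine genotyped members: five affected, four unaffected;
one implanted causal variant; 1,000 background variants), then run the
cascade with the four sequenced affecteds:

```sh
$ pedvar simulate --seed 7 --out-dir fix
$ pedvar filter --vcf fix/cohort.vcf --ped fix/pedigree.ped \
    --annotations fix/annotations.tsv --panel fix/panel.txt \
    --affected III-1,III-8,IV-1,IV-3 --out-dir out
panel_exclusion         1001    988
shared_heterozygous     988     2
maf                     2       1
consequence             1       1
cadd                    1       1
segregation             1       1
candidates      4:88394487:G:A
```

Reading the ledger: 13 of 1,001 variants fell in panel genes; only 2
variants were heterozygous in all four sequenced affecteds (background
genotypes are drawn independently, so sharing by all four is rare); the
rarity filter left the single novel exonic variant, which passed the CADD
and segregation stages.  `out/report.json` records the candidate with its
annotations (here: exonic, MAF 0.0, CADD 13.1 — the implanted variant).

The locus-exclusion verdict on the simulated ~385 kb marker interval:

```sh
$ pedvar haplotype --markers-vcf fix/markers.vcf --ped fix/pedigree.ped \
    --links fix/links.tsv --interval "12:91,251,926-91,637,312" \
    --individuals III-1,III-8,IV-1,IV-3 --out-dir out
```

prints a JSON report with `"shared"`, the number of informative markers,
and — when sharing holds — the witness haplotype; `out/phase_labels.tsv`
lists the per-marker phase of every individual with its confidence class.

## Layout

| module | contents |
| --- | --- |
| `pedvar.pedigree` | `Individual`, `Pedigree`, validation, PED I/O |
| `pedvar.variants` | biallelic `VariantRecord`, canonical keys, VCF I/O (pysam), multi-allelic decomposition |
| `pedvar.annotations` | gene/consequence/MAF/CADD table, TSV I/O, absent-value semantics |
| `pedvar.intervals` | 1-based `GenomicInterval`, region strings, BED3 |
| `pedvar.filtering` | the cascade and its stage ledger |
| `pedvar.segregation` | dominant co-segregation verdicts |
| `pedvar.haplotype` | phasing rules, phase sets, assembly, sharing test |
| `pedvar.expression` | TPM and tissue ranking |
| `pedvar.simulate` | gene-dropping cohort simulator and fixture I/O |
| `pedvar.pipeline` / `pedvar.cli` | orchestration and the `pedvar` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
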