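# Methods

## Background and model

Homozygosity mapping finds recessive disease genes through runs of
homozygosity around an autosomal-recessive variant inherited twice from a
common ancestor. `hetscan` implements the mirror-image idea for *dominant*
traits: an inherited dominant pathogenic variant travels on a founder
haplotype that, within the region R between the two recombination events
flanking it, is passed unchanged through the generations, while the
homologous chromosome is effectively a random draw from the population.
Markers in R therefore tend to be *heterozygous* in carriers.

The two-locus model (`hetscan.popgen`) makes this quantitative.  Let `e` be
the disease-allele frequency, `f` the population frequency of the marker
allele `A` carried by the founder haplotype, and `D` the disequilibrium
parameter.  Complete disequilibrium (`D' = 1`, `D = D_max = e(1-f)`) removes
the u–B haplotype, so a carrier is heterozygous at the marker exactly when
the non-disease chromosome carries `B`:

```
H_R      = (1 - f) / (1 - e)          (carrier het inside R)
H_random = 2 f (1 - f)                (HWE het at a random marker)
r        = H_R / H_random = 1 / [2 f (1 - e)]
```

The enrichment `r` is large precisely for rare founder alleles (small `f`),
which is why the scan works best on dense sequence data where most markers
are rare.

## The two-stage scan

**Stage 1** computes at every variant a `(2m+1)`-point moving-average
heterozygosity `H = h/(g+h)`, where `g` and `h` count homozygous and
heterozygous genotypes at the variant and the `m` variants on either side,
pooled over all analyzed individuals.  Missing genotypes contribute to
neither count; windows never cross chromosome boundaries, so the first and
last `m` variants per chromosome get no value.  Default `m = 50` (101-point
window).  Joint family analysis pools raw counts rather than averaging
per-individual H: the two differ under missingness, and pooling is what
satisfies `g + h = (2m+1)n` for complete data.  A window whose every
genotype is missing is skipped rather than assigned 0, which would bite a
hole into downstream segmentation.

A candidate variant's Stage-1 score is the competition rank of its H among
all emitted values (largest = 1, ties share the smallest rank) and
`top% = 100·rank/N_var` (displayed half-up at one decimal).

**Stage 2** partitions each chromosome's H values into regions of increased
heterozygosity (RIH): maximal runs that rise to a local maximum `H_max` and
then fall, scanned through the successive differences `C_i = H_i − H_{i−1}`
with zero differences skipped (plateaus are absorbed).  The source
description's verbal sign convention for `C` contradicts its own formula;
we implement the unambiguous operational intent (rise, peak, fall).
Consequences of the literal scan rule that we keep deliberately:

* a strictly falling prefix or strictly rising suffix of a chromosome
  belongs to no segment, as do plateau variants between a fall and the next
  rise — a target variant there gets the explicit "occurs in no RIH" state;
* when two segments would share their boundary valley variant, the valley
  is assigned to the *earlier* segment so index ranges stay disjoint.  This
  touches membership of single valley variants only and never changes any
  `H_max`;
* within a peak plateau, `hmax_pos` is the leftmost attaining variant.

Candidates are ranked by their containing segment's `H_max` (competition
ranking again).  Because short noise segments carry high maxima, ranks are
recomputed after discarding segments shorter than `w/4`, `w/2`, and `w`
(`rank2`–`rank4`), where `w` is the genome-wide mean segment length in bp
(a variant-count length is available behind `length_mode="variants"`).  The
"at least" reading of the cut (≥) is used.  The stricter cuts can discard
the target's own segment — the corresponding rank is then reported absent
rather than silently recomputed.  The estimated disease position is
`hmax_pos` of the containing segment; `d` is its distance to the candidate
in bp.

## Empirical significance

Genome-wide significance of an observed `H` (and of the containing
segment's `H_max`) is estimated by placing a null disease variant uniformly
at random among all markers that carry an H value, `N = 999` times by
default.  Because the scan is position-independent, each replicate reuses
the precomputed track — an exact shortcut, verified against a literal
re-scan per replicate in the tests.  With `k` = number of values (the `N`
replicates plus the observed one) at least as large as the observed value,
`p = k/(N+1)`; counting the observed value is forced by the stated floor
`p = 1/1000` at `N = 999`.  Draws are independent with replacement; null
positions outside every RIH contribute no `H_max` exceedance.  `p` is
therefore discretely super-uniform under the null, which the suite checks
on a no-carrier cohort (200 trials; tolerance = the 2/(N+1) discreteness
allowance plus three binomial SEs of the 200-trial CDF estimate, fixed a
priori).

## Carrier discrimination

Carriers of an inherited dominant variant show small top-% values at the
candidate site; noncarriers do not.  `hetscan.discrimination` classifies an
individual as a carrier when `top% < threshold`, sweeps the threshold just
above each observed score to build the ROC curve, and reports the
trapezoidal AUC (identical to the Mann–Whitney concordance with half-credit
ties) plus the cut maximizing total correct predictions (ties resolved
toward higher specificity, then the smaller cut).  The packaged reference
table (`hetscan/data/carrier_scores.tsv`, 9 carriers / 8 noncarriers from
sequenced families with known dominant pathogenic variants) reproduces
AUC = 0.85 and the operating rule "top% below ~21" (sensitivity 0.889,
specificity 0.750).  That rule is an estimate from n = 17 and is packaged
as a clearly-labelled constant, not a validated clinical cut-off.

## Synthetic cohorts

`hetscan.simulate` generates the minimal world the method needs: carriers
share a founder haplotype across an imposed region R (no pedigree or
recombination process is simulated — R *is* the modelling primitive);
everything else is an independent HWE draw per marker at a frequency from a
rare-skewed Beta(0.8, 4) law clipped to [0.01, 0.5].  Defaults are a
scaled-down WGS regime: 4 chromosomes × 50 Mb × 5,000 markers (the real
use case is ~6M markers; ~300× scale-down keeps the whole suite under a
minute), 3 carriers + 3 noncarriers, R half-width 600 kb (≈60 markers per
side, spanning the default window), 2% missingness, `e = 0.01`.

Founder allele convention: by default (`founder_mode="allele_a"`) the
founder haplotype carries the allele whose population frequency is `f` —
the complete-disequilibrium configuration of the closed-form model, where
`f` is by definition the frequency of the disease-haplotype allele.  The
carrier's homologous chromosome carries that allele with probability
`(f−e)/(1−e)`, giving per-site carrier heterozygosity exactly
`(1−f)/(1−e)` inside R.  Drawing the founder allele from the population
frequency instead (`founder_mode="random"`) marginalizes the heterozygosity
back to `2f(1−f)` — *no* mean elevation — and is provided as a structured
null; the suite verifies both behaviors.  In real joint-called data the
"allele_a" configuration is what variant discovery produces: the markers
present in a carrier's call set near the variant are largely those the
founder lineage itself contributes.

What a green synthetic test does **not** establish: the generator has no
background LD, no population structure, no genotyping-error model, no
variant-density heterogeneity and no call-set ascertainment, so absolute
ranks/p-values on real cohorts will differ; the tests establish correctness
of the statistics and qualitative recoverability of a planted signal.

## Numerical choices and degenerate inputs

* Genotype classes: any two distinct allele indices are heterozygous
  (`1/2` included); half-missing (`./1`) and haploid calls are MISSING.
* Unsorted or chromosome-interleaved VCFs are rejected with a "sort your
  input" error; duplicate positions are retained in file order.
* Ranks use competition (min) ranking throughout — conservative for the
  reported rank of a true variant.
* `H` is computed from exact integer counts; no floating accumulation.
* Constant-H chromosomes produce zero segments with a warning; empty
  matrices and windows larger than a chromosome raise errors that name the
  remedy.
* Display rounding of top-% is decimal half-up (banker's rounding would
  turn 20.65 into 20.6).

## Known limitations

* New (non-inherited) mutations show no founder region and are invisible
  to the method, as are variants whose R has eroded below the window span.
* Hemizygous sex-chromosome genotypes are scanned like autosomes but
  flagged; H there is not interpretable under the model.
* The empirical p-value treats one candidate per run; no multiple-testing
  correction across candidates is applied.
* Segment lengths in bp ignore local LD/map distance; a constant-LD map
  would make lengths more comparable across the genome.
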