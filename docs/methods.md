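# Methods

This note documents the statistical models implemented in `cilipop`, the
conventions and defaults chosen where the field offers more than one, what
the simulators do and do not emulate, and known limitations.

## Data model and conventions

External coordinates are 1-based inclusive (VCF, GFF3); everything internal
is 0-based half-open, with conversion confined to `cilipop.coords`. Only
biallelic SNPs enter the pipeline; multiallelic records, indels and
malformed sites are skipped with counts, never silently. Missing genotype
calls are retained: per-site sample sizes n_j are recomputed from
non-missing calls, and pairwise statistics are pairwise-complete (a
haplotype pair skips a site where either call is missing), which is
unbiased when data are missing at random.

VCF genotypes are treated as diploid calls. The ciliate macronucleus is in
fact highly polyploid; variant callers run against a macronuclear reference
nevertheless emit diploid-style genotypes, and all statistics here consume
those calls as given. This is a documented caveat, not a claim about
macronuclear ploidy.

## Diversity statistics

For a haplotype matrix of n rows (two pseudo-haplotypes per diploid
sample):

* S — count of columns with at least two distinct non-missing alleles.
* k̂ — mean pairwise difference count over all n(n−1)/2 pairs;
  π = k̂ / callable length. On complete data k̂ equals the frequency form
  Σ_j 2 p_j (1−p_j) n_j/(n_j−1), which the tests use as a cross-check.
* Watterson's θ̂_W = S / a₁ with a₁ = Σ_{i<n} 1/i.
* Tajima's D = (k̂ − S/a₁) / √(e₁ S + e₂ S(S−1)), with the full constant
  set a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ computed from their definitions.
  D is reported as undefined (not zero) when S = 0, and also for n < 4
  where the variance constants are unusable.

Silent-site diversity π_s restricts the numerator to synonymous
differences: per-haplotype CDS sequences are reconstructed from the gene
model (strand-aware; alleles complemented on minus-strand genes), pairwise
synonymous differences are counted per codon with NG86 pathway averaging,
and the denominator is the total fractional synonymous sites of the
reference CDS. "Silent sites" here means synonymous coding sites —
intronic/intergenic sites are not included; a four-fold-only variant would
be a trivial extension of the same machinery. Genes whose CDS length is not
a multiple of 3 after phase trimming are excluded from codon analyses and
reported in a rejects list.

Per-gene callable length defaults to the annotated gene span; per-gene D
uses only the gene's own S and k̂. The genome-wide row is computed on the
concatenated variant set, and per-class "mean D" is the unweighted mean of
per-gene D over genes where D is defined — both are reported because the
two conventions differ in general.

**Expectation of D under neutrality.** D is only approximately centred at
zero: the variance estimate in its denominator is correlated with the
numerator, giving a small negative expectation. Two independent
implementations (this package's coalescent simulator and an
msprime-equivalent check during development) agree on a mean of about
−0.10 at n = 20, θ = 10. Calibration tests therefore treat unbiasedness
claims as applying to π and θ̂_W (which are exactly unbiased), and
demographic effects on D as sign shifts relative to the neutral baseline.

## Codon-level counting (NG86)

Potential synonymous sites per codon: for each position, the fraction of
the three single-base changes that preserve the amino acid, summed over
positions; s + n = 3 exactly. Changes creating a stop codon count as
nonsynonymous. Differences between two codons are averaged over all
orderings of the differing positions; orderings passing through a stop are
excluded with renormalization, and codon pairs with no stop-free pathway
are dropped from totals. Site totals for a pair are the average of the two
sequences' totals, and the Jukes–Cantor correction
K = −(3/4) ln(1 − (4/3) p) is applied to p_s and p_n independently, with
p ≥ 3/4 flagged as saturated rather than extrapolated.

The genetic code is configurable by NCBI translation-table id (tables come
from Biopython). The default is table 1; table 6 — the ciliate nuclear
code, where TAA/TAG encode glutamine and only TGA is a stop — is fully
supported and is the natural choice for ciliate macronuclear genes.

## McDonald–Kreitman tests

Polymorphism: each site segregating in the ingroup counts once, classified
by substituting the most common minor allele into the ingroup major-allele
codon (ties broken toward the reference base). Divergence: sites
monomorphic in the ingroup and different from the outgroup, classified by
pathway averaging with ingroup-polymorphic positions neutralized — a site
both polymorphic and divergent counts as polymorphism only (the standard
MK convention). Codons containing stops, and codons whose divergence
pathways all cross stops, are excluded and counted.

NI = (Pn/Ps)/(Dn/Ds) is undefined at any zero denominator unless the
Haldane correction (+0.5 to all cells) is requested. The cross-gene
summary offers both the arithmetic mean of per-gene NI and the
Stoletzki–Eyre-Walker ratio-of-sums NI_TG, which is less biased at small
counts (per-gene NI inherits the upward bias of ratios of small Poisson
counts — about +4% at ~50 synonymous polymorphisms per gene, visibly more
below ~20). The Fisher exact test is the two-sided
sum-of-smaller-probabilities test on [[Dn, Ds], [Pn, Ps]] (via scipy),
with counts rounded to integers when pathway averaging produced fractions.

Because exact-test p-values are discrete and conservative — whenever the
observed table is the modal one the p-value is exactly 1 — their null
distribution is not uniform in the two-sided Kolmogorov–Smirnov sense at
any realistic count scale. Calibration is therefore checked one-sided: the
empirical CDF of null p-values must not significantly exceed the uniform
CDF (no spurious significance), plus a direct check that
P(p < 0.05) ≤ 0.05.

Class summaries join per-gene statistics to life-stage DEG-class labels
and family-expansion status (both are inputs, not computed here), with
seeded percentile bootstrap CIs (default B = 1000, gene-level resampling)
and expanding/contracting overlap fractions whose denominator includes
genes of unknown status by default.

## Linkage disequilibrium and inbreeding

Haplotype r² = D² / (p_A q_A p_B q_B) with D = p(AB) − p(A)p(B) from
pairwise-complete haplotypes; the genotype-dosage alternative is the
squared Pearson correlation of 0/1/2 dosages (Rogers–Huff style), for
unphased input. The haplotype method is the default because clonal isolate
strains are effectively phased; the method used is recorded in output
metadata. Decay curves enumerate all same-chromosome pairs within
`max_dist` (default 10 kb), with default bin edges
0/100/500/1000/5000/10000 bp and seeded uniform thinning above
`max_pairs_per_bin`.

The inbreeding coefficient is the method-of-moments estimator
F = (O_hom − E_hom)/(N − E_hom) with
E_hom = Σ_j [1 − 2 p_j q_j n_j/(n_j−1)] over that individual's usable
polymorphic sites. Allele frequencies include the focal individual by
default (an exclude-self option exists); overall-monomorphic sites are
skipped. F = 1 is exact for a fully homozygous individual, and F can be
negative for heterozygote excess.

## Ks distributions and WGD peaks

Ks per paralog pair comes from the NG86 machinery above; values at or
below `ks_min` (default 0.01; allelic pairs and assembly duplicates),
above `ks_max` (default 5; saturation regime) or flagged saturated are
excluded with counts. Mixtures are fitted on log Ks — Ks is positive and
right-skewed, so components are log-normal on the natural scale — by EM
(scikit-learn GaussianMixture) for k = 1..4 with 10 seeded restarts each,
selecting k by minimum BIC. Components with weight ≥ `min_weight`
(default 0.1) become peaks; the retained peak count is the WGD-event
proxy, and peak counts (not positions) are the robust contract. A
kernel-density mode finder is provided as an advisory cross-check, since
KDE modes depend on bandwidth. Fits need at least 50 retained values;
below that a density summary is the honest output.

## Telomere scanning and assembly features

The scanner looks for at least `min_repeats` (default 3) tandem copies of
TT(T/G)GGG — the degenerate position free to vary per copy — beginning
within `max_offset` (default 50 bp) of the 5′ end, inside a terminal
window (default 200 bp); the 3′ end expects the reverse-complement tract
(CCC(A/C)AA copies) ending within `max_offset` of the last base. Both
orientations are accepted at both ends by default because assembly
orientation is arbitrary. Scaffold telomere class is the number of
positive ends (0/1/2). N50 is the largest L such that scaffolds ≥ L sum
to at least half the assembly; GC excludes ambiguous bases from the
denominator. Exact telomere counts for a given assembly depend on these
scan parameters, which is why reports embed the configuration used.

## Simulators: what they emulate, and what they do not

All generators are pure functions of (config, seed) — reruns are
byte-identical — and always emit truth tables alongside the data.

* **Coalescent** — Kingman n-coalescent in coalescent units (2N
  generations = 1) with per-locus θ, so E[S] = θ·a₁ and E[k̂] = θ are
  exact anchors. Demography is a stepwise relative-size function
  (constant / expansion by `factor` at `time` / bottleneck of depth
  `factor` over [start, start+duration)), implemented by inverting the
  piecewise-constant coalescence hazard. Mutations are Poisson(θ/2 ×
  total branch length) placed uniformly on branches under infinite sites
  (distinct positions on a finite grid; collisions resampled and counted,
  impossible placements raise). No recombination, selection or gene
  conversion. Note the bottleneck signature on Tajima's D is
  non-monotone: a moderate bottleneck (a few lineages surviving it)
  yields positive D, while a catastrophic one collapses the genealogy to
  a star and yields negative D — the sign tests use the moderate regime
  (factor 0.1, start 0.02, duration 0.05).
* **LD copying chain** — each haplotype carries a latent uniform redrawn
  with probability 1 − exp(−d/d0) between adjacent sites; alleles are
  latent < p with a single dataset-wide frequency p. This makes the
  allelic correlation at distance d exactly exp(−d/d0) and expected r²
  approximately exp(−2d/d0) plus the 1/(n−1) sampling floor. The
  frequency is shared across sites deliberately: correlation between
  Bernoulli variables with unequal success probabilities is capped below
  1 (Fréchet bounds), so a per-site-frequency chain could not attain the
  closed-form curve. The chain is a validation scaffold with a known
  decay law, not a coalescent-with-recombination; it reproduces the
  qualitative "rapid decay within ~1 kb" shape without populational
  realism.
* **MK tables** — independent Poisson counts with
  E[NI] = ω_poly/ω_div by construction. Defaults (λ_ps = λ_ds = 50,
  N/S site ratio 2.5) give roughly 50 synonymous SNPs per gene, the
  scale implied by a megabase-level SNP set spread over tens of
  thousands of genes; at that scale the per-gene NI ratio bias is a few
  percent.
* **Ks mixtures** — log-normal components plus optional exponential
  background. Sequence emission builds pairs from four-fold-degenerate
  codons (exactly one synonymous site each, verified per genetic code)
  and applies third-position substitutions per site with probability
  p = (3/4)(1 − exp(−(4/3)Ks_target)), so NG86+JC estimation recovers
  the target in expectation. Real paralog pairs also diverge
  nonsynonymously; the emitted pairs isolate the synonymous channel.
* **Inbreeding genotypes** — per-site frequency p_j uniform on a range,
  genotypes from the standard F-mixture (hom-ref p² + Fpq, het
  2pq(1−F), hom-alt q² + Fpq). No linkage between sites.
* **Scaffolds** — i.i.d. background at the target GC with telomere
  tracts placed at 0/1/2 ends (5′ forward, 3′ reverse-complemented),
  optionally jittered up to a configurable offset; no interior tracts,
  repeats, or Ns.

Consequently, passing tests demonstrate estimator correctness and
end-to-end plumbing on data matching each model's assumptions; they do not
certify behavior under recombination, selection, alignment error,
polyploid allele dosage or assembly artifacts.

## Pipeline, determinism and problem sizes

Every stage derives its randomness from the single global seed through
named substreams (CRC-based), so changing one stage's stream does not
perturb others; reruns with the same config are byte-identical except the
manifest's timestamps, and the manifest records SHA-256 checksums per
output. Outputs are written atomically (write-temp-then-rename). The
bundled demo cohort uses nine diploid strains, 24 single-exon genes of
200 codons at θ = 8 per gene, 200 LD sites at 100-bp spacing with
d0 = 500 bp, 4000 inbreeding sites with F from 0.5 to 0.9, 700 + 500
paralog pairs of 300 codons, and 120 scaffolds — sizes chosen so the full
pipeline and its calibration replicates run in seconds while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Diploid genotype semantics on a polyploid macronucleus (above).
* No multiallelic sites, indels, or phasing; dosage LD is the fallback
  for unphased data.
* Per-gene D on short genes with few SNPs is noisy; class means inherit
  that noise.
* Mixture-based peak counting can merge WGD peaks closer than roughly
  two log-sds or split heavy-tailed single peaks; the KDE cross-check
  helps flag such cases.
* The MK implementation is the classic two-way contrast — no asymptotic
  MK, DFE inference, or polarized tests with two outgroups.
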