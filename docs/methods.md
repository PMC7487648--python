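# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, in the order the analyses run.

## Diploid reference construction

A personalized genome per parental strain is built by applying a validated
variant table (SNPs and indels ≤ 3 nt) to the haploid reference. Internal
coordinates are 0-based half-open; variant TSVs are 1-based on disk and
converted on load. Every ref allele is checked against the reference on
load and a mismatch is a hard error naming `chrom:pos`. Overlapping
variants on one strain are rejected rather than resolved — the strain
variant tables this emulates are non-overlapping.

Indels produce a piecewise-linear coordinate map (blocks of
`src_start, src_end, offset`). For a length-changing variant the aligned
prefix of `min(len(ref), len(alt))` bases keeps its offset; bases deleted
in the target are unmapped. Lifting annotation maps each exon by its
boundary bases; a transcript with a boundary inside a deleted span cannot
be represented without arbitrary truncation and is dropped with a logged
warning.

Annotation merging filters the primary set by biotype first, then accretes
additional sets in order, admitting a transcript only if it has no
same-strand exonic overlap (≥ 1 bp) with anything already merged. The
"not represented" notion of multi-source merging is not precisely
definable from the outside; ≥ 1 bp same-strand exonic overlap is the
strictest simple rule and is applied after biotype filtering (filtering
first removes material that should never block an addition).

## Posterior transcript-per-allele quantification

Equivalence classes — the set of (transcript, allele) assignments
compatible with a fragment — are the inference input; fragments whose
window covers no strain variant are allele-ambiguous and their ambiguity
is carried into the posterior, not resolved by assignment.

The model: fragment counts from transcript-allele *t* arise at rate
θ_t · ℓ_t with effective length ℓ_t, and θ_t carries a Gamma(α, β) prior
(defaults α = 0.01, β = 0.001 — weakly informative; these are
configuration, not substance). One Gibbs sweep allocates each class's
count multinomially among members with probability ∝ θ_t/ℓ_t, then draws
θ_t ~ Gamma(α + n_t, β + ℓ_t). Defaults: 1024 retained draws after 512
burn-in sweeps, thinning 2; a single explicitly seeded generator per call,
no global state. With all-singleton classes the chain reduces to iid draws
from the conjugate closed form, which is the oracle the sampler is tested
against.

Draws are reported in TPM: per draw, TPM_t = 10⁶·θ_t/Σθ. TPM values below
0.01 are raised to 0.01, and a transcript whose posterior **median** TPM
is below 0.01 has all draws set flat to 0.01 — the minimal measurable
expression level. Flat columns have zero variance and propagate as
undefined (NaN) posterior correlations. The flooring median is computed on
the raw (pre-floor) scale.

Two properties of this sampler are worth naming because tests must respect
them. First, a pair of transcripts sharing all of their fragments has an
unidentifiable split; the posterior of the share is wide and the
uncollapsed chain traverses it as a slow random walk, so split symmetry is
asserted on multi-chain averages with Monte-Carlo error estimated from the
spread across chains. This unidentifiability is precisely what the
combining stage absorbs. Second, exact bitwise symmetry under allele
relabeling is not attainable with a single shared random stream (the
stream consumption order follows label order), so allele symmetry is
tested distributionally at this stage and exactly at the combining and
calling stages, which are label-symmetric by construction.

## Transcript combining

For every same-locus pair of transcripts (or merged groups) the Pearson
correlation of posterior TPM draws is computed per RNA-seq sample per
allele; the pair's score is the arithmetic mean over all sample × allele
values, excluding undefined ones (a pair with no defined value is
ineligible). Pairs with mean r below the cutoff (default −0.25) are merged
greedily, most negative first, ties broken lexicographically on group ids;
a merged group's draws are the elementwise sum of its members' draws per
allele per sample, and scores are recomputed after every merge until no
pair qualifies. Merging is defined on transcript identity, so the grouping
is identical for the two alleles and the combined features can be tested
for allelic bias. Each merge reduces the group count by one, so at most
n − 1 iterations occur.

Whether the mean should pool the two alleles or be required separately
within each allele is genuinely open; both are implemented
(`mode="pooled"` default, `"per-allele"` behind the flag) and the mode is
recorded in the output metadata. On instances of ≤ 4 transcripts the
greedy fixpoint is tested against exhaustive enumeration of all admissible
merge orders.

## Allelic-bias calling

For a feature and allele, each posterior draw index d gives
Δ_d = mean over group-B samples of log TPM − mean over group-A samples of
log TPM (natural log on floored TPM; the floor prevents −∞). The
posterior probability of a directional difference is
PP = max(fraction of Δ_d > 0, fraction of Δ_d < 0), with exact zeros split
evenly so identical groups give PP = 0.5. A call is significant when
PP > 0.95. Draws are paired by index after verifying equal draw counts
across samples. No published formula exists for this quantity; this is the
simplest posterior-probability-of-direction consistent with a Bayesian PP
on posterior samples, computed on log TPM (invariant to monotone power and
scale transforms), with no multiplicity adjustment across features. Under
an exact null the exceedance rate of PP > 0.95 is the nominal 10%
(two-sided 1.645σ); the calibration test checks non-inflation at that
rate.

TPM is compositional: a perturbed locus deflates every other feature's
TPM by its library share. In the synthetic ASE experiment the background
loci therefore carry 100× the focal locus's abundance, keeping the focal
locus below 0.1% of the library as a single real gene would be; with that
in place the intact allele's significant-call rate equals the matched
null rate, which is the computational restatement of one-allele-only cis
dysregulation.

## Differential expression

Genes with counts below 3 in every replicate are filtered (a single
replicate at exactly 3 retains the gene). Library sizes use
median-of-ratios; TPM uses gene length and depth with columns summing to
10⁶.

The NB engine (variance = μ + φμ²) estimates gene-wise dispersion by
maximizing the Cox–Reid adjusted profile likelihood on a 45-point
logarithmic grid over φ ∈ [10⁻⁶, 10] with quadratic refinement; the CR
term (0.5·log det X'WX, factorizing over groups) removes most of the
small-sample downward bias of the plain MLE. A parametric trend
φ(μ) = a₀ + a₁/μ is fit by least squares on the gene-wise estimates and
the final dispersion is the log-space weighted average of trend and MLE
with weight 0.8 on the trend. Group means solve the NB GLM score equation
(log link, size-factor offsets) by vectorized Newton iteration; the Wald
statistic uses the analytic information-based standard error
√(1/Σ_A w + 1/Σ_B w), w = μ/(1+φμ). The statistic is referenced to a t
distribution with df = residual_df/(1 − shrink_weight) — the
moderated-statistic convention in which shrinkage toward the trend
contributes prior degrees of freedom; with weight 0.8 and 4 + 4
replicates that is t(30). BH adjustment runs over unfiltered genes.

The trend weight of 0.8 (rather than an equal split) was chosen because
the synthetic study conditions share a common mean–dispersion trend
across genes, where strong shrinkage is the correct prior; jointly with
the moderated df it gives raw-p type-I error 0.050 under the null
conditions (μ = 100, φ = 0.1, n = 4/group) and ≥ 0.9 detection of a
4-fold effect at μ = 500. Independent-filtering and outlier-replacement
refinements of reference implementations are deliberately not reproduced;
agreement with the reference NB engine is checked in a test, not assumed.

The cis-window report takes genes whose span midpoint lies within
± window/2 (default 2 Mb window) of the focal point, closed boundary, and
flags genes with adjusted p < 0.05 and point-estimate fold change
2^|log2FC| > 1.5. Window membership by midpoint and the closed boundary
are conventions that had to be fixed; centering is on a configurable
focal point (a gene midpoint by default) since TSS-centering cannot be
distinguished from midpoint-centering at 2 Mb scale. Recurrence tallies
flagged calls per gene across per-tissue reports with direction
annotation. Tissue clustering normalizes per-tissue mean TPM to
probability distributions, computes pairwise base-2 Jensen–Shannon
divergence (0 for identical, 1 for disjoint support), and applies Ward
linkage, serialized as newick.

## Reciprocal rescue

A gene is reciprocal iff adjusted p < 0.05 in both contrasts (KO vs WT
and RESCUE vs KO) and the log2FC signs are strictly opposite — the only
reading consistent with "reciprocally regulated". The 2×2 overlap table
(both / KO-only / rescue-only / neither) spans the genes unfiltered in
both results, and the two-sided Fisher exact p uses the probability-mass
rule (all tables with probability ≤ observed, margins fixed), with the
sample odds ratio ad/bc reported. The focal gene is not special-cased:
the intersection count is reported as computed, and whether a focal gene
sits inside or alongside it is bookkeeping the caller can do.

## ORF discovery and peptide properties

The scanner accepts AUG, CUG and UUG starts; within each frame every stop
codon is paired with the 5′-most allowed start after the previous stop
(one maximal ORF per stop per frame; all start codons rank equally; codons
containing N never match). The initiator translates as Met regardless of
codon, matching initiator-tRNA behavior, and the standard nuclear code is
used. The default minimum length is 25 aa — a common smORF convention;
it is configurable because no principled threshold exists. Scanning is
given-strand by default with a both-strands option.

Cross-species ORF pairs are anchored on a nucleotide alignment of the
parent sequences: ORFs pair when their start codons (or stop codons) fall
within one codon (± 3 columns) of each other; start and stop conservation
are reported separately and pairs at ≥ 70% global amino-acid identity
(Needleman–Wunsch, BLOSUM62, affine gaps open 11 / extend 1; identity =
identical columns / alignment columns) are flagged conserved.

Peptide molecular weight is the average-isotope residue-mass sum plus one
water; the net charge at pH 7.0 is the Henderson–Hasselbalch sum over the
termini and ionizable side chains with the EMBOSS pKa set (N-term 8.6,
C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1).

The riboprobe check reports a match if the probe's reverse complement
occurs verbatim in the cDNA, falling back to the probe's own U→T form for
probes published as the sense sequence; the packaged 492-nt probe is
sense-published and hits the packaged cDNA exactly once. The packaged
cDNA clone is the isoform lacking the 5′ region, so scans of it do not
contain the 5′ ORF; the conserved-pair analysis therefore demonstrates
the method on a synthetic ortholog (10% third-codon-position mutations)
rather than claiming the published cross-species identities, whose exact
input sequences are not printed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume:
per-bp SNP placement at 1/150 (the C57BL/6J × Cast/EiJ density) and indels
at 1/1500; overlapping multi-isoform loci so combining has genuinely
entangled pairs; single-end, error-free, uniform-start fragments whose
equivalence class is exact sequence compatibility; NB counts with group
effects in which cis genes keep their effect in the rescue group and trans
genes revert. Deletions never remove an exon-boundary base, so every
simulated transcript lifts to both alleles. Truth tables list every gene's
planted effects exactly once.

It does not emulate sequencing error, mapping bias, fragment-length
distributions, paired ends, positional coverage bias, biological
between-replicate variance in the allelic experiment beyond counting
noise, or correlated gene-gene structure. Passing tests therefore show
the inference machinery is correct under its own assumptions, not that it
is robust to artifacts real aligners introduce.

Study-condition defaults: 4 replicates per genotype for count matrices
(3 per group and depth 10⁵ fragments for the allelic experiment,
matching the scale of the hybrid design); null-calibration runs use
μ = 100, φ = 0.1, 2,000 genes; planted cis genes sit at base mean 500
with log2FC 2 and dispersion 0.05 — clearly expressed genes with a
strong cis response, which is what detected cis genes are; the background
gene panel is lognormal (σ = 1) around μ = 100. The acceptance script
runs 100 effect seeds and 50 null seeds for the allelic contrast and 50
seeds for each DE simulation, sizes at which every rate it reports has a
binomial standard error below 5 points.

## Known limitations

- The Gibbs sampler mixes slowly across unidentifiable splits (by
  design of the uncollapsed scheme); downstream inference uses combined
  groups, where mixing is not an issue.
- The PP is reported per feature with no multiplicity control, as a
  posterior quantity; calibration is checked at its nominal 10%
  PP > 0.95 null exceedance.
- The DE engine is a compact reimplementation of the standard NB recipe;
  its gene lists will not numerically equal those of reference
  implementations with different dispersion-trend and filtering
  refinements, and no empirical-null p-value re-estimation is applied.
- The minimal liftover handles substitutions and short indels only — no
  structural variants, no chain-file fidelity with genome-browser tools.
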