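# Methods

This note documents the models and procedures the package implements,
the defaults of the synthetic study world, the numerical choices made
where the design was open, and what the test suite does and does not
establish.

## Reference transcriptome assembly

A transcript model is `U5 + ORF' + U3` with 0-based half-open ORF
offsets. UTRs that are missing or shorter than 4 nt are replaced by the
1000 nt flanking segment. ORFs whose length is not divisible by 3 carry
a trailing partial codon; it is resolved against the reference protein
at the position immediately following the whole-codon prefix
(*positional* comparison — the only decidable reading): a unique
consistent synonymous codon completes the partial codon, several
consistent codons pad it with `N`, and a missing residue truncates the
ORF to whole codons. ORFs beginning with one or two `N` characters are
passed through untouched. A missing stop codon is supplemented with
`TAA` — deterministically rather than at random, trading literal
randomness for seedless reproducibility.

The effective gene length *L* is the number of distinct 30 nt windows
(1 nt slide) over the union of a gene's transcript sequences, so
sequence shared between isoforms is counted once. Genes whose
transcripts are all shorter than 30 nt are flagged unquantifiable.

## Read processing

Alignment is substitution-only, forward-strand, in transcript space: a
24 nt seed with at most 2 mismatches, all hits in the best (minimum
seed-mismatch) stratum reported. Candidates come from pigeonhole
seeding — three exact 8-mers — which is exhaustive for ≤2 mismatches.
Base qualities are ignored and indels are not modelled; at the scale of
a 24–35 nt insert these are the standard short-read seed-alignment
assumptions.

Multi-read resolution is two-pass. Pass 1: single hits, and multi-hits
with a unique minimum of the per-base mismatch score over a 30 nt
extension, take the full read. Extensions running past a transcript end
are scored over the available overlap, normalized per base, so
3′-proximal hits are not penalized. Pass 2: surviving ties are split in
proportion to the vicinity density — the number of *pass-1 unique*
5′ ends within ±30 nt on the same transcript — falling back to an even
split when every vicinity is empty. Using pass-1 reads only avoids any
circular dependence among multi-reads and makes the procedure
deterministic; total assigned weight per read is exactly 1, so read
mass is conserved through the pipeline.

## Quantification

Counts sum fractional weights whose 5′ end lies in the counting region
(last 40 nt of 5′UTR, ORF, first 40 nt of 3′UTR) of the hit transcript.
RPKM = 10⁹·C/(N·L). Coverage is the fraction of counting-region
positions carrying at least one assigned 5′ end — the minimal reading
consistent with the quantification inputs; the denominator is the
counting region, not the full transcript. Replicate averaging
normalizes each replicate by its mean before averaging and restores the
global scale afterwards, which removes depth differences without
changing the measurement's units.

## Proteomics filtering

Order is fixed: impute missing intensities (constant 18, interpreted on
the log2 scale, the conventional floor for MS intensity data) →
per-protein Welch two-sided t-test of all experimental samples pooled
against the 3 non-specific controls, Benjamini–Hochberg at q ≤ 0.01 →
detected-in-≥2-of-3-replicates per phase, evaluated on the
*pre-imputation* detection mask → triplicate mean per phase. Welch was
chosen for the unequal group sizes; zero-variance rows get p = 1. The
cascade is idempotent and the retained set grows monotonically with q.

## Differential expression

RP uses the classic NB exact test: median-of-ratios size factors
(geometric-mean-1 normalized); per-condition means and variances of
normalized counts pooled into one LOWESS fit of log variance on log
mean (span 0.3). Because a sample variance on m replicates is
χ²_{m−1}-scaled, regressing its log underestimates log σ² by
ψ((m−1)/2) − log((m−1)/2) (≈0.37 at m = 4); the analytic offset is
added before fitting, without which the test's type-I error roughly
doubles. The raw (overdispersion) variance is the fitted variance minus
shot noise, floored at zero, so the full variance never drops below the
mean. The test conditions on each gene's grand total and compares the
observed M/G1 split with all splits under independent NB sums whose
moments follow the fitted model; fractional counts are rounded to
integers for the exact test. Genes with zero total get p = 1.

PP uses a per-gene one-way ANOVA of the M vs G1 triplicates on log2
intensities as a significance gate (p < 0.05), then ranks by
|log2 fold-change|. Both assays select the top 10 % of their tested
universe — for PP the denominator is all quantified proteins, matching
the RP convention. Ties are broken by (q, |log2FC| descending,
gene id), deterministically.

## Integration

All headline correlations are Spearman; partial correlation is
computed on rank-transformed variables (residual correlation after
linear removal of the control variable's ranks). The steady-state
regression is OLS on log2-scale predictors scored by held-out Spearman
over 100 repeats of 2-fold cross-validation — the most parsimonious
reading of a "Spearman linear regressor"; a rank-on-ranks fit was
considered and set aside since only the held-out *ranking* is scored.
Log transforms use a pseudo-count of half the smallest positive value.
Genes missing after proteomics filtering are excluded pairwise, not
imputed.

## PPI analyses

The marked-distance statistic is the mean shortest-path length over all
unordered pairs of marked nodes in the main component. The null is 100
degree-preserving randomizations (10·|E| attempted double-edge swaps
each, rejecting self-loops and multi-edges); the p-value is
(b+1)/(R+1), whose floor 1/101 < 10⁻² corresponds to an observed
distance shorter than all 100 null distances. Marked pairs disconnected
in a randomized graph are excluded pairwise; with the dense-graph
defaults this is rare. Randomization and BFS run through igraph's C
core (seeded through Python's `random`), keeping 100 permutations on a
2000-node graph under a few seconds; the public
`degree_preserving_randomize` exposes the identical null model on a
networkx graph.

Clustering is Newman's leading-eigenvector method: per connected
component, recursive bisection along the sign of the dominant
eigenvector of the (generalized) modularity matrix B = A − kkᵀ/2m,
accepting a split only when it increases Q. Communities of ≥3 nodes are
reported as modules by default. Pathway enrichment is the upper-tail
hypergeometric test over pathways with ≥7 genes after intersection with
the universe, BH-corrected.

## The synthetic study world

One latent 4-vector per gene (mRNA, RP, PP, PSS) is drawn from a
multivariate normal whose correlation realizes the target *Spearman*
matrix through ρ_P = 2·sin(π·ρ_S/6). Default targets:
ρ(PSS,RP) = 0.70, ρ(PSS,PP) = 0.68, ρ(PSS,mRNA) = 0.61,
ρ(RP,PP) = 0.63, ρ(mRNA,RP) = 0.74, ρ(mRNA,PP) = 0.58. The four
marginals involving PSS and RP/PP are observed study-scale values; the
two mRNA cross-terms were set so that the implied conditional structure
simultaneously reproduces the observed partial correlations
(PSS with RP or PP given mRNA ≈ 0.45–0.52; RP with PP given
mRNA ≈ 0.37) and a small positive partial correlation (≈0.11) of mRNA
with PSS given RP and PP — the value implied by the observed ≈+0.003
gain from adding mRNA to the steady-state regression. The full set of
printed marginal and partial correlations is not jointly realizable by
any single Gaussian copula; this reconciliation favors the regression
behavior, which is what the qualitative reproduction tests check.

Counts: per phase and replicate, NB with mean 2^(6 + 2·Z) (median ≈64,
spread two orders of magnitude), dispersion 10 (variance = μ + μ²/10,
moderate bulk-RNA-seq overdispersion), ±15 % log-normal depth jitter
per replicate, 4 replicates. Intensities: log2 scale 24 + 1.5·Z plus
N(0, 0.5) replicate noise, 3 replicates per phase, detection
probability logistic in intensity with midpoint 20.5 and scale 1 —
abundance-dependent drop-out, the characteristic MS missingness
mechanism. The non-specific control arm is sparse low background
(detected 25 % of the time around 18.5). DE genes (10 % of genes)
receive a ±3 log2 shift in M, applied to RP counts and PP intensities
(post-transcriptional regulation: mRNA and PSS are unshifted); PP
shifts share the RP sign by default. Footprint coverage is a logistic
function of RP abundance plus noise, reflecting that coverage tracks
expression.

What the generator does *not* emulate: peptide-level identification,
shared-peptide protein inference, sequence-composition biases of RNase
or MS detection, length biases, batch structure, and correlated
replicate noise. A green recovery test therefore establishes that the
statistical machinery is correct and calibrated on data with the
stated correlation/noise structure — not that the pipeline is robust to
protocol-specific biases absent from that structure.

Planted-recovery accounting: MS drop-out deletes roughly a third of
planted DE proteins from the PP-testable universe (a gene shifted 3
log2 units below the detection midpoint simply is not observed), so PP
recall is measured against planted DE genes present in the filtered
universe; RP recall is against all planted genes.

The toy transcriptome plants every assembly edge case (missing 5′UTR,
3 nt UTR, ORF length 1 and 2 mod 3, missing stop codon) and
near-identical paralog pairs (≤2 mismatches) to exercise multi-read
resolution. Reads are insert (24–35 nt) + adapter + random padding to
51 nt with 0.1 % substitution noise; 10 bundled decoy rRNA/tRNA-like
sequences (regenerated from a fixed seed) serve as the contaminant
database. PPI graphs draw degrees from a discrete power law on
[3, 3√n] (minimum degree 3 keeps the graph and its rewirings connected,
emulating the dense main component of a real PPI network, where mean
degree is an order of magnitude above the connectivity threshold);
planted modules get a connecting path plus internal edges at
density 0.3.

## Numerical conventions

Coordinates 0-based half-open; the annotation TSV stores component
lengths. Spearman requires ≥3 complete pairs; constant vectors raise
rather than return NaN. The log-binned degree-slope estimator weights
bins by √count so near-empty tail bins do not dominate the fit.
Empirical p-values are never 0 by construction. All generators and
analyses accept explicit seeds; equal seeds give bit-identical output.

## Known limitations

The NB test's variance-function details follow the cited method's
published defaults rather than any particular tool version; calibration
properties (type-I error in [0.03, 0.07] at α = 0.05 under the matched
null), not value-matching against another implementation, are the
contract. The exact test is mildly conservative (≈0.04 observed). The
leading-eigenvector clustering implements plain recursive bisection
without Kernighan–Lin refinement. The aligner is exact for the
substitution-only, ≤2-seed-mismatch model but is a desk-scale
implementation, not a replacement for a production aligner.
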