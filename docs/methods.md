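# Methods

This note documents the statistical models behind `zeascan`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Estimators

**Nucleotide diversity.** π is the mean per-site pairwise difference count
over all C(n,2) haplotype pairs, divided by the effective length L_eff after
*complete deletion* (every column carrying `-` or `N` in the analyzed sample
set is dropped before any statistic; L_eff is reported alongside). Pairwise
differences count all mismatches, including at tri-allelic columns. Two
standard errors are offered: the default `total` variance
sqrt(b₁π/L + b₂π²) with b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1))
(evolutionary + sampling variance, no-recombination case), and a
`sampling`-only option that keeps just the π-linear term. Published
per-locus SEs rarely state which formula produced them, so neither option is
labelled canonical.

**Watterson's θ_W** is S/(a₁·L_eff) with a₁ = Σ_{i<n} 1/i, where S counts
segregating columns.

**π_a/π_s and d_N/d_S** share one Nei–Gojobori codon engine. Each codon
contributes fractional synonymous site counts (each position contributes the
fraction of its three possible changes that are synonymous; changes to stop
codons count as nonsynonymous), and observed codon differences are
apportioned by averaging over all orderings of the differing positions,
excluding orderings that pass through a stop codon (all orderings are used
if every one is blocked). Codons containing `-`/`N`, or that are stops, in
either sequence are skipped. Within-species π_a/π_s is reported without
distance correction by default (within-species p is small; Jukes–Cantor is
available by flag); between-taxon d_N and d_S apply Jukes–Cantor
d = −(3/4)ln(1 − 4p/3), flagged as an error when p ≥ 3/4. d_N/d_S against
the outgroup computes each ingroup haplotype against the outgroup and
averages d_N and d_S *before* forming the ratio (whether published tables
used a consensus is typically unstated; a consensus mode is provided). The
ratio is flagged NA when the denominator diversity is zero — monomorphic or
all-nonsynonymous loci genuinely have no defined ratio.

**Neutrality tests.** Tajima's D = (π̂ − S/a₁)/sqrt(e₁S + e₂S(S−1)) uses
unpolarized data (π̂ here is the mean pairwise difference *count*, not per
site). Fu & Li's D and F use the outgroup ("original") forms, not the
starred within-sample variants, because the target analysis style polarizes
against an explicit outgroup: η is the total mutation count and η_e the
number of derived singletons; D = (η − a₁η_e)/sqrt(u_D η + v_D η²) and
F = (π̂ − η_e)/sqrt(u_F η + v_F η²). The u/v constants follow the corrected
formulas of Simonsen, Churchill & Aquadro (1995); an independent
transcription of those formulas is kept in the test suite, and the neutral
simulation check (|mean| ≤ 0.15 over 10,000 constant-size replicates at
n = 25, θ = 5) guards against transcription slips. S = 0 (or η = 0) makes
all three statistics undefined; they propagate as `NA` strings in output
tables rather than crashing or being silently dropped.

**Polarization.** Bi-allelic ingroup columns where the single designated
outgroup carries one of the two alleles become matrix sites with the
outgroup allele ancestral. Columns with a third outgroup allele
(unpolarizable) or with ≥ 3 ingroup alleles (infinite-sites polarization
undefined) are excluded from η and η_e — the conservative choice — and
reported in a diagnostics record satisfying the conservation identity
polarized + unpolarizable + monomorphic + multiallelic = analyzed columns.
On infinite-sites data η = S; on real alignments multi-allelic columns can
make the two differ, and the distinction is surfaced rather than hidden.

**F_ST.** Hudson–Slatkin–Maddison 1 − H_w/H_b, with H_b the mean pairwise
difference count over all between-population pairs and H_w the unweighted
mean of the two within-population means taken over *ordered pairs with
replacement* (denominator n², self-pairs contributing zero — the
frequency-weighted convention). This makes the two boundary cases exact:
populations with identical haplotype contents score 0 and fixed-difference
populations score 1. The cost is a (n−1)/n down-weighting of within
diversity, so under vanishing split time the estimator converges to ≈ 1/n
rather than 0; with the deme sizes this package targets (14–17) that offset
is below 0.08. Negative estimates near zero differentiation are reported as
computed, not clipped. Weir–Cockerham and hierarchical F-statistics are out
of scope.

**Relative-rate test.** For lineages A, B and outgroup O on
complete-deletion columns: m_A counts sites where A is the odd one out
(A ≠ B, B = O), m_B symmetrically; (m_A−m_B)²/(m_A+m_B) is referred to χ²
with df = 1. m_A + m_B = 0 yields NA.

**K scale factor.** Branches of two trees on the same leaf set are matched
by leaf bipartition after derooting; K = Σ(l_ref·l_comp)/Σ(l_comp²) is the
least-squares minimizer of Σ(l_ref − K·l_comp)². Values below 1 mean the
comparison tree is larger (faster-diverging) than the reference. Topology
mismatches are an error that lists the unmatched bipartitions; only the
scale factor of the full Ktreedist output is implemented, restricted to
identical topologies.

## Coalescent null model

The significance engine is a hand-written Kingman coalescent in Hudson's ms
conventions: time in units of 4N₀ generations, sizes relative to N₀,
θ = 4N₀μ per locus. k lineages coalesce at rate k(k−1)/x(t) under a
piecewise-constant x(t); mutations are Poisson(θ × total branch length),
placed uniformly on branches at positions uniform on (0,1) (infinite
sites), with a fixed-S conditioning mode as an option. These conventions
give the textbook identities E[T₂] = 1/2, E[S] = θa₁, E[π̂] = θ and
E[T_MRCA] = 1 − 1/n, which the acceptance checks verify to 2% at 50,000
replicates; the distribution of S is additionally cross-validated against
msprime (KS test) under both constant-size and bottleneck histories.
Intra-locus recombination is deliberately absent (matching the conservative
assumption of the analysis style this reproduces), as are migration and
selection.

A bottleneck is parameterized by onset t_d, duration t_b, relative size x_b
and ancestral size x_a, with severity k = x_b/t_b reported as derived
metadata. The classic maize-domestication severity is k = 2.45; the default
illustrative instantiation (t_d = 0.01, t_b = 0.0204, x_b = 0.05) realizes
that severity, but absolute onset/duration calibrations are
population-specific and must be supplied for real analyses. Gene-specific
published percentiles are therefore not exactly reproducible without the
original per-locus θ and bottleneck calibration; the machinery, not any
specific percentile, is the tested artifact.

Null distributions drop replicates with S = 0 (the statistics are undefined
there), record the NA count, and are fully reproducible: the run seed
deterministically spawns one substream per replicate, so replicates can be
parallelized without changing results, and the pipeline logs each
per-(gene, subset) null seed (derived stably from run seed, gene name and
subset name) so any percentile is replayable in isolation.

**Percentiles and critical values.** Percentile placement uses the mid-rank
rule 100·(#below + ½·#equal)/size — ties take the middle rank; the choice
is stated because published analyses rarely define tie handling. Empirical
critical values are the α/2 and 1−α/2 quantiles with linear interpolation,
requiring ≥ 40 values; α = 1 degenerates to (min, max) with a warning.
Calls at ≤ 2.5 / ≥ 97.5 are labelled significant (two-tailed P < 0.05),
≤ 5 / ≥ 95 marginal (P < 0.10). The genome-wide empirical comparison is a
separate, optional channel: a file of one statistic value per line (e.g. a
survey of several hundred random loci), against which the pipeline places
Tajima's D — optionally recomputed on a configured sample subset matching
the survey's panel.

## Synthetic data generator

Each gene is a structured-coalescent draw for four populations — two
ingroup demes (temperate/tropical analog, default 14 + 17 haplotypes), a
sister subspecies (wild-progenitor analog, default 9) and one outgroup —
joined by clean backwards merges (deme split, default 0.007; sister join at
the end of the bottleneck, 0.0304; outgroup join at 0.5, all in 4N₀ units).
There is no migration: the clean split is the simplest mechanism producing
tunable F_ST, and at the default split time it yields F_ST around
0.03–0.08, in the range expected for temperate vs tropical germplasm. The
default ingroup demography is the illustrative k = 2.45 bottleneck; the
default θ/site of 0.0065 is chosen as a realistic wild-progenitor value so
that *post-bottleneck* ingroup diversity centers near π ≈ 0.003/site, with
the observed-in-practice band 0.001–0.007 covering most genes under a
constant-size history. Under the bottleneck, per-gene π is markedly
overdispersed (single non-recombining genealogies through a bottleneck);
that is a property of the model, not a bug, and it is why the
parameter-recovery checks run on the constant-size neutral configuration.

Rendering maps each infinite-sites mutation to a distinct alignment column
of a random ancestral sequence (coding frame free of stop codons). Columns
are drawn uniformly, but mutations landing in coding sequence are steered
to third codon positions with probability p_syn = 0.7 and given a
synonymous derived base when one exists, which produces realistic
π_a/π_s ≪ 1 without a codon substitution model. Extra private mutations on
the outgroup branch (rate 0.5·θ by default) guarantee outgroup divergence;
because every mutation occupies its own column, every ingroup-segregating
site is polarizable by construction. A truth table records θ, demography,
distortion and realized S per region class, satisfying the conservation
identity S_five_prime + S_coding + S_intron = S_total.

Site-frequency distortions emulate selection signatures by explicit
resampling rather than forward simulation: `sweep_like` turns a fraction
`strength` of eligible sites into derived singletons (excess rare variants,
D < 0), `balancing_like` sets them to derived count ⌊n/2⌋ (excess
intermediate frequencies, D > 0), preserving site count and positions and,
when restricted to the ingroup rows, leaving sister/outgroup states
untouched. This is auditable and exactly controllable, at the cost of not
modeling linkage around a sweep or the time-depth structure of balanced
polymorphisms.

What passing tests on these data do *not* show about real data: no indels
or alignment error (complete deletion is exercised only by constructed
fixtures), no intra-locus recombination, no sequencing error, no codon
usage or CpG effects, and selection only in caricature. The generator
validates the pipeline's bookkeeping and statistical machinery, not any
biological claim.

## Problem sizes and numerical choices

The shipped checks use sizes chosen to keep the full suite comfortably
reproducible on a single CPU: 50,000 replicates for the analytic coalescent
identities (2% tolerance), 10,000 for neutral centering (|mean| ≤ 0.15,
which comfortably contains the well-known small negative bias of D-type
statistics at moderate θ), 10,000-replicate nulls for the spiked-gene
detection checks (100 genes per distortion mode; genes share one length and
θ so a single matched null serves all trials), and 200 genes for Watterson
recovery (5% tolerance on the panel mean; the per-seed spread of that mean
is about 4%, dominated by the heavy-tailed per-gene S distribution under no
recombination). The acceptance script reports the same quantities at
slightly reduced sizes. Percentile calls warn below 1,000 replicates.

Degenerate inputs are handled explicitly rather than defensively:
monomorphic loci yield NA statistics and NA table rows; empty distributions,
all-NA null runs ("theta too small"), populations with fewer than two
haplotypes, zero shared codons, and topology mismatches raise errors with
specific messages. Coordinates are 0-based half-open throughout
(BED-compatible), forward strand only; reverse-strand genes must be
pre-oriented. The per-locus θ fed to the null is, by default, Watterson's
estimate from the sister (wild-progenitor) sample scaled to the analyzed
length — the progenitor carries the pre-bottleneck diversity the null's
ancestral population represents — falling back to the analyzed subset when
no sister sample exists, and overridable per gene.

## Known limitations

- Fu & Li tests use exactly one outgroup sequence; multiple-outgroup
  consensus polarization is not implemented (the outgroup is configurable
  per locus).
- The coalescent engine targets small panels (n of tens); it is a
  per-replicate event loop, not a vectorized or tree-sequence
  implementation, and large-n or high-θ use will be slow.
- d_S saturates (Jukes–Cantor undefined at p ≥ 3/4) for distant outgroups;
  the error is explicit rather than silently truncated.
- The empirical-distribution channel covers Tajima's D only, since
  genome-wide outgroup-polarized surveys are rarely available.
- K-score comparison requires identical topologies by design; trees that
  differ topologically need to be pruned to a shared backbone first.
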