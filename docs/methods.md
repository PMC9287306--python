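# Methods

## Stability model

The predictor maps a coding sequence to a score in arbitrary decay-rate
units via

    s = β₀ + Σ_c w_c · f_c

where `f_c` is the proportion of codon `c` among the sequence's codons
(terminal stop excluded — stop codons admit no synonymous choice and are
never mutated) and `w_c` is a per-codon stabilization weight in the style
of codon stabilization scores: positive weights mark codons enriched in
stable transcripts. The score is a convex combination of weights plus an
intercept, so it is invariant to codon order, bounded by the extreme
weights, and strictly increased by swapping any codon for a
higher-weight synonym.

A linear composition model is a deliberate design choice: it is the
minimal deterministic composition→score map the evolutionary search
needs (fast, order-free, monotone in single substitutions), and it keeps
the predictor pluggable — any 61-weight table plus intercept defines a
species. The shipped species tables are synthetic stand-ins (seeded
uniform draws on ±1.5, intercept 0, one table per species name, labelled
`*_synthetic.tsv`); they give the model realistic spread and distinct
per-species behaviour but are not fitted regression coefficients, and
numeric parity with any published predictor is not claimed unless the
user supplies published weights.

## Mutation sampling

For each amino acid, its codons are ranked by weight ascending (ties
share averaged ranks, which keeps the distribution deterministic), and
the sampling probabilities are `softmax(ranks)` for optimization or
`softmax(reversed ranks)` for deoptimization, at temperature 1. Ranking
within the family rather than across all 61 codons makes every family's
most stabilizing codon its most probable draw regardless of the family's
absolute weight range. When a mutation is drawn at a position, the
current codon is excluded and the remaining probabilities renormalized,
so a drawn position always changes.

## Evolutionary search

Parameters (units: `t` in score units, `p` a proportion, others counts):

| parameter | default | meaning |
|---|---|---|
| `t` | 1.0 | early-stop threshold; deoptimization stops below −t (symmetric by construction) |
| `N` | 10 | daughters per iteration |
| `p` | 0.05 | proportion of eligible positions mutated per daughter |
| `m` | 10 | maximum iterations |

Eligible positions are the interior codon indices (the first and last
codons are fixed) whose amino acid has ≥ 2 codons. Each daughter mutates
`k = max(1, round(p·E))` positions drawn uniformly without replacement
from the `E` eligible ones; the floor of 1 guarantees progress on short
sequences. Selection is elitist over `{parent} ∪ daughters`, which makes
the path score provably monotone and prevents regression; the recorded
path is the per-iteration parent, starting with the input. A sequence
already past the threshold returns a single-step path.

Target-seeking (`optimize_to_target`) replaces `t` by the target, runs
in the direction of the target from the current prediction, and returns
the path point closest to the target — always a sequence, flagged when
the residual gap exceeds the tolerance. The nine-variants-per-direction
design output is derived from the evolution path with duplicates
collapsed and ordered by predicted stability.

All randomness in a call flows through one seeded generator consumed in
a fixed order (daughter by daughter: positions, then one codon draw per
position), so identical inputs are byte-for-byte reproducible.

## Library design

Defaults: 10 base proteins of 100 residues sampled i.i.d. from an
average vertebrate proteome amino-acid usage table (a documented
approximation, configurable), expanded to 100 proteins by 10 uniform
random permutations each (an identity shuffle is re-drawn once), reverse
translated with uniform synonymous codons plus a TAA stop, then evolved
toward five stability targets (−0.99, −0.16, 0.08, 0.31, 0.77) in two
independent runs each: exactly 1000 variants over 100 proteins. No start
methionine is forced on sampled proteins — in the reporter construct the
cloning context supplies the fixed translation-initiation codons.
Unreachable targets return the closest achieved sequence, keeping the
variant count deterministic; under the default optimizer budget the
extreme targets are typically approached rather than hit, while the
achieved scores remain monotone in the targets within each protein.

## Reporter amplicon geometry

A designed variant's amplicon variable region is its coding sequence
minus the first codon and the terminal stop: the 5′ constant region
(`ATGGTGAGCAAGGGCGAGGAGCTGTCCCTCGAG`, eleven fixed codons ending in the
XhoI site) supplies the true start, and the 3′ constant region
(`TCTAGATAG`, XbaI site plus in-frame TAG) supplies the stop. A 100-residue
protein therefore yields a 3·(100−1) = 297-nt variable region, the
pipeline's default expected length; both the length and the constant
regions are configurable.

## Read classification and quantification

Trimming requires both constant motifs exactly (first occurrence of the
5′ motif, last occurrence of the 3′ motif downstream); reads missing
either are discarded. A trimmed region at the expected length matching a
designed region exactly is perfect. Anything else — wrong length or
unmatched — has the constant regions re-attached and its ORF parsed from
the first ATG in consecutive triplets to the first stop; distinct ORFs
become imperfect reporters. Exact string counting replaces alignment:
designed regions are unique random strings, so exact matching is
equivalent for unambiguous reads, and upstream read merging is assumed
done. Reads are assumed oriented (amplicon sequencing); no
reverse-complement search by default.

TPM is count / sample-total × 10⁶ with perfect and imperfect reporters
sharing the denominator and no length normalization (near-equal-length
amplicons). Detection filters: perfect reporters need a nonzero count in
every (timepoint × replicate) sample; imperfect reporters need ≥ 20
reads in every sample where they appear at all and detection in ≥ 2 of 3
replicates at every timepoint (≥ 6 points in the default 3×3 design),
plus a post-filter keeping only ORFs longer than 70 codons.

## Decay fitting

First-order decay: ordinary least squares of natural-log TPM against
time in hours, replicates pooled as independent points; the slope is the
decay rate, so higher (less negative) = more stable. The log base only
rescales slopes; sign and ordering, the downstream uses, are
base-invariant.

## Tool-comparison bootstrap

Only proteins with fitted variants from every compared tool are
eligible. Per repetition (default 300), one variant per (protein, tool)
is drawn uniformly; the focal tool scores 1 for a protein only when its
variant's decay rate strictly exceeds every counterpart's — ties score
0, biasing the probability conservatively downward — and the
per-protein scores are averaged. The mean of the repetition averages
estimates the probability the focal tool designed the most stable
variant.

## Synthetic data: what it emulates and what it does not

The simulator drives per-reporter abundance as `N₀·e^{r t}` and draws
each sample's counts as one multinomial at fixed depth — matching fixed
sequencing depth and keeping TPM denominators exact (a deliberate choice
over independent Poisson counts). Reads are the exact amplicon string
with optional per-read substitution/insertion/deletion corruption to
populate the imperfect set. It does not model sequencing quality scores,
PCR duplicates or amplification bias, reverse-transcription errors, or
biological deadenylation dynamics, so passing recovery tests demonstrates
the pipeline's estimator is correct under its own model, not that real
libraries are free of those artifacts.

Because TPM is a fixed-sum composition, every reporter's log-TPM
trajectory contains a common term, −log(library total abundance), whose
least-squares slope over the timepoints shifts all fitted slopes
equally. The simulator's reported ground truth is therefore the relative
decay rate — input rate minus that common slope (exact, since OLS is
linear in the response) — which is the quantity a compositional read-out
can measure; the raw input rates are returned alongside. Recovery under
the default conditions (100 reporters, rates uniform in [−0.6, 0.1] h⁻¹,
depth 10⁵ per sample, 2/5/8 h × 3 replicates, error-free) gives Pearson
r > 0.99 and essentially all slopes within ±0.05 h⁻¹ of truth.

## Numerical and degenerate-input choices

- Validation reports every applicable warning, not the first; U is
  accepted on input and mapped to T; a missing terminal stop is a
  warning, not an error, in the CLI (matching permissive interactive
  behaviour), while frameshifts and internal stops are hard errors.
- A weight table whose synonymous family has all-equal weights degrades
  sampling to uniform for that family; this is warned about, not
  rejected, and with an all-flat table the path score stays constant.
- Sequences with no mutable position (e.g. Met/Trp-only interiors)
  return daughters identical to the input with a warning, and variant
  design returns empty lists.
- Pigment absorbance uses base-10: A = −log₁₀(T) with
  T = (eye − dark)/(light − dark); T > 1 clips to 1 with a warning,
  T ≤ 0 is an error.
- Difference counts warn (not error) on non-synonymous same-length
  pairs; unequal lengths are errors.

## Known limitations

- The linear predictor ignores positional effects, k-mers, GC content,
  and RNA structure; it is a composition model by construction.
- The optimizer is single-objective; it does not avoid restriction
  sites, homopolymers, or structured regions.
- Exact-match classification has no mismatch tolerance by default; a
  single sequencing error moves a read to the imperfect set, which is
  faithful to the analysis contract but conservative for perfect-set
  abundance at high error rates.
- Built-in weight tables are synthetic; scientific conclusions about a
  real transcriptome require user-supplied fitted coefficients.
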