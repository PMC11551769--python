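# Methods

## The measurement model

An MPBA experiment compares the abundance of each library variant
before and after activating a TF–MNase fusion. A variant bound by the
TF in a fraction *f* of cells, with cleavage completing in a bound cell
with probability *e(t)* by activation time *t*, survives with
probability 1 − *f·e(t)*. Because PCR amplification and sequencing see
only the survivors, the log₂ change of a variant relative to its
pre-activation (time 0) abundance, after depth normalization, is

    Δ = log2(1 − f·e)  + (sample-wide scaling terms).

The sample-wide terms cancel when Δ is referenced to the fully mutated
variant of the same library, which carries no motifs and is treated as
unbound (*f* = 0). This gives the occupancy estimator

    occupancy = 1 − 2^(Δ_variant − Δ_fm)  =  f·e,

a *lower bound* on the bound fraction *f*, exact only when cleavage is
complete (*e* = 1). The estimator is total: a variant less depleted
than the reference yields a negative value. Negative occupancies are
reported as-is by default (a `clip` flag exists) because silently
truncating them would bias the interaction statistics, whose null
distribution is symmetric around zero.

## Normalization chain

Order of operations, chosen to match the assay's replicate structure:
counts × 10⁶ / assigned total per sample; technical replicates averaged
**on the per-million scale**; log2(x + pseudocount); activated sample
minus its paired time-0 sample *within the same biological replicate*;
biological replicates averaged in log space, with the SEM recorded
across them. The per-million denominator excludes the spiked control
sequence; any global scaling cancels in the fully-mutated reference.
The pseudocount (default 1 per-million unit) only matters for
zero-count cells; a zero-count fully-mutated reference raises a loud
warning because every occupancy in that library then leans on it.
Row and replicate order never affect results: groups are processed in
sorted order, so outputs are bit-identical under input permutation.

## Cooperativity, recruitment, self-motif occupancy

For a motif pair (A, B) inside an *n*-motif library, every assignment
of the other *n* − 2 motifs is a *context*. Within a context, the four
variants varying only A and B are compared against the both-mutated
one: the two single-motif occupancies give the independence expectation
1 − (1 − Occ_A)(1 − Occ_B), and the score is the unweighted mean over
all 2ⁿ⁻² contexts of observed minus expected joint occupancy (SEM over
contexts; a depth-weighted variant was considered and rejected as the
default because unweighted averaging matches the definition of the
score and keeps contexts exchangeable). Within a context each key set
is a single sequence; for recruitment and self-motif contrasts, where
the remaining motifs are free, Δ values are averaged in log space
before conversion — the geometric-mean form makes an independent third
motif cancel exactly (verified in the tests against the closed form
1 − Π(1 − pᵢ)).

Motif pair distance follows the gap convention: distance 0 means the
second motif starts one base pair after the end of the first. Pairs
with |score| above 0.1 are marked in reports (configurable); TF pairs
with Pearson *r* > 0.4 across shared variants are flagged as having
similar motif effects.

When a noise-driven marginal is negative the expectation is no longer
an upper bound for the marginals; such contexts are retained but
flagged (`negative_marginal`) rather than dropped, preserving the
symmetry of the null.

## Library design rules

The variable position of a motif is the PWM column with the highest
information content IC = 2 + Σ p·log₂p, ties broken by proximity to the
motif midpoint, then leftmost. The default mutant base is the lowest-
probability non-wild-type base of that column, ties preferring a
transversion, then alphabetical order; an explicit per-site override is
always honored, since real designs choose mutations with bespoke
knowledge. Variant keys are bit strings over sites in 5′→3′ order of
their variable positions. Region length is nominally 164 bp but only
warned about, keeping the tool usable for other amplicon sizes.

## Read assignment

Reads are matched per design: the 3′ terminal anchor (last 6 constant
bases) must align exactly at its expected offset, the constant scaffold
tolerates up to 2 mismatches (both configurable), and the bases at the
variable positions spell the variant key; a base matching neither the
wild-type nor the mutant allele makes the read `unassigned`. Indel
detection searches for the anchor at shifted offsets (±1..3): a 1-bp
insertion or deletion anywhere upstream of the anchor shifts it by one
and the read is classified `filtered_indel`. A prefix-mismatch rule was
rejected because an early indel corrupts most of the downstream
scaffold comparison and would be indistinguishable from junk. The four
categories (assigned, control, unassigned, filtered_indel) always
partition the stream. QC drops samples below a read-depth floor
(default 50 000 assigned) or whose log-count correlation with every
sibling technical replicate falls below 0.7; both thresholds are
conservative defaults, reported with reasons.

## Nucleosome rescaling

The genomic anchor is the 99th percentile (linear interpolation) of
164-bp window sums of MNase-seq signal over promoters at 10-bp steps; a
library's genomic occupancy is its region sum over the anchor, capped
at 1. For per-variant nucleosome occupancy the default contract is
fold-change × anchor: 2^Δ_vs_wt × genomic occupancy, so a variant
behaving like wild type gets exactly the genomic value. The literal
exponent placement 0.5^(Δ × occupancy) is dimensionally incoherent at
the boundary (a zero-occupancy anchor would force every variant to 1)
but is available behind `literal=True` for comparison.

## k-mer enrichment

All 4⁷ 7-mers collapse into 8192 strand-invariant classes (index = the
smaller of the two base-4 encodings; odd k has no palindromes). Each
promoter occurrence is scored by the mean signal over a 20-bp window on
the k-mer's central base (10 bases left through 9 right; the edge
convention of a "20 bp window" on an odd-length k-mer is not uniquely
determined, so one symmetric reading was fixed); occurrences whose window leaves the track
are skipped and logged. A pattern's enrichment is the mean score of
matching classes over the mean of all *observed* classes (classes never
seen in promoters carry no score and are excluded from the
denominator). Patterns accept IUPAC codes and bracket groups
(`GAATG[CT]`), and matching checks both strands of a class
representative, since indices are strand-collapsed.

## The simulator

The generator emulates the deposited experiment structure: per-variant
pre-activation abundances from a symmetric Dirichlet (concentration 5
per variant — moderate oligo-synthesis and cloning skew), cleavage
survival 1 − bf·e(t) with the bound fraction bf = 1 − Π(1 − pᵢ) over
intact sites plus additive pairwise terms c_ij (clamped to [0, 1] with
a clamp count in the ground-truth record), a never-cleaved control
spiked at 1%, and gamma-multinomial counts (gamma shape 50, i.e. ~14%
PCR-jackpot CV — pure multinomial noise understates replicate scatter)
at depth 10⁶ per sample, 3 biological × 2 technical replicates.
Interactions are injected *additively on the bound fraction* so that at
n = 2 the ground-truth c equals the cooperativity score by
construction; with a third intact site the reference survival rescales
the contrast and the per-context score becomes c/(1 − bf_ctx·e), which
is why the signal-recovery check uses a two-motif library. An
odds-scale injection is not provided; robustness to model mismatch can
be probed by scoring contexts of larger libraries instead.

What the simulator does **not** model: plasmid copy-number variation,
growth bottlenecks, nucleosome positioning on the plasmid,
base-quality-dependent sequencing error, or time-dependent binding
kinetics (cleavage efficiency per timepoint is a free parameter, not a
kinetic model). Passing parameter-recovery tests therefore shows the
estimator chain is unbiased under the stated noise model, not that
every bias of the real assay is corrected.

## Problem sizes and numerical choices

Recovery checks run at sequencing depth 10⁶ with libraries of 1–3
motifs: 200 seeded experiments for the null cooperativity check
(|mean| < 0.01), 20 for the injected c = 0.2 (±0.05), 10 for the
occupancy-consistency check (±0.02) — sizes at which the Monte-Carlo
standard error sits several-fold below each tolerance. Exhaustive
checks (2ⁿ enumeration, 1-bp indels, the 16384-7-mer class census) are
complete, not sampled. PWM columns must sum to 1 within 1e-9; PWMs of
unequal length are compared by sliding the shorter over the longer and
taking the minimum distance (uniform-column padding was rejected: it
inflates distances between otherwise identical cores). z-scores for
per-promoter TF counts use the population standard deviation with a
strict > threshold, and zero-variance columns are excluded with a
warning. All coordinates are 0-based, half-open.
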