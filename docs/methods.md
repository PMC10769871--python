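# Methods

This note documents the models, the defaults and why they hold, what the
synthetic data does and does not emulate, and the numerical choices.

## Fluorescence assay calls

A strain's reduction activity is summarised as the ratio of its mean
replicate fluorescence to the mean of an abiotic medium control; the call
is strictly `ratio > 5` (a ratio of exactly 5 is a non-reducer). Means are
used because the bar-plot summary of such assays is a mean; a median
variant is available (`center="median"`). Supporting statistics are
two-sample t-tests on log2-transformed raw fluorescence (not on ratios):
the log transform stabilises the multiplicative error of plate-reader
signals. The Welch (unequal-variance) form is the default since replicate
variances of strains and abiotic controls have no reason to be equal;
pooled-variance is available via `equal_var=True`. When both groups are
exactly constant the t ratio is degenerate; identical means then report
(t=0, one-sided p=0.5) and unequal means report an infinite statistic,
matching the limit behaviour.

## Comparative screen

Orthogroups are built as connected components of reciprocal-best-hit (RBH)
pairs: protein x's hit in strain T is the best-scoring protein of T by
Smith–Waterman local alignment (BLOSUM62; affine gaps costing
`gap_open + L*gap_extend` with defaults 11/1, i.e. standard protein-search
parameters) subject to `score >= 0.3 * self_score(x)`; ties break by
lexicographic protein id for determinism. This is a transparent stand-in
with the output contract of a dedicated orthology tool — a partition of
the protein universe with per-strain presence vectors — not a
reimplementation of any published clusterer. An exact 5-mer pre-screen
skips alignment of pairs sharing no peptide word; at the identity levels
where RBH edges are possible this cannot remove a true edge's score above
threshold in practice, and it can be disabled (`prefilter_k=None`).

The oxidoreductase filter keeps groups with at least three members whose
EC label has first field "1" (oxidoreductases). The alternative, stricter
reading — every member class-1 annotated and more than two members — is
behind `all_members=True`; the default reading is the natural one for a
count-based subset rule. Malformed EC strings warn and count as
unannotated.

The phenotype screen's strict mode demands presence in every reducer and
absence from every non-reducer; scored mode ranks groups by Hamming
distance between presence and phenotype vectors (distance 0 is the strict
match). The two filters act on disjoint criteria and commute; reported
candidates pass both.

## Profile HMM

The profile is Plan-7-like: per-match-column emissions over the 20
canonical residues with +1 Dirichlet smoothing (a column observing {A:4,
C:1} emits A with probability 5/25), insert emissions equal to the
background, and M/I/D transitions estimated from the per-sequence state
paths of the alignment with the same smoothing. Columns are first
restricted to those where the chosen reference sequence has a residue
inside the requested residue span (e.g. the first 373 residues — the TIM
barrel); restricted columns with more than 50 % gaps are demoted to insert
columns (configurable). The four catalytic-motif positions (HGDR,
His164-Gly165-Asp166-Arg167 in reference coordinates) are mapped to match
columns at build time and must land on match columns.

Search is local Viterbi in bits (log2 odds against the background): free
entry into any match column, free exit after any match column, so
flanking sequence is never penalised — the same "glocal-free" contract a
homology scanner provides. The inner dynamic program accumulates scores
sequentially (emission added after transition); the test suite holds it
exactly equal, in floating point, to brute-force enumeration of all state
paths on small instances. The kernel is numba-compiled when numba is
importable, with an identical pure-Python fallback.

E-values use a Gumbel (type-I extreme-value) null: Viterbi scores of
`n_random` i.i.d. background sequences (default 300 of length 400 in the
pipeline; at least 200 enforced) are fitted by maximum likelihood, and
`E(s) = N * (1 - exp(-exp(-lambda (s - mu))))` with N the database size.
The survival term is computed with `expm1` and saturates to 0 far in the
tail, which is the correct behaviour for the strict `E < 1e-100` cut. The
background is uniform by default (alignment-derived frequencies are an
option); calibration is deterministic for a fixed seed.

Classification applies four independent filters, all audited per target:
E-value strictly below 1e-100 (full-sequence score); target length at
least 50 % of the reference protein length (the reference length is an
explicit profile field — the full ungapped reference protein, not the
profile span — so the rule matches "50 % of the reference BilR protein");
the residues aligned to the four motif match columns spelling exactly
HGDR with no deletions (column-anchored detection rejects spurious HGDR
substrings elsewhere; a regex fallback exists via `motif_mode="regex"`);
and a domain set equal to {PF00724} (short) or {PF07992, PF00724} (long).
Domain annotations are consumed as an input table; a missing annotation
fails the domain filter with reason "unannotated" rather than raising.
Weakening any threshold can only grow the non-none verdict set
(monotonicity, property-tested).

## Metagenome profiling

Host subtraction removes a read when at least half of its k-mers (k = 31)
occur in the strand-collapsed k-mer set of the host reference; the
fraction is over all L−k+1 windows, windows containing ambiguous bases
counting as unshared. Mapping is exact-k-mer seed (k = 21) plus ungapped
extension on the seed diagonal, both reference strands indexed; a read
maps when extension reaches ≥ 90 % identity over the full read, positions
hanging off the reference counting as mismatches, and each read counts at
most once however many references it hits (presence semantics). This is a
deterministic, transparent stand-in for a general-purpose aligner used
purely as a presence counter.

CPM is `mapped / total * 1e6` with the total taken **after** host removal
(the count available at the alignment step); `cpm_denominator="raw"`
switches to the pre-removal total. Presence is strictly `CPM > 5`; the QC
gate is inclusive, `reads >= 1e6` (scaled down via `RunConfig.min_reads`
on desk-scale fixtures). Age bins are half-open `[30i, 30(i+1))` days over
0–365; samples without age metadata are excluded from binning. Cohort
rules: healthy-adult samples with recorded age below 3 years are excluded
(unknown age is retained — there is nothing to exclude on); IBD samples
split into Crohn's disease and ulcerative colitis groups.

The prevalence comparison follows R's `prop.test` exactly: the 2×2
chi-square with 1 df, Yates continuity correction on by default and capped
at `|p1 − p2| / (1/n1 + 1/n2)`, so equal proportions yield statistic 0 and
p = 1 even with correction. The implementation was validated against
frozen outputs of R 4.3.3 and against the closed-form Σ(O−E)²/E oracle.

## Synthetic data: what it emulates, and what it does not

**Pangenome.** Background orthogroups get i.i.d. Bernoulli(p = 0.7)
per-strain presence — a realistic accessory-genome occupancy that makes
the accidental phenotype-match probability per group exactly
p^R (1−p)^N ≈ 4.1e-4 for 5+5 strains. 6 % of background groups carry a
class-1 EC theme (matching the oxidoreductase share such annotation
screens report), 40 % a non-1 EC, the rest none. One planted causal group
tracks phenotype exactly, carries EC 1.6.99.1, and is indel-free so motif
positions stay addressable; background members may carry short indels.
Sequences evolve by i.i.d. substitutions from a random ancestor — no
phylogeny, no selection.

**BilR family.** Clade-1 members share a 373-residue random ancestral core
with HGDR planted at positions 164–167 and 3 % substitutions elsewhere;
long members add a 180-residue N-terminal (flavodoxin-like) segment and a
60-residue tail. Decoys cycle through single-filter violations: mutated
motif, truncation to 45 % of the core (motif retained), an extra PF01266
domain, or an unrelated random sequence (E-value violation). Real protein
families have heterogeneous divergence and genuine domain boundaries;
passing here shows filter logic, not detection power on remote homologs.

**Metagenome.** Reads are 150 bp over ACGT with constant Phred-40
qualities (quality is not used downstream) and i.i.d. substitution errors.
The *bilR*-gene read count per sample is deterministic — max(1,
round(f·N)) when the gene fraction f > 0 — and the host count is
round(host_fraction·N), with the remainder random background; this keeps
the recorded presence truth exact rather than Poisson-fuzzy at the
one-read depths the fixtures use, at the cost of not modelling sampling
noise in the planted counts themselves. Gene references are 3 × 900 nt and
the host reference 5 kb, large enough that chance 21/31-mer collisions are
negligible. No adaptors, no quality-score error model, no real genome
structure.

**Fluorescence.** Lognormal replicates with the requested coefficient of
variation; reducers at fold_change × the control mean.

## Problem sizes and determinism

Fixture-scale runs used throughout: 200-group pangenomes over 100 seeds
for screen recovery; 20-protein families with 300 × 400-residue
calibration nulls; 20-sample metagenomes of 50,000 reads. All generators
and the calibration draw from `numpy.random.default_rng(seed)` and are
byte-reproducible; the clustering, search and classification stages are
deterministic given their inputs (ties broken lexicographically).

## Known limitations

- The RBH clusterer is quadratic in proteome size and meant for
  tens-of-strains, hundreds-of-proteins inputs, not whole pangenomes.
- The Viterbi scanner reports best-path scores, not forward-sum
  probabilities; its E-values calibrate the Viterbi tail specifically.
- The mapper has no gapped extension, so indel-rich reads can fail the
  identity gate; at the fixture error model (substitutions only) this is
  exact.
- Cohort rules assume single-run samples; merging multi-run samples before
  QC is out of scope.
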