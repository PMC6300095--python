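# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Phyletic screen (alien-hit fraction)

For one query protein with homology hits `h_1..h_n`, each hit's taxon is
classified at **superkingdom** rank against the focal clade (default
Bacteria): `alien` if its superkingdom differs and is known, `focal` if it
matches, `excluded` if the taxon is missing from the lineage table or has
no superkingdom rank. The screening statistic is

    f = n_alien / (n_alien + n_focal)

and a query is a candidate when `f >= tau` with `tau = 0.80`, *inclusive*
("at least 80%").

Conventions and the reasoning behind them:

- **Unknown-taxon policy** defaults to exclusion from the denominator:
  counting unknowns as alien would inflate candidates, counting them as
  focal would suppress real signal; both remain available
  (`count_as_alien` / `count_as_focal`) for sensitivity analysis.
- **Self-hit removal**: the query proteome is normally present in the
  searched database, so hits whose taxon id is in a configurable
  `self_taxa` set are removed before anything else; otherwise every query
  carries a guaranteed focal hit.
- **Hit cap**: at most `max_hits = 250` hits per query, best by bitscore,
  so extremely common domains do not swamp the denominator. Configurable;
  `None` disables.
- **`min_hits = 5`**: a fraction computed from fewer than 5 usable hits
  says little; such queries get status `insufficient_hits` and are never
  candidates.

Pairwise percent identity/similarity between two named proteins uses a
Biopython global alignment (BLOSUM62, gap open 10, extend 0.5 — the
common defaults of protein aligners; all configurable, and `local` mode
available). Identity counts identical residue pairs over all alignment
columns; similarity counts pairs with positive substitution score;
coverage is the aligned span over the first sequence's length. Published
identity figures rarely state their alignment parameters, so comparisons
against them should allow a couple of percentage points either way.

## Tree-topology HGT test

The judgement usually made by eye — "the query sits inside the donor
clade with good support" — is formalized as:

1. Root the tree: on an explicit outgroup if given, else midpoint when
   branch lengths exist, else the tree is used as written. Supports are
   treated as **bipartition** properties (looked up by leaf set, from
   either side of the edge), so rooting cannot reattach them wrongly.
2. Find the smallest clade containing the query with at least
   `m_min = 2` non-query leaves.
3. Let `purity` be the fraction of those leaves that are alien. The call
   is `hgt_consistent` iff `purity >= p_min` (default 1.0 — a pure alien
   sister group) **and** the clade's support `>= s_min` (default 0.8);
   `unsupported` when the topology fits but support is below `s_min` or
   absent; otherwise `not_consistent`.

`p_min = 1.0` and `s_min = 0.8` are deliberate formalizations of a
qualitative practice, not published cutoffs; both are exposed, and the
verdict is monotone in them (raising either never upgrades a call).
Support scales are auto-detected per file: values above 1.5 are read as
bootstrap percentages and divided by 100; files mixing scales are
rejected rather than guessed at. Missing supports are recorded as absent,
never as zero.

## Compositional island scan

A deliberate, defined surrogate for interpolated variable-order island
predictors — not a re-implementation of any of them. For one contig:

- Background: conditional probabilities `P(x_k | x_1..x_{k-1})` of each
  k-mer (default `k = 4`), estimated on the whole contig with
  add-pseudocount smoothing (pseudocount 1).
- Windows of `w = 5000` bp at stride `s = 2500` are scored by the mean
  per-k-mer log-likelihood ratio of the window's own model against the
  background. Ambiguity codes invalidate the k-mers touching them.
- Scores are standardized against the track's own mean/SD; windows with
  `z >= z_min = 4.0` are merged (up to `merge_gap = 1` sub-threshold
  window between calls) into regions.

`w` and `s` mirror the 2,500 bp granularity visible in published island
coordinates; `z_min = 4` is conservative for ~40-window tracks, where a
homogeneous genome's max |z| stays below ~3 (the calling threshold is the
main false-positive guard, and is configurable). The merged regions are
pairwise disjoint and re-merging is a no-op.

Interval logic is 1-based inclusive throughout (GFF3 convention); BED is
converted at ingestion. `contained` requires the region to cover the gene
completely; `disjoint` reports the distance between the facing boundaries
(a gene ending at 19,709 with a region starting at 22,500 is 2,791 bp
away). Strand is ignored: composition and containment are
strand-symmetric.

## Domain isoelectric points

Net charge is the standard Henderson–Hasselbalch sum over ionizable
groups (N-terminus, H, K, R positive; C-terminus, C, D, E, Y negative);
`X` residues contribute nothing. `Q(pH)` is monotone non-increasing, so
the pI is the unique root on [0, 14], found by bisection to
`|dpH| <= 1e-4` and reported to two decimals. Sequences lacking a charged
group of one sign have no root; this is reported as an explicit
"undefined pI" error, never as 0 or 7.

Three pKa presets ship: `bjellqvist` (default; includes the published
residue-specific terminal adjustments, and matches Biopython's
independent implementation to < 0.002 pH on interior values),
`ipc_protein`, and `emboss`. Published pI tables rarely name their
constants, and presets can differ by several tenths of a pH unit (over
1 pH on short extreme segments), so `pi_preset_comparison` reports all
presets side by side with the spread; cross-tool comparisons should treat
values within ~0.3 pH as concordant, while *ranking* of segments (e.g.
"this CBD is the most acidic in the table") is stable across presets.

Domain segments are internal fragments, yet the termini are included in
the charge model by default: a single documented convention applied to
every row keeps the table comparable, and the choice is flagged in the
output (`termini_included`) and reversible per call.

## Synthetic data: what it emulates, what it does not

The generator produces the exact dialects the pipeline reads, with truth
files, and is byte-identical per seed.

- **Hit tables**: 1,000 queries by default (950 background, 50 planted),
  20–100 hits each; per-query alien fractions drawn from Beta(1, 19)
  (mean 0.05) for background and Beta(23, 2) (mean 0.92) for planted
  queries — straddling `tau = 0.8` with margin on both sides — and each
  hit alien by an independent Bernoulli draw. Because of those draws, a
  planted query's *realized* fraction can fall below 0.8 (expected
  probability ≈ 0.054 per planted query, beta-binomial arithmetic): the
  screen recovers realized fractions exactly, and recovery rates against
  the planted *labels* inherit that generator noise (long-run sensitivity
  ≈ 0.946 at these settings).
- **Genomes**: order-2 Markov background (each base copies the base 1 or
  2 positions back with probability 0.15/0.10, else i.i.d.) at GC 0.70 —
  actinobacterial composition with short-range autocorrelation, so the
  scanner is not tested against an unrealistically white background — with
  a 5 kb i.i.d. GC-0.30 island and a 750 bp gene inside it (the scale of
  an expansin ORF).
- **Trees**: random bifurcating donor (plant) and recipient (bacterial)
  clades of 8 leaves each, supports ~ Uniform(0.9, 1.0), joined by long
  stems so midpoint rooting is unambiguous; the query is grafted into
  either clade.

Not emulated: sequence evolution down the tree (leaves are labels, not
sequences), compositional amelioration of old islands, codon-bias
confounders, paralogy/incomplete lineage sorting in gene trees, and
database biases of real homology searches. Passing recovery tests
therefore shows the *statistics and bookkeeping* are right under the
stated models — not that the screen's error rates transfer to real
genomes, where surrogate island methods in particular are known to be
noisy.

## Problem sizes and determinism

Validation runs use the sizes above (1,000-query screens, 100 kb genomes,
200 tree replicates, 100 random peptides for the pI oracle); each
completes in seconds. Every stochastic routine takes an explicit seed
(numpy `default_rng`); pipeline outputs are pure functions of inputs,
parameters and seed, and the run report embeds the parameter echo and
SHA-256 checksums of all inputs.

## Known limitations

- Superkingdom is the only classification rank for the alien call;
  within-superkingdom transfers are invisible to this screen.
- The island scanner's z-normalization is per-track: a genome that is
  *mostly* alien would mask its own islands.
- The topology test assumes one query leaf per tree and correct leaf
  labelling; chimeric alignments or contamination upstream will be
  confidently mis-called.
- Identity/similarity percentages depend on alignment parameters that
  published figures usually omit; defaults are documented but not
  guaranteed to match any particular tool.
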