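# Methods

This note documents the models and procedures implemented in `termnorm`,
the assumptions behind them, the parameters that matter, and what the
synthetic test world does and does not establish.

## 1. Data model

A terminology is a flat table of term–code pairs. Each pair carries the
code type (`arbitrary_id` for opaque registry identifiers such as
`HP:0001337`, `lexicalized_symbol` for mnemonic codes such as `TP53`), an
optional namespace (used for the three GO hierarchies), and three
popularity proxies: how often the code, the term, and the pair's curated
annotations occur in a literature corpus. Counts arrive precomputed; the
package never queries a corpus API.

Text is UTF-8, NFC-normalized, and whitespace-trimmed at ingest; case is
preserved in storage and handled only at scoring time. The TSV dialect is
deliberately rigid (tab-separated, no quoting, literal tabs forbidden) so
round trips are bit-exact. When no pair id is supplied, one is derived as
a stable hash of (terminology, term, code), which lets recorded model
responses from different runs be joined.

## 2. Frequency-balanced sampling

Biomedical terminologies are long-tailed (approximately Zipfian), and
model accuracy tracks corpus exposure, so evaluating on a uniform random
sample would over-represent the tail. The sampler:

1. excludes codes with zero corpus count (no measurable evidence of use;
   in real ontologies this is 40–50% of identifiers);
2. ranks the rest by code count, descending, ties broken by code string
   so ranking is reproducible across platforms;
3. partitions ranks into `n_bins` contiguous bins (default 20), head bins
   absorbing any remainder;
4. draws `2 × per_bin` pairs per bin without replacement (default 30 per
   split), orders the draw by rank, and alternates it into train and
   withheld splits, a coin deciding which split leads in each bin.

Step 4 makes the "withheld set matched for popularity" contract
*structural* rather than statistical: both splits receive exactly
`per_bin` pairs from every bin, interleaved along the within-bin
frequency range, so per-bin mean log-popularity differences are bounded
by the draw's spacing rather than by sampling luck. The defaults yield
the standard 600 + 600 design.

For multi-hierarchy terminologies the sampler runs independently within
each namespace with per-namespace quotas (the three-hierarchy design uses
200 per hierarchy = 10 per bin per split), with namespace-tagged child
seeds so adding a namespace never perturbs another's draw. Per-namespace
binning is the default; quotas must be divisible by the bin count.

## 3. Prompt expansion and fine-tuning files

Five fixed forward templates ask for the code given the term; reverse
templates are generated mechanically by swapping the standalone words
"identifier" and "term" and substituting the code into the probe slot.
The mirroring is an involution, and the reverse strings are plain data —
callers can supply their own. For lexicalized-symbol pairs the requested
object word is "gene symbol" instead of "identifier" (the natural phrase
for that task; configurable via `OBJECT_WORDS`). No other prompt
engineering exists, by design.

600 pairs × 5 templates = 3,000 training prompts per terminology per
direction, exported as `{prompt, completion}` JSONL with the bare gold
answer as completion. Gradient-step arithmetic pools examples across
epochs: 3,000 × 20 epochs ÷ batch 32 = 1,875 exactly; a non-divisible
total counts its trailing partial batch as one step and the breakdown is
reported (`TrainingSteps`).

Running the actual LoRA fine-tuning on a hosted API is out of scope; the
package exports the training file and ingests recorded responses.

## 4. Scoring

hits@1 under greedy decoding: one output per instance, exact match after
normalization. Normalization trims whitespace, strips terminal sentence
punctuation, collapses internal whitespace, case-folds terms, upper-cases
registry prefixes and converts `HP_0001250`-style underscores to colon
form. It is deliberately light: `strict` mode (default) compares the
whole normalized output, because published protocols say "exactly
matched"; `lenient` mode first extracts code-shaped candidates (prefixed
`XX:digits` substrings, or all-caps tokens for bare symbols) and fails to
0 unless exactly one distinct candidate exists. Strict correctness
implies lenient correctness. Every report is labeled by mode; accuracies
are kept at full precision internally and rounded to one decimal only at
report time.

Responders are pluggable callables (instance → text). A responder
exception is recorded as an empty output scored 0 and logged, never a
run abort. Adapters exist for recorded-JSONL playback and the synthetic
responder; live-API adapters are intentionally outside the tested
surface.

## 5. Outcome taxonomy and derived metrics

The (B, F) truth table yields four mutually exclusive, exhaustive
categories; conservation (categories partition N per stratum) is asserted
in tests. Derived metrics follow the published definitions: memorization
and generalization are gainer fractions on seen/unseen instances;
degradation is the loser fraction on unseen instances (seen-side losers
are reported separately); derived accuracy on seen terms is
continuing-correct% + gainer% − loser%.

An absent split yields `None` plus a note, never a silent zero. Because
published summaries differ in whether "accuracy" pools both splits, the
summary reports the seen-only identity *and* a pooled fine-tuned
accuracy. `reference_results` stores the published category tables
verbatim; two published accuracy cells (HPO Term→ID 20.2, GO Term→ID
44.4) disagree with the identity applied to their own category rows
(21.2, 43.4) — `check_consistency` flags them and the package does not
force agreement. Transition counts (correct/incorrect before → after,
per split) are exported as JSON for any flow-diagram layer; figure
rendering itself is out of scope.

## 6. Lexicalization Δ

Δᵢ = cos(termᵢ, codeᵢ) − mean_{j≠i} cos(termᵢ, codeⱼ), with the
non-match pool scoped to the same terminology and mapping kind (n − 1
codes). Δ is scale-invariant and lives in [−2, 2]. Group comparisons use
a one-way ANOVA plus Tukey HSD at α = 0.05; all-zero within-group
variance is rejected as degenerate rather than jittered silently. The
2-D view uses PCA on centered data with each component's sign fixed so
its largest-magnitude loading is positive (reproducible plots).

Real-model embedding extraction (final-layer hidden states of an 8B
decoder, mean-pooled to 4,096 dimensions) is a provider-side concern
behind the `string → vector` contract; tests use the synthetic provider
only, so the published F statistic for the real embedding space is
explicitly not reproduced here.

## 7. Popularity statistics

Counts are transformed as log10(count + 1), making zero counts exactly 0
and taming the long tail. Group summaries report raw-count means and SDs
per outcome category (matching the published table format) while the
per-proxy one-way ANOVA across categories runs on the transformed counts,
where the normality assumption is defensible; significance is flagged at
p < 0.01. Pearson correlations among the three transformed proxies are
reported per terminology.

The two-way ANOVA (Terminology × Correctness) runs on one proxy —
defaulting to the code count, the most direct exposure proxy — via OLS
with **Type-II sums of squares** (standard for unbalanced observational
factors when the interaction is not the estimand; empty cells are noted).
When the terminology main effect or the interaction is significant at
α = 0.05, Games–Howell all-pairs comparisons (Welch degrees of freedom,
studentized-range distribution, via pingouin) follow, as they tolerate
the grossly unequal variances and group sizes these data have.

## 8. The synthetic world

The generator's defaults state the simulated experimental conditions;
they were chosen once and are not tuned to test outcomes.

* **Terminology** (default n = 5,000): code count for rank r is
  round(100,000 · r^−s) with s = 1; the bottom 40% of ranks are forced to
  zero count to exercise the zero-evidence exclusion. Terms are unique
  three-word pseudo-clinical phrases; arbitrary codes are zero-padded
  7-digit serials under a prefix (no surface overlap with terms);
  lexicalized symbols are the term's initials (plus digits only when
  needed for uniqueness), guaranteeing surface overlap. Term and
  annotation counts couple to the code count on the log scale
  (coupling 0.7, lognormal noise) so proxy correlations are positive but
  imperfect, as in real tables.
* **Responder**: B ~ Bernoulli(σ(a + b·z)), z = log10(count+1), defaults
  (a, b) = (−1.5, 0.8). After fine-tuning, correct items survive with
  probability 1 − d; incorrect seen items gain with probability
  m(z) = σ(logit(m) + b_mem·(z − z̄)), incorrect unseen items with flat
  probability g. The memorization popularity link (b_mem = 0.8, equal to
  the baseline slope: one popularity mechanism) is what lets the world
  reproduce the observed pattern that gainers are more popular than
  continuing-incorrect items; with b_mem = 0 that pattern provably
  vanishes, since gainers and continuing-incorrects would be equally
  popular subsets of the baseline-incorrect pool. Generalization is
  deliberately *not* popularity-linked (it is driven by lexicalization,
  not exposure), and no forward/reverse asymmetry is planted by default
  (`reverse_p_base_factor` exists for studying it). Wrong answers are
  other codes from the same table — confusable distractors. Analytic
  expectations (mean over pairs of (1−pᵢ)·mᵢ, (1−pᵢ)·g, pᵢ·d) are
  computed from the planted probabilities and serve as the oracle for
  recovery tests at 3 binomial SE.
* **Embeddings** (default d = 64): term vectors isotropic on the unit
  sphere; code vector = normalize(λ·t + √(1−λ²)·ε). λ = 0 ⇒ E[Δ] = 0;
  mean Δ is monotone in λ. Arbitrary-ID codes share a cluster offset so
  they separate from terms in 2-D projection, as opaque identifier
  strings do in real embedding spaces. The real extractor's 4,096
  dimensions are unnecessary here: under this model the dimension only
  sets the noise scale of Δ, and 64 keeps the suite fast.

**What a green test establishes — and does not.** The synthetic world
validates the *harness*: sampling balance, scoring, classification
algebra, statistical engines, and parameter recovery. It does not emulate
token-level generation, fine-tuning dynamics, directional asymmetry, or
real corpus count distributions, so it supports no claim about any real
model's accuracy; the published baseline accuracies and count summaries
require hosted LLMs and corpus data and are explicitly not reproduced.

## 9. Numerical and interface choices

* Percentages are rounded to one decimal only at report time.
* All randomness flows through numpy Generators seeded per stage with
  tagged child seeds (CRC/SHA-derived, < 2³¹), so runs are bit-reproducible
  and adding a stage never shifts earlier draws.
* Degenerate inputs (zero-norm embeddings, zero-variance ANOVA cells,
  rank-0 PCA input, empty splits) raise typed errors naming the offender
  instead of returning defaults.
* The CLI is a thin layer over the library: one subcommand per stage, a
  YAML-configured `run` pipeline writing a checksum manifest, and exit
  codes 0 / 2 / 3 / 1 for success / usage / validation / runtime failure.

## 10. Known limitations

* Lenient-mode extraction is pattern-based; it can misjudge outputs that
  mention several code-shaped strings while clearly intending one.
* The Δ non-match pool is within-terminology; cross-terminology pooling
  would change the statistic's scale.
* Games–Howell p-values come from the studentized-range approximation;
  at very small group sizes (< 5) they are rough.
* The synthetic responder draws one correctness bit per (pair,
  direction): template phrasing does not modulate correctness, which is
  a simplification of real model behaviour.
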