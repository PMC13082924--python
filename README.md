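# termnorm

An evaluation harness for **biomedical term-to-identifier normalization**:
measuring how well large language models map natural-language biomedical
terms to their standardized codes — HPO and GO identifiers (`HP:0001337`,
`GO:0005634`), HGNC gene identifiers (`HGNC:11998`), and lexicalized HGNC
gene symbols (`TP53`) — and how supervised fine-tuning shifts that ability
between three regimes:

* **memorization** — new correct answers on pairs *seen* during fine-tuning,
* **generalization** — new correct answers on *withheld* (unseen) pairs,
* **degradation** — loss of answers that were correct before fine-tuning.

It is written for researchers who run (or simulate) such experiments and
need the surrounding machinery to be reproducible and testable: dataset
construction, prompt expansion, scoring, outcome bookkeeping, and the
embedding and popularity analyses that explain *why* tasks differ.

## The core quantities

Each evaluated instance *i* carries two correctness bits, *Bᵢ* (baseline)
and *Fᵢ* (fine-tuned), under strict hits@1 exact match. The pair (*Bᵢ*,
*Fᵢ*) assigns one of four mutually exclusive categories — *gainer* (0→1),
*loser* (1→0), *continuing correct* (1→1), *continuing incorrect* (0→0) —
and the derived metrics are

```
Memorization(%)   = G_seen   / N_seen   × 100
Generalization(%) = G_unseen / N_unseen × 100
Degradation(%)    = losers on unseen terms, as %
Accuracy          = ContinuingCorrect% + Gainer% − Loser%   (on seen terms)
```

where *G* counts gainers. Two further analyses probe the mechanism:

* **Lexicalization Δ** — for pair *i*, Δᵢ = cos(termᵢ, codeᵢ) −
  mean_{j≠i} cos(termᵢ, codeⱼ) in an embedding space; Δ ≈ 0 means the
  matching code is no closer to its term than any other code (arbitrary
  identifier), Δ > 0 indicates semantic alignment (lexicalized symbol).
  Groups of Δ distributions are compared by one-way ANOVA + Tukey HSD.
* **Popularity** — literature/annotation counts per pair, Laplace-smoothed
  and log10-transformed, summarized per outcome category, correlated
  across proxies (Pearson), and tested by a Terminology × Correctness
  two-way ANOVA with Games–Howell post hoc.

Because querying hosted LLMs and extracting real hidden states are outside
a test environment, both are **pluggable contracts** (responder: prompt →
text; embedding provider: string → vector), and a synthetic module plants
recoverable structure behind both: Zipf-distributed popularity, a logistic
popularity link for baseline correctness, planted memorization /
generalization / degradation rates, and a tunable term–code alignment λ.

## Worked example

A fully synthetic experiment: 5,000-pair terminology, 20 frequency bins ×
30 pairs per bin per split, planted rates m = 0.4, g = 0.1, d = 0.05 and
baseline link p = σ(−1.5 + 0.8·log₁₀(count+1)).

```python
from termnorm import *
from termnorm.prompting import default_forward_templates

cfg = SyntheticConfig(n_pairs=5000, seed=7)
table = generate_terminology(cfg)
split = draw_balanced_splits(table, SamplingPlan(n_bins=20, per_bin=30, seed=7))
responder = make_responder(cfg, table, split)

tpl = [default_forward_templates()[0]]
inst = (expand_prompts([table[p] for p in split.train], "forward", tpl, split="seen")
        + expand_prompts([table[p] for p in split.withheld], "forward", tpl, split="unseen"))
base = score_responses(inst, run_responder(inst, responder.baseline, "baseline"))
fine = score_responses(inst, run_responder(inst, responder.finetuned, "finetuned"))
summary = summarize_metrics(classify_outcomes(base, fine,
                                              {i.instance_id: i.split for i in inst}))
print(summary.rounded())
```

prints (seed 7):

```
memorization_pct    27.0     # expected under the planted model: 26.1
generalization_pct   4.3     # expected: 4.8
degraded_pct         3.0     # expected: 2.6
accuracy_pct        72.8     # continuing_correct 48.7 + gainer 27.0 − loser 2.8
```

The observed values sit within binomial sampling error of the analytic
expectations computed from the planted per-pair probabilities
(`responder.expected_metrics()`); one of the 600 seen prompts looks like
`What is the SYN identifier for the SYN term generalized hepatic
agenesis?` with gold answer `SYN:0000001`.

The same pipeline runs from the shell:

```bash
termnorm run --config run.yaml      # simulate → sample → prompts → score →
                                    # outcomes → lexicalize → popularity
termnorm sample --table t.tsv --bins 20 --per-bin 30 --seed 1 --out split.jsonl
```

## Published-table regression

`termnorm.reference_results` carries the published per-category outcome
percentages for the eight fine-tuning tasks (HPO/GO/HGNC × direction) and
their reported summary rows. `derive_from_percentages` reapplies the
derived-metric formulas to the category table; `check_consistency` flags
the two cells whose published accuracy does not equal the identity applied
to their own category row (HPO Term→ID and GO Term→ID). The package
computes the formula and reports the discrepancy; it does not force
agreement.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the published outcome-category tables, the derived
post-fine-tuning accuracy for four mapping tasks (HGNC Symbol→Term, HGNC
Term→Symbol, GO ID→Term, HGNC Term→ID) by running them through the
package's metrics summarizer, and writes one JSON object keyed by target
id with the value (in percent) and the split size used.
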