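"""Planted-structure generators: terminology, responder, embeddings."""

import numpy as np
import pytest

from termnorm import (
    CodeType,
    SamplingPlan,
    SyntheticConfig,
    ValidationError,
    draw_balanced_splits,
    expand_prompts,
    generate_terminology,
    make_embedding_provider,
    make_responder,
    project_2d,
    score_responses,
    run_responder,
)
from termnorm.prompting import default_forward_templates


def test_zipf_rank_frequency_slope(synth_table):
    """log-log regression over ranks 10..500 recovers the unit exponent."""
    counts = np.sort([r.code_count for r in synth_table.rows])[::-1].astype(float)
    ranks = np.arange(1, len(counts) + 1)
    sel = slice(9, 500)
    slope = np.polyfit(np.log10(ranks[sel]), np.log10(counts[sel]), 1)[0]
    assert abs(slope - (-1.0)) < 0.05


def test_zero_evidence_fraction(synth_config, synth_table):
    n_zero = sum(1 for r in synth_table.rows if r.code_count == 0)
    assert n_zero == round(synth_config.zero_count_fraction * synth_config.n_pairs)


def test_generation_is_seed_deterministic(synth_config, synth_table):
    again = generate_terminology(synth_config)
    assert again.rows == synth_table.rows
    other = generate_terminology(SyntheticConfig(n_pairs=2000, seed=12))
    assert other.rows != synth_table.rows


def test_arbitrary_codes_are_opaque_serials(synth_table):
    for row in synth_table.rows[:50]:
        prefix, digits = row.code.split(":")
        assert prefix == "SYN" and len(digits) == 7 and digits.isdigit()
        # no surface overlap between term initials and code digits
        assert not (set(row.term) & set(digits))


def test_lexicalized_symbols_share_initials_with_terms():
    table = generate_terminology(
        SyntheticConfig(n_pairs=100, code_scheme=CodeType.LEXICALIZED_SYMBOL, seed=3)
    )
    codes = {r.code for r in table.rows}
    assert len(codes) == 100  # unique
    for row in table.rows:
        initials = "".join(w[0] for w in row.term.split()).upper()
        assert row.code.rstrip("0123456789") == initials


def test_counts_are_coupled_across_proxies(synth_table):
    log_code = np.log10([r.code_count + 1 for r in synth_table.rows])
    log_term = np.log10([r.term_count + 1 for r in synth_table.rows])
    assert np.corrcoef(log_code, log_term)[0, 1] > 0.5


def test_config_rejects_tiny_worlds():
    with pytest.raises(ValidationError):
        SyntheticConfig(n_pairs=10)


def _eval_bits(config, table, split, responder, which="finetuned", direction="forward"):
    tpl = [default_forward_templates()[0]]
    seen = expand_prompts([table[p] for p in split.train], direction, tpl, split="seen")
    unseen = expand_prompts([table[p] for p in split.withheld], direction, tpl, split="unseen")
    instances = seen + unseen
    fn = responder.finetuned if which == "finetuned" else responder.baseline
    scored = score_responses(instances, run_responder(instances, fn, which))
    return instances, {r.instance_id: r.correct for r in scored}


def test_perfect_memorization_no_degradation():
    """m=1, d=0: every seen instance is correct after fine-tuning."""
    config = SyntheticConfig(n_pairs=200, m=1.0, d=0.0, mem_link_b=0.0, seed=4)
    table = generate_terminology(config)
    split = draw_balanced_splits(table, SamplingPlan(n_bins=4, per_bin=10, seed=4))
    responder = make_responder(config, table, split)
    instances, bits = _eval_bits(config, table, split, responder)
    seen_bits = [bits[i.instance_id] for i in instances if i.split == "seen"]
    assert all(b == 1 for b in seen_bits)


def test_zero_degradation_means_zero_losers():
    config = SyntheticConfig(n_pairs=200, d=0.0, seed=5)
    table = generate_terminology(config)
    split = draw_balanced_splits(table, SamplingPlan(n_bins=4, per_bin=10, seed=5))
    responder = make_responder(config, table, split)
    instances, base = _eval_bits(config, table, split, responder, which="baseline")
    _, fine = _eval_bits(config, table, split, responder, which="finetuned")
    losers = [i for i in instances if base[i.instance_id] == 1 and fine[i.instance_id] == 0]
    assert losers == []


def test_flat_link_memorization_matches_analytic_expectation():
    """p_base = 0.2 flat, m = 0.4: expected memorization 0.8*0.4 = 32%."""
    config = SyntheticConfig(
        n_pairs=2000, baseline_link=(np.log(0.25), 0.0), m=0.4, mem_link_b=0.0, seed=6
    )
    table = generate_terminology(config)
    split = draw_balanced_splits(table, SamplingPlan(n_bins=20, per_bin=30, seed=6))
    responder = make_responder(config, table, split)
    expected = responder.expected_metrics()
    assert expected["memorization_pct"] == pytest.approx(32.0, abs=1e-9)
    instances, base = _eval_bits(config, table, split, responder, which="baseline")
    _, fine = _eval_bits(config, table, split, responder, which="finetuned")
    gainers = sum(
        1 for i in instances
        if i.split == "seen" and base[i.instance_id] == 0 and fine[i.instance_id] == 1
    )
    se = 100 * np.sqrt(0.32 * 0.68 / 600)
    assert abs(100 * gainers / 600 - 32.0) <= 3 * se


def test_responder_bits_are_reproducible():
    config = SyntheticConfig(n_pairs=200, seed=7)
    table = generate_terminology(config)
    split = draw_balanced_splits(table, SamplingPlan(n_bins=4, per_bin=10, seed=7))
    r1 = make_responder(config, table, split)
    r2 = make_responder(config, table, split)
    tpl = [default_forward_templates()[0]]
    instances = expand_prompts([table[p] for p in split.train], "forward", tpl, split="seen")
    assert [r1.baseline(i) for i in instances] == [r2.baseline(i) for i in instances]
    assert [r1.finetuned(i) for i in instances] == [r2.finetuned(i) for i in instances]


def test_wrong_answers_are_confusable_codes():
    config = SyntheticConfig(n_pairs=200, baseline_link=(-100.0, 0.0), m=0.0,
                             g=0.0, mem_link_b=0.0, seed=8)
    table = generate_terminology(config)
    split = draw_balanced_splits(table, SamplingPlan(n_bins=4, per_bin=10, seed=8))
    responder = make_responder(config, table, split)
    tpl = [default_forward_templates()[0]]
    instances = expand_prompts([table[p] for p in split.train], "forward", tpl, split="seen")
    for inst in instances[:20]:
        answer = responder.baseline(inst)
        assert answer != inst.gold_answer
        assert answer in {r.code for r in table.rows}  # a real but wrong code


def test_lambda_one_plants_perfect_match_cosine():
    config = SyntheticConfig(n_pairs=50, lambda_align=1.0, id_cluster_offset=False, seed=9)
    table = generate_terminology(config)
    provider = make_embedding_provider(config, table)
    for row in table.rows[:10]:
        t, c = provider.embed(row.term), provider.embed(row.code)
        assert np.dot(t, c) / (np.linalg.norm(t) * np.linalg.norm(c)) == pytest.approx(1.0)


def test_embeddings_are_deterministic_and_fixed_dim():
    config = SyntheticConfig(n_pairs=50, dim=16, seed=10)
    table = generate_terminology(config)
    p1 = make_embedding_provider(config, table)
    p2 = make_embedding_provider(config, table)
    for row in table.rows[:5]:
        assert np.array_equal(p1.embed(row.term), p2.embed(row.term))
        assert p1.embed(row.code).shape == (16,)
    # unknown strings also resolve deterministically
    assert np.array_equal(p1.embed("never seen"), p2.embed("never seen"))


def test_id_cluster_offset_separates_codes_from_terms():
    """Arbitrary-ID codes form their own cluster in the 2-D projection."""
    config = SyntheticConfig(n_pairs=150, lambda_align=0.0, id_cluster_offset=True, seed=11)
    table = generate_terminology(config)
    provider = make_embedding_provider(config, table)
    term_vecs = [provider.embed(r.term) for r in table.rows]
    code_vecs = [provider.embed(r.code) for r in table.rows]
    coords, _ = project_2d(term_vecs + code_vecs)
    terms2d, codes2d = coords[:150], coords[150:]
    centroid_gap = np.linalg.norm(terms2d.mean(axis=0) - codes2d.mean(axis=0))
    within = np.mean([
        np.linalg.norm(terms2d - terms2d.mean(axis=0), axis=1).mean(),
        np.linalg.norm(codes2d - codes2d.mean(axis=0), axis=1).mean(),
    ])
    assert centroid_gap > within
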