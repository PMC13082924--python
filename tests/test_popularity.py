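"""Popularity transforms, summaries, correlations, and the two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

from termnorm import (
    Category,
    CodeType,
    DegenerateInputError,
    TermCodePair,
    ValidationError,
    transform_counts,
    two_way_anova_popularity,
)
from termnorm.outcomes import OutcomeRecord
from termnorm.popularity import attach_outcomes, games_howell, group_summaries, proxy_correlations


def _pairs(counts, terminology="SYN"):
    return [
        TermCodePair(
            term=f"term {i}", code=f"{terminology}:{i:07d}",
            code_type=CodeType.ARBITRARY_ID, terminology=terminology,
            code_count=c, term_count=c * 2, annotation_count=max(c - 1, 0),
        )
        for i, c in enumerate(counts)
    ]


@pytest.mark.parametrize("count,expected", [(0, 0.0), (9, 1.0), (999, 3.0)])
def test_laplace_log10_transform(count, expected):
    df = transform_counts(_pairs([count, 5]))
    assert df["log_code"].iloc[0] == pytest.approx(expected)


def test_transform_is_monotone():
    df = transform_counts(_pairs([0, 1, 5, 50, 5000]))
    assert df["log_code"].is_monotonic_increasing


def test_negative_count_rejected():
    with pytest.raises(ValidationError):
        TermCodePair(term="x", code="SYN:1", code_type=CodeType.ARBITRARY_ID,
                     terminology="SYN", code_count=-1)


def _records_with_categories(values_by_cat):
    pairs, outcomes, pair_of_instance = [], [], {}
    i = 0
    for cat, counts in values_by_cat.items():
        for c in counts:
            pair = TermCodePair(
                term=f"t{i}", code=f"SYN:{i:07d}", code_type=CodeType.ARBITRARY_ID,
                terminology="SYN", code_count=c, term_count=c, annotation_count=c,
            )
            pairs.append(pair)
            iid = f"inst{i}"
            pair_of_instance[iid] = pair.pair_id
            B, F = {
                Category.GAINER: (0, 1),
                Category.LOSER: (1, 0),
                Category.CONTINUING_CORRECT: (1, 1),
                Category.CONTINUING_INCORRECT: (0, 0),
            }[cat]
            outcomes.append(OutcomeRecord(instance_id=iid, B=B, F=F, split="seen",
                                          category=cat))
            i += 1
    df = attach_outcomes(transform_counts(pairs), outcomes, pair_of_instance)
    return df


def test_group_summaries_match_hand_arithmetic():
    df = _records_with_categories({
        Category.GAINER: [10, 20, 30],
        Category.CONTINUING_CORRECT: [100, 200, 300],
        Category.CONTINUING_INCORRECT: [1, 2, 3],
    })
    table = group_summaries(df)
    gainer = table[table["category"] == "gainer"].iloc[0]
    assert gainer["N"] == 3
    assert gainer["code_mean"] == pytest.approx(20.0)
    assert gainer["code_sd"] == pytest.approx(10.0)
    all_row = table[table["category"] == "all"].iloc[0]
    assert all_row["N"] == 9
    assert all_row["code_mean"] == pytest.approx(np.mean([10, 20, 30, 100, 200, 300, 1, 2, 3]))
    # three clearly separated groups: the per-proxy ANOVA flags differences
    assert gainer["code_anova_significant"] is True or gainer["code_anova_significant"] == True  # noqa: E712


def test_single_category_anova_not_applicable():
    df = _records_with_categories({Category.GAINER: [10, 20, 30]})
    table = group_summaries(df)
    assert table["code_anova_significant"].iloc[0] is None


def test_identical_groups_are_not_flagged():
    df = _records_with_categories({
        Category.GAINER: [10, 20, 30],
        Category.LOSER: [10, 20, 30],
    })
    table = group_summaries(df)
    assert not table["code_anova_significant"].iloc[0]


def test_pearson_matches_hand_computation():
    counts = [2, 7, 19, 56, 170]
    pairs = _pairs(counts)
    df = transform_counts(pairs)
    corr = proxy_correlations(df)
    x = np.log10(np.array(counts) + 1.0)
    y = np.log10(np.array([max(c - 1, 0) for c in counts]) + 1.0)
    r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert corr.loc[("SYN", "log_code"), "log_annotation"] == pytest.approx(r_hand, abs=1e-12)
    assert corr.loc[("SYN", "log_code"), "log_code"] == pytest.approx(1.0)


def test_affine_proxy_correlates_exactly():
    # term_count = 2 * code_count: on raw counts the log transform is not
    # affine, so check self-correlation and symmetry instead
    df = transform_counts(_pairs([2, 7, 19, 56, 170]))
    corr = proxy_correlations(df).loc["SYN"]
    mat = corr.to_numpy()
    assert np.allclose(mat, mat.T, atol=1e-12)
    eigvals = np.linalg.eigvalsh(mat)
    assert eigvals.min() >= -1e-10  # positive semidefinite


def test_correlations_need_three_records():
    with pytest.raises(ValidationError):
        proxy_correlations(transform_counts(_pairs([1, 2])))


def _anova_frame(rng, n_per_cell, term_effects, correct_effect=0.0):
    rows = []
    for terminology, shift in term_effects.items():
        for correct in (0, 1):
            for k in range(n_per_cell):
                rows.append({
                    "pair_id": f"{terminology}:{correct}:{k}",
                    "terminology": terminology,
                    "log_code": shift + correct_effect * correct + rng.normal(),
                })
    df = pd.DataFrame(rows)
    correctness = {}
    for _, row in df.iterrows():
        correctness[row["pair_id"]] = int(row["pair_id"].split(":")[1])
    return df, correctness


def test_planted_terminology_effect_detected_correctness_not():
    """Cohen's d = 1 between terminologies, none for correctness, n=200/cell."""
    rng = np.random.default_rng(12)
    df, correctness = _anova_frame(
        rng, 200, {"A": 0.0, "B": 1.0, "C": 0.0}, correct_effect=0.0
    )
    report = two_way_anova_popularity(df, correctness, proxy="code")
    assert report.effect_p("terminology") < 0.05
    assert report.effect_p("correctness") > 0.05
    assert report.games_howell is not None  # post hoc triggered
    gh = report.games_howell
    ab = gh[(gh["A"] == "A") & (gh["B"] == "B")]
    assert ab["pval"].iloc[0] < 0.05


def test_games_howell_on_equal_groups_is_null():
    rng = np.random.default_rng(13)
    df = pd.DataFrame({
        "group": ["a"] * 40 + ["b"] * 40,
        "value": np.concatenate([rng.normal(5, 1, 40), rng.normal(5, 1, 40)]),
    })
    gh = games_howell(df, dv="value", between="group")
    assert abs(gh["diff"].iloc[0]) < 0.5
    assert gh["pval"].iloc[0] > 0.2


def test_constant_response_is_degenerate():
    df = pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(8)],
        "terminology": ["A"] * 4 + ["B"] * 4,
        "log_code": [1.0] * 8,
    })
    correctness = {f"p{i}": i % 2 for i in range(8)}
    with pytest.raises(DegenerateInputError, match="zero variance"):
        two_way_anova_popularity(df, correctness, proxy="code")


def test_missing_factor_levels_rejected():
    df = pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(6)],
        "terminology": ["A"] * 6,
        "log_code": np.arange(6.0),
    })
    with pytest.raises(ValidationError, match="terminology"):
        two_way_anova_popularity(df, {f"p{i}": i % 2 for i in range(6)}, proxy="code")
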