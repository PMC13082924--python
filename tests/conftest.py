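import pytest

from termnorm import (
    CodeType,
    SamplingPlan,
    SyntheticConfig,
    TermCodePair,
    TerminologyTable,
    draw_balanced_splits,
    generate_terminology,
)


@pytest.fixture()
def small_table() -> TerminologyTable:
    """Four hand-entered rows spanning arbitrary and lexicalized codes."""
    return TerminologyTable(
        rows=[
            TermCodePair(
                term="Nucleus", code="GO:0005634", code_type=CodeType.ARBITRARY_ID,
                terminology="GO", code_count=87, term_count=1_078_535, annotation_count=54,
            ),
            TermCodePair(
                term="Tremor", code="HP:0001337", code_type=CodeType.ARBITRARY_ID,
                terminology="HPO", code_count=10, term_count=360_215, annotation_count=308,
            ),
            TermCodePair(
                term="Tumor protein p53", code="TP53", code_type=CodeType.LEXICALIZED_SYMBOL,
                terminology="HGNC", code_count=11_032, term_count=20_917, annotation_count=35,
            ),
            TermCodePair(
                term="Tumor protein p53", code="HGNC:11998", code_type=CodeType.ARBITRARY_ID,
                terminology="HGNC", code_count=1, term_count=20_917, annotation_count=35,
            ),
        ],
        source_label="toy",
    )


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    return SyntheticConfig(n_pairs=2000, seed=11)


@pytest.fixture(scope="session")
def synth_table(synth_config):
    return generate_terminology(synth_config)


@pytest.fixture(scope="session")
def synth_split(synth_table):
    return draw_balanced_splits(synth_table, SamplingPlan(n_bins=20, per_bin=30, seed=11))
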