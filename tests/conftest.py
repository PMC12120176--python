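import pytest

from mavecalib import (
    FunctionalClass,
    GeneratorConfig,
    ScoreTable,
    VariantRecord,
    build_analysis_cohort,
    generate_mave_cohort,
)


def make_cohort(lof_scores, func_scores, tool="AM", **extra):
    """LoF/FUNC cohort with one tool scored; ids are generated."""
    records = []
    for i, s in enumerate(lof_scores):
        records.append(
            VariantRecord(
                f"lof{i}", -2.0, functional_class=FunctionalClass.LOF,
                scores={tool: s}, **extra,
            )
        )
    for i, s in enumerate(func_scores):
        records.append(
            VariantRecord(
                f"func{i}", 0.0, functional_class=FunctionalClass.FUNC,
                scores={tool: s}, **extra,
            )
        )
    return ScoreTable(records)


@pytest.fixture(scope="session")
def synthetic_table():
    """Default-config synthetic MAVE cohort (seed fixed for the session)."""
    return generate_mave_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def synthetic_cohort(synthetic_table):
    """LoF/FUNC analysis cohort from the synthetic table."""
    cohort, _ = build_analysis_cohort(synthetic_table)
    return cohort
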