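import numpy as np
import pandas as pd
import pytest

from consensusde.types import ComparisonTable


@pytest.fixture
def make_de_file(tmp_path):
    """Write a tab-separated DE table and return its path."""

    def _make(rows, header="id\tlog2fc\tpvalue\tadj_pvalue", name="table.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _make


@pytest.fixture
def make_table():
    """Build a ComparisonTable from compact record tuples."""

    def _make(
        records,
        comparison_id="cmp1",
        group_label="non_treated",
        canonical=False,
        passed=None,
    ):
        df = pd.DataFrame(records, columns=["source_id", "log2fc", "pvalue"])
        if canonical:
            df["canonical_id"] = df["source_id"]
        if passed is not None:
            df["passed"] = passed
        return ComparisonTable(
            comparison_id=comparison_id,
            group_label=group_label,
            n_case=5,
            n_control=5,
            records=df,
        )

    return _make


@pytest.fixture
def make_long():
    """Build a merged long table from (gene, comparison, group, lfc, p, passed)."""

    def _make(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "canonical_id",
                "comparison_id",
                "group_label",
                "log2fc",
                "pvalue",
                "passed",
            ],
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
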