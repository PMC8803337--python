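import pandas as pd
import pytest

from sigcross import DETable, GeneSetCollection, OrthologMap


@pytest.fixture
def de_table():
    """Five-gene table matching the worked signature example."""
    return DETable(
        pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D", "E"],
                "log2fc": [1.5, -2.0, 0.5, 2.0, 1.0],
                "pvalue": [0.01, 0.001, 0.005, 0.05, 0.02],
                "fdr": [0.05, 0.01, 0.01, 0.2, 0.1],
            }
        ),
        label="toy",
    )


@pytest.fixture
def write_de_file(tmp_path):
    """Write a DE table file from rows of (gene, log2fc, pvalue[, fdr])."""

    def _write(rows, header="gene\tlog2fc\tpvalue", name="de.tsv"):
        lines = [header] + ["\t".join(str(v) for v in row) for row in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def small_collection():
    return GeneSetCollection.from_dict(
        {"S1": {"A", "B"}, "S2": {"C", "D", "E"}}, source_label="toy"
    )


@pytest.fixture
def bijective_map():
    return OrthologMap(
        [(g, g.upper() + "H") for g in ["a", "b", "c", "d", "e"]],
        "mouse", "human",
    )
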