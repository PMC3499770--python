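import numpy as np
import pytest

from statispy.io_formats import ExpressionTable, TableCollection


def make_collection(arrays, condition_ids=None, control_id=None, times=None,
                    scale="log2", gene_ids=None):
    """Wrap raw (n x t) arrays into a TableCollection for tests."""
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n, t = arrays[0].shape
    if condition_ids is None:
        condition_ids = [f"C{i+1}" for i in range(len(arrays))]
    if control_id is None:
        control_id = condition_ids[0]
    if times is None:
        times = np.arange(t, dtype=float) * 20.0
    if gene_ids is None:
        gene_ids = [f"g{i+1:03d}" for i in range(n)]
    tables = [
        ExpressionTable(cid, gene_ids, times, a, scale)
        for cid, a in zip(condition_ids, arrays)
    ]
    return TableCollection(tables=tables, control_id=control_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_collection(rng):
    """Three small random log2 tables, 12 genes x 6 time points."""
    arrays = [8.0 + rng.normal(0, 1, size=(12, 6)) for _ in range(3)]
    return make_collection(arrays)


@pytest.fixture
def tiny_tsv_dir(tmp_path):
    """Two 3-gene x 4-time TSV condition files with identical headers."""
    header = "gene_id\t0\t20\t40\t60"
    rows_a = ["g2\t1.0\t2.0\t3.0\t4.0", "g1\t5.0\t6.0\t7.0\t8.0", "g3\t2.5\t2.5\t2.5\t2.5"]
    rows_b = ["g1\t1.1\t2.1\t3.1\t4.1", "g3\t0.5\t0.6\t0.7\t0.8", "g2\t9.0\t8.0\t7.0\t6.0"]
    (tmp_path / "condA.tsv").write_text("\n".join([header] + rows_a) + "\n")
    (tmp_path / "condB.tsv").write_text("\n".join([header] + rows_b) + "\n")
    return tmp_path
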