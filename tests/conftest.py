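import numpy as np
import pandas as pd
import pytest

from sepsispanel.io import LOG2_NORMALIZED, ExpressionMatrix, SampleRecord
from sepsispanel.panels import COMPOSITE, PanelScores, builtin_panels

ALL_PANEL_GENES = [g for p in builtin_panels() for g in p.genes]


def make_log2_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    genes = list(genes) if genes is not None else ALL_PANEL_GENES[: values.shape[0]]
    samples = list(samples) if samples is not None else [f"S{i+1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), scale=LOG2_NORMALIZED
    )


def make_scores(composite=None, sample_ids=None, **panel_cols) -> PanelScores:
    """Build a PanelScores directly from per-sample column values."""
    cols = dict(panel_cols)
    n = len(next(iter(cols.values()))) if cols else len(composite)
    if sample_ids is None:
        sample_ids = [f"S{i+1}" for i in range(n)]
    df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"), dtype=float)
    if composite is not None:
        df[COMPOSITE] = np.asarray(composite, dtype=float)
    elif "NDrG" in df.columns and "HLAd" in df.columns:
        df[COMPOSITE] = df["NDrG"] - df["HLAd"]
    coverage = {c: 1.0 for c in df.columns if c != COMPOSITE}
    return PanelScores(values=df, coverage=coverage)


@pytest.fixture
def full_matrix():
    """All 26 panel genes x 4 samples, deterministic log2 values."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(4, 12, size=(len(ALL_PANEL_GENES), 4))
    return make_log2_matrix(vals)


@pytest.fixture
def outcome_records():
    def rec(i, outcome, sofa=None):
        return SampleRecord(sample_id=f"S{i+1}", outcome=outcome, sofa=sofa)
    return [rec(0, "survivor", 4), rec(1, "survivor", 9), rec(2, "survivor", 6),
            rec(3, "non-survivor", 12), rec(4, "non-survivor", 7)]
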