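"""Cohort statistics on panel scores.

Two-group (Welch), paired (paired t on subject deltas), and multi-group
(Tukey–Kramer HSD) contrasts; Pearson correlation of a panel score with the
SOFA score; and PCA over the five standardized panel scores.

Mean differences are always oriented B − A (second group minus first), and
the test statistic carries the same orientation, so swapping the groups
negates both and leaves the p-value unchanged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleRecord
from .panels import COMPOSITE, PanelScores

logger = logging.getLogger(__name__)

WELCH_T = "welch_t"
PAIRED_T = "paired_t"
TUKEY_HSD = "tukey_hsd"


class ContrastError(ValueError):
    """Insufficient or degenerate data for the requested contrast."""


@dataclass
class GroupComparison:
    panel: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_diff: float  # mean(B) − mean(A), log2 units
    statistic: float
    df: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CorrelationResult:
    panel: str
    r: float
    n: int
    p_value: float


@dataclass
class PCAResult:
    """Loadings (panels × components, unit-norm columns), per-sample
    component scores, and variance-explained fractions (non-increasing)."""

    loadings: pd.DataFrame
    sample_scores: pd.DataFrame
    variance_fractions: np.ndarray


def _score_series(scores: PanelScores, panel: str) -> pd.Series:
    if panel not in scores.values.columns:
        raise ContrastError(f"panel {panel!r} not present in scores")
    return scores.values[panel]


def group_values(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    group: str,
    panel: str,
    timepoint: str | None = None,
) -> np.ndarray:
    """Panel-score values of the samples in ``group`` (optionally at one time point)."""
    s = _score_series(scores, panel)
    vals = [
        s[r.sample_id]
        for r in records
        if r.group == group
        and (timepoint is None or r.timepoint == timepoint)
        and r.sample_id in s.index
        and np.isfinite(s[r.sample_id])
    ]
    return np.asarray(vals, dtype=float)


def two_group_contrast(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    group_a: str,
    group_b: str,
    panel: str,
    timepoint_a: str | None = None,
    timepoint_b: str | None = None,
) -> GroupComparison:
    """Welch unequal-variance t test; mean difference is group_b − group_a."""
    records = list(records)
    a = group_values(scores, records, group_a, panel, timepoint_a)
    b = group_values(scores, records, group_b, panel, timepoint_b)
    if len(a) < 2 or len(b) < 2:
        raise ContrastError(f"both groups need n >= 2 (got {len(a)}, {len(b)})")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ContrastError("zero variance in both groups; Welch t undefined")
    res = sps.ttest_ind(b, a, equal_var=False)
    return GroupComparison(
        panel=panel, group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b),
        mean_diff=float(b.mean() - a.mean()),
        statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        method=WELCH_T,
    )


def paired_deltas(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    timepoint_a: str,
    timepoint_b: str,
    panel: str,
) -> tuple[np.ndarray, list[str], int]:
    """Per-subject score(b) − score(a) over complete pairs.

    Returns (deltas, subject ids, number of incomplete subjects dropped).
    """
    s = _score_series(scores, panel)
    at: dict[str, dict[str, float]] = {}
    for r in records:
        if r.timepoint in (timepoint_a, timepoint_b) and r.sample_id in s.index:
            v = s[r.sample_id]
            if np.isfinite(v):
                at.setdefault(r.subject_id, {})[r.timepoint] = float(v)
    subjects, deltas, dropped = [], [], 0
    for subj, tps in at.items():
        if timepoint_a in tps and timepoint_b in tps:
            subjects.append(subj)
            deltas.append(tps[timepoint_b] - tps[timepoint_a])
        else:
            dropped += 1
    if dropped:
        logger.info("paired contrast %s: dropped %d incomplete subject(s)", panel, dropped)
    return np.asarray(deltas), subjects, dropped


def paired_contrast(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    timepoint_a: str,
    timepoint_b: str,
    panel: str,
) -> GroupComparison:
    """Paired t test on subject-level deltas, df = n − 1."""
    records = list(records)
    d, _, _ = paired_deltas(scores, records, timepoint_a, timepoint_b, panel)
    if len(d) < 2:
        raise ContrastError(f"paired contrast needs >= 2 complete pairs, got {len(d)}")
    if d.var(ddof=1) == 0:
        raise ContrastError("degenerate paired contrast: zero delta variance")
    res = sps.ttest_1samp(d, 0.0)
    return GroupComparison(
        panel=panel, group_a=timepoint_a, group_b=timepoint_b,
        n_a=len(d), n_b=len(d),
        mean_diff=float(d.mean()),
        statistic=float(res.statistic), df=float(len(d) - 1), p_value=float(res.pvalue),
        method=PAIRED_T,
    )


def tukey_contrasts(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    groups: Sequence[str],
    panel: str,
) -> list[GroupComparison]:
    """All pairwise mean differences with family-wise Tukey–Kramer adjusted
    p-values (studentized-range distribution, pooled error variance)."""
    records = list(records)
    if len(groups) < 2:
        raise ContrastError("tukey_contrasts needs >= 2 groups")
    arrays = [group_values(scores, records, g, panel) for g in groups]
    for g, a in zip(groups, arrays):
        if len(a) < 2:
            raise ContrastError(f"group {g!r} needs n >= 2, got {len(a)}")
    res = sps.tukey_hsd(*arrays)
    df_err = sum(len(a) for a in arrays) - len(arrays)
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        out.append(
            GroupComparison(
                panel=panel, group_a=groups[i], group_b=groups[j],
                n_a=len(arrays[i]), n_b=len(arrays[j]),
                mean_diff=float(arrays[j].mean() - arrays[i].mean()),
                statistic=float(res.statistic[j, i]),
                df=float(df_err),
                p_value=float(res.pvalue[i, j]),
                method=TUKEY_HSD,
            )
        )
    return out


def permutation_fwer(
    arrays: Sequence[np.ndarray], n_perm: int = 10000, seed: int = 0
) -> np.ndarray:
    """Seeded max-statistic permutation FWER-adjusted p-values for all pairs.

    Independent validation route for the studentized-range adjustment: the
    null distribution of the maximum absolute pairwise mean difference is
    built by permuting group labels.
    """
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(arrays)
    sizes = [len(a) for a in arrays]
    pairs = list(itertools.combinations(range(len(arrays)), 2))

    def absdiffs(groups: list[np.ndarray]) -> np.ndarray:
        return np.array([abs(groups[j].mean() - groups[i].mean()) for i, j in pairs])

    observed = absdiffs(list(arrays))
    max_null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        chunks, pos = [], 0
        for n in sizes:
            chunks.append(perm[pos:pos + n])
            pos += n
        max_null[k] = absdiffs(chunks).max()
    return np.array([(1 + np.sum(max_null >= obs)) / (1 + n_perm) for obs in observed])


def score_sofa_correlation(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    panel: str,
    groups: Sequence[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation of a panel score with the SOFA score, complete cases."""
    s = _score_series(scores, panel)
    xs, ys = [], []
    for r in records:
        if groups is not None and r.group not in groups:
            continue
        if r.sofa is None or r.sample_id not in s.index:
            continue
        v = s[r.sample_id]
        if np.isfinite(v):
            xs.append(float(v))
            ys.append(float(r.sofa))
    if len(xs) < 3:
        raise ContrastError(f"correlation needs >= 3 complete cases, got {len(xs)}")
    x, y = np.asarray(xs), np.asarray(ys)
    if x.var() == 0 or y.var() == 0:
        raise ContrastError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(panel=panel, r=float(r), n=len(x), p_value=float(p))


def pca_panels(scores: PanelScores, k: int = 2) -> PCAResult:
    """PCA of the standardized panel scores (composite excluded).

    Columns are centered and scaled to unit variance before the SVD; each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    panel_cols = [c for c in scores.values.columns if c != COMPOSITE]
    X = scores.values[panel_cols].dropna()
    n, p = X.shape
    if n < k + 1:
        raise ContrastError(f"PCA with k={k} needs >= {k + 1} complete samples, got {n}")
    sd = X.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ContrastError(f"constant panel column(s): {const}")
    Z = (X - X.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    k = min(k, p)
    load = Vt[:k].T  # panels × k, unit-norm columns
    signs = np.sign(load[np.abs(load).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    load = load * signs
    comp_scores = Z.to_numpy() @ load
    var_frac = (S[:k] ** 2) / (Z.to_numpy() ** 2).sum()
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(load, index=panel_cols, columns=comp_names),
        sample_scores=pd.DataFrame(comp_scores, index=X.index, columns=comp_names),
        variance_fractions=var_frac,
    )


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])
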