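"""Survivor-identification decision rules and their evaluation.

The core rule predicts *survivor* when the composite score (NDrG − HLAd)
falls strictly below a threshold (default 1.50). It can be OR-combined with
a SOFA clause (SOFA strictly below 8) and an exploratory GBPs clause (GBPs
score strictly above 8.5). All inequalities are strict; boundary values are
not identified.

"False positive rate" is ambiguous for these rules, so the evaluation
reports both explicit fractions — FP/(TP+FP) among positive predictions and
FP/(FP+TN) among known non-survivors — and never calls either one "the"
false positive rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SampleRecord
from .panels import COMPOSITE, PanelScores

SURVIVOR = "survivor"
NON_SURVIVOR = "non-survivor"
NOT_IDENTIFIED = "not_identified"
UNEVALUABLE = "unevaluable"


class RuleError(ValueError):
    """Invalid rule specification or unevaluable inputs."""


@dataclass
class RuleSpec:
    """OR-combination of threshold clauses, each with a strict inequality.

    composite < theta_c, SOFA < theta_s, GBPs > theta_g. At least one clause
    must be enabled.
    """

    use_composite: bool = True
    composite_threshold: float = 1.50
    use_sofa: bool = False
    sofa_threshold: float = 8.0
    use_gbps: bool = False
    gbps_threshold: float = 8.5

    def __post_init__(self) -> None:
        if not (self.use_composite or self.use_sofa or self.use_gbps):
            raise RuleError("at least one clause must be enabled")
        for t in (self.composite_threshold, self.sofa_threshold, self.gbps_threshold):
            if not math.isfinite(t):
                raise RuleError("thresholds must be finite")

    @classmethod
    def parse(cls, text: str) -> "RuleSpec":
        """Parse e.g. ``"composite<1.5,sofa<8"`` or ``"gbps>8.5"``."""
        spec = cls.__new__(cls)
        spec.use_composite = spec.use_sofa = spec.use_gbps = False
        spec.composite_threshold, spec.sofa_threshold, spec.gbps_threshold = 1.50, 8.0, 8.5
        for clause in filter(None, (c.strip() for c in text.split(","))):
            for name, op in (("composite", "<"), ("sofa", "<"), ("gbps", ">")):
                if clause.lower().startswith(name):
                    rest = clause[len(name):].strip()
                    if not rest.startswith(op):
                        raise RuleError(f"clause {clause!r}: expected {name}{op}THRESHOLD")
                    setattr(spec, f"use_{name}", True)
                    setattr(
                        spec,
                        {"composite": "composite_threshold", "sofa": "sofa_threshold", "gbps": "gbps_threshold"}[name],
                        float(rest[len(op):]),
                    )
                    break
            else:
                raise RuleError(f"unrecognized clause {clause!r}")
        spec.__post_init__()
        return spec

    def describe(self) -> str:
        parts = []
        if self.use_composite:
            parts.append(f"composite<{self.composite_threshold:g}")
        if self.use_sofa:
            parts.append(f"sofa<{self.sofa_threshold:g}")
        if self.use_gbps:
            parts.append(f"gbps>{self.gbps_threshold:g}")
        return " OR ".join(parts)


@dataclass
class RuleEvaluation:
    """Confusion counts (positive class = survivor) and derived metrics.

    ``sensitivity`` = TP/(TP+FN); ``false_discovery_fraction`` = FP/(TP+FP)
    (0 when nothing is predicted positive); ``fpr_among_nonsurvivors`` =
    FP/(FP+TN). Samples with unknown outcome or unevaluable predictions are
    excluded from the counts and tallied separately.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_unknown_outcome: int = 0
    n_unevaluable: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def false_positives(self) -> int:
        return self.fp

    @property
    def false_discovery_fraction(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else 0.0

    @property
    def fpr_among_nonsurvivors(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "n_evaluated": self.n_evaluated,
            "n_unknown_outcome": self.n_unknown_outcome,
            "n_unevaluable": self.n_unevaluable,
            "sensitivity": self.sensitivity,
            "false_positives": self.false_positives,
            "false_discovery_fraction": self.false_discovery_fraction,
            "fpr_among_nonsurvivors": self.fpr_among_nonsurvivors,
        }


def apply_rule(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    rule: RuleSpec,
) -> pd.Series:
    """Per-sample prediction: survivor / not_identified / unevaluable.

    A sample is unevaluable when any *enabled* clause lacks its input
    (missing composite or GBPs score, or missing SOFA), even if another
    clause would fire.
    """
    preds: dict[str, str] = {}
    vals = scores.values
    for r in records:
        inputs: list[tuple[float | None, float, bool]] = []  # (value, threshold, is_greater)
        if rule.use_composite:
            v = vals.at[r.sample_id, COMPOSITE] if (r.sample_id in vals.index and COMPOSITE in vals.columns) else None
            inputs.append((v, rule.composite_threshold, False))
        if rule.use_sofa:
            inputs.append((r.sofa, rule.sofa_threshold, False))
        if rule.use_gbps:
            v = vals.at[r.sample_id, "GBPs"] if (r.sample_id in vals.index and "GBPs" in vals.columns) else None
            inputs.append((v, rule.gbps_threshold, True))
        if any(v is None or (isinstance(v, float) and not math.isfinite(v)) for v, _, _ in inputs):
            preds[r.sample_id] = UNEVALUABLE
            continue
        fired = any((v > t) if gt else (v < t) for v, t, gt in inputs)
        preds[r.sample_id] = SURVIVOR if fired else NOT_IDENTIFIED
    return pd.Series(preds, name="prediction")


def evaluate_rule(predictions: pd.Series, records: Iterable[SampleRecord]) -> RuleEvaluation:
    """Confusion counts over samples with known outcome and evaluable prediction."""
    tp = fp = fn = tn = unk = unev = 0
    any_known = False
    for r in records:
        pred = predictions.get(r.sample_id, UNEVALUABLE)
        if r.outcome not in (SURVIVOR, NON_SURVIVOR):
            unk += 1
            continue
        any_known = True
        if pred == UNEVALUABLE:
            unev += 1
            continue
        positive = pred == SURVIVOR
        if r.outcome == SURVIVOR:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    if not any_known:
        raise RuleError("no samples with known outcome to evaluate")
    return RuleEvaluation(tp=tp, fp=fp, fn=fn, tn=tn, n_unknown_outcome=unk, n_unevaluable=unev)


def _composite_by_outcome(
    scores: PanelScores, records: Iterable[SampleRecord]
) -> tuple[np.ndarray, np.ndarray]:
    vals = scores.values
    if COMPOSITE not in vals.columns:
        raise RuleError("scores carry no composite column")
    surv, nonsurv, missing = [], [], []
    for r in records:
        if r.outcome not in (SURVIVOR, NON_SURVIVOR):
            continue
        v = vals.at[r.sample_id, COMPOSITE] if r.sample_id in vals.index else np.nan
        if not np.isfinite(v):
            missing.append(r.sample_id)
            continue
        (surv if r.outcome == SURVIVOR else nonsurv).append(float(v))
    if missing:
        raise RuleError(f"missing composite values for known-outcome sample(s): {missing}")
    return np.asarray(surv), np.asarray(nonsurv)


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    n_survivors: int
    n_nonsurvivors: int


def zero_fp_threshold(scores: PanelScores, records: Iterable[SampleRecord]) -> ThresholdResult:
    """Largest composite threshold admitting no known non-survivor.

    theta* is the minimum composite among non-survivors (composite < theta*
    is then free of false positives); the achieved sensitivity is the
    fraction of survivors below theta*.
    """
    records = list(records)
    surv, nonsurv = _composite_by_outcome(scores, records)
    if len(surv) == 0 or len(nonsurv) == 0:
        raise RuleError("need at least one known survivor and one known non-survivor")
    theta = float(nonsurv.min())
    sens = float((surv < theta).mean())
    return ThresholdResult(threshold=theta, sensitivity=sens,
                           n_survivors=len(surv), n_nonsurvivors=len(nonsurv))


def threshold_sweep(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Sensitivity and false-positive count of ``composite < theta`` over a
    threshold grid (defaults to the observed composite values plus 1.50)."""
    records = list(records)
    surv, nonsurv = _composite_by_outcome(scores, records)
    if grid is None:
        grid = np.unique(np.concatenate([surv, nonsurv, [1.50]]))
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise RuleError("empty threshold grid")
    rows = [
        {
            "theta": float(t),
            "sensitivity": float((surv < t).mean()) if len(surv) else 0.0,
            "fp": int((nonsurv < t).sum()),
        }
        for t in grid
    ]
    return pd.DataFrame(rows)
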