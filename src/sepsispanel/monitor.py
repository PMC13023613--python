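"""Serial monitoring of immune dysregulation across ICU time points.

Per-subject panel-score deltas between two time points, reversal-of-
dysregulation flags (a delta whose sign opposes the panel's sepsis
dysregulation direction), and responder/non-responder contrasts combining
within-group paired tests with the cross-group comparison of the later
responder time point against the earlier non-responder one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import SampleRecord
from .panels import COMPOSITE, GenePanel, PanelScores, panel_directions
from .stats import GroupComparison, paired_contrast, paired_deltas, two_group_contrast

logger = logging.getLogger(__name__)


class MonitoringError(ValueError):
    """No usable longitudinal data."""


@dataclass
class DeltaRecord:
    """One subject's panel-score change between two time points.

    ``reversal`` is True when the change opposes the panel's dysregulation
    direction (strictly nonzero), False when it does not, and None for
    bidirectional panels (direction 0), where a reversal is undefined.
    """

    subject_id: str
    panel: str
    timepoint_from: str
    timepoint_to: str
    delta: float
    reversal: bool | None = None


def compute_deltas(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    from_tp: str,
    to_tp: str,
    panels: Sequence[str] | None = None,
) -> list[DeltaRecord]:
    """score(to) − score(from) per subject and panel, complete subjects only."""
    records = list(records)
    if panels is None:
        panels = [c for c in scores.values.columns if c != COMPOSITE]
    out: list[DeltaRecord] = []
    complete_any = False
    for panel in panels:
        deltas, subjects, dropped = paired_deltas(scores, records, from_tp, to_tp, panel)
        if dropped:
            logger.info("compute_deltas %s: skipped %d subject(s) lacking a time point", panel, dropped)
        complete_any = complete_any or len(subjects) > 0
        out.extend(
            DeltaRecord(subject_id=s, panel=panel, timepoint_from=from_tp,
                        timepoint_to=to_tp, delta=float(d))
            for s, d in zip(subjects, deltas)
        )
    if not complete_any:
        raise MonitoringError(f"no subject has scores at both {from_tp!r} and {to_tp!r}")
    return out


def flag_reversals(
    deltas: Iterable[DeltaRecord],
    panels: Sequence[GenePanel] | None = None,
) -> tuple[list[DeltaRecord], dict[str, float]]:
    """Mark reversals and summarize the fraction reversed per directional panel.

    A reversal is a strictly nonzero delta whose sign is the negative of the
    panel's direction (e.g. NDrG, direction +1, decreasing). Bidirectional
    panels (ISGa, GBPs) are left unflagged and excluded from the summary,
    since opposite changes are expected across patients.
    """
    directions = panel_directions(panels)
    flagged: list[DeltaRecord] = []
    counts: dict[str, list[int]] = {}
    for d in deltas:
        direction = directions.get(d.panel, 0)
        if direction == 0:
            rev: bool | None = None
        else:
            rev = d.delta != 0 and (d.delta < 0) == (direction > 0)
        flagged.append(DeltaRecord(**{**d.__dict__, "reversal": rev}))
        if direction != 0:
            counts.setdefault(d.panel, []).append(int(bool(rev)))
    summary = {p: sum(v) / len(v) for p, v in counts.items() if v}
    return flagged, summary


def deltas_to_frame(deltas: Sequence[DeltaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": d.subject_id, "panel": d.panel,
                "from": d.timepoint_from, "to": d.timepoint_to,
                "delta": d.delta,
                "reversal": "" if d.reversal is None else d.reversal,
            }
            for d in deltas
        ]
    )


@dataclass
class ResponderContrast:
    """Within-group paired contrasts per panel plus the cross-group contrast
    of group_a at the later time point vs group_b at the earlier one."""

    within: dict[str, list[GroupComparison]]
    cross: list[GroupComparison]


def responder_contrast(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    group_a: str,
    group_b: str,
    timepoints: tuple[str, str],
    panels: Sequence[str] | None = None,
) -> ResponderContrast:
    """Treatment-response contrasts for two patient groups at two time points.

    ``timepoints`` is (earlier, later). The cross contrast mirrors the most
    discriminative comparison in responder analyses: group_a (typically the
    responders) at the later time point against group_b at the earlier one.
    """
    records = list(records)
    tp_early, tp_late = timepoints
    if panels is None:
        panels = [c for c in scores.values.columns if c != COMPOSITE]
    within: dict[str, list[GroupComparison]] = {}
    for g in (group_a, group_b):
        sub = [r for r in records if r.group == g]
        if not sub:
            raise MonitoringError(f"group {g!r} absent from records")
        within[g] = [paired_contrast(scores, sub, tp_early, tp_late, p) for p in panels]
    cross = [
        two_group_contrast(
            scores, records, group_b, group_a, p,
            timepoint_a=tp_early, timepoint_b=tp_late,
        )
        for p in panels
    ]
    return ResponderContrast(within=within, cross=cross)
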