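"""Summed percent-change inhibition scores and classification bands.

A transporter's inhibition score for one experiment is the plain sum of
the signed percent changes of its signature metabolites. Decreased
metabolites contribute negatively — nothing is folded by expected
direction — which is why the BCRP band (three decreasing members, one
increasing) is negative. Classification bands:

    Pgp interaction   score > 600
    MRP2 interaction  300 <= score <= 600
    BCRP interaction  score < 0

Flags are reported independently per transporter: the bands overlap in
practice (Pgp and MRP2 share signature members) and no precedence rule is
imposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import PercentChangeTable, SignatureSet, TRANSPORTERS

__all__ = [
    "ScoreThresholds",
    "ScoreResult",
    "InhibitionScoreReport",
    "inhibition_score",
    "classify",
    "score_report",
]


@dataclass(frozen=True)
class ScoreThresholds:
    """Published score bands for calling a transporter interaction."""

    pgp_min: float = 600.0
    mrp2_min: float = 300.0
    mrp2_max: float = 600.0
    bcrp_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.mrp2_min < self.mrp2_max:
            raise ValueError("mrp2_min must be below mrp2_max")


@dataclass(frozen=True)
class ScoreResult:
    """One transporter's score for one experiment, with panel bookkeeping."""

    score: float
    missing_members: list[str]
    n_members_used: int


@dataclass(frozen=True)
class InhibitionScoreReport:
    """Per-compound scores and interaction flags for all three transporters."""

    compound: str
    scores: dict[str, float]
    flags: dict[str, bool]
    missing_members: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "scores": self.scores,
            "flags": self.flags,
            "missing_members": self.missing_members,
        }


def inhibition_score(
    changes: PercentChangeTable,
    signature: SignatureSet,
    max_missing_fraction: float = 0.5,
) -> ScoreResult:
    """Sum of signature-member percent changes (signed, %-points).

    Members absent from the panel, or with an undefined percent change, are
    skipped and recorded; more than ``max_missing_fraction`` of the
    signature missing is an error because the score is then meaningless.
    """
    present, missing = [], []
    for met, _ in signature.members:
        if met in changes.metabolite_ids and np.isfinite(changes.percent_change(met)):
            present.append(met)
        else:
            missing.append(met)
    if len(missing) > max_missing_fraction * len(signature.members):
        raise ValueError(
            f"{len(missing)}/{len(signature.members)} signature members missing "
            f"for {signature.transporter}: {missing}"
        )
    score = float(sum(changes.percent_change(m) for m in present))
    return ScoreResult(score=score, missing_members=missing, n_members_used=len(present))


def classify(
    scores: Mapping[str, float], thresholds: ScoreThresholds | None = None
) -> dict[str, bool]:
    """Independent interaction flags from the three transporter scores.

    Boundary conventions follow the published wording: Pgp strict
    (score > 600), MRP2 inclusive on both ends (300 <= score <= 600), BCRP
    strict (score < 0).
    """
    thr = thresholds or ScoreThresholds()
    missing = [t for t in TRANSPORTERS if t not in scores]
    if missing:
        raise KeyError(f"scores missing for transporter(s): {missing}")
    return {
        "pgp": scores["pgp"] > thr.pgp_min,
        "mrp2": thr.mrp2_min <= scores["mrp2"] <= thr.mrp2_max,
        "bcrp": scores["bcrp"] < thr.bcrp_max,
    }


def score_report(
    experiments: Sequence[tuple[PercentChangeTable, str]],
    signatures: Mapping[str, SignatureSet],
    thresholds: ScoreThresholds | None = None,
) -> list[InhibitionScoreReport]:
    """Score and classify each experiment against all three signatures.

    ``experiments`` is a list of (percent-change table, compound label);
    one report per experiment, in input order.
    """
    for t in TRANSPORTERS:
        if t not in signatures:
            raise KeyError(f"signature for {t!r} not supplied")
    reports = []
    for changes, compound in experiments:
        scores, missing = {}, {}
        for t in TRANSPORTERS:
            res = inhibition_score(changes, signatures[t])
            scores[t] = res.score
            missing[t] = res.missing_members
        reports.append(
            InhibitionScoreReport(
                compound=compound,
                scores=scores,
                flags=classify(scores, thresholds),
                missing_members=missing,
            )
        )
    return reports


def report_frame(reports: Sequence[InhibitionScoreReport]) -> pd.DataFrame:
    """Tabular view of score reports (one row per compound)."""
    rows = []
    for r in reports:
        row = {"compound": r.compound}
        for t in TRANSPORTERS:
            row[f"{t}_score"] = r.scores[t]
            row[f"{t}_flag"] = r.flags[t]
            row[f"{t}_missing"] = ";".join(r.missing_members.get(t, []))
        rows.append(row)
    return pd.DataFrame(rows)


def reports_to_json(reports: Sequence[InhibitionScoreReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)
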