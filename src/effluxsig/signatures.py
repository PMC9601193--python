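"""Per-metabolite statistics and consensus efflux-transporter signatures.

The unit of evidence is the percent change of a metabolite's normalized
intracellular level between treated and control cells,

    100 × (mean_treated − mean_control) / mean_control,

with an unpaired two-sided Mann–Whitney test per metabolite (no
multiplicity correction gates anything; a Benjamini–Hochberg column is
carried along for reference). A metabolite enters a transporter's
signature only when it clears the VIP threshold in *every* supporting
experiment — each chemically distinct inhibitor and the transporter
knockout — with the same direction of change throughout, so that the
signature reflects transporter activity rather than off-target effects of
any one compound.

Reference signatures for Pgp (11 metabolites, all increased), BCRP
(glutamate, hypoxanthine, xanthine decreased; pantothenate increased) and
MRP2 (nine metabolites, acetylcarnitine decreased) ship with the package.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .opls import VipResult
from .peaks import PeakTable

__all__ = [
    "PercentChangeTable",
    "SignatureSet",
    "percent_change_table",
    "mann_whitney_u",
    "derive_signature",
    "concentration_trend",
    "reference_signatures",
    "significance_tier",
]

TRANSPORTERS = ("pgp", "bcrp", "mrp2")


def significance_tier(p: float) -> str:
    """Star notation: **** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not np.isfinite(p):
        return "ns"
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class PercentChangeTable:
    """Per-metabolite percent change and Mann–Whitney statistics.

    ``table`` is indexed by metabolite with columns percent_change,
    u_statistic, p_value, p_adjusted, tier and undefined (True where the
    control mean was zero and the percent change has no value).
    """

    table: pd.DataFrame

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    def percent_change(self, metabolite: str) -> float:
        return float(self.table.loc[metabolite, "percent_change"])

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "metabolite"
        out.to_csv(path)


@dataclass(frozen=True)
class SignatureSet:
    """A transporter's metabolomic signature: members with expected direction."""

    transporter: str
    members: list[tuple[str, str]]  # (metabolite, "up"/"down")
    provenance: dict[str, list[str]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m for m, _ in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolites in signature")
        for _, d in self.members:
            if d not in ("up", "down"):
                raise ValueError(f"direction must be up/down, got {d!r}")

    @property
    def metabolites(self) -> list[str]:
        return [m for m, _ in self.members]

    def direction(self, metabolite: str) -> str:
        return dict(self.members)[metabolite]

    def to_json(self) -> str:
        return json.dumps(
            {
                "transporter": self.transporter,
                "members": [{"metabolite": m, "direction": d} for m, d in self.members],
                "provenance": self.provenance,
                "excluded": self.excluded,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureSet":
        obj = json.loads(text)
        return cls(
            transporter=obj["transporter"],
            members=[(m["metabolite"], m["direction"]) for m in obj["members"]],
            provenance=obj.get("provenance", {}),
            excluded=obj.get("excluded", {}),
        )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of two independent samples.

    Exact null distribution when both groups have <= 8 observations and the
    pooled data are tie-free; otherwise the normal approximation with
    midrank tie correction and continuity correction. Returns (U of the
    first sample, two-sided p).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def percent_change_table(table: PeakTable, labels: np.ndarray) -> PercentChangeTable:
    """Percent change treated vs control plus Mann–Whitney p per metabolite.

    ``labels`` is the binary class vector (1 = treated). A metabolite whose
    control mean is zero is marked undefined (NaN percent change) rather
    than dropped.
    """
    y = np.asarray(labels).ravel().astype(int)
    if y.size != table.n_samples:
        raise ValueError("labels length does not match number of samples")
    rows = []
    for met in table.metabolite_ids:
        col = table.areas[met].to_numpy(dtype=float)
        treated = col[y == 1]
        control = col[y == 0]
        treated = treated[~np.isnan(treated)]
        control = control[~np.isnan(control)]
        mc = control.mean() if control.size else np.nan
        mt = treated.mean() if treated.size else np.nan
        undefined = not np.isfinite(mc) or mc == 0 or not np.isfinite(mt)
        pct = np.nan if undefined else 100.0 * (mt - mc) / mc
        if treated.size and control.size:
            u, p = mann_whitney_u(treated, control)
        else:
            u, p = np.nan, np.nan
        rows.append((met, pct, u, p, undefined))
    df = pd.DataFrame(
        rows, columns=["metabolite", "percent_change", "u_statistic", "p_value", "undefined"]
    ).set_index("metabolite")
    padj = np.full(len(df), np.nan)
    ok = np.isfinite(df["p_value"].to_numpy())
    if ok.any():
        padj[ok] = stats.false_discovery_control(df["p_value"].to_numpy()[ok])
    df["p_adjusted"] = padj
    df["tier"] = [significance_tier(p) for p in df["p_value"]]
    return PercentChangeTable(
        table=df[["percent_change", "u_statistic", "p_value", "p_adjusted", "tier", "undefined"]]
    )


def derive_signature(
    experiments: Sequence[tuple[PercentChangeTable, VipResult, str]],
    transporter: str = "unspecified",
    vip_threshold: float = 0.75,
) -> SignatureSet:
    """Consensus signature across inhibitor and knockout experiments.

    A metabolite is admitted iff its VIP score is strictly greater than
    ``vip_threshold`` in every experiment and its percent change has the
    same (nonzero) sign in every experiment; the shared sign becomes the
    recorded direction. Requires at least one inhibitor and one knockout
    experiment. Metabolites that clear the VIP bar everywhere but change
    direction between experiments are excluded with a logged reason. The
    result is independent of the order in which experiments are listed.
    """
    kinds = {kind for _, _, kind in experiments}
    if "inhibitor" not in kinds or "knockout" not in kinds:
        raise ValueError("need at least one inhibitor and one knockout experiment")
    common: set[str] | None = None
    for pct, vip, _ in experiments:
        mets = set(pct.metabolite_ids)
        if set(vip.metabolite_ids) != mets:
            raise ValueError("experiment percent-change and VIP panels disagree")
        common = mets if common is None else common & mets

    members: list[tuple[str, str]] = []
    provenance: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    labels = [f"{kind}_{i}" for i, (_, _, kind) in enumerate(experiments)]
    for met in sorted(common):
        vips = [vip.as_dict()[met] for _, vip, _ in experiments]
        if not all(v > vip_threshold for v in vips):
            continue
        signs = [np.sign(pct.percent_change(met)) for pct, _, _ in experiments]
        if any(s == 0 or not np.isfinite(s) for s in signs):
            excluded[met] = "zero or undefined percent change in a supporting experiment"
            continue
        if len(set(signs)) > 1:
            excluded[met] = "direction conflict between supporting experiments"
            continue
        members.append((met, "up" if signs[0] > 0 else "down"))
        provenance[met] = sorted(labels)
    return SignatureSet(
        transporter=transporter, members=members, provenance=provenance, excluded=excluded
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact Spearman p by full enumeration of rank permutations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def concentration_trend(
    tables: Sequence[PercentChangeTable],
    metabolite: str,
    doses: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Spearman trend of a metabolite's percent change across a dose series.

    ``tables`` are ordered by increasing dose (explicit dose values are
    optional; only ranks matter). Returns (rho, two-sided p), with an exact
    enumeration p-value for <= 8 dose levels. A constant series has no
    defined rank correlation and is reported as (0, 1).
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 dose levels for a trend")
    changes = []
    for t in tables:
        if metabolite not in t.metabolite_ids:
            raise KeyError(f"metabolite {metabolite!r} missing from a dose table")
        changes.append(t.percent_change(metabolite))
    x = np.asarray(doses, dtype=float) if doses is not None else np.arange(len(tables), dtype=float)
    if len(x) != len(changes):
        raise ValueError("doses length does not match number of tables")
    y = np.asarray(changes, dtype=float)
    if np.unique(y).size == 1 or np.unique(x).size == 1:
        return 0.0, 1.0
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= 8:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def reference_signatures() -> dict[str, SignatureSet]:
    """The packaged Pgp / BCRP / MRP2 signatures used for inhibition scoring."""
    out = {}
    for name in TRANSPORTERS:
        text = resources.files("effluxsig").joinpath(f"signatures/{name}.json").read_text()
        out[name] = SignatureSet.from_json(text)
    return out
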