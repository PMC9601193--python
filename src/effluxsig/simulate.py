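"""Seeded synthetic LC-MS peak-area experiments with planted transporter effects.

The generator emulates the statistical shape of a targeted intracellular
metabolomics experiment on transwell-grown Caco-2 cells:

* per-metabolite baseline peak areas drawn log-normally, with medians
  spanning ~3.5 orders of magnitude across the panel;
* a per-sample multiplicative size factor (CV ~10%) standing in for
  extraction-volume and cell-count variation — this is exactly what
  total-sum normalization removes;
* multiplicative replicate noise on every cell of the matrix;
* planted fold-change effects on designated signature metabolites in the
  treated group, applied before the size factor so the normalized data
  carry the effect;
* occasional outlier samples whose per-metabolite areas receive a heavy
  (typical 5x) multiplicative distortion that survives normalization;
* a spiked instrument-control analyte of near-constant area (CV ~1%),
  which tracks the instrument rather than the cells and is excluded from
  normalization downstream.

Signature metabolites are modelled as low-to-mid-abundance analytes while
a few filler analytes dominate the total signal, as in real targeted
panels; planted effects therefore perturb the total-sum denominator only
mildly. Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .peaks import PeakTable
from .signatures import reference_signatures
from .transport import TransportSeries

__all__ = [
    "Scenario",
    "GroundTruth",
    "CONTROL_ANALYTE",
    "generate_peak_table",
    "builtin_scenarios",
    "generate_experiment_set",
    "generate_dose_series",
    "generate_transport_series",
    "load_scenario",
]

#: Name of the spiked instrument-control analyte added to every table.
CONTROL_ANALYTE = "olomoucine"

_CONTROL_AREA = 5.0e5
_CONTROL_CV = 0.01
_SIZE_FACTOR_CV = 0.10
_OUTLIER_LOG_SIGMA = float(np.log(5.0))

# Default planted effect magnitudes (calibration choices, not measured values).
UP_FOLD = 1.6
DOWN_FOLD = 0.6

# log10 baseline-median ranges: signature analytes are low-to-mid abundance,
# fillers span the full dynamic range and dominate the total signal.
_EFFECT_LOG10_RANGE = (4.3, 5.3)
_FILLER_LOG10_RANGE = (4.0, 7.5)


@dataclass(frozen=True)
class Scenario:
    """One simulated treatment-vs-control experiment design."""

    name: str
    transporter: str  # pgp | bcrp | mrp2 | none
    role: str  # inhibitor | knockout | substrate | vehicle
    effects: dict[str, float] = field(default_factory=dict)
    n_treated: int = 6
    n_control: int = 6
    noise_cv: float = 0.10
    outlier_rate: float = 0.05
    dose_series: list[tuple[float, float]] | None = None  # (dose, attenuation)

    def __post_init__(self) -> None:
        if self.transporter not in ("pgp", "bcrp", "mrp2", "none"):
            raise ValueError(f"unknown transporter {self.transporter!r}")
        if self.role not in ("inhibitor", "knockout", "substrate", "vehicle"):
            raise ValueError(f"unknown role {self.role!r}")
        for met, fc in self.effects.items():
            if fc <= 0:
                raise ValueError(f"fold-change for {met!r} must be > 0, got {fc}")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must be in [0, 0.5)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "transporter": self.transporter,
            "role": self.role,
            "effects": dict(self.effects),
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "noise_cv": self.noise_cv,
            "outlier_rate": self.outlier_rate,
        }
        if self.dose_series is not None:
            d["dose_series"] = [list(x) for x in self.dose_series]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        dose = d.get("dose_series")
        return cls(
            name=d["name"],
            transporter=d["transporter"],
            role=d["role"],
            effects={k: float(v) for k, v in d.get("effects", {}).items()},
            n_treated=int(d.get("n_treated", 6)),
            n_control=int(d.get("n_control", 6)),
            noise_cv=float(d.get("noise_cv", 0.10)),
            outlier_rate=float(d.get("outlier_rate", 0.05)),
            dose_series=[tuple(map(float, x)) for x in dose] if dose else None,
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the recovery-test oracle for a generated table."""

    altered_metabolites: list[tuple[str, str, float]]  # (metabolite, up/down, fold)
    outlier_samples: list[str]

    @property
    def altered_names(self) -> list[str]:
        return [m for m, _, _ in self.altered_metabolites]


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a YAML (or JSON — valid YAML) file."""
    with open(path) as fh:
        return Scenario.from_dict(yaml.safe_load(fh))


def _cv_to_sigma(cv: float) -> float:
    """Log-normal sigma giving a multiplicative coefficient of variation cv."""
    return float(np.sqrt(np.log1p(cv**2)))


def _panel(effects: dict[str, float], n_metabolites: int) -> tuple[list[str], set[str]]:
    """Build the analyte panel: signature metabolites first, then fillers.

    Filler names are deterministic (``analyte_001`` ...), so custom
    scenarios can plant effects on them; an effect naming anything outside
    the generated panel is an error.
    """
    signature_union: list[str] = []
    for sig in reference_signatures().values():
        for met in sig.metabolites:
            if met not in signature_union:
                signature_union.append(met)
    if n_metabolites < len(effects):
        raise ValueError(
            f"n_metabolites={n_metabolites} below the {len(effects)} metabolites named in effects"
        )
    panel = sorted(signature_union)[:n_metabolites]
    i = 1
    while len(panel) < n_metabolites:
        panel.append(f"analyte_{i:03d}")
        i += 1
    unknown = sorted(set(effects) - set(panel))
    if unknown:
        raise ValueError(f"effect metabolite(s) not in generated panel: {unknown}")
    known = set(signature_union) | set(effects)
    return panel, known


def generate_peak_table(
    scenario: Scenario,
    n_metabolites: int = 80,
    seed: int = 0,
) -> tuple[PeakTable, GroundTruth]:
    """Simulate one treated-vs-control peak-area table plus its ground truth.

    The returned table contains ``n_metabolites`` cellular analytes (the
    scenario's effect metabolites, the packaged signature metabolites, and
    generic fillers) plus the spiked instrument-control analyte. Identical
    (scenario, n_metabolites, seed) calls reproduce the table bit-for-bit.
    """
    panel, known = _panel(scenario.effects, n_metabolites)
    rng = np.random.default_rng(seed)
    lo_e, hi_e = _EFFECT_LOG10_RANGE
    lo_f, hi_f = _FILLER_LOG10_RANGE
    log10_median = np.array(
        [
            rng.uniform(lo_e, hi_e) if met in known else rng.uniform(lo_f, hi_f)
            for met in panel
        ]
    )
    baseline = 10.0**log10_median

    n_t, n_c = scenario.n_treated, scenario.n_control
    sample_ids = [f"treated_{i+1}" for i in range(n_t)] + [
        f"control_{i+1}" for i in range(n_c)
    ]
    groups = ["treated"] * n_t + ["control"] * n_c
    n = n_t + n_c
    p = len(panel)

    fold = np.ones(p)
    for j, met in enumerate(panel):
        if met in scenario.effects:
            fold[j] = scenario.effects[met]

    size = rng.lognormal(mean=0.0, sigma=_cv_to_sigma(_SIZE_FACTOR_CV), size=n)
    noise = rng.lognormal(
        mean=0.0, sigma=_cv_to_sigma(scenario.noise_cv), size=(n, p)
    )
    treated_mask = np.array([g == "treated" for g in groups])
    areas = baseline[None, :] * np.where(treated_mask[:, None], fold[None, :], 1.0)
    areas = areas * size[:, None] * noise

    outlier_flags = rng.random(n) < scenario.outlier_rate
    if outlier_flags.any():
        distort = rng.lognormal(
            mean=0.0, sigma=_OUTLIER_LOG_SIGMA, size=(int(outlier_flags.sum()), p)
        )
        areas[outlier_flags] = areas[outlier_flags] * distort

    control_col = _CONTROL_AREA * rng.lognormal(
        mean=0.0, sigma=_cv_to_sigma(_CONTROL_CV), size=n
    )

    df = pd.DataFrame(areas, index=sample_ids, columns=panel)
    df[CONTROL_ANALYTE] = control_col
    table = PeakTable(
        areas=df, groups=pd.Series(groups, index=sample_ids, name="group")
    )
    truth = GroundTruth(
        altered_metabolites=[
            (m, "up" if fc > 1 else "down", fc)
            for m, fc in sorted(scenario.effects.items())
            if fc != 1.0
        ],
        outlier_samples=[s for s, o in zip(sample_ids, outlier_flags) if o],
    )
    return table, truth


def builtin_scenarios() -> dict[str, Scenario]:
    """Packaged default scenarios, one per transporter/role combination.

    Planted effects follow the packaged signature directions; fold changes
    default to 1.6 for increased and 0.6 for decreased metabolites
    (calibration choices — real per-metabolite magnitudes are not pinned
    down numerically). All scenarios use 6 replicates per group.
    """
    sigs = reference_signatures()

    def effects_for(transporter: str) -> dict[str, float]:
        return {
            met: (UP_FOLD if direction == "up" else DOWN_FOLD)
            for met, direction in sigs[transporter].members
        }

    out: dict[str, Scenario] = {}
    for t in ("pgp", "bcrp", "mrp2"):
        out[f"{t}_inhibitor"] = Scenario(
            name=f"{t}_inhibitor", transporter=t, role="inhibitor", effects=effects_for(t)
        )
        out[f"{t}_ko"] = Scenario(
            name=f"{t}_ko", transporter=t, role="knockout", effects=effects_for(t)
        )
    out["substrate_nonInhibitor"] = Scenario(
        name="substrate_nonInhibitor", transporter="none", role="substrate", effects={}
    )
    out["vehicle"] = Scenario(
        name="vehicle", transporter="none", role="vehicle", effects={}
    )
    return out


_INHIBITOR_LABELS = {
    "pgp": ["zosuquidar", "ritonavir", "valspodar"],
    "bcrp": ["ko143", "fumitremorgin_c", "novobiocin"],
    "mrp2": ["mk571", "benzbromarone", "probenecid"],
}


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 1000003 + 7919 * i + 1) % (2**31))


def generate_experiment_set(
    transporter: str,
    seed: int = 0,
    n_metabolites: int = 80,
    n_inhibitors: int = 3,
) -> list[tuple[PeakTable, GroundTruth, dict]]:
    """Simulate the signature-derivation design: 3 inhibitor runs + 1 KO run.

    All experiments share the transporter's planted effect set but use
    distinct sub-seeds, so their noise realizations differ. Metadata labels
    each experiment with its compound and kind (inhibitor/knockout).
    """
    if transporter not in ("pgp", "bcrp", "mrp2"):
        raise ValueError(f"unknown transporter {transporter!r}")
    scenarios = builtin_scenarios()
    out = []
    for i in range(n_inhibitors):
        label = (
            _INHIBITOR_LABELS[transporter][i]
            if i < len(_INHIBITOR_LABELS[transporter])
            else f"inhibitor_{i+1}"
        )
        scen = replace(scenarios[f"{transporter}_inhibitor"], name=label)
        table, truth = generate_peak_table(scen, n_metabolites, _sub_seed(seed, i))
        out.append((table, truth, {"kind": "inhibitor", "compound": label}))
    ko = scenarios[f"{transporter}_ko"]
    table, truth = generate_peak_table(ko, n_metabolites, _sub_seed(seed, n_inhibitors))
    out.append(
        (table, truth, {"kind": "knockout", "compound": f"{transporter}_ko"})
    )
    return out


def generate_dose_series(
    scenario: Scenario,
    n_metabolites: int = 80,
    seed: int = 0,
) -> list[tuple[float, PeakTable, GroundTruth]]:
    """Simulate a concentration series with attenuated effects per dose.

    Each (dose, attenuation) entry scales every planted fold change on the
    log scale (fold**attenuation), so attenuation 1 is the full effect and
    0 is no effect; the series emulates a concentration-dependent response.
    """
    if not scenario.dose_series:
        raise ValueError("scenario has no dose_series")
    out = []
    for i, (dose, atten) in enumerate(scenario.dose_series):
        effects = {m: float(fc**atten) for m, fc in scenario.effects.items()}
        scen = replace(scenario, effects=effects, dose_series=None,
                       name=f"{scenario.name}_dose{i}")
        table, truth = generate_peak_table(scen, n_metabolites, _sub_seed(seed, i))
        out.append((float(dose), table, truth))
    return out


def generate_transport_series(
    papp_true: float,
    c0: float = 10.0,
    vr: float = 0.3,
    area: float = 0.11,
    n_timepoints: int = 5,
    noise_cv: float = 0.0,
    seed: int = 0,
    direction: str = "AtoB",
) -> TransportSeries:
    """Simulate a receiver-compartment concentration time course.

    The receiver concentration rises linearly at papp_true * area * c0 / vr
    (µM/s), sampled at ``n_timepoints`` evenly spaced times inside the
    sink-condition window (receiver kept below ~8% of the donor
    concentration), with multiplicative log-normal noise of coefficient of
    variation ``noise_cv``.
    """
    if papp_true < 0:
        raise ValueError("papp_true must be >= 0")
    for name, v in (("c0", c0), ("vr", vr), ("area", area)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    slope = papp_true * area * c0 / vr  # µM/s
    t_end = 0.08 * c0 / slope if slope > 0 else 3600.0
    times = np.linspace(0.0, t_end, n_timepoints)
    conc = slope * times
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        conc = conc * rng.lognormal(
            mean=0.0, sigma=_cv_to_sigma(noise_cv), size=n_timepoints
        )
    return TransportSeries(
        direction=direction,
        times=times,
        receiver_concentration=conc,
        c0=c0,
        vr=vr,
        area=area,
    )
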