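"""End-to-end orchestration: normalize → QC → OPLS-DA → signature → score.

The per-experiment path mirrors the assay's analysis order: instrument QC
on raw areas, total-sum normalization (control analyte excluded),
multivariate outlier elimination, cross-validated orthogonal-component
selection, the final OPLS-DA fit with VIP scores, and the per-metabolite
percent-change table. :func:`run_pipeline` drives that path over a
manifest of experiments, scores each against the packaged signatures and
persists every intermediate for auditability.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .opls import (
    OplsModel,
    OutlierReport,
    VipResult,
    cross_validated_q2,
    fit_opls_da,
    permutation_test,
    remove_outliers_and_refit,
    select_n_orthogonal,
    vip_scores,
)
from .peaks import (
    PeakTable,
    QCReport,
    qc_instrument_control,
    read_peak_table,
    total_sum_normalize,
    write_peak_table,
)
from .scoring import (
    InhibitionScoreReport,
    ScoreThresholds,
    report_frame,
    reports_to_json,
    score_report,
)
from .signatures import (
    PercentChangeTable,
    SignatureSet,
    derive_signature,
    percent_change_table,
    reference_signatures,
)
from .simulate import CONTROL_ANALYTE

__all__ = [
    "ExperimentAnalysis",
    "AnalysisOptions",
    "RunManifest",
    "analyze_experiment",
    "derive_signature_from_tables",
    "run_pipeline",
    "validate_manifest",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable knobs of the per-experiment analysis."""

    control_analyte: str | None = CONTROL_ANALYTE
    control_cv_limit: float = 0.2
    scaling: str = "unit_variance"
    alpha: float = 0.001  # outlier-elimination level; diagnostics report at 0.05
    max_outlier_rounds: int = 3
    max_orthogonal: int = 2
    cv_folds: int = 7
    vip_threshold: float = 0.75
    permutations: int = 0  # 0 disables the permutation test
    seed: int = 0


@dataclass(frozen=True)
class ExperimentAnalysis:
    """Everything the pipeline computes for one treated-vs-control table."""

    normalized: PeakTable
    labels: np.ndarray
    model: OplsModel
    q2: float
    n_orthogonal: int
    vip: VipResult
    percent_changes: PercentChangeTable
    outliers: OutlierReport
    qc: QCReport | None
    removed_samples: list[str]


def analyze_experiment(
    table: PeakTable,
    options: AnalysisOptions | None = None,
    positive_group: str = "treated",
) -> ExperimentAnalysis:
    """Run the single-experiment analysis path on a raw peak table."""
    opt = options or AnalysisOptions()
    qc = None
    control = opt.control_analyte
    if control is not None and control in table.areas.columns:
        qc = qc_instrument_control(table, control, cv_limit=opt.control_cv_limit)
    else:
        control = None
    norm = total_sum_normalize(table, control_analyte=control)
    labels = norm.binary_labels(positive=positive_group)
    cleaned, _, out_rep = remove_outliers_and_refit(
        norm,
        labels,
        alpha=opt.alpha,
        max_rounds=opt.max_outlier_rounds,
        scaling=opt.scaling,
    )
    removed = [s for s in norm.sample_ids if s not in set(cleaned.sample_ids)]
    labels = cleaned.binary_labels(positive=positive_group)
    k = select_n_orthogonal(
        cleaned,
        labels,
        max_k=opt.max_orthogonal,
        cv_folds=min(opt.cv_folds, cleaned.n_samples),
        seed=opt.seed,
        scaling=opt.scaling,
    )
    model = fit_opls_da(cleaned, labels, n_orthogonal=k, scaling=opt.scaling)
    q2 = cross_validated_q2(
        cleaned,
        labels,
        n_orthogonal=k,
        cv_folds=min(opt.cv_folds, cleaned.n_samples),
        seed=opt.seed,
        scaling=opt.scaling,
    )
    vip = vip_scores(model, cleaned, labels, threshold=opt.vip_threshold)
    pct = percent_change_table(cleaned, labels)
    final_outliers = OutlierReport(
        sample_ids=out_rep.sample_ids,
        dmodx=out_rep.dmodx,
        dmodx_critical=out_rep.dmodx_critical,
        t2=out_rep.t2,
        t2_critical=out_rep.t2_critical,
        flagged=out_rep.flagged,
    )
    return ExperimentAnalysis(
        normalized=cleaned,
        labels=labels,
        model=model,
        q2=q2,
        n_orthogonal=k,
        vip=vip,
        percent_changes=pct,
        outliers=final_outliers,
        qc=qc,
        removed_samples=removed,
    )


def derive_signature_from_tables(
    experiments: Sequence[tuple[PeakTable, str]],
    transporter: str,
    options: AnalysisOptions | None = None,
) -> tuple[SignatureSet, list[ExperimentAnalysis]]:
    """Analyze raw (table, kind) experiments and derive the consensus signature."""
    opt = options or AnalysisOptions()
    analyses = [analyze_experiment(t, opt) for t, _ in experiments]
    sig = derive_signature(
        [
            (a.percent_changes, a.vip, kind)
            for a, (_, kind) in zip(analyses, experiments)
        ],
        transporter=transporter,
        vip_threshold=opt.vip_threshold,
    )
    return sig, analyses


@dataclass(frozen=True)
class RunManifest:
    """Validated description of a multi-experiment analysis run."""

    experiments: list[dict]
    output_dir: Path
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        problems = _manifest_problems(raw, base=Path(path).parent)
        if problems:
            raise ValueError("invalid manifest:\n" + "\n".join(f"- {p}" for p in problems))
        opts = raw.get("options", {})
        thr = opts.pop("thresholds", {})
        known = {f for f in AnalysisOptions.__dataclass_fields__}
        return cls(
            experiments=raw["experiments"],
            output_dir=Path(raw["output_dir"]),
            options=AnalysisOptions(**{k: v for k, v in opts.items() if k in known}),
            thresholds=ScoreThresholds(**thr),
        )


def _manifest_problems(raw: object, base: Path) -> list[str]:
    problems: list[str] = []
    if not isinstance(raw, dict):
        return ["manifest must be a mapping"]
    exps = raw.get("experiments")
    if not isinstance(exps, list) or not exps:
        problems.append("experiments must be a non-empty list")
        exps = []
    for i, exp in enumerate(exps):
        label = exp.get("compound", f"experiment {i}") if isinstance(exp, dict) else f"experiment {i}"
        if not isinstance(exp, dict):
            problems.append(f"{label}: must be a mapping")
            continue
        path = exp.get("peak_table")
        if not path:
            problems.append(f"{label}: missing peak_table path")
        elif not (base / path).exists() and not Path(path).exists():
            problems.append(f"{label}: peak_table {path!r} does not exist")
        design = exp.get("design")
        if design and not (base / design).exists() and not Path(design).exists():
            problems.append(f"{label}: design {design!r} does not exist")
    if "output_dir" not in raw:
        problems.append("missing output_dir")
    opts = raw.get("options", {})
    if isinstance(opts, dict):
        vt = opts.get("vip_threshold")
        if vt is not None and vt < 0:
            problems.append("vip_threshold must be >= 0")
        alpha = opts.get("alpha")
        if alpha is not None and not 0 < alpha < 1:
            problems.append("alpha must be in (0, 1)")
    return problems


def validate_manifest(path: str | Path) -> list[str]:
    """Return human-readable manifest problems (empty when valid)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _manifest_problems(raw, base=Path(path).parent)


def _load_experiment_table(exp: dict, base: Path) -> PeakTable:
    path = Path(exp["peak_table"])
    if not path.exists():
        path = base / path
    table = read_peak_table(path, dialect=exp.get("dialect", "wide_csv"))
    design = exp.get("design")
    if design:
        dpath = Path(design)
        if not dpath.exists():
            dpath = base / dpath
        ddf = pd.read_csv(dpath).set_index("sample")
        groups = ddf["group"].astype(str).reindex(table.areas.index)
        if groups.isna().any():
            missing = list(groups[groups.isna()].index)
            raise ValueError(f"design {design!r} lacks group for samples {missing}")
        table = PeakTable(areas=table.areas, groups=groups)
    return table


def _model_summary(a: ExperimentAnalysis) -> dict:
    return {
        "r2x": a.model.r2x,
        "r2y": a.model.r2y,
        "q2": a.q2,
        "n_orthogonal": a.n_orthogonal,
        "removed_samples": a.removed_samples,
        "flagged": [{"sample": s, "criterion": c} for s, c in a.outliers.flagged],
        "qc": None
        if a.qc is None
        else {"control_cv": a.qc.control_cv, "pass": a.qc.passed},
    }


def run_pipeline(manifest: RunManifest, manifest_dir: Path | None = None) -> dict:
    """Execute the full analysis over a manifest; returns the run summary.

    Every stage writes its intermediate under ``output_dir/<compound>/``
    (normalized table, model summary JSON, VIP CSV sorted descending,
    percent-change CSV) and the run-level score report and provenance
    record land at the top level. Re-running the same manifest reproduces
    identical outputs.
    """
    base = manifest_dir or Path(".")
    out_dir = manifest.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    signatures = reference_signatures()
    analyses: list[tuple[ExperimentAnalysis, dict]] = []
    for exp in manifest.experiments:
        compound = exp.get("compound", Path(exp["peak_table"]).stem)
        try:
            table = _load_experiment_table(exp, base)
            analysis = analyze_experiment(table, manifest.options)
        except Exception as err:
            raise RuntimeError(
                f"stage 'analyze' failed for experiment {compound!r}: {err}"
            ) from err
        analyses.append((analysis, {**exp, "compound": compound}))
        exp_dir = out_dir / compound
        exp_dir.mkdir(parents=True, exist_ok=True)
        write_peak_table(analysis.normalized, exp_dir / "normalized.csv")
        (exp_dir / "model.json").write_text(json.dumps(_model_summary(analysis), indent=2))
        vip_df = pd.DataFrame(
            {"metabolite": analysis.vip.metabolite_ids, "vip": analysis.vip.vip}
        ).sort_values("vip", ascending=False)
        vip_df.to_csv(exp_dir / "vip.csv", index=False)
        analysis.percent_changes.to_csv(exp_dir / "percent_change.csv")

    reports = score_report(
        [(a.percent_changes, meta["compound"]) for a, meta in analyses],
        signatures,
        manifest.thresholds,
    )
    report_frame(reports).to_csv(out_dir / "score_report.csv", index=False)
    (out_dir / "score_report.json").write_text(reports_to_json(reports))
    provenance = {
        "package": "effluxsig",
        "version": __version__,
        "python": platform.python_version(),
        "seed": manifest.options.seed,
        "vip_threshold": manifest.options.vip_threshold,
        "alpha": manifest.options.alpha,
        "thresholds": vars(manifest.thresholds),
        "n_experiments": len(analyses),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "reports": reports,
        "analyses": [a for a, _ in analyses],
        "output_dir": str(out_dir),
        "provenance": provenance,
    }
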