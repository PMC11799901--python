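"""End-to-end study orchestration: the full PSQA replica on a synthetic cohort.

``run_study`` simulates a cohort of paired CT / clinical-sCT phantoms,
recalculates dose on every image set with monitor units unchanged, computes
the per-patient metrics (mean error per structure, DVH deltas for the PTV,
3D local gamma pass rate) of the clinical sCT against each configured
reference (the CT and emulated QA generators), applies tolerance limits,
builds the per-generator confusion ledger and sensitivity/specificity
matrix, and optionally runs the DRR-based positioning comparison.

Generator emulation (defaults):

* ``CT`` - the ground-truth anatomy itself.
* ``sCT_QA_AI_1`` - a faithful generator (noise only) that *refuses*
  patients with metal artifacts; refused patients are excluded from its
  confusion counts and logged.
* ``sCT_QA_AI_2`` - faithful except near-sinus patients, where it
  mispredicts the sinus cavity.
* ``sCT_QA_BD`` - bulk-density assignment, soft-tissue class calibrated so
  its planted phantom shows a target mean PTV dose error (default -1%).

Everything is deterministic for a fixed master seed, and report files are
written with stable formatting so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from sctqa import classification as cls
from sctqa import dvh as dvhmod
from sctqa.dose import DensityCalibration, PlanSpec, compute_plan_dose, default_plan
from sctqa.geometry import StructureMask, Volume
from sctqa.metrics import GammaCriteria, MetricReport, gamma_map, mean_error
from sctqa.phantom import (
    CohortSpec,
    ErrorMode,
    PhantomPair,
    PhantomSpec,
    calibrate_bias,
    generate_phantom_pair,
    generate_cohort,
)
from sctqa.positioning import (
    ProjectionGeometry,
    RigidPose,
    positioning_delta,
    register_2d2d,
    register_3d_rigid,
    simulate_kv_pair,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "summarize_boxplot", "demo_cohort"]

log = logging.getLogger("sctqa")

POINT_METRICS = ("ME_PTV", "DeltaD2%_PTV", "DeltaD95%_PTV", "DeltaD98%_PTV", "DeltaDmean_PTV")
GAMMA_METRIC = "GammaPassRate"
QA_REFERENCES = ("sCT_QA_AI_1", "sCT_QA_AI_2", "sCT_QA_BD")


def demo_cohort(
    n_patients: int = 20,
    master_seed: int = 0,
    base_spec: PhantomSpec | None = None,
    n_metal: int = 2,
    n_bulk: int = 2,
    bd_bias_hu: float = 0.0,
) -> CohortSpec:
    """The default demo cohort: mostly faithful sCTs plus planted failures.

    Metal-artifact patients sit at the end-quarter ids (like the clinical
    cohort's single implant patient); bulk-density patients right before.
    """
    base = base_spec or PhantomSpec()
    if (n_metal or n_bulk) and n_patients < 8:
        raise ValueError("planted failure modes need a cohort of at least 8 patients")
    modes: list[tuple[int, ErrorMode, dict]] = []
    metal_ids = [n_patients - 6 + i for i in range(n_metal)]
    bulk_ids = [n_patients - 2 + i for i in range(n_bulk)]
    for pid in metal_ids:
        modes.append((pid, ErrorMode.metal_artifact(), {}))
    for pid in bulk_ids:
        modes.append((pid, ErrorMode.bulk_density(soft_bias_hu=bd_bias_hu), {}))
    return CohortSpec(
        n_patients=n_patients,
        mode_assignment=tuple(modes),
        base_spec=base,
        master_seed=master_seed,
    )


@dataclass
class StudyConfig:
    """Everything ``run_study`` needs, with study-scale defaults."""

    cohort: CohortSpec
    plan: PlanSpec | None = None  # derived per-patient from the PTV when None
    calibration: DensityCalibration = field(default_factory=DensityCalibration)
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    tolerances: cls.ToleranceSet = field(default_factory=cls.ToleranceSet)
    references: tuple[str, ...] = ("CT",) + QA_REFERENCES
    bd_target_me_percent: float = -1.0
    bd_bias_hu: float | None = None  # calibrated at run time when None
    sinus_fill_hu: float = 30.0
    positioning_patients: tuple[int, ...] = ()
    positioning_fractions: int = 1
    positioning_noise: float = 0.01
    make_figures: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.references) - {"CT", *QA_REFERENCES}
        if unknown:
            raise ValueError(f"unknown reference roles: {sorted(unknown)}")


@dataclass
class StudyReport:
    metrics: pd.DataFrame  # long table of per-patient metric values
    verdicts: pd.DataFrame
    sensitivity: pd.DataFrame  # metric x generator
    boxplot_summaries: pd.DataFrame
    positioning: pd.DataFrame
    truth: pd.DataFrame
    excluded: dict[str, list[int]]
    seed: int


def summarize_boxplot(values, patient_ids=None) -> dict:
    """Median/quartiles (linear-interpolation convention) and 1.5 IQR outliers.

    Outliers are tagged with their patient ids, mirroring how per-patient
    QA reports label the patients a physicist must review.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if patient_ids is None:
        patient_ids = list(range(1, values.size + 1))
    q1, median, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [
        (int(pid), float(v)) for pid, v in zip(patient_ids, values) if v < lo or v > hi
    ]
    return {
        "median": float(median),
        "q1": float(q1),
        "q3": float(q3),
        "fence_low": float(lo),
        "fence_high": float(hi),
        "outliers": outliers,
    }


def _qa_reference_volume(
    role: str, pair: PhantomPair, spec: PhantomSpec, config: StudyConfig, bd_bias: float
) -> Volume | None:
    """The emulated QA generator's sCT for one patient (None = refused)."""
    # distinct noise realisations per generator, still deterministic
    role_seed = int((pair.truth.seed * 1000003 + {"sCT_QA_AI_1": 1, "sCT_QA_AI_2": 2, "sCT_QA_BD": 3}[role]) % (2**31))
    qa_spec = replace(spec, seed=role_seed)
    if role == "sCT_QA_AI_1":
        if pair.truth.mode_kind == "METAL_ARTIFACT":
            return None  # automatic artifact rejection
        mode = ErrorMode.none()
    elif role == "sCT_QA_AI_2":
        if pair.truth.ptv_placement == "near_sinus":
            mode = ErrorMode.sinus_misprediction(config.sinus_fill_hu)
        else:
            mode = ErrorMode.none()
    else:  # sCT_QA_BD
        mode = ErrorMode.bulk_density(soft_bias_hu=bd_bias)
    return generate_phantom_pair(qa_spec, mode, patient_id=pair.patient_id).sct


def _patient_metrics(
    pair: PhantomPair,
    reference_label: str,
    ref_image: Volume,
    plan: PlanSpec,
    mu_factor: float,
    dose_clin: Volume,
    structures: dict[str, StructureMask],
    config: StudyConfig,
) -> MetricReport:
    dose_ref, _ = compute_plan_dose(
        ref_image, plan, config.calibration, structures["PTV"], mu_factor=mu_factor
    )
    report = MetricReport(patient_id=pair.patient_id, reference_label=reference_label)
    for name in ("PTV", "Brain", "Skull"):
        gy, pct = mean_error(dose_clin, dose_ref, structures[name], plan.prescription_gy)
        report.me_gy[name] = gy
        report.me_percent[name] = pct
    dvh_clin = dvhmod.DVH.from_volume(dose_clin, structures["PTV"])
    dvh_ref = dvhmod.DVH.from_volume(dose_ref, structures["PTV"])
    report.delta_dx_percent = dvhmod.delta_dx(
        dvhmod.dvh_metrics(dvh_clin), dvhmod.dvh_metrics(dvh_ref), plan.prescription_gy
    )
    _, pass_rate = gamma_map(dose_ref, dose_clin, config.gamma)
    report.gamma_pass_rate = pass_rate
    return report


def _verdict_value(row: pd.Series) -> tuple[str, float]:
    if row["metric"] == GAMMA_METRIC:
        return "gamma_rate", row["value_percent"]
    return "point_percent", row["value_percent"]


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Run the full study replica; see the module docstring.

    Deterministic for a fixed ``config.cohort.master_seed``; when ``outdir``
    is given, all tables are written there with stable formatting.
    """
    seed = config.cohort.master_seed
    bd_bias = config.bd_bias_hu
    needs_bd = "sCT_QA_BD" in config.references or any(
        mode.kind == "BULK_DENSITY" for _, mode, _ in config.cohort.patients()
    )
    if bd_bias is None and needs_bd:
        log.info("calibrating bulk-density soft-tissue bias to %.2f%% mean PTV dose error",
                 config.bd_target_me_percent)
        bd_bias = calibrate_bias(
            config.bd_target_me_percent,
            spec=config.cohort.base_spec,
            mode_kind="BULK_DENSITY",
        )
        log.info("calibrated bulk-density soft bias: %.1f HU", bd_bias)
    elif bd_bias is None:
        bd_bias = 0.0

    # patients with a planted BULK_DENSITY mode inherit the calibrated bias
    assignment = tuple(
        (pid, replace(mode, bulk_soft_bias_hu=bd_bias) if mode.kind == "BULK_DENSITY" else mode, ov)
        for pid, mode, ov in config.cohort.mode_assignment
    )
    cohort = replace(config.cohort, mode_assignment=assignment)
    pairs, truth = generate_cohort(cohort)

    rows: list[dict] = []
    excluded: dict[str, list[int]] = {role: [] for role in config.references if role != "CT"}
    for pair in pairs:
        log.info("patient %d (%s)", pair.patient_id, pair.truth.mode_kind)
        spec = replace(cohort.base_spec, seed=pair.truth.seed)
        structures = {s.name: s for s in pair.structures}
        # brain/skull by CT thresholding, as in a contour-free QA workflow
        brain, skull = dvhmod.threshold_structures(pair.ct)
        structures["Brain"], structures["Skull"] = brain, skull
        ptv_idx = np.argwhere(structures["PTV"].mask)
        ptv_center = pair.ct.index_to_physical(ptv_idx.astype(float)).mean(axis=0)
        plan = config.plan or default_plan(tuple(ptv_center), spec.ptv_radius_mm)
        dose_ct, mu_factor = compute_plan_dose(
            pair.ct, plan, config.calibration, structures["PTV"]
        )
        dose_clin, _ = compute_plan_dose(
            pair.sct, plan, config.calibration, structures["PTV"], mu_factor=mu_factor
        )
        for role in config.references:
            if role == "CT":
                ref_image = pair.ct
            else:
                ref_image = _qa_reference_volume(role, pair, spec, config, bd_bias)
                if ref_image is None:
                    excluded[role].append(pair.patient_id)
                    log.info("patient %d refused by %s (artifact auto-rejection)", pair.patient_id, role)
                    continue
            report = _patient_metrics(
                pair, role, ref_image, plan, mu_factor, dose_clin, structures, config
            )
            rows.extend(report.rows())

    metrics = pd.DataFrame(rows)

    # ---- verdicts -------------------------------------------------------
    verdict_rows = []
    scored = metrics[metrics["metric"].isin([*POINT_METRICS, GAMMA_METRIC])]
    for _, row in scored.iterrows():
        kind, value = _verdict_value(row)
        decision = cls.apply_tolerance(value, kind, config.tolerances)
        verdict_rows.append(
            {
                "patient_id": row["patient_id"],
                "reference": row["reference"],
                "metric": row["metric"],
                "value_percent": value,
                "decision": decision,
            }
        )
    verdicts = pd.DataFrame(verdict_rows)

    # ---- sensitivity matrix --------------------------------------------
    sens_rows = []
    for role in config.references:
        if role == "CT":
            continue
        for metric in [*POINT_METRICS, GAMMA_METRIC]:
            ct_v = _verdict_map(verdicts, "CT", metric)
            qa_v = _verdict_map(verdicts, role, metric)
            common = sorted(set(ct_v) & set(qa_v))
            counts = cls.confusion({p: ct_v[p] for p in common}, {p: qa_v[p] for p in common})
            sens_rows.append(
                {
                    "reference": role,
                    "metric": metric,
                    "tp": counts.tp,
                    "fn": counts.fn,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "n": counts.total,
                    "sensitivity": _none_to_nan(cls.sensitivity(counts)),
                    "specificity": _none_to_nan(cls.specificity(counts)),
                }
            )
    sensitivity = pd.DataFrame(sens_rows)

    # ---- boxplot summaries (with Wilcoxon vs the CT distribution, which
    # is delegated to scipy's standard routine) ---------------------------
    from scipy.stats import wilcoxon

    box_rows = []
    for (role, metric), grp in scored.groupby(["reference", "metric"], sort=True):
        summary = summarize_boxplot(grp["value_percent"].to_numpy(), grp["patient_id"].tolist())
        p_value = np.nan
        if role != "CT":
            ct_grp = scored[(scored["reference"] == "CT") & (scored["metric"] == metric)]
            merged = grp.merge(ct_grp, on="patient_id", suffixes=("", "_ct"))
            diffs = merged["value_percent"] - merged["value_percent_ct"]
            if len(diffs) > 0 and not np.allclose(diffs, 0):
                p_value = float(wilcoxon(diffs).pvalue)
        box_rows.append(
            {
                "reference": role,
                "metric": metric,
                **{k: v for k, v in summary.items() if k != "outliers"},
                "outliers": json.dumps(summary["outliers"]),
                "p_wilcoxon_vs_CT": p_value,
            }
        )
    boxplots = pd.DataFrame(box_rows)

    # ---- positioning ----------------------------------------------------
    positioning = _positioning_table(pairs, config)

    report = StudyReport(
        metrics=metrics,
        verdicts=verdicts,
        sensitivity=sensitivity,
        boxplot_summaries=boxplots,
        positioning=positioning,
        truth=truth,
        excluded=excluded,
        seed=seed,
    )
    if outdir is not None:
        _write_report(report, Path(outdir), config)
    return report


def _verdict_map(verdicts: pd.DataFrame, role: str, metric: str) -> dict[int, str]:
    sel = verdicts[(verdicts["reference"] == role) & (verdicts["metric"] == metric)]
    return dict(zip(sel["patient_id"].astype(int), sel["decision"]))


def _none_to_nan(v):
    return np.nan if v is None else v


def _positioning_table(pairs: list[PhantomPair], config: StudyConfig) -> pd.DataFrame:
    rows = []
    selected = [p for p in pairs if p.patient_id in set(config.positioning_patients)]
    for pair in selected:
        geom = ProjectionGeometry.default_orthogonal()
        offset = register_3d_rigid(pair.sct, pair.ct).pose
        rng = np.random.default_rng(pair.truth.seed + 17)
        for fraction in range(config.positioning_fractions):
            applied = RigidPose(
                tuple(rng.uniform(-5.0, 5.0, 3)), tuple(rng.uniform(-3.0, 3.0, 3))
            )
            kv = simulate_kv_pair(
                pair.ct, applied, geom, noise_level=config.positioning_noise,
                seed=int(rng.integers(2**31)),
            )
            ct_reg = register_2d2d(kv, pair.ct, geom)
            sct_reg = register_2d2d(kv, pair.sct, geom)
            delta = positioning_delta(ct_reg.pose, sct_reg.pose, offset)
            for axis, name in enumerate(("lateral", "longitudinal", "vertical")):
                rows.append(
                    {
                        "patient_id": pair.patient_id,
                        "fraction": fraction + 1,
                        "axis": name,
                        "shift_diff_mm": delta.shift_mm[axis],
                        "rotation_diff_deg": delta.rotation_deg[axis],
                        "ct_similarity": ct_reg.similarity,
                        "sct_similarity": sct_reg.similarity,
                    }
                )
    columns = [
        "patient_id", "fraction", "axis", "shift_diff_mm", "rotation_diff_deg",
        "ct_similarity", "sct_similarity",
    ]
    return pd.DataFrame(rows, columns=columns)


def _write_report(report: StudyReport, outdir: Path, config: StudyConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.metrics.to_csv(outdir / "metrics.csv", index=False, float_format=fmt)
    report.verdicts.to_csv(outdir / "verdicts.csv", index=False, float_format=fmt)
    report.sensitivity.to_csv(outdir / "sensitivity.csv", index=False, float_format=fmt)
    report.boxplot_summaries.to_csv(outdir / "boxplot_summaries.csv", index=False, float_format=fmt)
    report.positioning.to_csv(outdir / "positioning.csv", index=False, float_format=fmt)
    report.truth.to_csv(outdir / "truth.csv", index=False, float_format=fmt)
    meta = {
        "seed": report.seed,
        "excluded": report.excluded,
        "tolerances": {
            "point_metric_tolerance_percent": config.tolerances.point_metric_tolerance,
            "gamma_pass_floor_percent": config.tolerances.gamma_pass_floor,
        },
        "gamma": {
            "dose_percent": config.gamma.dose_percent,
            "distance_mm": config.gamma.distance_mm,
            "threshold_fraction": config.gamma.threshold_fraction,
        },
    }
    (outdir / "study.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if config.make_figures:
        _write_figures(report, outdir)


def _write_figures(report: StudyReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, grp in report.metrics.groupby("metric"):
        fig, ax = plt.subplots(figsize=(6, 4))
        roles = sorted(grp["reference"].unique())
        data = [grp[grp["reference"] == r]["value_percent"].to_numpy() for r in roles]
        ax.boxplot(data, tick_labels=roles)
        ax.set_title(metric)
        ax.set_ylabel("%")
        fig.tight_layout()
        safe = metric.replace("%", "pct").replace("/", "_")
        fig.savefig(outdir / f"fig_{safe}.png", dpi=100)
        plt.close(fig)
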