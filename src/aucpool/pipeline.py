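"""End-to-end orchestration: schedule → pooling design → (simulated or
loaded) peak areas → AUC estimates → exposure ranking → correlation screen →
Q-marker report, with all artifacts written to an output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .auc import (
    AUCEstimate,
    ConcentrationProfile,
    MethodComparison,
    compare_methods,
    pooled_auc,
    replicate_summary,
    trapezoid_auc,
)
from .errors import StageError, ValidationError
from .io import (
    PeakAreaMatrix,
    RunConfig,
    read_peak_table,
    write_design,
    write_peak_table,
    write_profiles,
)
from .pooling import PoolingDesign, pooling_volumes
from .screen import (
    ExposureTable,
    QMarkerReport,
    CorrelationResult,
    cumulative_fraction,
    exposure_table,
    pearson,
    percent_profile,
    select_qmarker,
    species_share,
    top_compounds,
)
from .simulate import AssayModel, CompoundPanel, apply_assay, default_panel, simulate_cohort

log = logging.getLogger("aucpool")


@dataclass(frozen=True)
class RunReport:
    """Everything a screening run produced, with provenance."""

    config: RunConfig
    design: PoolingDesign
    matrix: PeakAreaMatrix
    exposure_tables: Mapping[str, ExposureTable]
    comparisons: tuple[MethodComparison, ...]
    correlations: tuple[CorrelationResult, ...]
    qmarker: QMarkerReport
    top_n_fraction_pct: float
    species_shares_pct: Mapping[str, float]
    provenance: Mapping[str, object] = field(default_factory=dict)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 — re-raised with stage name
                raise StageError(name, exc) from exc

        return inner

    return wrap


@_stage("design")
def _build_design(config: RunConfig) -> PoolingDesign:
    design = pooling_volumes(
        config.schedule(), config.total_volume_uL, config.rounding_increment_uL
    )
    log.info("pooling design: total %.1f μL over %d time points",
             config.total_volume_uL, len(design.volumes))
    return design


@_stage("data")
def _acquire_data(config: RunConfig, panel: CompoundPanel, design: PoolingDesign):
    """Pooled peak-area matrix plus (simulation only) noisy serial profiles."""
    assay = AssayModel(cv=config.noise_cv, lloq=config.lloq)
    schedule = config.schedule()
    if config.peak_table is not None:
        matrix = read_peak_table(config.peak_table)
        for d in matrix.diagnostics:
            log.warning(d)
        return matrix, {}
    matrix = simulate_cohort(
        list(config.species), panel, schedule, assay, config.replicates,
        seed=config.seed, design=design,
    )
    # Serial sampling measured with independent analytical noise, one noisy
    # profile per replicate, averaged per compound — the traditional arm.
    serial: dict[tuple[str, str], ConcentrationProfile] = {}
    root = np.random.SeedSequence([config.seed, 1])
    for sp_i, sp in enumerate(config.species):
        truths = panel.species_profiles(sp, schedule.times)
        for c_i, cid in enumerate(panel.compound_ids()):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(sp_i, c_i)
            )
            seeds = child.generate_state(config.replicates)
            reps = [
                apply_assay(truths[cid], assay, int(s)) for s in seeds
            ]
            mean_vals = np.mean([r.values for r in reps], axis=0)
            serial[(sp, cid)] = ConcentrationProfile(
                compound_id=cid,
                times=tuple(schedule.times),
                values=tuple(float(v) for v in mean_vals),
                unit_label="area",
            )
    return matrix, serial


@_stage("auc")
def _method_comparisons(
    config: RunConfig,
    matrix: PeakAreaMatrix,
    serial: Mapping[tuple[str, str], ConcentrationProfile],
    design: PoolingDesign,
) -> tuple[MethodComparison, ...]:
    """Pooled vs serial-trapezoid AUC per compound, where serial data exist."""
    schedule = config.schedule()
    comparisons = []
    d = matrix.data
    for (sp, cid), prof in serial.items():
        trad = trapezoid_auc(prof)
        areas = d[(d["species"] == sp) & (d["compound_id"] == cid)]["area"]
        pooled_estimates = [
            pooled_auc(float(a), schedule, compound_id=cid, unit_label="area")
            for a in areas
        ]
        mean, _sd = replicate_summary(pooled_estimates)
        pooled = AUCEstimate(
            compound_id=cid, value=mean, method="pooled",
            t_start=schedule.times[0], t_end=schedule.times[-1], unit_label="area*h",
        )
        if trad.value > 0:
            comparisons.append(compare_methods(trad, pooled))
    return tuple(comparisons)


@_stage("screen")
def _screen(config: RunConfig, matrix: PeakAreaMatrix,
            serial: Mapping[tuple[str, str], ConcentrationProfile]):
    schedule = config.schedule()
    tables = {
        sp: exposure_table(
            matrix, schedule, species=sp,
            reference_available=config.reference_compounds,
        )
        for sp in matrix.species
    }
    ref_sp = config.reference_species
    if ref_sp not in tables:
        raise ValidationError(f"reference species '{ref_sp}' not in data")
    ref_table = tables[ref_sp]
    top_n = min(config.top_n, len(ref_table))
    frac = cumulative_fraction(ref_table, top_n)
    top_set = top_compounds(ref_table, top_n)
    shares = {
        sp: species_share(top_set, tables[sp]) for sp in tables if sp != ref_sp
    }

    correlations: list[CorrelationResult] = []
    qrep = QMarkerReport(candidate_id=None, reason="no serial profiles available",
                        r_threshold=config.r_threshold,
                        p_threshold=config.p_threshold, top_k=config.top_k)
    ref_avail = ref_table.data[ref_table.data["reference_available"]]
    if serial and not ref_avail.empty:
        cand = str(ref_avail["compound_id"].iloc[0])
        cand_pp = percent_profile(serial[(ref_sp, cand)])
        top_k = min(config.top_k, len(ref_table))
        for cid in top_compounds(ref_table, top_k):
            if cid == cand:
                continue
            correlations.append(pearson(cand_pp, percent_profile(serial[(ref_sp, cid)])))
        qrep = select_qmarker(
            ref_table, correlations,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            top_k=top_k,
        )
    return tables, frac, shares, tuple(correlations), qrep


def run_pipeline(config: RunConfig, panel: CompoundPanel | None = None,
                 write: bool = True) -> RunReport:
    """Run the full screening workflow; deterministic for a given seed.

    Writes every table plus a human-readable summary under
    ``config.out_dir`` when ``write`` is true.
    """
    log.info("run seed=%d thresholds: ppm=%g r=%g p=%g top_k=%d top_n=%d",
             config.seed, config.ppm_tolerance, config.r_threshold,
             config.p_threshold, config.top_k, config.top_n)
    if panel is None:
        panel = default_panel()
    design = _build_design(config)
    matrix, serial = _acquire_data(config, panel, design)
    comparisons = _method_comparisons(config, matrix, serial, design)
    tables, frac, shares, correlations, qrep = _screen(config, matrix, serial)
    report = RunReport(
        config=config,
        design=design,
        matrix=matrix,
        exposure_tables=tables,
        comparisons=comparisons,
        correlations=correlations,
        qmarker=qrep,
        top_n_fraction_pct=frac,
        species_shares_pct=shares,
        provenance={
            "config_sha256": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "synthetic": config.peak_table is None,
        },
    )
    if write:
        _write_report(report, serial)
    return report


@_stage("write")
def _write_report(report: RunReport,
                  serial: Mapping[tuple[str, str], ConcentrationProfile]) -> None:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(report.design, out / "design.csv")
    write_peak_table(report.matrix, out / "peak_table.csv")
    if serial:
        for sp in report.config.species:
            profs = [p for (s, _c), p in serial.items() if s == sp]
            if profs:
                write_profiles(profs, out / f"serial_profiles_{sp}.csv")
    for sp, table in report.exposure_tables.items():
        table.data.to_csv(out / f"exposure_{sp}.csv", index=False)
    pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "auc_traditional": c.auc_traditional.value,
                "auc_pooled": c.auc_pooled.value,
                "percent_difference": c.percent_difference,
            }
            for c in report.comparisons
        ]
    ).to_csv(out / "method_comparison.csv", index=False)
    pd.DataFrame(
        [
            {"compound_id": c.compound_id, "reference_id": c.reference_id,
             "r": c.r, "p": c.p, "n": c.n}
            for c in report.correlations
        ]
    ).to_csv(out / "correlations.csv", index=False)
    q = report.qmarker
    qdoc = {
        "candidate_id": q.candidate_id,
        "candidate_rank": q.candidate_rank,
        "selected": q.selected,
        "reason": q.reason,
        "r_threshold": q.r_threshold,
        "p_threshold": q.p_threshold,
        "top_k": q.top_k,
        "companions": [
            {"compound_id": c.compound_id, "r": c.r, "p": c.p,
             "r_pass": c.r_pass, "p_pass": c.p_pass}
            for c in q.companions
        ],
        "provenance": dict(report.provenance),
    }
    with open(out / "qmarker.yaml", "w") as fh:
        yaml.safe_dump(qdoc, fh, sort_keys=False)
    _write_summary(report, out / "summary.txt")


def _write_summary(report: RunReport, path: Path) -> None:
    lines = [
        f"aucpool {__version__} — run summary",
        f"seed: {report.config.seed}   config: {report.provenance['config_sha256']}",
        f"schedule: {list(report.config.times_h)} h, "
        f"total volume {report.config.total_volume_uL:g} μL",
        "",
        f"top-{report.config.top_n} exposure fraction "
        f"({report.config.reference_species}): {report.top_n_fraction_pct:.2f}%",
    ]
    for sp, share in report.species_shares_pct.items():
        lines.append(f"share of {report.config.reference_species} top compounds in "
                     f"{sp}: {share:.2f}%")
    if report.comparisons:
        worst = max(report.comparisons, key=lambda c: c.percent_difference)
        lines.append(
            f"largest pooled-vs-trapezoid difference: {worst.percent_difference:.2f}% "
            f"({worst.compound_id})"
        )
    q = report.qmarker
    lines.append(
        f"Q-marker: {q.candidate_id or 'none'} "
        f"({'selected' if q.selected else 'not selected'}; {q.reason})"
    )
    path.write_text("\n".join(lines) + "\n")
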