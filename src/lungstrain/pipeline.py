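"""End-to-end orchestration: phantom cohort -> aeration -> registration ->
mesh strain -> ROI statistics -> group significance maps and reports.

The pipeline mirrors the analysis workflow of paired EE/EI lung CT at two
study times in two groups: per subject and time, lung voxels are
classified into aeration compartments, the aerated masks at EE and EI are
registered, a tetrahedral mesh of the aerated EI lung is warped to its
expiratory reference, per-tet volumetric strain is binned into the
10 x 10 AB x DV ROI grid, and subject-level ROI summaries feed the three
per-ROI test families.

Displacement backends: ``"ffd"`` runs the built-in mask registration;
``"ground_truth"`` injects the phantom's analytic field (strain-recovery
oracle and fast smoke runs).
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aeration, mesh as meshmod, roi as roimod, stats_tests as st
from .aeration import AerationThresholds
from .core import Compartment
from .phantom import PhantomSpec, PhantomSubject, generate_cohort
from .registration import DisplacementField, FFDParams, register_ffd

log = logging.getLogger("lungstrain")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a cohort analysis run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_per_group: int = 5
    thresholds: AerationThresholds = field(default_factory=AerationThresholds)
    registration: FFDParams = field(default_factory=FFDParams)
    backend: str = "ffd"  # "ffd" | "ground_truth"
    n_grid: int = 10
    alpha: float = 0.05
    alternative: str = "greater"
    spi_mode: str = "signed_rank"
    fdr_correct: bool = False
    sample_cap: int = 2000  # per-cell per-subject tet subsample for CV tests
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grid < 2:
            raise ValueError("ROI grid needs n >= 2")
        if not 0.0 < self.alpha < 1.0 and self.alpha != 0.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.backend not in ("ffd", "ground_truth"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class SubjectTimeResult:
    """All per-(subject, time) derived artefacts."""

    subject_id: str
    group: str
    time: str
    fractions: dict
    metrics: aeration.GlobalMetrics
    aeration_ee: aeration.AerationMap
    displacement: DisplacementField
    strain: meshmod.StrainField
    grid: roimod.ROIGrid
    roi_stats: roimod.ROIStats
    cell_samples: dict
    qc: dict
    mesh: meshmod.TetMesh | None = None  # retained only when requested


@dataclass
class SubjectData:
    """Minimal per-(subject, time) input bundle loaded from disk.

    Interface-compatible with :class:`PhantomSubject` for analysis; no
    ground truth is available, so only the ``"ffd"`` (or imported-field)
    backend applies.
    """

    subject_id: str
    group: str
    time: str
    ct_ee: object
    ct_ei: object
    mask_ee: object
    mask_ei: object
    manifest: dict
    ground_truth: None = None


def load_cohort_manifest(path: str | Path) -> dict[tuple[str, str], SubjectData]:
    """Read a cohort manifest CSV (one row per subject x time x phase).

    Expects columns subject_id, group, time, phase, path, mask_path,
    body_mass_g, rr_per_min, as written by the phantom generator.  Raises
    when a subject/time is missing one of its EE/EI phases.
    """
    from .core import load_ct, load_mask

    df = pd.read_csv(path)
    subjects: dict[tuple[str, str], SubjectData] = {}
    for (sid, time), rows in df.groupby(["subject_id", "time"]):
        by_phase = {r.phase: r for r in rows.itertuples()}
        missing = {"EE", "EI"} - set(by_phase)
        if missing:
            raise ValueError(f"subject {sid}/{time}: missing phase image(s) {sorted(missing)}")
        ee, ei = by_phase["EE"], by_phase["EI"]
        subjects[(sid, time)] = SubjectData(
            subject_id=str(sid),
            group=str(ee.group),
            time=str(time),
            ct_ee=load_ct(ee.path),
            ct_ei=load_ct(ei.path),
            mask_ee=load_mask(ee.mask_path),
            mask_ei=load_mask(ei.mask_path),
            manifest=dict(
                subject_id=str(sid), group=str(ee.group), time=str(time),
                body_mass_g=float(ee.body_mass_g), rr_per_min=float(ee.rr_per_min),
            ),
        )
    return subjects


def ground_truth_field(subj: PhantomSubject) -> DisplacementField:
    """Dense displacement field sampled from the phantom's analytic map."""
    shape = subj.ct_ei.shape
    h = subj.ct_ei.spacing
    pts = np.indices(shape).reshape(3, -1).T * h
    u = subj.ground_truth.displacement(pts).reshape(shape + (3,))
    return DisplacementField(u, h, info=dict(backend="ground_truth"))


def analyze_subject_time(
    subj: PhantomSubject,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    keep_mesh: bool = False,
) -> SubjectTimeResult:
    """Run the full per-(subject, time) analysis chain."""
    t0 = _time.time()
    if abs(subj.ct_ee.spacing - subj.ct_ei.spacing) > 1e-9:
        raise ValueError(
            f"subject {subj.subject_id}/{subj.time}: EE spacing {subj.ct_ee.spacing} "
            f"!= EI spacing {subj.ct_ei.spacing}"
        )
    if config.backend == "ground_truth" and subj.ground_truth is None:
        raise ValueError("no ground-truth field available for this subject")
    am_ee = aeration.classify_aeration(subj.ct_ee, subj.mask_ee, config.thresholds)
    am_ei = aeration.classify_aeration(subj.ct_ei, subj.mask_ei, config.thresholds)
    fractions = aeration.compartment_fractions(am_ee)
    aer_ee, qc_ee = aeration.clean_aerated_mask(aeration.aerated_mask(am_ee))
    aer_ei, qc_ei = aeration.clean_aerated_mask(aeration.aerated_mask(am_ei))
    metrics = aeration.global_metrics(
        aer_ee, aer_ei,
        body_mass_kg=subj.manifest["body_mass_g"] / 1000.0,
        rr_per_min=subj.manifest["rr_per_min"],
    )

    if config.backend == "ground_truth":
        fld = ground_truth_field(subj)
    else:
        fld = register_ffd(aer_ei, aer_ee, config.registration)

    tet = meshmod.tetrahedralize_mask(aer_ei)
    ref = meshmod.warp_mesh_to_reference(tet, fld)
    strain = meshmod.volumetric_strain(tet, ref)
    grid = roimod.make_roi_grid(strain, config.n_grid)
    stats = roimod.roi_weighted_stats(strain, grid)

    samples = roimod.cell_strain_samples(strain, grid)
    if config.sample_cap and rng is not None:
        samples = {
            k: (v if len(v) <= config.sample_cap
                else rng.choice(v, size=config.sample_cap, replace=False))
            for k, v in samples.items()
        }

    qc = dict(
        eilv_raw_mm3=float(strain.ei_volume.sum()),
        eelv_mesh_mm3=float(strain.ref_volume.sum()),
        eelv_mask_mm3=aer_ee.volume_mm3(),
        mesh_mask_volume_ratio=float(strain.ei_volume.sum() / aer_ei.volume_mm3()),
        registration=dict(fld.info, energy_history=None),
        n_clamped=am_ee.n_clamped + am_ei.n_clamped,
        mask_qc=dict(EE=qc_ee, EI=qc_ei),
        occupied_cells=grid.n_occupied,
        elapsed_s=_time.time() - t0,
    )
    log.info(
        "subject %s %s: %d tets, %d occupied cells, %.1fs",
        subj.subject_id, subj.time, strain.strain.size, grid.n_occupied, qc["elapsed_s"],
    )
    return SubjectTimeResult(
        subj.subject_id, subj.group, subj.time, fractions, metrics,
        am_ee, fld, strain, grid, stats, samples, qc,
        mesh=tet if keep_mesh else None,
    )


@dataclass
class CohortResult:
    """Group-level report of a cohort run."""

    metrics_table: pd.DataFrame
    aeration_table: pd.DataFrame
    group_data: dict[str, st.GroupROIData]
    significance: dict[str, dict[str, st.SignificanceMap]]
    spi_maps: dict[str, np.ndarray]  # group -> mean SPI matrix over subjects
    shi_maps: dict[str, dict[str, np.ndarray]]  # group -> time -> mean SHI
    strain_maps: dict[str, dict[str, np.ndarray]]  # group -> time -> mean ROI strain
    summary: dict


def run_cohort(config: RunConfig, subjects: dict | None = None) -> CohortResult:
    """Run the full analysis on a cohort.

    ``subjects`` may be a pre-loaded cohort (e.g. from
    :func:`load_cohort_manifest`); by default the phantom cohort is
    generated from the configuration.
    """
    master = np.random.SeedSequence(config.seed)
    _, cap_seed = master.spawn(2)
    cap_rng = np.random.default_rng(cap_seed)
    if subjects is None:
        _, subjects = generate_cohort(config.phantom, config.seed, n_per_group=config.n_per_group)

    results: dict[tuple[str, str], SubjectTimeResult] = {}
    for (sid, time), subj in subjects.items():
        results[(sid, time)] = analyze_subject_time(subj, config, cap_rng)

    groups = sorted({r.group for r in results.values()})
    n = config.n_grid
    group_data: dict[str, st.GroupROIData] = {}
    significance = {}
    spi_maps, shi_maps, strain_maps = {}, {}, {}
    metrics_rows, aer_rows = [], []

    for g in groups:
        sids = sorted({sid for (sid, _), r in results.items() if r.group == g})
        means = {t: np.stack([results[(sid, t)].roi_stats.mean for sid in sids]) for t in ("T1", "T3")}
        sds = {t: np.stack([results[(sid, t)].roi_stats.sd for sid in sids]) for t in ("T1", "T3")}
        samples = {t: [results[(sid, t)].cell_samples for sid in sids] for t in ("T1", "T3")}
        gd = st.GroupROIData(mean=means, samples=samples)
        group_data[g] = gd
        significance[g] = st.roi_significance_maps(
            gd, alpha=config.alpha, alternative=config.alternative,
            spi_mode=config.spi_mode, fdr_correct=config.fdr_correct, n_grid=n,
        )
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message="Mean of empty slice")
            subj_spi = roimod.spi(means["T1"], means["T3"])
            spi_maps[g] = np.nanmean(subj_spi, axis=0) if len(sids) else np.full((n, n), np.nan)
            shi_maps[g] = {
                t: np.nanmean(roimod.shi(means[t], sds[t]), axis=0) for t in ("T1", "T3")
            }
            strain_maps[g] = {t: np.nanmean(means[t], axis=0) for t in ("T1", "T3")}

        for t in ("T1", "T3"):
            for sid in sids:
                r = results[(sid, t)]
                m = r.metrics
                metrics_rows.append(dict(
                    group=g, time=t, subject_id=sid,
                    rr_per_min=m.rr_per_min, vt_ml_kg=m.vt_ml_kg,
                    vmin_ml_min_kg=m.vmin_ml_min_kg, eelv_ml_kg=m.eelv_ml_kg,
                    eilv_ml_kg=m.eilv_ml_kg, global_strain_pct=m.global_strain_pct,
                ))
                aer_rows.append(dict(
                    group=g, time=t, subject_id=sid,
                    **{c.name.lower(): r.fractions[c] for c in (
                        Compartment.NON_AERATED, Compartment.POORLY_AERATED,
                        Compartment.NORMALLY_AERATED, Compartment.HYPER_AERATED)},
                ))

    summary = dict(
        n_per_group=config.n_per_group,
        backend=config.backend,
        alpha=config.alpha,
        alternative=config.alternative,
        families={
            g: {
                fam: dict(
                    n_testable=sm.n_testable,
                    n_significant=sm.n_significant,
                    percentage=sm.percentage if sm.n_testable else None,
                )
                for fam, sm in significance[g].items()
            }
            for g in groups
        },
    )
    return CohortResult(
        metrics_table=pd.DataFrame(metrics_rows),
        aeration_table=pd.DataFrame(aer_rows),
        group_data=group_data,
        significance=significance,
        spi_maps=spi_maps,
        shi_maps=shi_maps,
        strain_maps=strain_maps,
        summary=summary,
    )


# ------------------------------------------------------------- reporting


def render_roi_heatmap(
    matrix: np.ndarray,
    flags: np.ndarray | None,
    path: str | Path,
    title: str = "",
    cbar_label: str = "",
) -> None:
    """Heatmap of a 10 x 10 ROI matrix; void cells blanked, stars on flags.

    AB runs along the vertical axis (apical at the top), DV along the
    horizontal (dorsal at the left).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    m = np.asarray(matrix, float)
    if flags is not None:
        flags = np.asarray(flags, bool)
        if flags.shape != m.shape:
            raise ValueError(f"flags shape {flags.shape} != matrix shape {m.shape}")
    fig, ax = plt.subplots(figsize=(4.2, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    im = ax.imshow(np.ma.masked_invalid(m), cmap=cmap, origin="upper")
    if flags is not None:
        for i, j in np.argwhere(flags):
            ax.text(j, i, "*", ha="center", va="center", color="red", fontsize=12)
    ax.set_xlabel("dorsal - ventral")
    ax.set_ylabel("basal - apical")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=cbar_label)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(result: CohortResult, out_dir: str | Path, render: bool = True) -> None:
    """Write the group-level tables, matrices and (optionally) figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_table.to_csv(out / "metrics.csv", index=False)
    result.aeration_table.to_csv(out / "aeration_fractions.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    for g, mat in result.spi_maps.items():
        np.savetxt(out / f"spi_{g}.csv", mat, delimiter=",", fmt="%.6g")
        if render:
            render_roi_heatmap(
                mat, result.significance[g]["spi_vs_1"].flags,
                out / f"spi_{g}.png", title=f"SPI {g}", cbar_label="SPI",
            )
    for g, per_time in result.strain_maps.items():
        for t, mat in per_time.items():
            np.savetxt(out / f"strain_{g}_{t}.csv", mat, delimiter=",", fmt="%.6g")
    for g, per_time in result.shi_maps.items():
        for t, mat in per_time.items():
            np.savetxt(out / f"shi_{g}_{t}.csv", mat, delimiter=",", fmt="%.6g")


def write_subject_artifacts(
    res: SubjectTimeResult,
    out_dir: str | Path,
    tet_mesh: meshmod.TetMesh | None = None,
) -> None:
    """Per-subject artefact dump: aeration labels, field, VTU mesh, ROI CSVs."""
    from .core import save_nifti
    from .registration import save_displacement_field

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{res.subject_id}_{res.time}"
    save_nifti(res.aeration_ee.labels, res.aeration_ee.spacing, out / f"{stem}_aeration_EE.nii.gz")
    save_displacement_field(res.displacement, out / f"{stem}_displacement.nii.gz")
    if tet_mesh is not None:
        meshmod.write_vtu(
            out / f"{stem}_strain.vtu", tet_mesh,
            cell_data=dict(strain=res.strain.strain, ref_volume=res.strain.ref_volume),
        )
    np.savetxt(out / f"{stem}_roi_mean.csv", res.roi_stats.mean, delimiter=",", fmt="%.6g")
    np.savetxt(out / f"{stem}_roi_sd.csv", res.roi_stats.sd, delimiter=",", fmt="%.6g")
    pd.DataFrame([dict(
        subject_id=res.subject_id, group=res.group, time=res.time,
        eelv_ml_kg=res.metrics.eelv_ml_kg, eilv_ml_kg=res.metrics.eilv_ml_kg,
        vt_ml_kg=res.metrics.vt_ml_kg, global_strain_pct=res.metrics.global_strain_pct,
        vmin_ml_min_kg=res.metrics.vmin_ml_min_kg,
    )]).to_csv(out / f"{stem}_metrics.csv", index=False)
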