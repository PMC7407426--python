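"""Synthetic lung phantom cohort with analytically known deformation.

Each phantom subject is a superellipsoidal "lung" imaged at end-expiration
(EE) and end-inspiration (EI), at two study times (T1, T3), for one of two
groups: spontaneously breathing (SB) or mechanically ventilated (MV).

The EE -> EI deformation is a separable monotone stretch about the lung
centre, so its Jacobian determinant (and hence the volumetric strain
``J - 1``) is available in closed form everywhere.  This gives every
downstream stage -- registration, meshing, strain, ROI statistics -- an
exact oracle.

Disease progression is modelled as ventral-anchored de-recruitment: a
ventrally weighted sub-region of the lung is relabelled non-aerated, and
its volume fraction grows between T1 and T3 in the SB group only, while
regional stretch amplifies dorsally.  The MV group uses identical presets
at both times, so any measured T1/T3 difference there is pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AB, DV, LR, BinaryMask, Compartment, CTImage, SOFT_TISSUE_HU, save_nifti

Group = Literal["SB", "MV"]
Time = Literal["T1", "T3"]

#: Default compartment HU means (non, poor, normal, hyper): centres of the
#: standard quantitative-CT aeration ranges.
DEFAULT_HU_MEANS = {
    Compartment.NON_AERATED: -50.0,
    Compartment.POORLY_AERATED: -300.0,
    Compartment.NORMALLY_AERATED: -700.0,
    Compartment.HYPER_AERATED: -950.0,
}


@dataclass(frozen=True)
class StrainProfile:
    """Separable stretch map about the lung centre.

    The EE -> EI (inflation) map is, per axis and about centre ``c``::

        AB:  x' = c_ab + a_ab * (x - c_ab)
        DV:  y' = c_dv + a_dv * (y - c_dv)
        LR:  z' = c_lr + a_lr(y) * (z - c_lr)

    where the LR stretch factor varies linearly along the dorsal-ventral
    coordinate: ``a_lr(y) = a_lr + dv_gradient * (1/2 - t(y))`` with
    ``t`` the normalised DV position (0 = dorsal lung edge, 1 = ventral).
    A positive ``dv_gradient`` therefore concentrates stretch dorsally,
    as observed when ventral regions de-recruit.  The Jacobian is the
    product of the three axis factors,

        J(x_EE) = a_ab * a_dv * a_lr(y_EE),

    exactly, because the deformation gradient is triangular.
    """

    a_ab: float = 1.07
    a_dv: float = 1.07
    a_lr: float = 1.07
    dv_gradient: float = 0.0

    def validate(self, t_range: tuple[float, float] = (-1.0, 2.0)) -> None:
        """Require J > 0 over the stated normalised-DV range."""
        if min(self.a_ab, self.a_dv, self.a_lr) <= 0:
            raise ValueError("stretch factors must be positive")
        for t in t_range:
            if self.a_lr + self.dv_gradient * (0.5 - t) <= 0:
                raise ValueError(
                    f"dv_gradient {self.dv_gradient} drives the LR factor non-positive at t={t}"
                )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom lung at one phase pair (EE, EI)."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 0.1  # mm/voxel; 100 um isotropic voxels
    lung_axes: tuple[float, float, float] = (3.6, 2.9, 3.2)  # semi-axes, mm (AB, DV, LR)
    superellipse_exponent: float = 2.0
    #: DV shear per unit normalised AB position, as a fraction of the DV
    #: semi-axis: the apical end sits dorsally, the basal end ventrally.
    #: Makes the lung oblique so some AB x DV ROI cells are void.
    dv_tilt_frac: float = 0.35
    compartment_fractions: tuple[float, float, float, float] = (0.10, 0.15, 0.70, 0.05)
    compartment_hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_noise_sd: float = 30.0
    strain_profile: StrainProfile = field(default_factory=StrainProfile)
    seed: int = 0

    def validate(self) -> None:
        f = np.asarray(self.compartment_fractions, float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("compartment fractions must be >= 0 and sum to 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.lung_axes) <= 0:
            raise ValueError("lung semi-axes must be positive")
        self.strain_profile.validate()

    @property
    def center(self) -> np.ndarray:
        """Lung centre: the grid centre, in mm."""
        return (np.asarray(self.grid_shape) - 1) / 2.0 * self.spacing

    def dv_extent(self) -> tuple[float, float]:
        """Dorsal and ventral lung edge along DV, in mm."""
        c = self.center[DV]
        b = self.lung_axes[DV]
        return c - b, c + b


@dataclass
class GroundTruth:
    """Analytic deformation oracle attached to a phantom subject.

    ``displacement(points)`` maps EI-space points (mm, shape (n, 3)) to the
    backward displacement ``u = x_EE - x_EI``; ``jacobian(points)`` gives
    the forward (EE -> EI) Jacobian determinant at those EI points, so the
    true volumetric strain there is ``jacobian(p) - 1``.
    ``compartment_layout`` is the EE label volume (strain ground truth is
    meaningful on aerated labels only).
    """

    displacement: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    compartment_layout: np.ndarray
    spacing: float


# ----------------------------------------------------------------- geometry


def make_lung_mask(spec: PhantomSpec) -> BinaryMask:
    """Superellipsoid lung mask centred in the grid.

    Requires a >= 2-voxel margin between the lung surface and every grid
    face; degenerate semi-axes (< 2 voxels) are rejected.
    """
    spec.validate()
    shape = spec.grid_shape
    h = spec.spacing
    semi = np.asarray(spec.lung_axes, float)
    if (semi < 2 * h).any():
        raise ValueError(f"degenerate lung semi-axes {tuple(semi)} (< 2 voxels)")
    half_extent = (np.asarray(shape) - 1) / 2.0 * h
    tilt = spec.dv_tilt_frac * semi[DV]
    needed = semi + 2 * h
    needed[DV] += tilt
    if (needed > half_extent).any():
        raise ValueError(
            f"lung semi-axes {tuple(semi)} mm (DV tilt {tilt:.2f} mm) do not fit "
            f"grid {shape} at spacing {h} mm with a 2-voxel margin"
        )
    coords = [(np.arange(n) - (n - 1) / 2.0) * h for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    p = spec.superellipse_exponent
    y_eff = Y - tilt * (X / semi[AB])  # oblique: DV centre drifts along AB
    r = (
        np.abs(X / semi[0]) ** p
        + np.abs(y_eff / semi[1]) ** p
        + np.abs(Z / semi[2]) ** p
    )
    return BinaryMask(r <= 1.0, h)


def make_compartment_layout(
    mask: BinaryMask,
    fractions: tuple[float, float, float, float],
    rng: np.random.Generator,
    collapse_score: np.ndarray | None = None,
) -> np.ndarray:
    """Assign aeration-compartment labels to lung voxels.

    The non-aerated compartment is ventral-anchored: lung voxels are ranked
    by a collapse score (normalised ventral position plus a smooth random
    perturbation) and the top ``fractions[0]`` quantile collapses.  Reusing
    the same ``collapse_score`` across time points makes the T3 collapse
    region a superset of the T1 region (progressive de-recruitment).
    Remaining voxels are split i.i.d. among poor/normal/hyper.
    """
    f = np.asarray(fractions, float)
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be >= 0 and sum to 1")
    m = mask.data
    n_lung = int(m.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask")
    layout = np.zeros(mask.shape, dtype=np.uint8)
    if collapse_score is None:
        collapse_score = default_collapse_score(mask, rng)
    score = collapse_score[m]
    order = np.argsort(score)[::-1]  # most ventral (highest score) first
    n_non = int(round(f[0] * n_lung))
    lin = np.flatnonzero(m.ravel())
    flat = layout.ravel()
    flat[lin[order[:n_non]]] = Compartment.NON_AERATED
    rest = lin[order[n_non:]]
    if len(rest):
        p_rest = f[1:] / f[1:].sum() if f[1:].sum() > 0 else np.array([0.0, 1.0, 0.0])
        labels = rng.choice(
            [Compartment.POORLY_AERATED, Compartment.NORMALLY_AERATED, Compartment.HYPER_AERATED],
            size=len(rest),
            p=p_rest,
        )
        flat[rest] = labels
    return layout


def default_collapse_score(mask: BinaryMask, rng: np.random.Generator, jitter: float = 0.15) -> np.ndarray:
    """Ventral-position score with a smooth random perturbation.

    The perturbation makes the collapse front irregular rather than a flat
    DV plane, while keeping the region ventral-anchored and connected.
    """
    shape = mask.shape
    t = np.zeros(shape)
    dv = np.arange(shape[DV], dtype=float)
    idx = np.flatnonzero(mask.data.any(axis=(0, 2)))
    lo, hi = (idx[0], idx[-1]) if len(idx) else (0, shape[DV] - 1)
    tv = (dv - lo) / max(hi - lo, 1)
    t += tv[None, :, None]
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=max(min(shape) / 12.0, 2.0))
    sd = noise.std()
    if sd > 0:
        noise /= sd
    return t + jitter * noise


# ------------------------------------------------------------------ imaging


def make_ct_from_labels(
    layout: np.ndarray, spec: PhantomSpec, rng: np.random.Generator | int
) -> CTImage:
    """Forward imaging model: Gaussian HU around each compartment mean.

    Background voxels take the soft-tissue HU constant.  Reproducible for a
    fixed seed/generator.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    known = {int(c) for c in Compartment}
    present = set(np.unique(layout).tolist())
    if not present <= known:
        raise ValueError(f"unknown labels in layout: {sorted(present - known)}")
    hu = np.full(layout.shape, SOFT_TISSUE_HU, dtype=np.float32)
    for comp, mean in spec.compartment_hu_means.items():
        sel = layout == int(comp)
        if sel.any():
            hu[sel] = mean
    lung = layout != int(Compartment.BACKGROUND)
    if spec.hu_noise_sd > 0 and lung.any():
        hu[lung] += rng.normal(0.0, spec.hu_noise_sd, size=int(lung.sum())).astype(np.float32)
    return CTImage(hu, spec.spacing)


# ----------------------------------------------------------------- the warp


def make_separable_warp(spec: PhantomSpec) -> GroundTruth:
    """Closed-form separable stretch with exact Jacobian.

    Returns a :class:`GroundTruth` whose ``displacement`` is the backward
    (EI -> EE) map and whose ``jacobian`` is the forward determinant at EI
    points; both are smooth closed forms consistent with each other (a
    finite-difference check of the displacement reproduces the Jacobian).
    """
    spec.strain_profile.validate()
    prof = spec.strain_profile
    c = spec.center
    ylo, yhi = spec.dv_extent()
    span = yhi - ylo

    def a_lr_of_y(y: np.ndarray) -> np.ndarray:
        t = (y - ylo) / span
        return prof.a_lr + prof.dv_gradient * (0.5 - t)

    # Guard J > 0 over the whole grid's DV extent.
    y_grid = np.array([0.0, (spec.grid_shape[DV] - 1) * spec.spacing])
    if (a_lr_of_y(y_grid) <= 0).any():
        raise ValueError("strain profile folds (a_lr <= 0) inside the grid")

    def forward(points_ee: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_ee, float))
        out = np.empty_like(p)
        out[:, AB] = c[AB] + prof.a_ab * (p[:, AB] - c[AB])
        out[:, DV] = c[DV] + prof.a_dv * (p[:, DV] - c[DV])
        out[:, LR] = c[LR] + a_lr_of_y(p[:, DV]) * (p[:, LR] - c[LR])
        return out

    def inverse(points_ei: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_ei, float))
        out = np.empty_like(p)
        out[:, DV] = c[DV] + (p[:, DV] - c[DV]) / prof.a_dv
        out[:, AB] = c[AB] + (p[:, AB] - c[AB]) / prof.a_ab
        out[:, LR] = c[LR] + (p[:, LR] - c[LR]) / a_lr_of_y(out[:, DV])
        return out

    def displacement(points_ei: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_ei, float))
        return inverse(p) - p

    def jacobian(points_ei: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_ei, float))
        y_ee = c[DV] + (p[:, DV] - c[DV]) / prof.a_dv
        return prof.a_ab * prof.a_dv * a_lr_of_y(y_ee)

    gt = GroundTruth(
        displacement=displacement,
        jacobian=jacobian,
        compartment_layout=np.zeros(spec.grid_shape, np.uint8),
        spacing=spec.spacing,
    )
    gt.forward = forward  # type: ignore[attr-defined]  # handy for warping layouts
    gt.inverse = inverse  # type: ignore[attr-defined]
    return gt


def warp_layout_forward(layout: np.ndarray, gt: GroundTruth, spec: PhantomSpec) -> np.ndarray:
    """Resample an EE label volume onto the EI grid (nearest neighbour).

    For every EI voxel centre the closed-form inverse map gives the exact
    EE pre-image; the label there is looked up with nearest-neighbour
    rounding, so the warped layout has no interpolation mixing.
    """
    shape = layout.shape
    h = spec.spacing
    idx = np.indices(shape).reshape(3, -1).T * h
    pre = gt.inverse(idx) / h  # type: ignore[attr-defined]
    pre = np.round(pre).astype(int)
    ok = np.all((pre >= 0) & (pre < np.asarray(shape)), axis=1)
    out = np.zeros(np.prod(shape), dtype=layout.dtype)
    out[ok] = layout[pre[ok, 0], pre[ok, 1], pre[ok, 2]]
    return out.reshape(shape)


# ------------------------------------------------------------------- cohort

#: Group/time presets.  Stretch magnitudes are set so the whole-lung strain
#: matches the global-strain scale reported for each group (SB ~23% at T1
#: rising to ~33% at T3; MV ~19% at both times), the SB non-aerated fraction
#: grows 13.3% -> 37.5% while MV stays flat, and strain heterogeneity
#: (the dorsoventral stretch gradient) amplifies over time in SB only.
PRESETS: dict[tuple[str, str], dict] = {
    ("SB", "T1"): dict(
        fractions=(0.133, 0.170, 0.647, 0.050), fraction_sd=0.016,
        stretch=1.07, dv_gradient=0.05,
    ),
    ("SB", "T3"): dict(
        fractions=(0.375, 0.200, 0.395, 0.030), fraction_sd=0.031,
        stretch=1.10, dv_gradient=0.15,
    ),
    ("MV", "T1"): dict(
        fractions=(0.100, 0.150, 0.700, 0.050), fraction_sd=0.016,
        stretch=1.06, dv_gradient=0.05,
    ),
    ("MV", "T3"): dict(
        fractions=(0.100, 0.150, 0.700, 0.050), fraction_sd=0.016,
        stretch=1.06, dv_gradient=0.05,
    ),
}

#: Physiology presets: body mass (g) and respiratory rate (1/min) as
#: group-level mean and between-subject SD.  Body mass is scaled to the
#: default phantom's lung volume (the phantom is a miniature) so that the
#: volumetric indices land on the scale reported for small rodents:
#: aerated EE volume / mass ~ 26 ml/kg (SB) and ~ 33 ml/kg (MV) at T1.
#: Relative between-subject spreads match the reported ones.
PHYSIOLOGY = {
    "SB": dict(mass_g=(4.6, 0.27), rr={"T1": (117.0, 22.0), "T3": (129.0, 29.0)}),
    "MV": dict(mass_g=(3.8, 0.42), rr={"T1": (90.0, 0.0), "T3": (90.0, 0.0)}),
}


@dataclass
class PhantomSubject:
    """All per-(subject, time) phantom artefacts."""

    subject_id: str
    group: str
    time: str
    ct_ee: CTImage
    ct_ei: CTImage
    mask_ee: BinaryMask
    mask_ei: BinaryMask
    layout_ee: np.ndarray
    layout_ei: np.ndarray
    ground_truth: GroundTruth
    manifest: dict


def _jitter_preset(
    preset: dict, stretch_mult: float, frac_shift: float
) -> tuple[tuple, StrainProfile]:
    base = np.asarray(preset["fractions"], float)
    f_non = float(np.clip(base[0] + frac_shift, 0.02, 0.80))
    rest = base[1:] * (1 - f_non) / base[1:].sum()
    fractions = (f_non, *rest.tolist())
    a = 1.0 + (preset["stretch"] - 1.0) * stretch_mult
    prof = StrainProfile(a_ab=a, a_dv=a, a_lr=a, dv_gradient=preset["dv_gradient"] * stretch_mult)
    return fractions, prof


def generate_subject(
    group: Group,
    time: Time,
    spec: PhantomSpec,
    seed: int | np.random.SeedSequence,
    *,
    subject_id: str = "s00",
    subject_scale: dict | None = None,
) -> PhantomSubject:
    """Generate the EE/EI pair for one subject at one study time.

    ``subject_scale`` carries the per-subject random effects (stretch
    multiplier, collapse-fraction shift, collapse score field, body mass,
    respiratory rates) shared between T1 and T3 so that progression within
    a subject is monotone; when omitted it is drawn from ``seed``.
    """
    if (group, time) not in PRESETS:
        raise ValueError(f"unknown group/time preset: {group}/{time}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng_anat, rng_collapse, rng_ee, rng_ei = (np.random.default_rng(s) for s in ss.spawn(4))

    mask_ee = make_lung_mask(spec)
    if subject_scale is None:
        subject_scale = draw_subject_effects(group, mask_ee, rng_anat, rng_collapse)
    preset = PRESETS[(group, time)]
    fractions, prof = _jitter_preset(
        preset,
        subject_scale["stretch_mult"][time],
        subject_scale["frac_shift"][time] * preset["fraction_sd"] / 0.016,
    )
    spec_t = replace(spec, compartment_fractions=fractions, strain_profile=prof)

    layout_ee = make_compartment_layout(
        mask_ee, fractions, rng_anat, collapse_score=subject_scale["collapse_score"]
    )
    gt = make_separable_warp(spec_t)
    gt.compartment_layout = layout_ee
    layout_ei = warp_layout_forward(layout_ee, gt, spec_t)
    ct_ee = make_ct_from_labels(layout_ee, spec_t, rng_ee)
    ct_ei = make_ct_from_labels(layout_ei, spec_t, rng_ei)
    mask_ei = BinaryMask(layout_ei != int(Compartment.BACKGROUND), spec.spacing)

    manifest = dict(
        subject_id=subject_id,
        group=group,
        time=time,
        body_mass_g=subject_scale["mass_g"],
        rr_per_min=subject_scale["rr"][time],
    )
    return PhantomSubject(
        subject_id, group, time, ct_ee, ct_ei, mask_ee, mask_ei,
        layout_ee, layout_ei, gt, manifest,
    )


def draw_subject_effects(
    group: Group,
    mask: BinaryMask,
    rng_anat: np.random.Generator,
    rng_collapse: np.random.Generator,
) -> dict:
    """Per-subject random effects shared across the subject's time points."""
    phys = PHYSIOLOGY[group]
    mult = {t: float(np.exp(rng_anat.normal(0.0, 0.08))) for t in ("T1", "T3")}
    if group == "MV":
        mult["T3"] = mult["T1"]  # MV presets identical up to imaging noise
    shift = {t: float(rng_anat.normal(0.0, 0.016)) for t in ("T1", "T3")}
    if group == "MV":
        shift["T3"] = shift["T1"]
    return dict(
        stretch_mult=mult,
        frac_shift=shift,
        collapse_score=default_collapse_score(mask, rng_collapse),
        mass_g=float(rng_anat.normal(*phys["mass_g"])),
        rr={t: float(rng_anat.normal(*phys["rr"][t])) for t in ("T1", "T3")},
    )


def generate_cohort(
    spec: PhantomSpec,
    seed: int,
    *,
    n_per_group: int = 5,
    groups: tuple[str, ...] = ("SB", "MV"),
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PhantomSubject]]:
    """Generate the full two-group, two-time cohort.

    Returns the manifest (one row per subject x time x phase) and the
    in-memory subjects keyed by ``(subject_id, time)``.  When ``out_dir``
    is given, CT volumes and whole-lung masks are written as NIfTI-1 and
    the manifest as CSV; an existing non-empty directory is refused unless
    ``overwrite`` is set.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
        out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(int(seed))
    subject_seeds = master.spawn(len(groups) * n_per_group)
    rows = []
    subjects: dict[tuple[str, str], PhantomSubject] = {}
    k = 0
    for group in groups:
        for i in range(n_per_group):
            sid = f"{group.lower()}{i + 1:02d}"
            ss = subject_seeds[k]
            k += 1
            # Shared subject effects: drawn once, reused for T1 and T3.
            eff_streams = ss.spawn(3)
            mask0 = make_lung_mask(spec)
            effects = draw_subject_effects(
                group,
                mask0,
                np.random.default_rng(eff_streams[0]),
                np.random.default_rng(eff_streams[1]),
            )
            time_seeds = eff_streams[2].spawn(2)
            for time, tss in zip(("T1", "T3"), time_seeds):
                subj = generate_subject(
                    group, time, spec, tss, subject_id=sid, subject_scale=effects
                )
                subjects[(sid, time)] = subj
                for phase in ("EE", "EI"):
                    ct = subj.ct_ee if phase == "EE" else subj.ct_ei
                    msk = subj.mask_ee if phase == "EE" else subj.mask_ei
                    row = dict(subj.manifest)
                    row["phase"] = phase
                    if out_dir is not None:
                        img_path = out_dir / f"{sid}_{time}_{phase}_ct.nii.gz"
                        mask_path = out_dir / f"{sid}_{time}_{phase}_mask.nii.gz"
                        save_nifti(ct.data, spec.spacing, img_path)
                        save_nifti(msk.data, spec.spacing, mask_path)
                        row["path"] = str(img_path)
                        row["mask_path"] = str(mask_path)
                    rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, subjects
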