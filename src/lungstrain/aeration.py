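"""HU aeration compartments, aerated-lung masks and global volume metrics.

Lung voxels are classified into four aeration compartments from their
Hounsfield-unit value.  The default thresholds are the standard
quantitative-CT ranges,

    hyper-aerated   [-1000, -900)
    normally aerated [-900, -500)
    poorly aerated   [-500, -100)
    non-aerated      [-100, +100]

with half-open, lower-closed intervals so every voxel lands in exactly one
compartment.  They are configurable: published studies vary in the exact
cut-points.

Global metrics follow the usual CT-volumetry definitions: EELV and EILV are
the aerated-lung volumes at end-expiration and end-inspiration,
Vt = EILV - EELV, global strain = Vt / EELV, and Vmin = RR x Vt.  Volumes
are normalised per kilogram of body mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AerationMap, BinaryMask, CTImage, Compartment

HU_RANGE = (-1000.0, 100.0)


@dataclass(frozen=True)
class AerationThresholds:
    """Strictly increasing HU boundaries partitioning [-1000, +100].

    ``hyper_normal`` separates hyper- from normally aerated, and so on;
    intervals are half-open, closed on the lower (more negative) side.
    """

    hyper_normal: float = -900.0
    normal_poor: float = -500.0
    poor_non: float = -100.0

    def __post_init__(self) -> None:
        b = (HU_RANGE[0], self.hyper_normal, self.normal_poor, self.poor_non, HU_RANGE[1])
        if not all(b[i] < b[i + 1] for i in range(4)):
            raise ValueError(f"thresholds must be strictly increasing inside {HU_RANGE}: {b}")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.hyper_normal, self.normal_poor, self.poor_non])


#: Compartment order along increasing HU, matching the threshold edges.
_HU_ORDER = (
    Compartment.HYPER_AERATED,
    Compartment.NORMALLY_AERATED,
    Compartment.POORLY_AERATED,
    Compartment.NON_AERATED,
)


def classify_aeration(
    ct: CTImage,
    whole_mask: BinaryMask,
    thresholds: AerationThresholds | None = None,
) -> AerationMap:
    """Classify every masked voxel into exactly one aeration compartment.

    Voxels with HU outside [-1000, +100] are clamped to the nearest
    compartment and counted in the map's ``n_clamped`` QC field.
    """
    if thresholds is None:
        thresholds = AerationThresholds()
    if ct.shape != whole_mask.shape:
        raise ValueError(f"CT grid {ct.shape} != mask grid {whole_mask.shape}")
    if abs(ct.spacing - whole_mask.spacing) > 1e-9:
        raise ValueError("CT and mask spacing differ")
    m = whole_mask.data
    hu = np.asarray(ct.data, float)[m]
    n_clamped = int(((hu < HU_RANGE[0]) | (hu > HU_RANGE[1])).sum())
    # searchsorted with side='right' makes intervals lower-closed:
    # hu == edge goes to the compartment above the edge.
    bins = np.searchsorted(thresholds.edges, hu, side="right")
    labels = np.zeros(ct.shape, dtype=np.uint8)
    lut = np.array([int(c) for c in _HU_ORDER], dtype=np.uint8)
    labels[m] = lut[bins]
    return AerationMap(labels, ct.spacing, n_clamped=n_clamped)


def compartment_fractions(am: AerationMap) -> dict[Compartment, float]:
    """Volume fraction of each compartment within the lung; sums to 1."""
    lung = am.labels != int(Compartment.BACKGROUND)
    total = int(lung.sum())
    if total == 0:
        raise ValueError("empty aeration map")
    counts = np.bincount(am.labels[lung].ravel(), minlength=5)
    return {
        c: counts[int(c)] / total
        for c in (
            Compartment.NON_AERATED,
            Compartment.POORLY_AERATED,
            Compartment.NORMALLY_AERATED,
            Compartment.HYPER_AERATED,
        )
    }


def aerated_mask(am: AerationMap) -> BinaryMask:
    """Poor + normal + hyper compartments; the non-aerated region is excluded."""
    sel = (
        (am.labels == int(Compartment.POORLY_AERATED))
        | (am.labels == int(Compartment.NORMALLY_AERATED))
        | (am.labels == int(Compartment.HYPER_AERATED))
    )
    mask = BinaryMask(sel, am.spacing)
    if mask.voxel_count == 0:
        import warnings

        warnings.warn("aerated mask is empty (entire lung non-aerated)", stacklevel=2)
    return mask


def clean_aerated_mask(mask: BinaryMask, min_fraction: float = 0.01) -> tuple[BinaryMask, dict]:
    """Morphological QC of a classified aerated mask.

    HU noise at compartment boundaries produces isolated misclassified
    voxels (speckle) inside collapsed regions.  A binary opening removes
    them and the largest connected component is kept; components above
    ``min_fraction`` of the total would indicate a genuinely split lung
    and are reported in the QC dict.  This automated step replaces the
    manual expert review of segmentation masks.
    """
    import scipy.ndimage as ndi

    m = mask.data
    opened = ndi.binary_opening(m)
    labels, n_comp = ndi.label(opened)
    if n_comp == 0:
        return BinaryMask(opened, mask.spacing), dict(removed_voxels=int(m.sum()), n_components=0)
    sizes = np.bincount(labels.ravel())[1:]
    keep = labels == (int(np.argmax(sizes)) + 1)
    qc = dict(
        removed_voxels=int(m.sum() - keep.sum()),
        n_components=int(n_comp),
        secondary_components_above_threshold=int(
            ((sizes >= min_fraction * sizes.sum()).sum()) - 1
        ),
    )
    return BinaryMask(keep, mask.spacing), qc


def dorsoventral_split(mask: BinaryMask) -> tuple[BinaryMask, BinaryMask, dict]:
    """Split a mask into dorsal and ventral halves of (near-)equal volume.

    The cut plane is placed along the DV axis where the cumulative volume
    is closest to half, so the two halves differ by at most one DV-slab
    volume.  Returns (dorsal, ventral, info); ``info['degenerate']`` is set
    when all mass lies in a single slab and an equal split is impossible.
    """
    m = mask.data
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty mask")
    per_slab = m.sum(axis=(0, 2))  # DV axis is axis 1
    cum = np.cumsum(per_slab)
    cut = int(np.argmin(np.abs(cum - total / 2.0))) + 1
    dorsal = np.zeros_like(m)
    ventral = np.zeros_like(m)
    dorsal[:, :cut, :] = m[:, :cut, :]
    ventral[:, cut:, :] = m[:, cut:, :]
    info = {
        "cut_index": cut,
        "imbalance_voxels": int(abs(2 * cum[cut - 1] - total)),
        "degenerate": bool((per_slab > 0).sum() <= 1),
    }
    return BinaryMask(dorsal, mask.spacing), BinaryMask(ventral, mask.spacing), info


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-lung volume and ventilation metrics (volumes in ml/kg)."""

    eelv_ml_kg: float
    eilv_ml_kg: float
    vt_ml_kg: float
    global_strain_pct: float
    vmin_ml_min_kg: float
    rr_per_min: float
    body_mass_kg: float


def global_metrics(
    aerated_ee: BinaryMask,
    aerated_ei: BinaryMask,
    body_mass_kg: float,
    rr_per_min: float,
) -> GlobalMetrics:
    """EELV/EILV from the aerated masks; Vt, global strain and Vmin derived.

    Mask volumes are voxel count x voxel volume (1 mm^3 = 0.001 ml),
    normalised per kg of body mass.  Raises when EELV is zero (global
    strain undefined) or body mass is non-positive.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    ml_ee = aerated_ee.volume_mm3() * 1e-3
    ml_ei = aerated_ei.volume_mm3() * 1e-3
    if ml_ee == 0:
        raise ValueError("EELV is zero; global strain undefined")
    eelv = ml_ee / body_mass_kg
    eilv = ml_ei / body_mass_kg
    vt = eilv - eelv
    return GlobalMetrics(
        eelv_ml_kg=eelv,
        eilv_ml_kg=eilv,
        vt_ml_kg=vt,
        global_strain_pct=100.0 * vt / eelv,
        vmin_ml_min_kg=rr_per_min * vt,
        rr_per_min=rr_per_min,
        body_mass_kg=body_mass_kg,
    )
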