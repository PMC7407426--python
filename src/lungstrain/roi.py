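"""10 x 10 ROI partition of the lung and regional strain statistics.

The lung is cut into ten apical-basal (AB) slabs and ten dorsal-ventral
(DV) slabs of approximately equal tetrahedral volume; intersecting them
yields a 10 x 10 grid of regions of interest.  AB x DV cells that no
tetrahedron falls into are *void* and carry no statistics.  Per occupied
cell the package reports the volume-weighted mean and SD of the
per-tetrahedron volumetric strain, and from them two indices:

* SPI, strain progression index: (1 + mean_T3) / (1 + mean_T1) for the
  positionally corresponding cell at the two study times.  SPI = 1 means
  no evolution; SPI > 1 temporal amplification of regional strain.
* SHI, strain heterogeneity index: (1 + SD) / (1 + mean) within a cell
  at one time, a dispersion measure on the relative-volume scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .mesh import StrainField


def axis_partition(field: StrainField, axis: int, n: int = 10) -> np.ndarray:
    """Slab boundaries along ``axis`` with ~equal tet volume per slab.

    Boundaries are read off the volume-weighted cumulative distribution of
    tet centroid coordinates; each slab then holds total/n volume up to
    the granularity of tied centroid coordinates.  Returns n+1 boundaries;
    slabs are half-open with the last slab closed.
    """
    if n < 2:
        raise ValueError("need at least 2 slabs")
    if field.centroid.shape[0] == 0:
        raise ValueError("empty strain field")
    coord = field.centroid[:, axis]
    w = field.ei_volume
    order = np.argsort(coord, kind="stable")
    c_sorted = coord[order]
    cum = np.cumsum(w[order])
    total = cum[-1]
    bounds = np.empty(n + 1)
    bounds[0], bounds[-1] = c_sorted[0], c_sorted[-1]
    for k in range(1, n):
        i = int(np.searchsorted(cum, total * k / n))
        # place the cut between this coordinate and the next distinct one
        j = int(np.searchsorted(c_sorted, c_sorted[i], side="right"))
        if j >= len(c_sorted):
            bounds[k] = c_sorted[-1]
        else:
            bounds[k] = 0.5 * (c_sorted[min(i, j - 1)] + c_sorted[j])
    return bounds


@dataclass
class ROIGrid:
    """Assignment of every tet to one AB x DV cell (centroid rule)."""

    ab_bounds: np.ndarray
    dv_bounds: np.ndarray
    cell_of_tet: np.ndarray  # (n_tets,) flat cell index ab * n + dv
    occupied: np.ndarray  # (n, n) bool
    n: int = 10

    @property
    def void(self) -> np.ndarray:
        return ~self.occupied

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    def degenerate(self) -> bool:
        """True when some inner boundaries coincide (equal split impossible)."""
        return bool(
            (np.diff(self.ab_bounds) <= 0).any() or (np.diff(self.dv_bounds) <= 0).any()
        )


def _bin_index(coord: np.ndarray, bounds: np.ndarray, n: int) -> np.ndarray:
    # half-open slabs, ties to the lower slab; last slab closed
    idx = np.searchsorted(bounds[1:-1], coord, side="left")
    return np.clip(idx, 0, n - 1)


def build_roi_grid(
    field: StrainField, ab_bounds: np.ndarray, dv_bounds: np.ndarray, n: int = 10
) -> ROIGrid:
    """Bin tets into the AB x DV grid by centroid; flag void cells."""
    from .core import AB, DV

    ab_idx = _bin_index(field.centroid[:, AB], np.asarray(ab_bounds, float), n)
    dv_idx = _bin_index(field.centroid[:, DV], np.asarray(dv_bounds, float), n)
    cell = ab_idx * n + dv_idx
    counts = np.bincount(cell, minlength=n * n)
    return ROIGrid(
        ab_bounds=np.asarray(ab_bounds, float),
        dv_bounds=np.asarray(dv_bounds, float),
        cell_of_tet=cell,
        occupied=(counts > 0).reshape(n, n),
        n=n,
    )


def make_roi_grid(field: StrainField, n: int = 10) -> ROIGrid:
    """Equal-volume partition along AB and DV, then intersection."""
    from .core import AB, DV

    return build_roi_grid(
        field, axis_partition(field, AB, n), axis_partition(field, DV, n), n
    )


@dataclass
class ROIStats:
    """Per-cell volume-weighted strain statistics (NaN on void cells)."""

    mean: np.ndarray  # (n, n)
    sd: np.ndarray
    volume: np.ndarray  # total EI tet volume per cell, mm^3
    count: np.ndarray  # tets per cell
    n: int = 10

    @property
    def shi(self) -> np.ndarray:
        return shi(self.mean, self.sd)


def roi_weighted_stats(field: StrainField, grid: ROIGrid) -> ROIStats:
    """Volume-weighted mean and population SD of strain per occupied cell.

    mean = sum(w e) / sum(w), sd = sqrt(sum(w (e - mean)^2) / sum(w)) with
    w the EI tet volume.  Void cells get NaN, not zero.
    """
    n = grid.n
    w = field.ei_volume
    e = field.strain
    cell = grid.cell_of_tet
    size = n * n
    sw = np.bincount(cell, weights=w, minlength=size)
    swe = np.bincount(cell, weights=w * e, minlength=size)
    swe2 = np.bincount(cell, weights=w * e * e, minlength=size)
    count = np.bincount(cell, minlength=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = swe / sw
        var = np.maximum(swe2 / sw - mean**2, 0.0)
    mean[sw == 0] = np.nan
    var[sw == 0] = np.nan
    return ROIStats(
        mean=mean.reshape(n, n),
        sd=np.sqrt(var).reshape(n, n),
        volume=sw.reshape(n, n),
        count=count.reshape(n, n),
        n=n,
    )


def cell_strain_samples(field: StrainField, grid: ROIGrid) -> dict[tuple[int, int], np.ndarray]:
    """Per-cell arrays of tet strains (for distribution-level tests)."""
    n = grid.n
    order = np.argsort(grid.cell_of_tet, kind="stable")
    sorted_cells = grid.cell_of_tet[order]
    boundaries = np.searchsorted(sorted_cells, np.arange(n * n + 1))
    out = {}
    for c in range(n * n):
        lo, hi = boundaries[c], boundaries[c + 1]
        if hi > lo:
            out[(c // n, c % n)] = field.strain[order[lo:hi]]
    return out


def spi(mean_t1: np.ndarray | float, mean_t3: np.ndarray | float) -> np.ndarray | float:
    """Strain progression index (1 + mean_T3) / (1 + mean_T1).

    NaN inputs (void cells) propagate; finite means <= -1 are physically
    impossible (negative volume) and raise.
    """
    m1 = np.asarray(mean_t1, float)
    m3 = np.asarray(mean_t3, float)
    if (m1[np.isfinite(m1)] <= -1).any() or (m3[np.isfinite(m3)] <= -1).any():
        raise ValueError("ROI mean strain <= -1 is not a valid volume change")
    out = (1.0 + m3) / (1.0 + m1)
    return float(out) if np.isscalar(mean_t1) and np.isscalar(mean_t3) else out


def shi(mean: np.ndarray | float, sd: np.ndarray | float) -> np.ndarray | float:
    """Strain heterogeneity index (1 + SD) / (1 + mean)."""
    m = np.asarray(mean, float)
    s = np.asarray(sd, float)
    if (m[np.isfinite(m)] <= -1).any():
        raise ValueError("ROI mean strain <= -1 is not a valid volume change")
    if (s[np.isfinite(s)] < 0).any():
        raise ValueError("SD must be non-negative")
    out = (1.0 + s) / (1.0 + m)
    return float(out) if np.isscalar(mean) and np.isscalar(sd) else out


def percentage_significant(flags: np.ndarray, occupied_count: int) -> float:
    """100 x significant / occupied, rounded half-up to one decimal.

    Reproduces the reporting arithmetic used for ROI-map summaries (e.g.
    38 significant of 87 occupied -> 43.7).
    """
    if occupied_count < 1:
        raise ValueError("no occupied ROIs")
    k = int(np.asarray(flags, bool).sum())
    pct = Decimal(100 * k) / Decimal(occupied_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
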