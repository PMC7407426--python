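"""Tetrahedral meshing of the aerated lung and per-element volumetric strain.

Each aerated voxel is split into six tetrahedra by the Kuhn (Freudenthal)
decomposition along a globally consistent main diagonal, so the mesh is
conforming across voxel faces and partitions the mask volume exactly.  The
mesh lives in the end-inspiration (EI) configuration; warping its nodes by
the backward displacement field gives the end-expiration (EE) reference
configuration, and the per-tetrahedron volumetric strain is

    epsilon = J - 1,    J = det F = V_EI / V_EE,

the relative volume change of the element from expiration to inspiration
(inflation => epsilon > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np

from .core import BinaryMask
from .registration import DisplacementField, sample_displacement


def _kuhn_corner_tets() -> np.ndarray:
    """The 6 tetrahedra of the unit cube sharing diagonal (0,0,0)-(1,1,1).

    Corners are numbered ``c = 4*x + 2*y + z``.  Each permutation of the
    axes yields one tet walking the diagonal; vertex order is fixed so the
    signed volume is positive.
    """
    tets = []
    for perm in permutations(range(3)):
        verts = [(0, 0, 0)]
        v = [0, 0, 0]
        for ax in perm:
            v = list(v)
            v[ax] = 1
            verts.append(tuple(v))
        p = np.array(verts, float)
        vol = np.linalg.det(p[1:] - p[0]) / 6.0
        if vol < 0:
            verts[2], verts[3] = verts[3], verts[2]
        tets.append([4 * x + 2 * y + z for (x, y, z) in verts])
    return np.array(tets, dtype=np.int64)


KUHN_TETS = _kuhn_corner_tets()

#: Corner offsets of a voxel cube, indexed as c = 4*dx + 2*dy + dz.
_CORNER_OFFSETS = np.array([[c >> 2 & 1, c >> 1 & 1, c & 1] for c in range(8)], dtype=np.int64)


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh over a voxel mask.

    nodes: (n_nodes, 3) coordinates in mm (EI configuration);
    tets: (n_tets, 4) node indices, all positively oriented;
    tet_voxel: (n_tets,) linear index of the source voxel (QC provenance).
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_voxel: np.ndarray
    spacing: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self, nodes: np.ndarray | None = None) -> np.ndarray:
        nodes = self.nodes if nodes is None else nodes
        p = nodes[self.tets]
        return signed_tet_volume(p[:, 0], p[:, 1], p[:, 2], p[:, 3])

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)


def signed_tet_volume(p0, p1, p2, p3) -> np.ndarray:
    """Signed volume det[p1-p0, p2-p0, p3-p0] / 6 (mm^3); vectorised."""
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, float)) for p in (p0, p1, p2, p3))
    e = np.stack([p1 - p0, p2 - p0, p3 - p0], axis=-2)
    return np.linalg.det(e) / 6.0


def tetrahedralize_mask(mask: BinaryMask) -> TetMesh:
    """Kuhn-split every masked voxel into 6 tets with shared corner nodes.

    Voxel (i, j, k) occupies the cube centred at (i, j, k) * h; its corner
    lattice point (ci, cj, ck) in {0..n} maps to coordinate (c - 1/2) * h.
    The decomposition partitions the mask volume exactly: the total mesh
    volume equals voxel_count * h^3.
    """
    m = mask.data
    if not m.any():
        raise ValueError("cannot mesh an empty mask")
    h = mask.spacing
    shape = m.shape
    vox = np.argwhere(m)  # (nvox, 3)

    corner_shape = tuple(n + 1 for n in shape)
    used = np.zeros(corner_shape, dtype=bool)
    for off in _CORNER_OFFSETS:
        used[off[0] : off[0] + shape[0], off[1] : off[1] + shape[1], off[2] : off[2] + shape[2]] |= m
    node_id = np.full(corner_shape, -1, dtype=np.int64)
    corner_idx = np.argwhere(used)
    node_id[used] = np.arange(len(corner_idx))
    nodes = (corner_idx - 0.5) * h

    # Node ids of the 8 corners of each masked voxel, then the 6 Kuhn tets.
    corner_ids = np.empty((len(vox), 8), dtype=np.int64)
    for c, off in enumerate(_CORNER_OFFSETS):
        p = vox + off
        corner_ids[:, c] = node_id[p[:, 0], p[:, 1], p[:, 2]]
    tets = corner_ids[:, KUHN_TETS]  # (nvox, 6, 4)
    tets = tets.reshape(-1, 4)
    lin = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
    tet_voxel = np.repeat(lin, 6)
    return TetMesh(nodes=nodes, tets=tets, tet_voxel=tet_voxel, spacing=h)


def warp_mesh_to_reference(mesh: TetMesh, field: DisplacementField) -> np.ndarray:
    """Push EI nodes to the EE configuration: x_ref = x + u(x).

    Displacements are sampled trilinearly; nodes outside the field grid
    raise (no extrapolation).
    """
    u = sample_displacement(field, mesh.nodes)
    return mesh.nodes + u


@dataclass
class StrainField:
    """Per-tetrahedron volumetric strain over the EI mesh.

    strain: epsilon = J - 1 per tet; ref_volume: EE (reference) volume in
    mm^3; ei_volume: EI volume in mm^3; centroid: tet centroid in EI
    coordinates (mm).
    """

    strain: np.ndarray
    ref_volume: np.ndarray
    ei_volume: np.ndarray
    centroid: np.ndarray
    spacing: float

    @property
    def jacobian(self) -> np.ndarray:
        return self.strain + 1.0


def volumetric_strain(mesh: TetMesh, reference_nodes: np.ndarray) -> StrainField:
    """Per-tet strain from EI and reference (EE) configurations.

    J is the volume ratio V_EI / V_EE, identical to det(F) for the
    element-wise affine map between the configurations (see
    :func:`deformation_gradient_jacobians` for the explicit cross-check).
    Raises if any reference tet is degenerate or inverted.
    """
    v_ei = mesh.tet_volumes()
    v_ee = mesh.tet_volumes(np.asarray(reference_nodes, float))
    bad = np.flatnonzero(v_ee <= 0)
    if len(bad):
        raise ValueError(
            f"{len(bad)} reference tet(s) with non-positive volume, "
            f"e.g. tet ids {bad[:10].tolist()}"
        )
    jac = v_ei / v_ee
    return StrainField(
        strain=jac - 1.0,
        ref_volume=v_ee,
        ei_volume=v_ei,
        centroid=mesh.centroids(),
        spacing=mesh.spacing,
    )


def deformation_gradient_jacobians(mesh: TetMesh, reference_nodes: np.ndarray) -> np.ndarray:
    """det F per tet via the edge-matrix deformation gradient.

    F = E_EI . E_EE^-1 with E the 3x3 matrix of edge vectors from node 0.
    Used as an independent cross-check of the volume-ratio Jacobian.
    """
    ref = np.asarray(reference_nodes, float)
    p_ei = mesh.nodes[mesh.tets]
    p_ee = ref[mesh.tets]
    e_ei = np.stack([p_ei[:, i] - p_ei[:, 0] for i in (1, 2, 3)], axis=-1)
    e_ee = np.stack([p_ee[:, i] - p_ee[:, 0] for i in (1, 2, 3)], axis=-1)
    f = e_ei @ np.linalg.inv(e_ee)
    return np.linalg.det(f)


def write_vtu(path: str | Path, mesh: TetMesh, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (+ per-tet scalars) as an ASCII VTU unstructured grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_pts, n_cells = mesh.n_nodes, mesh.n_tets
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines.append("\n".join(" ".join(f"{v:.8g}" for v in row) for row in mesh.nodes))
    lines += [
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in tet) for tet in mesh.tets),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(n_cells)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("10" for _ in range(n_cells)),
        "        </DataArray>",
        "      </Cells>",
    ]
    if cell_data:
        lines.append("      <CellData>")
        for name, arr in cell_data.items():
            lines.append(f'        <DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(" ".join(f"{v:.8g}" for v in np.asarray(arr, float)))
            lines.append("        </DataArray>")
        lines.append("      </CellData>")
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
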