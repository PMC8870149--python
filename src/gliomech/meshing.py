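"""Tetrahedral meshes for the concentric-spheres domain, plus P1 geometry helpers.

The default geometry replaces the anatomical brain with a host ball (radius
50 mm) containing a concentric 5 mm spherical tumor seed; the brain surface
only contributes the far-field fixed boundary, so this loses nothing the model
uses.  The mesh is a "spherified cube": a structured hex lattice on [-1,1]^3 is
Kuhn-split into 6 conforming tetrahedra per cell and each cubic shell
``max|p| = const`` is mapped onto a sphere whose radius follows a graded radial
schedule (uniform inside the tumor, geometric in the host so the tumor rim is
resolved).  Node shells land exactly on the tumor surface.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["Mesh", "ball_mesh", "write_vtk"]

# Kuhn/Freudenthal split: 6 tets per hex, all sharing the main diagonal v0-v7.
# Vertex bits (x, y, z) -> local index x + 2y + 4z.
_KUHN_PATHS = [
    (0, 1, 3, 7),  # x, y, z
    (0, 1, 5, 7),  # x, z, y
    (0, 2, 3, 7),  # y, x, z
    (0, 2, 6, 7),  # y, z, x
    (0, 4, 5, 7),  # z, x, y
    (0, 4, 6, 7),  # z, y, x
]


@dataclasses.dataclass
class Mesh:
    """Spherified-cube mesh carrying both hexahedra and their Kuhn tetrahedra.

    The mechanics solver integrates on the trilinear hexahedra (selective
    reduced integration avoids volumetric locking); the scalar transport
    solves use the conforming P1 tetrahedra obtained by splitting each hex.
    Both share the same node set, so nodal fields move freely between them.

    nodes : (n_nodes, 3) mm; hexes : (n_hexes, 8) int (vertex bit order
    x + 2y + 4z); tets : (n_tets, 4) int; tet_parent : (n_tets,) hex index of
    each tet; region : (n_hexes,) int, 1 = tumor, 0 = host;
    outer_nodes : fixed-boundary node ids.
    """

    nodes: np.ndarray
    hexes: np.ndarray
    tets: np.ndarray
    tet_parent: np.ndarray
    region: np.ndarray
    outer_nodes: np.ndarray
    tumor_radius: float = 5.0
    host_radius: float = 50.0
    # node ids lying on each symmetry plane (x=0, y=0, z=0); empty for the
    # full ball, populated by ``ball_mesh(octant=True)``
    symmetry_planes: tuple = (None, None, None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_hexes(self) -> int:
        return self.hexes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def tet_region(self) -> np.ndarray:
        return self.region[self.tet_parent]

    def hex_to_tet(self, values: np.ndarray) -> np.ndarray:
        """Broadcast a per-hex field to the child tetrahedra."""
        return np.asarray(values)[self.tet_parent]

    def tet_to_hex(self, values: np.ndarray) -> np.ndarray:
        """Volume-weighted average of a per-tet field over each parent hex."""
        vol, _ = self.geometry()
        num = np.zeros(self.n_hexes)
        den = np.zeros(self.n_hexes)
        np.add.at(num, self.tet_parent, np.asarray(values, dtype=float) * vol)
        np.add.at(den, self.tet_parent, vol)
        return num / den

    # -- P1 geometry -------------------------------------------------------
    def geometry(self, coords: np.ndarray | None = None):
        """Element volumes and shape-function gradients for given coordinates.

        Returns (volumes (n_tets,), grads (n_tets, 4, 3)) where grads[e, a]
        is ∇N_a, constant on element e.  Raises if any element is inverted.
        """
        x = self.nodes if coords is None else coords
        v = x[self.tets]  # (m, 4, 3)
        d = v[:, 1:] - v[:, :1]  # edge matrix rows (m, 3, 3)
        det = np.linalg.det(d)
        vol = det / 6.0
        if np.any(vol <= 0):
            raise ValueError(f"{int((vol <= 0).sum())} non-positive-volume elements")
        dinv = np.linalg.inv(d)  # (m, 3, 3): grad of (N1,N2,N3) wrt x in columns
        g = dinv.swapaxes(-1, -2)  # rows -> gradients of N1..N3
        g0 = -g.sum(axis=1, keepdims=True)
        grads = np.concatenate([g0, g], axis=1)
        return vol, grads

    def element_centroids(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        return x[self.tets].mean(axis=1)

    def node_volumes(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Lumped (volume/4 per vertex) nodal volumes."""
        vol, _ = self.geometry(coords)
        nv = np.zeros(self.n_nodes)
        np.add.at(nv, self.tets.ravel(), np.repeat(vol / 4.0, 4))
        return nv

    def tumor_node_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[self.tets[self.tet_region == 1].ravel()] = True
        return mask

    def element_to_node(self, values: np.ndarray, coords: np.ndarray | None = None) -> np.ndarray:
        """Volume-weighted projection of element-constant values onto nodes."""
        vol, _ = self.geometry(coords)
        values = np.asarray(values, dtype=float)
        out_shape = (self.n_nodes,) + values.shape[1:]
        num = np.zeros(out_shape)
        den = np.zeros(self.n_nodes)
        w = vol / 4.0
        for a in range(4):
            idx = self.tets[:, a]
            np.add.at(num, idx, values * w.reshape((-1,) + (1,) * (values.ndim - 1)))
            np.add.at(den, idx, w)
        return num / den.reshape((-1,) + (1,) * (values.ndim - 1))


def _radial_schedule(tumor_radius: float, host_radius: float, n_tumor: int, n_host: int,
                     ratio: float = 1.9) -> np.ndarray:
    """Shell radii: n_tumor uniform steps to the seed surface, then a geometric
    progression (factor ``ratio``) out to the host radius."""
    r_t = np.linspace(0.0, tumor_radius, n_tumor + 1)
    steps = ratio ** np.arange(n_host)
    steps *= (host_radius - tumor_radius) / steps.sum()
    r_h = tumor_radius + np.cumsum(steps)
    return np.concatenate([r_t, r_h])


def ball_mesh(
    tumor_radius: float = 5.0,
    host_radius: float = 50.0,
    n_tumor_shells: int = 3,
    n_host_shells: int = 3,
    grading_ratio: float = 1.9,
    octant: bool = False,
) -> Mesh:
    """Concentric-spheres mesh (tumor seed inside host ball), spherified-cube tets.

    The lattice has ``m = n_tumor_shells + n_host_shells`` shells, i.e. a
    (2m)^3-cell structured grid before triangulation.  With ``octant=True``
    only the x, y, z >= 0 octant is built (8x fewer cells at the same
    resolution); solutions with octant mirror symmetry can then be computed by
    constraining the normal displacement on the recorded ``symmetry_planes``.
    """
    if tumor_radius <= 0 or host_radius <= tumor_radius:
        raise ValueError("need 0 < tumor_radius < host_radius")
    m = n_tumor_shells + n_host_shells
    radii = _radial_schedule(tumor_radius, host_radius, n_tumor_shells, n_host_shells,
                             grading_ratio)
    n = m if octant else 2 * m
    axis = np.arange(0, m + 1) if octant else np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    shell = np.abs(lattice).max(axis=1).astype(int)  # 0..m
    norm2 = np.linalg.norm(lattice, axis=1)
    norm2[norm2 == 0] = 1.0
    nodes = lattice / norm2[:, None] * radii[shell][:, None]

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    # hex cells and Kuhn split
    rng = np.arange(n)
    ci, cj, ck = np.meshgrid(rng, rng, rng, indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corners = np.empty((ci.size, 8), dtype=np.int64)
    for b in range(8):
        bx, by, bz = b & 1, (b >> 1) & 1, (b >> 2) & 1
        corners[:, b] = nid(ci + bx, cj + by, ck + bz)
    tets = np.concatenate([corners[:, p] for p in _KUHN_PATHS], axis=0)
    tet_parent = np.tile(np.arange(corners.shape[0]), 6)

    mesh_nodes = nodes
    # orient tets: positive volume
    v = mesh_nodes[tets]
    det = np.linalg.det(v[:, 1:] - v[:, :1])
    if np.any(np.abs(det) < 1e-12 * np.abs(det).max()):
        raise RuntimeError("degenerate tetrahedra in spherified-cube mesh")
    flip = det < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()

    cent = mesh_nodes[corners].mean(axis=1)
    r_c = np.linalg.norm(cent, axis=1)
    region = (r_c < tumor_radius - 1e-9).astype(int)

    node_r = np.linalg.norm(mesh_nodes, axis=1)
    outer = np.where(node_r > host_radius * (1.0 - 1e-9))[0]

    planes = (None, None, None)
    if octant:
        planes = tuple(np.where(np.abs(mesh_nodes[:, a]) < 1e-12 * host_radius)[0]
                       for a in range(3))
    mesh = Mesh(mesh_nodes, corners, tets, tet_parent, region, outer,
                tumor_radius, host_radius, planes)
    mesh.geometry()  # validates positivity
    return mesh


def write_vtk(path: str | Path, nodes: np.ndarray, tets: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid writer for inspection output."""
    lines = ["# vtk DataFile Version 3.0", "gliomech output", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(nodes)} double"]
    lines += [" ".join(f"{c:.8g}" for c in p) for p in nodes]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)

    def emit(data: dict[str, np.ndarray], kind: str, count: int) -> None:
        lines.append(f"{kind} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.8g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.8g}" for c in row) for row in arr.reshape(count, -1)[:, :3]]

    if point_data:
        emit(point_data, "POINT_DATA", len(nodes))
    if cell_data:
        emit(cell_data, "CELL_DATA", len(tets))
    Path(path).write_text("\n".join(lines) + "\n")
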