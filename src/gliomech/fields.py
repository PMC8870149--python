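"""Synthetic "virtual patient" voxel fields: MRE-like moduli and DTI-like tensors.

Real patient elastography volumes are not publicly available, so this module
generates spatially correlated, strictly positive storage/loss modulus maps and
symmetric positive-definite diffusion-tensor maps on a regular voxel lattice,
embeds a "patient tumor" block into the spherical tumor seed, and interpolates
voxel data onto mesh nodes.

Conventions: 0-based voxel indices, world coordinate = origin + index * spacing
(axis-aligned, no oblique affines).  Tensor channels are stored in
lower-triangular order (xx, yx, yy, zx, zy, zz).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelField",
    "FieldGeneratorSpec",
    "TumorSeedSpec",
    "generate_modulus_field",
    "generate_dti_field",
    "embed_tumor_data",
    "interpolate_to_mesh",
    "write_nifti",
    "read_nifti",
]

TENSOR_ORDER = ("xx", "yx", "yy", "zx", "zy", "zz")
# (row, col) of each lower-triangular channel
_TRI = ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))


class InvalidSpecError(ValueError):
    """Raised when a field-generator or geometry spec violates its preconditions."""


@dataclasses.dataclass
class VoxelField:
    """Scalar or tensor channels on a regular 3D lattice.

    Parameters
    ----------
    origin : (3,) array, mm — world position of voxel (0,0,0)
    spacing : (3,) array, mm — strictly positive voxel edge lengths
    dims : (3,) ints — lattice size
    channels : dict name -> array of shape dims (scalar) or dims+(6,) (tensor)
    """

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]
    channels: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise InvalidSpecError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise InvalidSpecError("voxel spacing must be positive")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise InvalidSpecError("dims must be 3 positive integers")
        for name, arr in self.channels.items():
            if arr.shape[:3] != self.dims:
                raise InvalidSpecError(
                    f"channel {name!r} shape {arr.shape} does not match dims {self.dims}"
                )

    # -- geometry helpers -------------------------------------------------
    @property
    def extent(self) -> np.ndarray:
        """World-coordinate bounds [(xmin,xmax),(ymin,ymax),(zmin,zmax)] of voxel centers."""
        lo = self.origin
        hi = self.origin + (np.array(self.dims) - 1) * self.spacing
        return np.stack([lo, hi], axis=1)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel coordinates of world-space points."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def tensor_array(self, name: str = "dti_mm2_per_day") -> np.ndarray:
        """Expand a 6-channel tensor field to full (..., 3, 3) symmetric matrices."""
        tri = self.channels[name]
        out = np.empty(self.dims + (3, 3))
        for c, (i, j) in enumerate(_TRI):
            out[..., i, j] = tri[..., c]
            out[..., j, i] = tri[..., c]
        return out


@dataclasses.dataclass(frozen=True)
class FieldGeneratorSpec:
    """Targets for a correlated random modulus field (units of target_mean)."""

    target_mean: float = 1500.0
    target_sd: float = 400.0
    correlation_length: float = 8.0  # mm
    loss_to_storage_ratio: float = 0.4
    seed: int = 0
    clip_floor: float = 100.0

    def validate(self) -> None:
        if self.target_mean <= 0:
            raise InvalidSpecError("target_mean must be positive")
        if self.target_sd < 0:
            raise InvalidSpecError("target_sd must be non-negative")
        if self.correlation_length <= 0:
            raise InvalidSpecError("correlation_length must be positive")
        if not (0 < self.loss_to_storage_ratio < 1):
            raise InvalidSpecError("loss_to_storage_ratio must lie in (0,1)")
        if self.clip_floor <= 0:
            raise InvalidSpecError("clip_floor must be positive")


@dataclasses.dataclass(frozen=True)
class TumorSeedSpec:
    """Spherical initial tumor seed (default radius 5 mm)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 5.0

    def validate(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("seed radius must be positive")


def _grid_like(grid: VoxelField) -> VoxelField:
    return VoxelField(grid.origin.copy(), grid.spacing.copy(), grid.dims, {})


def generate_modulus_field(spec: FieldGeneratorSpec, grid: VoxelField) -> VoxelField:
    """Correlated random storage/loss modulus field on ``grid``.

    White Gaussian noise is smoothed with a Gaussian kernel of
    sigma = correlation_length (in mm, converted to voxels per axis), then
    affinely rescaled to the target mean/SD and clipped at ``clip_floor``.
    The loss modulus is a fixed fraction of the storage modulus, since the
    downstream mechanics keeps only the elastic branch.
    Identical (spec, grid) give bit-identical output.
    """
    spec.validate()
    if any(d < 4 for d in grid.dims):
        raise InvalidSpecError("grid must have at least 4 voxels per axis")
    rng = np.random.default_rng(spec.seed)
    if spec.target_sd == 0.0:
        g_storage = np.full(grid.dims, spec.target_mean)
    else:
        noise = rng.standard_normal(grid.dims)
        sigma_vox = spec.correlation_length / grid.spacing
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
        sd = smooth.std()
        if sd == 0.0:  # pathological: kernel wider than grid
            smooth = noise
            sd = smooth.std()
        g_storage = spec.target_mean + (smooth - smooth.mean()) * (spec.target_sd / sd)
        g_storage = np.maximum(g_storage, spec.clip_floor)
    out = _grid_like(grid)
    out.channels["storage_modulus_Pa"] = g_storage
    out.channels["loss_modulus_Pa"] = spec.loss_to_storage_ratio * g_storage
    return out


def generate_dti_field(
    base_diffusivity: float,
    anisotropy_fraction: float,
    seed: int,
    grid: VoxelField,
    correlation_length: float = 8.0,
) -> VoxelField:
    """Voxelwise SPD diffusion tensors with trace/3 near ``base_diffusivity``.

    Tensors are built as D = base * R diag(1+a e) R^T with random smooth
    log-perturbations e of the eigenvalues and spatially varying rotations,
    where a = ``anisotropy_fraction`` in [0, 1).  a = 0 returns exactly
    base_diffusivity * I everywhere.
    """
    if base_diffusivity <= 0:
        raise InvalidSpecError("base_diffusivity must be positive")
    if not (0 <= anisotropy_fraction < 1):
        raise InvalidSpecError("anisotropy_fraction must lie in [0,1)")
    out = _grid_like(grid)
    dims = grid.dims
    tri = np.zeros(dims + (6,))
    if anisotropy_fraction == 0.0:
        for c, (i, j) in enumerate(_TRI):
            tri[..., c] = base_diffusivity if i == j else 0.0
        out.channels["dti_mm2_per_day"] = tri
        return out

    rng = np.random.default_rng(seed)
    sigma_vox = correlation_length / grid.spacing
    # smooth unit-norm director field
    v = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(dims), sigma_vox, mode="reflect") for _ in range(3)],
        axis=-1,
    )
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    v /= norm
    a = anisotropy_fraction
    # axisymmetric tensor: (1 - a/2) on the plane, (1 + a) along the director,
    # scaled so the trace stays 3*base exactly
    d_long = base_diffusivity * (1.0 + a)
    d_perp = base_diffusivity * (1.0 - a / 2.0)
    outer = v[..., :, None] * v[..., None, :]
    eye = np.eye(3)
    tens = d_perp * eye + (d_long - d_perp) * outer
    for c, (i, j) in enumerate(_TRI):
        tri[..., c] = tens[..., i, j]
    out.channels["dti_mm2_per_day"] = tri
    return out


def embed_tumor_data(
    patient_field: VoxelField,
    channel: str,
    bbox: np.ndarray,
    seed: TumorSeedSpec,
    points: np.ndarray,
) -> np.ndarray:
    """Sample patient data, affinely squeezed into the tumor seed, at ``points``.

    The rectangular parallelepiped ``bbox`` (shape (3,2): per-axis lo/hi in the
    patient field's world frame) is mapped affinely onto the axis-aligned cube
    circumscribing the seed sphere, then the field is sampled (trilinear, with
    nearest-voxel extrapolation) at the requested seed-frame points.
    """
    seed.validate()
    bbox = np.asarray(bbox, dtype=float)
    if bbox.shape != (3, 2):
        raise InvalidSpecError("bbox must have shape (3, 2)")
    extent = bbox[:, 1] - bbox[:, 0]
    if np.any(extent <= 0):
        raise InvalidSpecError("bbox must have positive extent on every axis")
    center = np.asarray(seed.center, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # seed cube [-r, r]^3 about center -> unit [0,1]^3 -> bbox
    unit = (pts - center + seed.radius) / (2.0 * seed.radius)
    world = bbox[:, 0] + unit * extent
    vox = patient_field.world_to_voxel(world)
    data = patient_field.channels[channel]
    if data.ndim == 3:
        return ndimage.map_coordinates(data, vox.T, order=1, mode="nearest")
    out = np.empty((pts.shape[0], data.shape[-1]))
    for c in range(data.shape[-1]):
        out[:, c] = ndimage.map_coordinates(data[..., c], vox.T, order=1, mode="nearest")
    return out


def interpolate_to_mesh(field: VoxelField, channel: str, nodes: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a voxel channel at mesh node coordinates.

    Nodes outside the grid take the value of the nearest in-bounds voxel.
    Globally linear fields are reproduced exactly (to round-off) at interior
    nodes, which is the fidelity the regular-lattice data require.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    if nodes.size == 0:
        raise ValueError("empty node set")
    vox = field.world_to_voxel(nodes)
    data = field.channels[channel]
    if data.ndim == 3:
        return ndimage.map_coordinates(data, vox.T, order=1, mode="nearest")
    out = np.empty((nodes.shape[0], data.shape[-1]))
    for c in range(data.shape[-1]):
        out[:, c] = ndimage.map_coordinates(data[..., c], vox.T, order=1, mode="nearest")
    return out


# -- NIfTI I/O -------------------------------------------------------------

def write_nifti(field: VoxelField, channel: str, path: str | Path) -> None:
    """Write one channel as .nii/.nii.gz with a diagonal scaling affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(field.spacing)
    affine[:3, 3] = field.origin
    img = nib.Nifti1Image(np.asarray(field.channels[channel], dtype=np.float64), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path, channel: str) -> VoxelField:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.diag(affine[:3, :3]).copy()
    if np.any(spacing <= 0) or np.any(np.abs(affine[:3, :3] - np.diag(spacing)) > 1e-9 * np.abs(spacing).max()):
        raise InvalidSpecError("only axis-aligned diagonal affines are supported")
    data = np.asarray(img.dataobj, dtype=float)
    dims = data.shape[:3]
    return VoxelField(affine[:3, 3].copy(), spacing, dims, {channel: data})


def write_provenance(path: str | Path, payload: dict) -> None:
    """JSON sidecar recording generator specs and seeds next to NIfTI outputs."""
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
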