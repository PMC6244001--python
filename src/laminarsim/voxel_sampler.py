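"""Isotropic voxel sampling of continuous activation fields.

A square isotropic voxel lattice is placed over the cortical patch at a
jittered sub-voxel offset, emulating the quasi-random position of
acquisition voxels relative to the cortical laminae.  Each voxel's
noiseless signal is the mean of the field over its footprint (boxcar
sampling kernel), computed on the patch's fine raster via summed-area
tables; a tabulated 1-D depth-direction kernel can be substituted for the
boxcar.  Measurement noise is additive white Gaussian with standard
deviation ``peak(noiseless) / SNR``, so ``SNR = 1`` ("realistic") puts the
noise on the scale of the strongest voxel signal and ``SNR = inf``
("ideal") returns the noiseless values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cortex_model import CortexPatch, Tissue
from .activation_fields import ActivationField

__all__ = [
    "VoxelGrid",
    "VoxelSample",
    "VoxelMeasurer",
    "place_grid",
    "measure",
    "partial_volume_fractions",
]


@dataclass(frozen=True)
class VoxelGrid:
    """An isotropic voxel lattice over a patch.

    Voxel (i, j) spans ``[y0 + i*s, y0 + (i+1)*s) x [x0 + j*s, x0 + (j+1)*s)``
    with ``s = voxel_size_mm``.  The lattice always covers the full raster
    extent of the patch it was placed on.
    """

    voxel_size_mm: float
    offset_mm: tuple
    x0: float
    y0: float
    n_rows: int
    n_cols: int

    @property
    def centroid_x(self) -> np.ndarray:
        s = self.voxel_size_mm
        return self.x0 + (np.arange(self.n_cols) + 0.5) * s

    @property
    def centroid_y(self) -> np.ndarray:
        s = self.voxel_size_mm
        return self.y0 + (np.arange(self.n_rows) + 0.5) * s

    def x_edges(self) -> np.ndarray:
        return self.x0 + np.arange(self.n_cols + 1) * self.voxel_size_mm

    def y_edges(self) -> np.ndarray:
        return self.y0 + np.arange(self.n_rows + 1) * self.voxel_size_mm


def place_grid(
    patch: CortexPatch,
    voxel_size_mm: float,
    jitter_seed: int | np.random.Generator | None = None,
    offset_mm: tuple | None = None,
) -> VoxelGrid:
    """Place an isotropic lattice over ``patch`` at a jittered offset.

    The offset is drawn uniformly from ``[0, voxel_size)^2`` using
    ``jitter_seed`` (an int seed or a Generator), or taken verbatim from
    ``offset_mm``.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    s = float(voxel_size_mm)
    if offset_mm is not None:
        ox, oy = float(offset_mm[0]), float(offset_mm[1])
        if not (0 <= ox < s and 0 <= oy < s):
            raise ValueError("offsets must lie in [0, voxel_size) per axis")
    else:
        rng = (
            jitter_seed
            if isinstance(jitter_seed, np.random.Generator)
            else np.random.default_rng(jitter_seed)
        )
        ox, oy = rng.uniform(0.0, s, size=2)
    # start one voxel early when the offset leaves a gap at the origin, but
    # never include a leading voxel with no overlap with the raster domain
    x0 = ox - s if ox > 0 else 0.0
    y0 = patch.y_bottom + (oy - s if oy > 0 else 0.0)
    n_cols = int(math.ceil((patch.length_mm - x0) / s - 1e-9))
    n_rows = int(math.ceil((patch.y_top - y0) / s - 1e-9))
    return VoxelGrid(s, (ox, oy), x0, y0, n_rows, n_cols)


@dataclass(frozen=True)
class VoxelSample:
    """Measured voxel signals on a grid (arrays shaped ``(n_rows, n_cols)``).

    ``centroid_depth`` is normalized depth for GM-centroid voxels and NaN
    otherwise; ``centroid_tissue`` carries the :class:`Tissue` class.
    """

    grid: VoxelGrid
    centroid_depth: np.ndarray
    centroid_tissue: np.ndarray
    noiseless: np.ndarray
    measured: np.ndarray
    snr: float
    noise_sd: float
    seed: int | None
    meta: dict = field(default_factory=dict)

    @property
    def centroid_x(self) -> np.ndarray:
        return self.grid.centroid_x

    @property
    def centroid_y(self) -> np.ndarray:
        return self.grid.centroid_y

    def gm_mask(self) -> np.ndarray:
        return self.centroid_tissue == int(Tissue.GM)

    def to_dataframe(self, patch: CortexPatch | None = None):
        """Long-format per-voxel table (TSV sidecar layout)."""
        import pandas as pd

        nr, nc = self.noiseless.shape
        ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        cols = {
            "row": ii.ravel(),
            "col": jj.ravel(),
            "centroid_x_mm": np.broadcast_to(self.centroid_x, (nr, nc)).ravel(),
            "centroid_y_mm": np.broadcast_to(self.centroid_y[:, None], (nr, nc)).ravel(),
            "centroid_depth": self.centroid_depth.ravel(),
            "signal_noiseless": self.noiseless.ravel(),
            "signal_measured": self.measured.ravel(),
        }
        if patch is not None:
            f = partial_volume_fractions(patch, self.grid)
            for k in ("f_gm", "f_wm", "f_csf"):
                cols[k] = f[k].ravel()
        return pd.DataFrame(cols)

    def save_nifti(self, path) -> None:
        import nibabel as nib

        s = self.grid.voxel_size_mm
        img = nib.Nifti1Image(
            self.measured.T.astype(np.float32), np.diag([s, s, 1.0, 1.0])
        )
        nib.save(img, str(path))


def _edges_to_indices(edges: np.ndarray, origin: float, pitch: float, n: int) -> np.ndarray:
    """Snap physical edge coordinates to raster cell boundaries (clipped)."""
    idx = np.rint((edges - origin) / pitch).astype(np.int64)
    return np.clip(idx, 0, n)


class VoxelMeasurer:
    """Reusable sampler: rasterizes the field once, measures many grids.

    Monte-Carlo drivers jitter hundreds of grids over one (patch, field)
    pair; caching the summed-area table makes each measurement O(#voxels).
    """

    def __init__(
        self,
        patch: CortexPatch,
        fieldobj: ActivationField,
        kernel: tuple | None = None,
    ):
        self.patch = patch
        self.field = fieldobj
        F = fieldobj.rasterize(patch)
        self._shape = F.shape
        if kernel is not None:
            # Tabulated 1-D depth-direction kernel (offsets_mm, weights):
            # pre-convolve the raster along y; a voxel then averages the
            # convolved field over its x footprint at its centroid row.
            from scipy.ndimage import convolve1d

            offs, w = (np.asarray(a, dtype=float) for a in kernel)
            pitch = patch.resolution_mm
            fine = np.arange(offs.min(), offs.max() + pitch / 2, pitch)
            wf = np.interp(fine, offs, w)
            wf = wf / wf.sum()
            self._Fk = convolve1d(F, wf[::-1], axis=0, mode="nearest")
        else:
            self._Fk = None
        S = np.zeros((F.shape[0] + 1, F.shape[1] + 1))
        np.cumsum(np.cumsum(F, axis=0), axis=1, out=S[1:, 1:])
        self._sat = S
        self._y_origin = patch.y_bottom
        self._x_origin = 0.0

    def noiseless(self, grid: VoxelGrid) -> np.ndarray:
        """Per-voxel boxcar (or kernel) means of the field."""
        p = self.patch
        pitch = p.resolution_mm
        ny, nx = self._shape
        je = _edges_to_indices(grid.x_edges(), self._x_origin, pitch, nx)
        ie = _edges_to_indices(grid.y_edges(), self._y_origin, pitch, ny)
        if self._Fk is not None:
            ic = np.clip(
                ((grid.centroid_y - self._y_origin) / pitch).astype(np.int64), 0, ny - 1
            )
            colsum = np.cumsum(self._Fk[ic, :], axis=1)
            colsum = np.concatenate([np.zeros((ic.size, 1)), colsum], axis=1)
            sums = colsum[:, je[1:]] - colsum[:, je[:-1]]
            counts = np.maximum(je[1:] - je[:-1], 1)[None, :]
            return sums / counts
        S = self._sat
        sums = (
            S[np.ix_(ie[1:], je[1:])]
            - S[np.ix_(ie[:-1], je[1:])]
            - S[np.ix_(ie[1:], je[:-1])]
            + S[np.ix_(ie[:-1], je[:-1])]
        )
        cells = np.maximum((ie[1:] - ie[:-1])[:, None] * (je[1:] - je[:-1])[None, :], 1)
        return sums / cells

    def sample(
        self,
        grid: VoxelGrid,
        snr: float,
        rng: int | np.random.Generator | None = None,
    ) -> VoxelSample:
        if not (snr > 0):
            raise ValueError("snr must be positive (use float('inf') for ideal)")
        clean = self.noiseless(grid)
        p = self.patch
        csf, wm = p.boundaries_at(grid.centroid_x)
        d = (csf[None, :] - grid.centroid_y[:, None]) / (csf - wm)[None, :]
        tissue = np.full(d.shape, int(Tissue.GM), dtype=np.int8)
        tissue[d < 0] = int(Tissue.CSF)
        tissue[d > 1] = int(Tissue.WM)
        depth = np.where(tissue == int(Tissue.GM), d, np.nan)
        seed = None
        if np.isinf(snr):
            noise_sd = 0.0
            meas = clean.copy()
        else:
            gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            seed = rng if isinstance(rng, (int, np.integer)) else None
            noise_sd = float(np.abs(clean).max()) / snr
            meas = clean + gen.normal(0.0, noise_sd, size=clean.shape)
        return VoxelSample(
            grid=grid,
            centroid_depth=depth,
            centroid_tissue=tissue,
            noiseless=clean,
            measured=meas,
            snr=float(snr),
            noise_sd=noise_sd,
            seed=seed,
            meta={"kernel": "boxcar" if self._Fk is None else "tabulated"},
        )


def measure(
    fieldobj: ActivationField,
    patch: CortexPatch,
    grid: VoxelGrid,
    snr: float,
    seed: int | np.random.Generator | None = None,
    kernel: tuple | None = None,
) -> VoxelSample:
    """One-shot voxel measurement (see :class:`VoxelMeasurer`)."""
    return VoxelMeasurer(patch, fieldobj, kernel=kernel).sample(grid, snr, seed)


def partial_volume_fractions(patch: CortexPatch, grid: VoxelGrid) -> dict:
    """Per-voxel (GM, WM, CSF) area fractions from fine-raster counting.

    Fractions are relative to the part of each voxel footprint inside the
    rasterized domain; they are non-negative and sum to one.
    """
    lab = patch.label_map()
    pitch = patch.resolution_mm
    ny, nx = lab.shape
    je = _edges_to_indices(grid.x_edges(), 0.0, pitch, nx)
    ie = _edges_to_indices(grid.y_edges(), patch.y_bottom, pitch, ny)
    out = {}
    total = np.maximum((ie[1:] - ie[:-1])[:, None] * (je[1:] - je[:-1])[None, :], 1)
    for name, cls in (("f_csf", Tissue.CSF), ("f_gm", Tissue.GM), ("f_wm", Tissue.WM)):
        M = (lab == int(cls)).astype(np.float64)
        S = np.zeros((ny + 1, nx + 1))
        np.cumsum(np.cumsum(M, axis=0), axis=1, out=S[1:, 1:])
        cnt = (
            S[np.ix_(ie[1:], je[1:])]
            - S[np.ix_(ie[:-1], je[1:])]
            - S[np.ix_(ie[1:], je[:-1])]
            + S[np.ix_(ie[:-1], je[:-1])]
        )
        out[name] = cnt / total
    return out
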