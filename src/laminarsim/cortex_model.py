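"""Synthetic 2-D cortical-ribbon geometry.

The cortex is modelled as a 2-D ribbon: a tangential axis ``x`` (cortical
distance, mm) and a normal axis ``y`` (mm).  Two slowly varying boundary
curves delimit grey matter (GM): the GM–CSF boundary (CSFB) above and the
GM–WM boundary (WMB) below.  A convoluted cortex is locally flat, so a
single-slice ribbon with gentle boundary undulation is an adequate stand-in
for a flat patch of real cortex.

Normalized cortical depth is equidistant: ``d = 0`` exactly on the CSFB and
``d = 1`` exactly on the WMB.  A 2-D ribbon has no volume-wedge effect, so
the equidistant and equivolume conventions coincide here; the convention is
recorded in patch metadata.

Patches carry an internal raster (default pitch 0.01 mm, at least 10x finer
than the finest voxel considered) on which activation fields are evaluated
and partial-volume integrals are taken.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Tissue",
    "CortexPatch",
    "make_flat_patch",
    "make_variable_patch",
    "depth_coordinate",
]


class Tissue(enum.IntEnum):
    """Tissue classes of the ribbon raster."""

    CSF = 0
    GM = 1
    WM = 2


@dataclass(frozen=True)
class CortexPatch:
    """A rasterized 2-D cortical ribbon.

    Attributes
    ----------
    x : ndarray
        Raster cell-centre x coordinates (mm), uniformly spaced.
    csf_y, wm_y : ndarray
        Boundary heights (mm) at each ``x``; ``csf_y > wm_y`` everywhere.
    resolution_mm : float
        Raster pitch (mm), identical in x and y.
    margin_mm : float
        Extra CSF (above) and WM (below) margin included in the raster so
        voxel grids can straddle the boundaries.
    meta : dict
        Provenance (generator parameters, seed, depth convention).
    """

    x: np.ndarray
    csf_y: np.ndarray
    wm_y: np.ndarray
    resolution_mm: float
    margin_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.csf_y - self.wm_y <= 0):
            raise ValueError("cortical thickness must be positive everywhere")

    # -- geometry queries ---------------------------------------------------

    @property
    def length_mm(self) -> float:
        """Tangential extent of the patch (mm)."""
        return float(self.x[-1] + self.resolution_mm / 2.0)

    @property
    def y(self) -> np.ndarray:
        """Raster cell-centre y coordinates (mm), increasing (WM -> CSF)."""
        res = self.resolution_mm
        y0 = self.y_bottom
        ny = int(np.ceil((self.y_top - y0) / res - 1e-9))
        return y0 + (np.arange(ny) + 0.5) * res

    @property
    def y_bottom(self) -> float:
        return float(self.wm_y.min() - self.margin_mm)

    @property
    def y_top(self) -> float:
        return float(self.csf_y.max() + self.margin_mm)

    def thickness(self, x) -> np.ndarray | float:
        """Local cortical thickness (mm) at tangential position(s) ``x``."""
        t = np.interp(x, self.x, self.csf_y - self.wm_y)
        return t

    def boundaries_at(self, x):
        """CSFB and WMB heights (mm) at tangential position(s) ``x``."""
        return np.interp(x, self.x, self.csf_y), np.interp(x, self.x, self.wm_y)

    def depth_map(self) -> np.ndarray:
        """Normalized depth on the raster, shape ``(ny, nx)``.

        Values below 0 are CSF, above 1 are WM; GM is ``0 <= d <= 1``.
        """
        t = self.csf_y - self.wm_y
        return (self.csf_y[None, :] - self.y[:, None]) / t[None, :]

    def label_map(self) -> np.ndarray:
        """Tissue class per raster cell (:class:`Tissue` values)."""
        d = self.depth_map()
        lab = np.full(d.shape, int(Tissue.GM), dtype=np.int8)
        lab[d < 0] = int(Tissue.CSF)
        lab[d > 1] = int(Tissue.WM)
        return lab

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write boundary curves as TSV (x_mm, csf_y_mm, wm_y_mm)."""
        import pandas as pd

        pd.DataFrame(
            {"x_mm": self.x, "csf_y_mm": self.csf_y, "wm_y_mm": self.wm_y}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, resolution_mm=None, margin_mm=1.0) -> "CortexPatch":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        x = df["x_mm"].to_numpy()
        res = resolution_mm if resolution_mm is not None else float(x[1] - x[0])
        return cls(
            x=x,
            csf_y=df["csf_y_mm"].to_numpy(),
            wm_y=df["wm_y_mm"].to_numpy(),
            resolution_mm=res,
            margin_mm=margin_mm,
            meta={"source": str(path), "depth_convention": "equidistant"},
        )

    def to_nifti(self, path) -> None:
        """Write the tissue label raster (0=CSF, 1=GM, 2=WM) as 2-D NIfTI."""
        import nibabel as nib

        affine = np.diag([self.resolution_mm, self.resolution_mm, 1.0, 1.0])
        img = nib.Nifti1Image(self.label_map().astype(np.int16).T, affine)
        nib.save(img, str(path))


def _check_positive(**kwargs) -> None:
    for name, val in kwargs.items():
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {val!r}")


def make_flat_patch(
    thickness_mm: float,
    length_mm: float,
    resolution_mm: float = 0.01,
    margin_mm: float = 1.0,
) -> CortexPatch:
    """Ribbon with constant thickness: two parallel straight boundaries.

    The WMB sits at y = 0 and the CSFB at y = ``thickness_mm``.
    """
    _check_positive(
        thickness_mm=thickness_mm, length_mm=length_mm, resolution_mm=resolution_mm
    )
    nx = int(round(length_mm / resolution_mm))
    x = (np.arange(nx) + 0.5) * resolution_mm
    return CortexPatch(
        x=x,
        csf_y=np.full(nx, float(thickness_mm)),
        wm_y=np.zeros(nx),
        resolution_mm=resolution_mm,
        margin_mm=margin_mm,
        meta={
            "kind": "flat",
            "thickness_mm": float(thickness_mm),
            "depth_convention": "equidistant",
        },
    )


def _smooth_noise(n: int, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth random field; plain Gaussian-filtered white noise."""
    z = rng.standard_normal(n)
    s = gaussian_filter1d(z, sigma_cells, mode="reflect")
    s -= s.mean()
    return s


def make_variable_patch(
    thickness_min_mm: float,
    thickness_max_mm: float,
    length_mm: float,
    smoothness_mm: float,
    seed: int,
    resolution_mm: float = 0.01,
    margin_mm: float = 1.0,
    undulation_mm: float = 0.3,
) -> CortexPatch:
    """Anatomically-inspired ribbon with variable cortical thickness.

    The thickness field is seeded smooth noise (tangential correlation
    length set by ``smoothness_mm``) rescaled to exactly span
    ``[thickness_min_mm, thickness_max_mm]``; the human range used
    throughout is 1.7-3.7 mm.  Local curvature is emulated by a smooth
    undulation of the ribbon midline of peak amplitude ``undulation_mm``.
    Identical seeds give bit-identical patches.
    """
    _check_positive(
        thickness_min_mm=thickness_min_mm,
        length_mm=length_mm,
        smoothness_mm=smoothness_mm,
        resolution_mm=resolution_mm,
    )
    if thickness_min_mm >= thickness_max_mm:
        raise ValueError("thickness_min_mm must be strictly less than thickness_max_mm")
    rng = np.random.default_rng(seed)
    nx = int(round(length_mm / resolution_mm))
    x = (np.arange(nx) + 0.5) * resolution_mm
    sigma_cells = smoothness_mm / resolution_mm

    t_raw = _smooth_noise(nx, sigma_cells, rng)
    ptp = t_raw.max() - t_raw.min()
    if ptp > 0:
        t = thickness_min_mm + (t_raw - t_raw.min()) / ptp * (
            thickness_max_mm - thickness_min_mm
        )
    else:  # pathologically over-smoothed field: fall back to the mid thickness
        t = np.full(nx, 0.5 * (thickness_min_mm + thickness_max_mm))

    mid = _smooth_noise(nx, sigma_cells, rng)
    peak = np.abs(mid).max()
    if undulation_mm > 0 and peak > 0:
        mid *= undulation_mm / peak
    else:
        mid = np.zeros(nx)
    mid += 0.5 * (thickness_min_mm + thickness_max_mm) / 2.0  # keep WMB near y=0

    return CortexPatch(
        x=x,
        csf_y=mid + t / 2.0,
        wm_y=mid - t / 2.0,
        resolution_mm=resolution_mm,
        margin_mm=margin_mm,
        meta={
            "kind": "variable",
            "thickness_range_mm": [float(thickness_min_mm), float(thickness_max_mm)],
            "smoothness_mm": float(smoothness_mm),
            "undulation_mm": float(undulation_mm),
            "seed": int(seed),
            "depth_convention": "equidistant",
        },
    )


def depth_coordinate(patch: CortexPatch, point) -> float | Tissue:
    """Normalized depth of a 2-D point ``(x, y)`` in mm.

    Returns a float in [0, 1] for GM points (0 on the CSFB, 1 on the WMB)
    and the :class:`Tissue` sentinel ``CSF`` or ``WM`` outside GM.  Points
    outside the rasterized bounding box are rejected.
    """
    px, py = float(point[0]), float(point[1])
    if not (0.0 <= px <= patch.length_mm) or not (patch.y_bottom <= py <= patch.y_top):
        raise ValueError(f"point {point!r} lies outside the rasterized domain")
    csf, wm = patch.boundaries_at(px)
    if py > csf:
        return Tissue.CSF
    if py < wm:
        return Tissue.WM
    return float((csf - py) / (csf - wm))
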