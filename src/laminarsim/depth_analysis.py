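"""Cortical depth-profile estimation from voxel samples.

Two estimators:

* :func:`upsample_and_bin` — the standard laminar analysis path: voxel
  values are linearly interpolated onto a grid ``upsample_factor`` times
  finer, every fine sample falling inside GM is assigned to one of
  ``n_depths`` equidistant depth bins by its normalized depth, and bins
  are averaged over the whole ROI.
* :func:`centroid_sort_profile` — the interpolation-free alternative:
  whole voxels are assigned to depth bins by the normalized depth of their
  centroids; voxels whose centroid is not in GM are excluded.

Depth bins are half-open ``[k/N, (k+1)/N)`` with the last bin closed; bin
centres are reported at ``(k + 0.5)/N``.  Profiles are ordered from the
CSF boundary (index 0, d = 0) to the WM boundary.  Empty bins are flagged
as missing (NaN), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .cortex_model import CortexPatch
from .voxel_sampler import VoxelSample

__all__ = [
    "DepthProfile",
    "upsample_and_bin",
    "centroid_sort_profile",
    "extract_positive_and_undershoot",
    "normalize_profile",
]


@dataclass(frozen=True)
class DepthProfile:
    """Signal amplitude at ordered normalized depths (CSFB -> WMB).

    ``values`` may contain NaN for empty (missing) bins; ``n_samples``
    optionally records how many fine samples or voxels fed each bin.
    """

    depths: np.ndarray
    values: np.ndarray
    normalization: str = "none"
    n_samples: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if d.ndim != 1 or d.size != np.asarray(self.values).size:
            raise ValueError("depths and values must be 1-D and equally long")
        if np.any(np.diff(d) <= 0) or d[0] < 0 or d[-1] > 1:
            raise ValueError("depths must be strictly increasing within [0, 1]")

    @property
    def n_depths(self) -> int:
        return int(np.asarray(self.depths).size)

    def has_missing(self) -> bool:
        return bool(np.any(~np.isfinite(np.asarray(self.values, dtype=float))))

    def to_tsv(self, path) -> None:
        import pandas as pd

        n = (
            self.n_samples
            if self.n_samples is not None
            else np.full(self.n_depths, -1, dtype=int)
        )
        df = pd.DataFrame(
            {
                "depth_center": self.depths,
                "value": self.values,
                "n_samples": n,
                "normalization": self.normalization,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DepthProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        n = df["n_samples"].to_numpy()
        return cls(
            depths=df["depth_center"].to_numpy(),
            values=df["value"].to_numpy(),
            normalization=str(df["normalization"].iloc[0]),
            n_samples=None if np.all(n < 0) else n,
            meta={"source": str(path)},
        )


def upsample_and_bin(
    sample: VoxelSample,
    patch: CortexPatch,
    n_depths: int,
    upsample_factor: int = 10,
    col_range: tuple | None = None,
) -> DepthProfile:
    """Standard analysis: upsample, assign fine GM samples to depth bins.

    ``col_range = (j0, j1)`` restricts the analysis to a contiguous block
    of grid columns (the tangential ROI); all grid rows take part in the
    interpolation, so CSF/WM-adjacent partial-volume voxels contribute
    near the boundaries exactly as in a real upsampled image.
    """
    if n_depths < 1:
        raise ValueError("n_depths must be at least 1")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be a positive integer")
    j0, j1 = (0, sample.grid.n_cols) if col_range is None else map(int, col_range)
    if not (0 <= j0 < j1 <= sample.grid.n_cols):
        raise ValueError(f"invalid column range ({j0}, {j1})")
    if not np.any(sample.gm_mask()[:, j0:j1]):
        raise ValueError("ROI contains no GM voxels")

    xs = sample.centroid_x[j0:j1]
    ys = sample.centroid_y
    V = sample.measured[:, j0:j1]
    h = sample.grid.voxel_size_mm / upsample_factor
    fx = (
        np.linspace(xs[0], xs[-1], int(round((xs[-1] - xs[0]) / h)) + 1)
        if xs.size > 1
        else xs
    )
    fy = np.linspace(ys[0], ys[-1], int(round((ys[-1] - ys[0]) / h)) + 1)
    if xs.size > 1:
        rgi = RegularGridInterpolator((ys, xs), V, method="linear")
        FY, FX = np.meshgrid(fy, fx, indexing="ij")
        Vf = rgi((FY, FX))
    else:  # single tangential column: interpolate along depth only
        Vf = np.interp(fy, ys, V[:, 0])[:, None]

    csf, wm = patch.boundaries_at(fx)
    D = (csf[None, :] - fy[:, None]) / (csf - wm)[None, :]
    inside = (D >= 0.0) & (D <= 1.0)
    k = np.minimum((D[inside] * n_depths).astype(np.int64), n_depths - 1)
    vals = Vf[inside]
    counts = np.bincount(k, minlength=n_depths)
    sums = np.bincount(k, weights=vals, minlength=n_depths)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DepthProfile(
        depths=(np.arange(n_depths) + 0.5) / n_depths,
        values=values,
        normalization="none",
        n_samples=counts,
        meta={
            "method": "upsample_and_bin",
            "upsample_factor": int(upsample_factor),
            "voxel_size_mm": sample.grid.voxel_size_mm,
            "orientation": "index 0 = CSFB",
        },
    )


def centroid_sort_profile(sample: VoxelSample, n_bins: int) -> DepthProfile:
    """Interpolation-free profile: bin whole voxels by centroid depth."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    d = sample.centroid_depth[sample.gm_mask()]
    v = sample.measured[sample.gm_mask()]
    k = np.minimum((d * n_bins).astype(np.int64), n_bins - 1)
    counts = np.bincount(k, minlength=n_bins)
    sums = np.bincount(k, weights=v, minlength=n_bins)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DepthProfile(
        depths=(np.arange(n_bins) + 0.5) / n_bins,
        values=values,
        normalization="none",
        n_samples=counts,
        meta={"method": "centroid_sort", "orientation": "index 0 = CSFB"},
    )


def _window_mask(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    if start < times[0] - 1e-9 or stop > times[-1] + 1e-9:
        raise ValueError(
            f"window [{start}, {stop}] s lies outside the sampled time range "
            f"[{times[0]}, {times[-1]}] s"
        )
    m = (times >= start - 1e-9) & (times <= stop + 1e-9)
    if not np.any(m):
        raise ValueError(f"window [{start}, {stop}] s contains no time samples")
    return m


def extract_positive_and_undershoot(
    timecourses: np.ndarray,
    times: np.ndarray,
    depths: np.ndarray,
    stimulus_onset_s: float,
    stimulus_duration_s: float,
    rise_lag_s: float = 2.0,
    undershoot_window_s: float = 10.0,
):
    """Window-average per-depth timecourses into two depth profiles.

    Positive BOLD: mean over ``[onset + rise_lag, onset + duration]``.
    Post-stimulus undershoot: mean over
    ``[offset + rise_lag, offset + rise_lag + undershoot_window]``.
    ``timecourses`` has shape ``(n_depths, n_times)``.
    """
    tc = np.asarray(timecourses, dtype=float)
    times = np.asarray(times, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != times.size:
        raise ValueError("timecourses must be (n_depths, n_times) matching times")
    offset = stimulus_onset_s + stimulus_duration_s
    pos_m = _window_mask(times, stimulus_onset_s + rise_lag_s, offset)
    und_m = _window_mask(times, offset + rise_lag_s, offset + rise_lag_s + undershoot_window_s)
    mk = lambda vals, name: DepthProfile(  # noqa: E731
        depths=np.asarray(depths, dtype=float),
        values=vals,
        normalization="none",
        meta={"window": name, "orientation": "index 0 = CSFB"},
    )
    return mk(tc[:, pos_m].mean(axis=1), "positive"), mk(tc[:, und_m].mean(axis=1), "undershoot")


def normalize_profile(profile: DepthProfile, mode: str) -> DepthProfile:
    """Rescale a profile: ``peak`` (max |value| = 1) or ``unit_area``
    (trapezoidal area over depth = 1).  Missing bins propagate."""
    vals = np.asarray(profile.values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("profile has no non-missing values")
    if mode == "peak":
        scale = np.abs(finite).max()
        if scale == 0:
            raise ValueError("cannot peak-normalize an all-zero profile")
    elif mode == "unit_area":
        if profile.has_missing():
            raise ValueError("cannot area-normalize a profile with missing bins")
        scale = np.trapezoid(vals, profile.depths)
        if scale == 0:
            raise ValueError("cannot area-normalize a zero-area profile")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(
        profile,
        values=vals / scale,
        normalization=mode,
        meta={**profile.meta, "scale_factor": float(scale)},
    )
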