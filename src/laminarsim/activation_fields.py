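"""Ground-truth activation patterns over the synthetic cortex.

Three generators:

* :func:`induced_psf` — the laminar point-spread function injected into the
  resolution simulation: a Gaussian in normalized depth with FWHM a fixed
  fraction (default 1/5) of the local cortical depth, constant along the
  tangential axis.
* :func:`pial_boundary_field` — a thin boxcar rim of signal centred on the
  GM–CSF boundary, used to study how large-vessel signal at the pial
  surface leaks into depth profiles through partial-volume effects.
* :func:`simulate_trials` — per-trial depth x distance x time BOLD signals
  from a double-gamma HRF with a post-stimulus undershoot, an amplitude
  profile increasing toward the CSF boundary, and a seeded tangential
  modulation shared across trials (the structure the trial PCA recovers).

The induced PSF is treated as an activation profile, not a probability
density: truncation at the depth limits loses the tails without
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as _gamma_dist

from .cortex_model import CortexPatch

__all__ = [
    "ActivationField",
    "ConstantField",
    "GaussianDepthPSF",
    "PialRimField",
    "induced_psf",
    "pial_boundary_field",
    "TimecourseModel",
    "TrialSimulation",
    "simulate_trials",
    "FWHM_TO_SIGMA",
]

#: FWHM of a Gaussian = FWHM_TO_SIGMA * sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class ActivationField:
    """A continuous scalar signal field over a cortical patch.

    Subclasses implement :meth:`rasterize`, returning the field evaluated
    on the patch raster (zero outside the field's support).
    """

    def rasterize(self, patch: CortexPatch) -> np.ndarray:
        raise NotImplementedError

    def save_nifti(self, patch: CortexPatch, path) -> None:
        import nibabel as nib

        res = patch.resolution_mm
        img = nib.Nifti1Image(
            self.rasterize(patch).T.astype(np.float32), np.diag([res, res, 1.0, 1.0])
        )
        nib.save(img, str(path))


@dataclass(frozen=True)
class ConstantField(ActivationField):
    """Spatially constant field (useful as a sampling-consistency probe)."""

    value: float = 1.0
    gm_only: bool = False

    def rasterize(self, patch: CortexPatch) -> np.ndarray:
        d = patch.depth_map()
        out = np.full(d.shape, float(self.value))
        if self.gm_only:
            out[(d < 0) | (d > 1)] = 0.0
        return out


@dataclass(frozen=True)
class GaussianDepthPSF(ActivationField):
    """Gaussian laminar activation profile in normalized depth.

    ``amplitude(d) = peak * exp(-(d - center)^2 / (2 sigma^2))`` inside GM,
    zero outside; ``sigma = fwhm_fraction / (2 sqrt(2 ln 2))``.  Because
    depth is normalized, the physical FWHM is ``fwhm_fraction`` times the
    local cortical thickness.
    """

    center_depth: float = 0.5
    fwhm_fraction: float = 0.2
    peak_amplitude: float = 1.0

    @property
    def sigma(self) -> float:
        return self.fwhm_fraction / FWHM_TO_SIGMA

    def amplitude(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.peak_amplitude * np.exp(
            -((d - self.center_depth) ** 2) / (2.0 * self.sigma**2)
        )

    def rasterize(self, patch: CortexPatch) -> np.ndarray:
        d = patch.depth_map()
        out = self.amplitude(d)
        out[(d < 0) | (d > 1)] = 0.0
        return out


def induced_psf(
    center_depth: float = 0.5,
    fwhm_fraction: float = 0.2,
    peak_amplitude: float = 1.0,
) -> GaussianDepthPSF:
    """The laminar PSF induced in the resolution simulation.

    Defaults follow the simulation setup: mid-cortex centre and FWHM one
    fifth of the cortical depth.
    """
    if not (0.0 <= center_depth <= 1.0):
        raise ValueError("center_depth must lie in [0, 1]")
    if not (0.0 < fwhm_fraction < 1.0):
        raise ValueError("fwhm_fraction must lie in (0, 1)")
    if peak_amplitude <= 0:
        raise ValueError("peak_amplitude must be positive")
    return GaussianDepthPSF(center_depth, fwhm_fraction, peak_amplitude)


@dataclass(frozen=True)
class PialRimField(ActivationField):
    """Boxcar rim of signal of width ``rim_width_mm`` centred on the CSFB.

    Mimics BOLD signal confined to the large vessels at the pial surface;
    half the rim lies in CSF, half in the most superficial GM.
    """

    rim_width_mm: float = 0.1
    peak_amplitude: float = 1.0

    def rasterize(self, patch: CortexPatch) -> np.ndarray:
        y = patch.y[:, None]
        dist = np.abs(y - patch.csf_y[None, :])
        return np.where(dist <= self.rim_width_mm / 2.0, self.peak_amplitude, 0.0)


def pial_boundary_field(
    rim_width_mm: float, peak_amplitude: float, patch: CortexPatch
) -> PialRimField:
    """Validated pial-rim field for ``patch``."""
    if rim_width_mm <= 0 or peak_amplitude < 0:
        raise ValueError("rim_width_mm must be positive and peak_amplitude non-negative")
    tmin = float((patch.csf_y - patch.wm_y).min())
    if rim_width_mm >= tmin:
        raise ValueError(
            f"rim width {rim_width_mm} mm is not small compared with the thinnest "
            f"cortex ({tmin:.2f} mm)"
        )
    return PialRimField(rim_width_mm, peak_amplitude)


# ---------------------------------------------------------------------------
# Time-resolved trial generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimecourseModel:
    """Parametric BOLD timecourse and its spatial modulation.

    The HRF is a double-gamma difference ``g1 - undershoot_ratio * g2``
    convolved with the stimulus boxcar and scaled to unit peak, giving a
    positive response during stimulation and a post-stimulus undershoot.
    The spatial amplitude is separable: a linear depth gain running from
    ``depth_gain_wm`` at the WMB to ``depth_gain_csf`` at the CSFB (both
    the positive response and the undershoot therefore grow toward the CSF
    boundary), times a smooth seeded tangential modulation with relative
    standard deviation ``tangential_sd``.
    """

    stimulus_onset_s: float = 10.0
    stimulus_duration_s: float = 20.0
    total_duration_s: float = 70.0
    dt_s: float = 1.0
    peak_delay_s: float = 5.5
    undershoot_delay_s: float = 12.0
    dispersion_s: float = 1.0
    undershoot_ratio: float = 0.35
    depth_gain_csf: float = 3.0
    depth_gain_wm: float = 1.0
    trial_count: int = 10
    trial_amplitude_sd: float = 0.2
    tangential_sd: float = 0.3
    tangential_smoothness_mm: float = 1.0

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.total_duration_s + 1e-9, self.dt_s)

    def hrf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        g1 = _gamma_dist.pdf(t, self.peak_delay_s / self.dispersion_s, scale=self.dispersion_s)
        g2 = _gamma_dist.pdf(
            t, self.undershoot_delay_s / self.dispersion_s, scale=self.dispersion_s
        )
        g1 = g1 / g1.max() if g1.max() > 0 else g1
        g2 = g2 / g2.max() if g2.max() > 0 else g2
        return g1 - self.undershoot_ratio * g2

    def response(self) -> np.ndarray:
        """Unit-peak BOLD response to the stimulus boxcar."""
        t = self.times()
        box = ((t >= self.stimulus_onset_s) & (t < self.stimulus_onset_s + self.stimulus_duration_s)).astype(float)
        h = self.hrf(t - t[0])
        r = np.convolve(box, h)[: t.size] * self.dt_s
        peak = np.abs(r).max()
        return r / peak if peak > 0 else r

    def depth_gain(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.depth_gain_csf + (self.depth_gain_wm - self.depth_gain_csf) * d

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, dct: dict) -> "TimecourseModel":
        return cls(**dct)


@dataclass(frozen=True)
class TrialSimulation:
    """Per-trial noisy spatio-temporal BOLD signals.

    ``data`` has shape ``(n_trials, n_depths, n_positions, n_times)``;
    ``modulation`` is the shared ground-truth tangential gain.
    """

    data: np.ndarray
    depths: np.ndarray
    positions: np.ndarray
    times: np.ndarray
    modulation: np.ndarray
    model: TimecourseModel
    noise_sd: float
    seed: int
    meta: dict = field(default_factory=dict)


def simulate_trials(
    model: TimecourseModel,
    patch: CortexPatch,
    n_trials: int,
    noise_sd: float,
    seed: int,
    n_depths: int = 30,
    n_positions: int = 40,
) -> TrialSimulation:
    """Generate seeded noisy trials sharing one tangential modulation.

    Each trial is the separable signal
    ``gain_trial * response(t) * depth_gain(d) * modulation(x)`` plus iid
    Gaussian noise of standard deviation ``noise_sd``.  The modulation is
    drawn once from the seed and reused for every trial, emulating
    reproducible (non thermal-noise) tangential variability; the per-trial
    amplitude gain (``1 + N(0, trial_amplitude_sd)``) emulates the global
    response-strength fluctuation of real trials, which is what exposes
    the shared pattern to an across-trial (column-centred) PCA.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be at least 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ss = np.random.SeedSequence(seed)
    rng_mod, rng_gain, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    positions = np.linspace(0.0, patch.length_mm, n_positions, endpoint=False)
    positions = positions + (patch.length_mm / n_positions) / 2.0
    dx = positions[1] - positions[0]
    raw = gaussian_filter1d(
        rng_mod.standard_normal(n_positions),
        max(model.tangential_smoothness_mm / dx, 1e-6),
        mode="wrap",
    )
    sd = raw.std()
    modulation = 1.0 + (raw - raw.mean()) / sd * model.tangential_sd if sd > 0 else np.ones(n_positions)

    depths = (np.arange(n_depths) + 0.5) / n_depths
    resp = model.response()
    base = (
        model.depth_gain(depths)[:, None, None]
        * modulation[None, :, None]
        * resp[None, None, :]
    )
    if model.trial_amplitude_sd > 0:
        gains = 1.0 + rng_gain.normal(0.0, model.trial_amplitude_sd, size=n_trials)
    else:
        gains = np.ones(n_trials)
    data = gains[:, None, None, None] * base[None, ...]
    if noise_sd > 0:
        data += rng_noise.normal(0.0, noise_sd, size=data.shape)
    return TrialSimulation(
        data=data,
        depths=depths,
        positions=positions,
        times=model.times(),
        modulation=modulation,
        model=model,
        noise_sd=float(noise_sd),
        seed=int(seed),
        meta={"n_depths": n_depths, "n_positions": n_positions},
    )
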