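"""Experiment configuration and pipeline orchestration.

Experiments are described by a YAML file with a top-level ``experiment``
key (``resolution | pial | trials | pca | depth-profile``) plus sections
for the patch, the induced field, the sampler, the analysis and the
experiment sweep.  Infinite SNR is encoded as the literal string
``"inf"``.  Every stochastic stage derives its substream from the single
master ``seed``, so a config runs to byte-identical numeric outputs.

:func:`run_pipeline` executes one config and writes TSV outputs plus a
``metadata.json`` with the resolved parameters, seed and package
version; on failure, partially written outputs are removed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cortex_model import make_flat_patch, make_variable_patch
from .activation_fields import TimecourseModel, induced_psf, simulate_trials
from .voxel_sampler import VoxelMeasurer, place_grid
from .depth_analysis import upsample_and_bin, normalize_profile
from .resolution_experiment import (
    OverlapConfig,
    PialConfig,
    run_overlap_experiment,
    run_pial_leakage_experiment,
)
from .tangential_variability import (
    TrialStack,
    build_trial_matrix,
    pca_explained_variance,
)

__all__ = ["ConfigError", "load_config", "validate_config", "run_pipeline"]

EXPERIMENTS = ("resolution", "pial", "trials", "pca", "depth-profile")


class ConfigError(ValueError):
    """Raised with one message per offending config field."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


def _parse_snr(value) -> float:
    if isinstance(value, str):
        if value.lower() in ("inf", "infinite", "infinity"):
            return float("inf")
        raise ValueError(f"snr string must be 'inf', got {value!r}")
    return float(value)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config file must contain a mapping at top level"])
    return cfg


def validate_config(cfg: dict) -> list:
    """Collect schema violations, one message per field."""
    errors = []
    exp = cfg.get("experiment")
    if exp not in EXPERIMENTS:
        errors.append(f"experiment: must be one of {EXPERIMENTS}, got {exp!r}")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")
    patch = cfg.get("patch", {})
    if not isinstance(patch, dict):
        errors.append("patch: must be a mapping")
        patch = {}
    if patch.get("kind", "variable") not in ("variable", "flat"):
        errors.append("patch.kind: must be 'variable' or 'flat'")
    for key in ("length_mm", "smoothness_mm", "resolution_mm", "thickness_mm"):
        if key in patch and not (isinstance(patch[key], (int, float)) and patch[key] > 0):
            errors.append(f"patch.{key}: must be a positive number")
    sampler = cfg.get("sampler", {})
    if isinstance(sampler, dict) and "snr" in sampler:
        try:
            _parse_snr(sampler["snr"])
        except ValueError as exc:
            errors.append(f"sampler.snr: {exc}")
    analysis = cfg.get("analysis", {})
    if isinstance(analysis, dict):
        nd = analysis.get("n_depths")
        if nd is not None and (not isinstance(nd, int) or nd < 2):
            errors.append("analysis.n_depths: must be an integer >= 2")
    spec = cfg.get("experiment_spec", {})
    if isinstance(spec, dict):
        rs = spec.get("roi_sizes")
        if rs is not None and (
            not isinstance(rs, (list, tuple)) or any(not isinstance(v, int) or v < 1 for v in rs)
        ):
            errors.append("experiment_spec.roi_sizes: must be a list of positive integers")
    if exp == "pca" and "input_trials" not in cfg:
        errors.append("input_trials: required for the pca experiment")
    return errors


def _build_patch_from_cfg(patch_cfg: dict, seed: int):
    kind = patch_cfg.get("kind", "variable")
    res = patch_cfg.get("resolution_mm", 0.01)
    if kind == "flat":
        return make_flat_patch(
            patch_cfg.get("thickness_mm", 3.0), patch_cfg.get("length_mm", 20.0), res
        )
    tmin, tmax = patch_cfg.get("thickness_range_mm", [1.7, 3.7])
    return make_variable_patch(
        tmin,
        tmax,
        patch_cfg.get("length_mm", 20.0),
        patch_cfg.get("smoothness_mm", 5.0),
        seed,
        resolution_mm=res,
        undulation_mm=patch_cfg.get("undulation_mm", 0.3),
    )


def _overlap_config(cfg: dict, seed: int) -> OverlapConfig:
    patch = cfg.get("patch", {})
    fieldc = cfg.get("field", {})
    sampler = cfg.get("sampler", {})
    analysis = cfg.get("analysis", {})
    spec = cfg.get("experiment_spec", {})
    tr = patch.get("thickness_range_mm", [1.7, 3.7])
    return OverlapConfig(
        patch_kind=patch.get("kind", "variable"),
        thickness_mm=patch.get("thickness_mm", 3.0),
        thickness_range_mm=(tr[0], tr[1]),
        length_mm=patch.get("length_mm", 40.0),
        smoothness_mm=patch.get("smoothness_mm", 5.0),
        undulation_mm=patch.get("undulation_mm", 0.3),
        resolution_mm=patch.get("resolution_mm", 0.01),
        psf_center_depth=fieldc.get("center_depth", 0.5),
        psf_fwhm_fraction=fieldc.get("fwhm_fraction", 0.2),
        psf_peak=fieldc.get("peak", 1.0),
        voxel_size_mm=sampler.get("voxel_size_mm", 0.75),
        kernel=sampler.get("kernel"),
        snr=_parse_snr(sampler.get("snr", "inf")),
        n_depths=analysis.get("n_depths", 21),
        upsample_factor=analysis.get("upsample_factor", 10),
        roi_sizes=tuple(spec.get("roi_sizes", [24])),
        n_realizations=spec.get("n_realizations", 500),
        seed=seed,
    )


def _pial_config(cfg: dict, seed: int) -> PialConfig:
    patch = cfg.get("patch", {})
    fieldc = cfg.get("field", {})
    sampler = cfg.get("sampler", {})
    analysis = cfg.get("analysis", {})
    spec = cfg.get("experiment_spec", {})
    tr = patch.get("thickness_range_mm", [1.7, 3.7])
    return PialConfig(
        patch_kind=patch.get("kind", "variable"),
        thickness_mm=patch.get("thickness_mm", 3.0),
        thickness_range_mm=(tr[0], tr[1]),
        length_mm=patch.get("length_mm", 10.0),
        smoothness_mm=patch.get("smoothness_mm", 5.0),
        undulation_mm=patch.get("undulation_mm", 0.3),
        resolution_mm=patch.get("resolution_mm", 0.01),
        rim_width_mm=fieldc.get("rim_width_mm", 0.1),
        rim_peak=fieldc.get("rim_peak", 1.0),
        voxel_sizes_mm=tuple(sampler.get("voxel_sizes_mm", [0.75, 0.125])),
        snr=_parse_snr(sampler.get("snr", "inf")),
        n_depths=analysis.get("n_depths", 30),
        upsample_factor=analysis.get("upsample_factor", 10),
        n_realizations=spec.get("n_realizations", 100),
        seed=seed,
    )


def run_pipeline(config_path, seed=None, out=None, quiet=False) -> dict:
    """Execute the experiment named in the config; return output paths.

    ``seed`` and ``out`` override the config's ``seed`` / ``output_dir``.
    Outputs are deterministic given identical resolved configs.
    """
    cfg = load_config(config_path)
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)
    exp = cfg["experiment"]
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out_dir = Path(cfg.get("output_dir", "laminarsim_out") if out is None else out)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines = [f"experiment={exp} seed={seed} config={config_path}"]
    t_start = time.perf_counter()

    def _emit(path: Path):
        written.append(path)
        if not quiet:
            print(f"wrote {path}")

    try:
        meta = {
            "experiment": exp,
            "seed": seed,
            "package_version": __version__,
            "config": cfg,
        }
        if exp == "resolution":
            curve = run_overlap_experiment(_overlap_config(cfg, seed))
            p = out_dir / "overlap_curve.tsv"
            curve.to_tsv(p)
            _emit(p)
            meta["resolved"] = curve.meta
        elif exp == "pial":
            res = run_pial_leakage_experiment(_pial_config(cfg, seed))
            for size, prof in res.profiles.items():
                p = out_dir / f"pial_profile_{size:g}mm.tsv"
                prof.to_tsv(p)
                _emit(p)
            meta["resolved"] = res.meta
            meta["extent_10pct"] = {str(k): v for k, v in res.extent_10pct.items()}
        elif exp == "trials":
            ss = np.random.SeedSequence(seed)
            patch_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
            patch = _build_patch_from_cfg(cfg.get("patch", {"kind": "flat", "length_mm": 20.0}), patch_seed)
            tc_cfg = cfg.get("timecourse", {})
            model = TimecourseModel(**tc_cfg)
            trials_cfg = cfg.get("trials", {})
            sim = simulate_trials(
                model,
                patch,
                trials_cfg.get("n_trials", model.trial_count),
                trials_cfg.get("noise_sd", 0.1),
                sim_seed,
                n_depths=trials_cfg.get("n_depths", 30),
                n_positions=trials_cfg.get("n_positions", 40),
            )
            stack = build_trial_matrix(sim)
            p = out_dir / "trials.tsv"
            stack.to_tsv(p)
            _emit(p)
            import pandas as pd

            p2 = out_dir / "modulation.tsv"
            pd.DataFrame({"position_mm": sim.positions, "modulation": sim.modulation}).to_csv(
                p2, sep="\t", index=False
            )
            _emit(p2)
        elif exp == "pca":
            stack = TrialStack.from_tsv(cfg["input_trials"])
            res = pca_explained_variance(stack)
            import pandas as pd

            p = out_dir / "explained_variance.tsv"
            pd.DataFrame(
                {
                    "component": np.arange(1, res.explained_variance_pct.size + 1),
                    "explained_variance_pct": res.explained_variance_pct,
                }
            ).to_csv(p, sep="\t", index=False)
            _emit(p)
            p2 = out_dir / "pc1_profile.tsv"
            pd.DataFrame({"position_mm": res.positions, "pc1": res.pc1}).to_csv(
                p2, sep="\t", index=False
            )
            _emit(p2)
            meta["pc1_explained_variance_pct"] = float(res.explained_variance_pct[0])
        elif exp == "depth-profile":
            ss = np.random.SeedSequence(seed)
            patch_seed_ss, jitter_ss = ss.spawn(2)
            patch = _build_patch_from_cfg(
                cfg.get("patch", {}), int(patch_seed_ss.generate_state(1)[0] % (2**31))
            )
            fieldc = cfg.get("field", {})
            psf = induced_psf(
                fieldc.get("center_depth", 0.5),
                fieldc.get("fwhm_fraction", 0.2),
                fieldc.get("peak", 1.0),
            )
            sampler = cfg.get("sampler", {})
            analysis = cfg.get("analysis", {})
            rng = np.random.default_rng(jitter_ss)
            grid = place_grid(patch, sampler.get("voxel_size_mm", 0.75), jitter_seed=rng)
            vs = VoxelMeasurer(patch, psf).sample(grid, _parse_snr(sampler.get("snr", "inf")), rng)
            prof = upsample_and_bin(
                vs, patch, analysis.get("n_depths", 30), analysis.get("upsample_factor", 10)
            )
            norm = analysis.get("normalization", "none")
            if norm != "none":
                prof = normalize_profile(prof, norm)
            p = out_dir / "depth_profile.tsv"
            prof.to_tsv(p)
            _emit(p)

        meta["wall_clock_s"] = round(time.perf_counter() - t_start, 3)
        meta_path = out_dir / "metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        _emit(meta_path)
        log_lines.append(f"done in {meta['wall_clock_s']} s")
        log_path = out_dir / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        written.append(log_path)
        return {"outputs": [str(p) for p in written]}
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
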