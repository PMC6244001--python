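"""Trial-to-trial tangential BOLD variability via PCA.

The laminar analysis of isotropic data assumes the depth profile is the
same everywhere in the ROI.  To test whether tangential structure is
reproducible (physiological/physical) rather than thermal noise, the
positive-BOLD tangential profile of each trial is stacked into a
trials x positions matrix and decomposed by PCA: if a fixed tangential
pattern repeats across trials, the first principal component (PC1)
captures it and its explained-variance percentage is high; pure thermal
noise spreads variance across all components.

Conventions: trials are observations (rows), tangential positions are
variables (columns); the matrix is column-mean centred; explained
variance of component k is ``100 * s_k^2 / sum(s^2)`` from the singular
values; PC1's sign is fixed so that it correlates non-negatively with
the mean tangential profile.  No rotation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .activation_fields import TrialSimulation

__all__ = [
    "TrialStack",
    "PCAResult",
    "build_trial_matrix",
    "pca_explained_variance",
    "pc1_similarity",
]


@dataclass(frozen=True)
class TrialStack:
    """Per-trial positive-BOLD tangential profiles (trials x positions)."""

    positions: np.ndarray
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.positions.size:
            raise ValueError("matrix must be (n_trials, n_positions)")
        if self.matrix.shape[0] < 2:
            raise ValueError("a trial stack needs at least 2 trials")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        import pandas as pd

        nt, npos = self.matrix.shape
        tt, pp = np.meshgrid(np.arange(nt), self.positions, indexing="ij")
        pd.DataFrame(
            {"trial": tt.ravel(), "position_mm": pp.ravel(), "value": self.matrix.ravel()}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialStack":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="trial", columns="position_mm", values="value")
        return cls(
            positions=wide.columns.to_numpy(dtype=float),
            matrix=wide.to_numpy(dtype=float),
            provenance={"source": str(path)},
        )


@dataclass(frozen=True)
class PCAResult:
    """SVD decomposition of a centred trial stack.

    ``components`` rows are orthonormal tangential profiles;
    ``explained_variance_pct`` sums to 100 over all components.
    """

    components: np.ndarray
    singular_values: np.ndarray
    explained_variance_pct: np.ndarray
    mean: np.ndarray
    positions: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.components[0]


def build_trial_matrix(
    sim: TrialSimulation,
    rise_lag_s: float = 2.0,
) -> TrialStack:
    """Collapse simulated trials to positive-BOLD tangential profiles.

    Per trial the signal is averaged over the positive-BOLD window
    ``[onset + rise_lag, onset + duration]`` and over all GM depths,
    leaving one tangential profile per trial.
    """
    m = sim.model
    t0, t1 = m.stimulus_onset_s + rise_lag_s, m.stimulus_onset_s + m.stimulus_duration_s
    tm = (sim.times >= t0 - 1e-9) & (sim.times <= t1 + 1e-9)
    if not np.any(tm):
        raise ValueError("positive-BOLD window contains no time samples")
    # (trials, depths, positions, times) -> window mean -> depth mean
    matrix = sim.data[..., tm].mean(axis=-1).mean(axis=1)
    return TrialStack(
        positions=sim.positions,
        matrix=matrix,
        provenance={
            "generator": "simulate_trials",
            "seed": sim.seed,
            "noise_sd": sim.noise_sd,
            "rise_lag_s": rise_lag_s,
        },
    )


def pca_explained_variance(stack: TrialStack) -> PCAResult:
    """PCA of the column-centred trial matrix via SVD."""
    X = np.asarray(stack.matrix, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 tangential positions")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = np.sum(Xc**2)
    if total == 0:
        raise ValueError(
            "trial stack has zero across-trial variance; explained variance undefined"
        )
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evp = 100.0 * s**2 / np.sum(s**2)
    mean_profile = X.mean(axis=0)
    if np.std(mean_profile) > 0 and np.std(Vt[0]) > 0:
        r = np.corrcoef(Vt[0], mean_profile)[0, 1]
        if r < 0:
            Vt = Vt.copy()
            Vt[0] = -Vt[0]
    return PCAResult(
        components=Vt,
        singular_values=s,
        explained_variance_pct=evp,
        mean=mean,
        positions=stack.positions,
    )


def pc1_similarity(result: PCAResult, reference: np.ndarray) -> float:
    """Pearson correlation between PC1 and a reference tangential profile."""
    ref = np.asarray(reference, dtype=float)
    if ref.size != result.pc1.size:
        raise ValueError("reference must share the PC1 position grid")
    if np.std(ref) == 0 or np.std(result.pc1) == 0:
        raise ValueError("correlation undefined for constant profiles")
    return float(stats.pearsonr(result.pc1, ref).statistic)
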