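"""Synthetic multi-task connectivity cohorts with planted structure.

Emulates a developmental-cohort study: every subject contributes one ROI-level
time-series matrix per task, from which Pearson connectivity is computed.  A
non-negative block basis W_true plants latent "functional networks"; a subset
of factors has loadings that scale linearly with the subject's age (a
common-cause mechanism), so that connectivity among the ROIs of those factors
genuinely co-varies with age.  The resulting matrices are real correlation
matrices — the full pipeline (correlation -> positive thresholding -> joint
factorization -> graph attention) is exercised end to end.

The generator emulates cohort conditions (two tasks, ages uniform on 8-22
years, 124 time points, 264-ROI parcellation) but none of the scanner physics:
no hemodynamics, head motion or physiological noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import synthetic_atlas
from .connectivity import TimeSeriesMatrix, compute_fc, threshold_positive
from .data import CohortData

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "cohort_to_dataset",
    "PlantedMechanismModel",
]


@dataclass
class SyntheticSpec:
    """Cohort-generation parameters.

    effect_factors are 1-based factor indices whose loadings scale with age
    as 1 + effect_size * (age - midpoint) / (half-range), clipped at 0.
    """

    n_subjects: int = 622
    n_rois: int = 264
    n_tasks: int = 2
    rank: int = 5
    age_range: tuple = (8.0, 22.0)
    effect_factors: tuple = (1, 2)
    effect_size: float = 1.0
    timepoints: int = 124
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.rank <= self.n_rois:
            raise ValueError("rank must be in [1, n_rois]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        if not set(self.effect_factors) <= set(range(1, self.rank + 1)):
            raise ValueError("effect_factors must be a subset of 1..rank")
        if self.timepoints <= self.rank:
            raise ValueError("timepoints must exceed rank (degenerate correlations)")


@dataclass
class SyntheticCohort:
    spec: SyntheticSpec
    ages: np.ndarray
    fc: dict
    truth: dict = field(default_factory=dict)


def _planted_basis(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Block-structured non-negative basis: contiguous ROI blocks per factor
    with 10% overlap into the next block."""
    n, r = spec.n_rois, spec.rank
    block = n // r
    overlap = math.ceil(0.10 * block)
    w = np.zeros((n, r))
    for f in range(r):
        lo = f * block
        hi = n if f == r - 1 else min(n, (f + 1) * block + overlap)
        w[lo:hi, f] = rng.uniform(0.5, 1.0, size=hi - lo)
    return w


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Simulate the cohort; deterministic given spec.seed.

    Per subject s and task k the T x N time series is S = Z Lambda^T + E with
    Z ~ N(0,1) T x R latent signals, Lambda = W_true * diag(scales_s) and E
    Gaussian noise of sd `noise_sd`; connectivity is the Pearson correlation
    of S's columns.
    """
    rng = np.random.default_rng(spec.seed)
    w_true = _planted_basis(spec, rng)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_subjects)
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    effect_idx = np.array([f - 1 for f in spec.effect_factors], dtype=int)

    tasks = [f"task{k + 1}" for k in range(spec.n_tasks)]
    fc = {}
    scales_all = np.ones((spec.n_subjects, spec.rank))
    for si in range(spec.n_subjects):
        scale = np.ones(spec.rank)
        scale[effect_idx] = max(
            0.0, 1.0 + spec.effect_size * (ages[si] - mid) / half
        )
        scales_all[si] = scale
        lam = w_true * scale[None, :]
        for task in tasks:
            z = rng.standard_normal((spec.timepoints, spec.rank))
            e = rng.standard_normal((spec.timepoints, spec.n_rois)) * spec.noise_sd
            s = z @ lam.T + e
            fc[(si, task)] = compute_fc(
                TimeSeriesMatrix(values=s, subject_id=str(si), task_id=task)
            )

    support = w_true > 0
    informative = sorted(
        {
            (i, j)
            for f in effect_idx
            for idx in [np.flatnonzero(support[:, f])]
            for a, i in enumerate(idx)
            for j in idx[a + 1:]
        }
    )
    labels = [f"NET{int(np.argmax(w_true[i])) + 1}" for i in range(spec.n_rois)]
    truth = {
        "W_true": w_true,
        "factor_scales": scales_all,
        "informative_edges": informative,
        "atlas": synthetic_atlas(spec.n_rois, labels),
        "tasks": tasks,
    }
    return SyntheticCohort(spec=spec, ages=ages, fc=fc, truth=truth)


class PlantedMechanismModel:
    """Synthetic predictor whose output depends only on a known edge subset.

    Exposes the same masking interface as the trained regressor
    (`explain_edge_pairs` / `masked_forward`) but computes its prediction as a
    weighted sum of the gates of the planted edges, so the ground-truth
    explanation is the planted set itself.  Used to validate the explainer:
    masks learned on this model should rank planted edges above the rest.
    """

    def __init__(self, pairs, planted_pairs, n_features: int = 4,
                 edge_weight: float = 2.0, feature_weights=None):
        self.pairs = sorted(pairs)
        self.planted = set(planted_pairs)
        if not self.planted <= set(self.pairs):
            raise ValueError("planted pairs must be a subset of the edge pairs")
        self.n_features_ = n_features
        self._w = np.array(
            [[edge_weight if p in self.planted else 0.0] for p in self.pairs]
        )
        self._fw = (
            np.zeros((1, n_features)) if feature_weights is None
            else np.asarray(feature_weights, float).reshape(1, -1)
        )

    def explain_edge_pairs(self, data, subject):
        return list(self.pairs)

    def masked_forward(self, data, subject, edge_gate, feature_gate):
        from ._autodiff import Tensor

        out = (edge_gate * Tensor(self._w)).sum()
        return out + (feature_gate * Tensor(self._fw)).sum()


def cohort_to_dataset(cohort: SyntheticCohort) -> CohortData:
    """Bundle the cohort for modeling: positive-thresholded matrices, targets, atlas."""
    tasks = cohort.truth["tasks"]
    subjects = list(range(cohort.spec.n_subjects))
    return CohortData(
        subjects=subjects,
        tasks=tasks,
        ages=cohort.ages,
        fc=cohort.fc,
        X={k: threshold_positive(v) for k, v in cohort.fc.items()},
        atlas=cohort.truth["atlas"],
        truth=cohort.truth,
    )
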