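"""Cohort container: per-subject, per-task connectivity plus targets and atlas."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import RoiAtlas
from .connectivity import ConnectivityMatrix, NonnegConnectivity, threshold_positive


@dataclass
class CohortData:
    """Model-ready dataset.

    fc maps (subject_id, task_id) to the raw correlation matrix; X holds the
    positive-thresholded version consumed by the factorization. ages align
    with `subjects`.
    """

    subjects: list
    tasks: list
    ages: np.ndarray
    fc: dict
    X: dict = field(default_factory=dict)
    atlas: RoiAtlas | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if len(self.ages) != len(self.subjects):
            raise ValueError("ages and subjects must align")
        for s in self.subjects:
            for t in self.tasks:
                if (s, t) not in self.fc:
                    raise ValueError(f"missing connectivity for {(s, t)!r}")
        if not self.X:
            self.X = {k: threshold_positive(v) for k, v in self.fc.items()}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        first = self.fc[(self.subjects[0], self.tasks[0])]
        v = first.values if isinstance(first, ConnectivityMatrix) else np.asarray(first)
        return v.shape[0]
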