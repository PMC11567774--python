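"""Shared domain containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Default parcel labels: 180 areas per hemisphere, left then right.
def parcel_labels(n_parcels: int = 360) -> list[str]:
    """Canonical parcel labels ``L_001..L_xxx, R_001..R_xxx``.

    Half the parcels are assigned to each hemisphere; for odd counts the
    left hemisphere gets the extra parcel.
    """
    n_left = (n_parcels + 1) // 2
    left = [f"L_{i + 1:03d}" for i in range(n_left)]
    right = [f"R_{i + 1:03d}" for i in range(n_parcels - n_left)]
    return left + right


#: The 34 subcortical / non-cortical structures carried as volumes (mm^3):
#: paired gray-matter nuclei, white-matter structures including the corpus
#: callosum subdivisions, brainstem, and CSF spaces.
SUBCORTICAL_LABELS: tuple[str, ...] = (
    "Left-Amygdala", "Right-Amygdala",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Thalamus", "Right-Thalamus",
    "Left-VentralDC", "Right-VentralDC",
    "Left-Caudate", "Right-Caudate",
    "Left-Cerebellum-Cortex", "Right-Cerebellum-Cortex",
    "Left-Pallidum", "Right-Pallidum",
    "Left-Putamen", "Right-Putamen",
    "Left-Accumbens-area", "Right-Accumbens-area",
    "Brainstem",
    "Optic-Chiasm",
    "CC_Anterior", "CC_Central", "CC_Mid_Anterior",
    "CC_Mid_Posterior", "CC_Posterior",
    "Left-Cerebellum-White-Matter", "Right-Cerebellum-White-Matter",
    "CSF",
    "3rd-Ventricle", "4th-Ventricle",
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Inf-Lat-Vent", "Right-Inf-Lat-Vent",
)


@dataclass
class ParcellatedSample:
    """One subject's parcellated structural phenotypes and metadata.

    Parameters
    ----------
    subject_id
        Unique identifier.
    group
        ``"case"`` or ``"control"``.
    batch
        Acquisition batch (site/scanner source), ``1..n_batches``.
    sex
        ``"F"`` or ``"M"``.
    age
        Age in years.
    n_types
        Number of trait types reported (cases only; 0 for controls).
    area, thickness, myelin
        Per-parcel surface area (mm^2), cortical thickness (mm) and
        T1w/T2w myelin-proxy ratio.
    subcortical
        Volumes (mm^3) of the non-cortical structures.
    etiv
        Estimated total intracranial volume (mm^3).
    global_area
        Total cortical surface area (mm^2); equals ``sum(area)``.
    """

    subject_id: str
    group: str
    batch: int
    sex: str
    age: float
    n_types: int
    area: np.ndarray
    thickness: np.ndarray
    myelin: np.ndarray
    subcortical: np.ndarray
    etiv: float
    global_area: float

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("area", "thickness", "myelin", "subcortical"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values for {self.subject_id}")
            setattr(self, name, v)
        if not self.etiv > 0:
            raise ValueError(f"etiv must be positive for {self.subject_id}")
        total = float(np.sum(self.area))
        if total > 0 and abs(self.global_area - total) > 1e-3 * total:
            raise ValueError(
                f"global_area {self.global_area:g} deviates from sum(area) "
                f"{total:g} by more than 0.1% for {self.subject_id}"
            )


@dataclass
class RestingTimeseries:
    """One subject's parcel x timepoint resting-state signal matrix."""

    subject_id: str
    data: np.ndarray
    tr: float = 0.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be 2-D (parcels x timepoints)")
        if np.any(self.data.std(axis=1) == 0):
            raise ValueError(f"zero-variance parcel row in timeseries {self.subject_id}")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class Connectome:
    """Symmetric parcel x parcel edge-weight matrix with zero diagonal."""

    weights: np.ndarray
    kind: str  # "pearson" | "partial"
    parcel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be square")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("connectome weights must be symmetric within 1e-8")
        if self.kind not in ("pearson", "partial"):
            raise ValueError(f"kind must be 'pearson' or 'partial', got {self.kind!r}")
        if self.kind == "pearson" and np.any(np.abs(w) > 1 + 1e-8):
            raise ValueError("pearson connectome entries must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.parcel_labels:
            self.parcel_labels = parcel_labels(w.shape[0])

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge weights in the fixed (i < j) row-major order."""
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.weights[iu]


@dataclass
class FeatureMatrix:
    """Subjects x named features for one biomarker.

    ``needs_reduction`` marks wide pairwise feature sets that must be
    PCA-reduced inside training folds rather than up front (leakage
    contract); ``reducer_state`` records the fitted reducer when one has
    been applied.
    """

    biomarker_id: str
    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] = field(default_factory=list)
    needs_reduction: bool = False
    reducer_state: Any = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (subjects x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"missing/non-finite values in biomarker {self.biomarker_id}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GradientSet:
    """Per-parcel scores on the first two connectome gradients."""

    scores: np.ndarray  # n_parcels x 2
    explained_variance: np.ndarray  # length 2, fraction of variance
    reference_aligned: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 2:
            raise ValueError("gradient scores must be n_parcels x 2")
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
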