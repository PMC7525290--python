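"""Stress-difference features of the disc and the 18-dimensional model input.

For each of the eight anatomical subregions the stress field is summarized
by its maximum and volume-weighted average element von Mises stress.  The
model features are the signed differences (post-operative minus
pre-operative) of those 16 summaries, followed by age and encoded gender.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fem import FemSolution
from .geometry import SUBREGIONS, TetMesh

__all__ = [
    "DELTA_FEATURE_NAMES",
    "FEATURE_NAMES",
    "FeatureVector",
    "Standardizer",
    "SubregionStressSummary",
    "build_feature_vector",
    "delta_features",
    "encode_gender",
    "summarize_stress",
]

#: Fixed order of the 16 stress-difference features: per subregion in
#: :data:`~pjaplan.geometry.SUBREGIONS` order, max then volume-weighted avg.
DELTA_FEATURE_NAMES = tuple(
    f"d{stat}_{region}" for region in SUBREGIONS for stat in ("max", "avg")
)

#: Full 18-entry feature order of the risk model input.
FEATURE_NAMES = DELTA_FEATURE_NAMES + ("age", "gender")

_GENDER_CODE = {"M": 0.0, "F": 1.0}


def encode_gender(gender: str | float | int) -> float:
    """Encode gender as M -> 0, F -> 1 (numeric 0/1 passes through)."""
    if isinstance(gender, str):
        try:
            return _GENDER_CODE[gender]
        except KeyError:
            raise ValueError(f"gender must be 'M' or 'F', got {gender!r}") from None
    value = float(gender)
    if value not in (0.0, 1.0):
        raise ValueError(f"numeric gender must be 0 or 1, got {gender!r}")
    return value


@dataclasses.dataclass(frozen=True)
class SubregionStressSummary:
    """Max and volume-weighted average von Mises stress per subregion (MPa).

    Arrays are aligned with :data:`~pjaplan.geometry.SUBREGIONS`.  The
    ``geometry_id`` records which mesh the summary was computed on so that
    differences across mismatched geometries are rejected.
    """

    max_stress: np.ndarray
    avg_stress: np.ndarray
    geometry_id: str

    def __post_init__(self) -> None:
        if self.max_stress.shape != (8,) or self.avg_stress.shape != (8,):
            raise ValueError("summaries must cover exactly 8 subregions")
        if np.any(self.max_stress + 1e-12 < self.avg_stress) or np.any(self.avg_stress < 0):
            raise ValueError("require max >= avg >= 0 in every subregion")

    def as_vector(self) -> np.ndarray:
        """Interleave to the fixed 16-entry order (max, avg per subregion)."""
        out = np.empty(16)
        out[0::2] = self.max_stress
        out[1::2] = self.avg_stress
        return out

    def scaled(self, factor: float) -> "SubregionStressSummary":
        """Summary under a load scaled by ``factor >= 0`` (FEM linearity)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return dataclasses.replace(
            self, max_stress=self.max_stress * factor, avg_stress=self.avg_stress * factor
        )


def summarize_stress(solution: FemSolution, mesh: TetMesh) -> SubregionStressSummary:
    """Summarize a stress field over the eight labelled subregions.

    The average is volume-weighted so it is insensitive to local mesh
    density.  An empty subregion means the mesh is too coarse to resolve
    all regions and is rejected.
    """
    if solution.von_mises.shape[0] != mesh.n_elements:
        raise ValueError("solution and mesh element counts differ")
    vols = mesh.element_volumes()
    max_s = np.empty(8)
    avg_s = np.empty(8)
    for i, region in enumerate(SUBREGIONS):
        sel = mesh.subregion_of_element == region
        if not np.any(sel):
            raise ValueError(f"subregion {region!r} has no elements; refine the mesh")
        vm = solution.von_mises[sel]
        w = vols[sel]
        max_s[i] = vm.max()
        avg_s[i] = float(np.average(vm, weights=w))
    return SubregionStressSummary(max_s, avg_s, mesh.geometry_id())


def delta_features(
    pre: SubregionStressSummary, post: SubregionStressSummary
) -> np.ndarray:
    """Signed stress-difference features: post minus pre, 16 values (MPa).

    Both summaries must come from the same disc geometry (pre- and
    post-operative states are simulated on the same model).
    """
    if pre.geometry_id != post.geometry_id:
        raise ValueError(
            f"pre/post summaries computed on different geometries "
            f"({pre.geometry_id} vs {post.geometry_id})"
        )
    return post.as_vector() - pre.as_vector()


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """The 18-entry risk-model input in fixed, documented order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} entries, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def build_feature_vector(
    delta: np.ndarray, age: float, gender: str | float
) -> FeatureVector:
    """Assemble the 16 stress deltas plus age and encoded gender."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (16,):
        raise ValueError(f"expected 16 stress-difference values, got shape {delta.shape}")
    if age is None or not np.isfinite(age):
        raise ValueError(f"age is required and must be finite, got {age!r}")
    return FeatureVector(np.concatenate([delta, [float(age), encode_gender(gender)]]))


@dataclasses.dataclass
class Standardizer:
    """Column z-scoring with statistics from the training set only.

    Constant columns get unit scale so they map to zero rather than NaN.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale
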