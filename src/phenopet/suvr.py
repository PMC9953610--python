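"""Regional SUVR feature extraction.

The standard uptake value ratio (SUVR) of a region is its mean tracer activity
divided by the mean activity of a reference region (pooled voxel-count-weighted
when several labels form the reference). One PET study yields one SUVR vector
over the atlas regions (166 by default); a cohort of studies is assembled into
a subjects x ROIs matrix — the feature set the phenotyping pipelines consume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionalMeans",
    "SUVRVector",
    "SUVRMatrix",
    "regional_means",
    "compute_suvr",
    "assemble_matrix",
    "suvr_from_image",
]

DEFAULT_N_ROIS = 166


class RegionalMeans(NamedTuple):
    roi_ids: np.ndarray
    means: np.ndarray
    counts: np.ndarray


@dataclass
class SUVRVector:
    """Per-study SUVR values over an ordered set of regions."""

    roi_ids: np.ndarray
    values: np.ndarray
    reference_roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.roi_ids = np.asarray(self.roi_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.reference_roi_ids = np.asarray(self.reference_roi_ids)
        if self.roi_ids.shape != self.values.shape:
            raise ValueError("roi_ids and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUVR values must be finite")


@dataclass
class SUVRMatrix:
    """Subjects x ROIs SUVR feature matrix with provenance.

    Stored subjects-as-rows; columns are ``ROI_<id>`` in ascending id order.
    ``provenance`` records at least the PVC method and FWHM used upstream.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("SUVR matrix contains missing entries")
        ids = self.roi_ids
        if np.any(np.diff(ids) <= 0):
            raise ValueError("ROI columns must be in strictly ascending id order")

    @property
    def roi_ids(self) -> np.ndarray:
        return np.array([int(c.split("_", 1)[1]) for c in self.data.columns])

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        """Write the matrix as CSV plus a ``.provenance.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index_label="subject_id")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "SUVRMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
        # normalise orientation: a file stored ROIs-as-rows is transposed on load
        if all(str(c).startswith("ROI_") for c in df.index) and not all(
            str(c).startswith("ROI_") for c in df.columns
        ):
            df = df.T
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data=df, provenance=prov)


def regional_means(image: np.ndarray, labels: np.ndarray, roi_ids=None) -> RegionalMeans:
    """Mean image value over each labelled region.

    Regions are the positive labels, sorted ascending. If ``roi_ids`` is given,
    ids absent from the volume are excluded with a warning rather than failing,
    mirroring how atlas regions can be empty in a given parcellation.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError(f"labels shape {labels.shape} != image shape {image.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError("label volume must be integer-typed")

    n_bins = int(labels.max()) + 1
    counts = np.bincount(labels.ravel(), minlength=n_bins)
    sums = np.bincount(labels.ravel(), weights=image.ravel(), minlength=n_bins)

    if roi_ids is None:
        roi_ids = np.flatnonzero(counts)
        roi_ids = roi_ids[roi_ids > 0]
    else:
        roi_ids = np.sort(np.asarray(roi_ids))
        have = (roi_ids < n_bins) & (counts[np.clip(roi_ids, 0, n_bins - 1)] > 0)
        if not np.all(have):
            warnings.warn(
                f"excluding empty region(s): {roi_ids[~have].tolist()}",
                RuntimeWarning,
                stacklevel=2,
            )
            roi_ids = roi_ids[have]
    return RegionalMeans(
        roi_ids=roi_ids,
        means=sums[roi_ids] / counts[roi_ids],
        counts=counts[roi_ids],
    )


def compute_suvr(
    means: np.ndarray,
    roi_ids: Sequence[int],
    reference_roi_ids: Sequence[int],
    voxel_counts: Sequence[int],
) -> SUVRVector:
    """Normalise regional means by the pooled reference-region mean.

    The reference pool is voxel-count-weighted: pooled = sum_r count_r*mean_r /
    sum_r count_r, i.e. the plain mean over all reference voxels.
    """
    roi_ids = np.asarray(roi_ids)
    means = np.asarray(means, dtype=float)
    counts = np.asarray(voxel_counts)
    reference_roi_ids = np.asarray(reference_roi_ids)
    ref_mask = np.isin(roi_ids, reference_roi_ids)
    if ref_mask.sum() != len(np.unique(reference_roi_ids)):
        missing = np.setdiff1d(reference_roi_ids, roi_ids)
        raise ValueError(f"reference region(s) not present: {missing.tolist()}")
    pooled = float(np.sum(means[ref_mask] * counts[ref_mask]) / np.sum(counts[ref_mask]))
    if pooled <= 0:
        raise ValueError(f"pooled reference mean must be positive, got {pooled}")
    return SUVRVector(
        roi_ids=roi_ids, values=means / pooled, reference_roi_ids=reference_roi_ids
    )


def suvr_from_image(
    image: np.ndarray, labels: np.ndarray, reference_roi_ids, roi_ids=None
) -> SUVRVector:
    """Convenience path: regional means then SUVR normalisation."""
    rm = regional_means(image, labels, roi_ids=roi_ids)
    return compute_suvr(rm.means, rm.roi_ids, reference_roi_ids, rm.counts)


def assemble_matrix(
    vectors: Sequence[SUVRVector],
    subject_ids: Sequence,
    provenance: dict | None = None,
    sort_subjects: bool = False,
) -> SUVRMatrix:
    """Stack per-study SUVR vectors into a subjects x ROIs matrix.

    All vectors must share the same ROI ordering; a mismatch is rejected naming
    the offending subject. ``sort_subjects`` canonicalises row order.
    """
    if len(vectors) != len(subject_ids):
        raise ValueError("one subject id per vector required")
    if len(vectors) == 0:
        raise ValueError("no vectors to assemble")
    ref = vectors[0].roi_ids
    for sid, vec in zip(subject_ids, vectors):
        if not np.array_equal(vec.roi_ids, ref):
            raise ValueError(f"ROI ids of subject {sid!r} do not match the first vector")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"ROI_{i}" for i in ref],
    )
    if sort_subjects:
        df = df.sort_index()
    prov = dict(provenance or {})
    prov.setdefault("reference_roi_ids", np.asarray(vectors[0].reference_roi_ids).tolist())
    return SUVRMatrix(data=df, provenance=prov)
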