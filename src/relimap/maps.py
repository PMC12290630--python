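"""Voxel-wise reliability maps and similarity between 3D statistical images.

Applies the scalar estimators of :mod:`relimap.stats` independently at every
in-mask voxel of a set of subject x occasion volumes, and computes binary
(Jaccard/Dice on thresholded maps) and continuous (Spearman rank) similarity
between statistical images.

Volumes are matched by list order, not by filename: occasion ``j`` holds the
same subjects, in the same order, as occasion ``0``. Outside-mask and
degenerate (zero-variance) voxels carry NaN in every output map; medians and
similarities skip them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (
    ICC_TYPES,
    InvalidDesignError,
    ReliabilityError,
    _icc_bounds,
    _icc_point,
    _twoway_tables,
)

__all__ = [
    "VolumeSet",
    "BrainMask",
    "ReliabilityMaps",
    "SimilarityResult",
    "voxelwise_icc",
    "masked_median",
    "binarize",
    "image_similarity",
    "pairwise_similarity",
]

SIMILARITY_METRICS = ("dice", "jaccard", "spearman")


def _as_array(vol) -> np.ndarray:
    """Accept a nibabel image or ndarray and return float data."""
    if isinstance(vol, nib.spatialimages.SpatialImage):
        return np.asarray(vol.get_fdata(), dtype=float)
    return np.asarray(vol, dtype=float)


def _grids_match(affine_a, affine_b) -> bool:
    return np.allclose(affine_a, affine_b, atol=1e-4)


@dataclass(frozen=True)
class BrainMask:
    """Binary 3D mask; any nonzero voxel is in-mask."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data) != 0
        if arr.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if not arr.any():
            raise ValueError("mask selects no voxels")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @classmethod
    def from_image(cls, img) -> "BrainMask":
        img = nib.load(img) if isinstance(img, (str, Path)) else img
        return cls(img.get_fdata(), img.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)


@dataclass(frozen=True)
class VolumeSet:
    """Subject x occasion stack of 3D volumes on a shared grid.

    ``data`` has shape ``(n_subjects, k_occasions, X, Y, Z)``; the subject
    order is identical across occasions.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_ids: tuple = None
    occasion_ids: tuple = None

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 5:
            raise ValueError("data must have shape (n_subjects, k_occasions, X, Y, Z)")
        n, k = arr.shape[:2]
        if n < 2 or k < 2:
            raise InvalidDesignError(f"need >= 2 subjects and >= 2 occasions, got {n} x {k}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        subj = self.subject_ids or tuple(f"sub-{i + 1:03d}" for i in range(n))
        occ = self.occasion_ids or tuple(f"ses-{j + 1}" for j in range(k))
        if len(subj) != n or len(occ) != k:
            raise ValueError("label lengths do not match data shape")
        object.__setattr__(self, "subject_ids", tuple(subj))
        object.__setattr__(self, "occasion_ids", tuple(occ))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def k_occasions(self) -> int:
        return self.data.shape[1]

    @property
    def grid_dims(self) -> tuple:
        return self.data.shape[2:]

    @classmethod
    def from_arrays(cls, occasions, affine, **kw) -> "VolumeSet":
        """Build from ``[occasion][subject]`` nested lists of 3D arrays."""
        ks = [len(o) for o in occasions]
        if len(occasions) < 2:
            raise InvalidDesignError("need at least 2 occasions")
        if len(set(ks)) != 1:
            raise InvalidDesignError(f"unequal subject counts across occasions: {ks}")
        stacked = np.stack([np.stack(list(o)) for o in occasions])  # (k, n, X, Y, Z)
        return cls(stacked.transpose(1, 0, 2, 3, 4), affine, **kw)

    @classmethod
    def from_images(cls, occasions, **kw) -> "VolumeSet":
        """Build from ``[occasion][subject]`` nested lists of NIfTI images/paths.

        Every volume must share the grid of the first; a mismatch raises an
        error naming the offending volume.
        """
        loaded = []
        for j, occ in enumerate(occasions):
            row = []
            for i, img in enumerate(occ):
                name = str(img) if isinstance(img, (str, Path)) else f"occasion {j}, subject {i}"
                img = nib.load(img) if isinstance(img, (str, Path)) else img
                row.append((name, img))
            loaded.append(row)
        ref_name, ref = loaded[0][0]
        for occ in loaded:
            for name, img in occ:
                if img.shape != ref.shape or not _grids_match(img.affine, ref.affine):
                    raise ValueError(
                        f"grid mismatch between volume '{name}' "
                        f"(shape {img.shape}) and '{ref_name}' (shape {ref.shape})"
                    )
        arrays = [[np.asarray(img.get_fdata(), dtype=float) for _, img in occ] for occ in loaded]
        return cls.from_arrays(arrays, ref.affine, **kw)


@dataclass(frozen=True)
class ReliabilityMaps:
    """Voxel-wise ICC results: five 3D maps (six for ICC(2,1)).

    ``estimate``, ``lower``, ``upper`` are the ICC point estimate and its
    confidence bounds; ``between_subject_var`` and ``within_subject_var`` are
    the ANOVA variance components; ``between_measure_var`` (ICC(2,1) only) is
    the occasion/measurement additive-bias variance. Outside-mask and
    degenerate voxels are NaN everywhere.
    """

    icc_type: str
    alpha: float
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    between_subject_var: np.ndarray
    within_subject_var: np.ndarray
    affine: np.ndarray
    between_measure_var: Optional[np.ndarray] = None
    n_subjects: int = 0
    k_occasions: int = 0

    def maps(self) -> dict:
        out = {
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "between_subject_var": self.between_subject_var,
            "within_subject_var": self.within_subject_var,
        }
        if self.between_measure_var is not None:
            out["between_measure_var"] = self.between_measure_var
        return out

    def to_images(self) -> dict:
        return {
            name: nib.Nifti1Image(arr.astype(np.float64), self.affine)
            for name, arr in self.maps().items()
        }

    def save(self, outdir, prefix: str = "") -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, img in self.to_images().items():
            p = outdir / f"{prefix}{self.icc_type}_{name}.nii.gz"
            nib.save(img, p)
            paths[name] = p
        return paths


@dataclass(frozen=True)
class SimilarityResult:
    metric: str
    coefficient: float
    image_labels: tuple
    threshold_used: Optional[float] = None
    note: str = ""


def voxelwise_icc(
    vs: VolumeSet,
    mask: BrainMask,
    icc_type: str = "icc_3",
    alpha: float = 0.05,
    compute_ci: bool = True,
) -> ReliabilityMaps:
    """Voxel-wise ICC with variance components across masked volumes.

    At every in-mask voxel the subject x occasion values form a
    :class:`~relimap.stats.MeasurementMatrix` and the requested ICC is
    estimated exactly as the scalar routine would, in one vectorised pass.

    Parameters
    ----------
    vs, mask
        Volumes and binary mask on the same grid.
    icc_type, alpha
        As in :func:`relimap.stats.icc`.
    compute_ci
        When False the bound maps are NaN; used by the bootstrap stability
        loop where only the point estimate and components are needed.
    """
    if icc_type not in ICC_TYPES:
        raise ValueError(f"unknown icc_type {icc_type!r}; expected one of {ICC_TYPES}")
    if vs.grid_dims != mask.data.shape or not _grids_match(vs.affine, mask.affine):
        raise ValueError(
            f"mask grid {mask.data.shape} does not match volume grid {vs.grid_dims}"
        )
    n, k = vs.n_subjects, vs.k_occasions
    flat = vs.data.reshape(n, k, -1)[:, :, mask.data.ravel()]
    t = _twoway_tables(flat)
    est, s2b, s2w, s2m, degen = _icc_point(t, icc_type)
    if compute_ci:
        lower, upper = _icc_bounds(t, est, icc_type, alpha)
    else:
        lower = upper = np.full_like(est, np.nan)

    def fill(values):
        out = np.full(mask.data.shape, np.nan)
        out[mask.data] = np.where(degen, np.nan, values)
        return out

    return ReliabilityMaps(
        icc_type=icc_type,
        alpha=alpha,
        estimate=fill(est),
        lower=fill(lower),
        upper=fill(upper),
        between_subject_var=fill(s2b),
        within_subject_var=fill(s2w),
        between_measure_var=fill(s2m) if icc_type == "icc_2" else None,
        affine=vs.affine,
        n_subjects=n,
        k_occasions=k,
    )


def masked_median(volume, mask: BrainMask) -> float:
    """Median over in-mask, non-missing voxels of a 3D map."""
    arr = _as_array(volume)
    if arr.shape != mask.data.shape:
        raise ValueError(f"map shape {arr.shape} does not match mask {mask.data.shape}")
    vals = arr[mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ReliabilityError("no defined voxels inside the mask")
    return float(np.median(vals))


def binarize(stat_map, threshold: float, mask: Optional[BrainMask] = None) -> np.ndarray:
    """Binary map: voxel is 1 iff value > threshold (inside the mask if given).

    A threshold of exactly 0 marks *every* in-mask voxel as 1 — with that
    convention two maps binarized at 0 always have similarity 1. Thresholding
    is one-sided on positive values (negative tails are never selected).
    """
    if not np.isfinite(threshold) or threshold < 0:
        raise ValueError("threshold must be finite and >= 0")
    arr = _as_array(stat_map)
    if threshold == 0:
        out = np.ones(arr.shape, dtype=bool)
    else:
        out = arr > threshold
    if mask is not None:
        if arr.shape != mask.data.shape:
            raise ValueError("map and mask grids differ")
        out &= mask.data
    return out


def image_similarity(
    img1,
    img2,
    mask: Optional[BrainMask] = None,
    threshold: Optional[float] = None,
    metric: str = "dice",
    labels: tuple = ("image_1", "image_2"),
) -> SimilarityResult:
    """Similarity between two statistical volumes.

    * ``jaccard``: |A n B| / |A u B| on maps binarized at ``threshold``;
    * ``dice``: 2 |A n B| / (|A| + |B|);
    * ``spearman``: rank correlation (average ranks for ties) of the
      unthresholded in-mask values.

    Undefined cases (empty union; zero rank variance) return NaN with a note
    rather than raising.
    """
    if metric not in SIMILARITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {SIMILARITY_METRICS}")
    a, b = _as_array(img1), _as_array(img2)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if mask is not None and a.shape != mask.data.shape:
        raise ValueError("image and mask grids differ")

    if metric == "spearman":
        sel = mask.data if mask is not None else np.ones(a.shape, dtype=bool)
        sel = sel & np.isfinite(a) & np.isfinite(b)
        if sel.sum() < 3:
            return SimilarityResult(metric, float("nan"), labels, None, "too few voxels")
        rho = sps.spearmanr(a[sel], b[sel]).statistic
        note = "" if np.isfinite(rho) else "zero rank variance"
        return SimilarityResult(metric, float(rho), labels, None, note)

    if a.dtype == bool and b.dtype == bool and threshold is None:
        ba, bb = a, b
        if mask is not None:
            ba, bb = ba & mask.data, bb & mask.data
    else:
        if threshold is None:
            raise ValueError("jaccard/dice need a threshold (or pre-binarized inputs)")
        ba = binarize(a, threshold, mask)
        bb = binarize(b, threshold, mask)
    inter = float(np.logical_and(ba, bb).sum())
    union = float(np.logical_or(ba, bb).sum())
    if union == 0:
        return SimilarityResult(metric, float("nan"), labels, threshold, "empty union")
    coef = inter / union if metric == "jaccard" else 2.0 * inter / (ba.sum() + bb.sum())
    return SimilarityResult(metric, float(coef), labels, threshold, "")


def pairwise_similarity(
    images: Sequence,
    labels: Optional[Sequence[str]] = None,
    mask: Optional[BrainMask] = None,
    threshold: Optional[float] = None,
    metric: str = "dice",
) -> pd.DataFrame:
    """Similarity for every unordered pair of >= 2 labeled volumes.

    Returns a DataFrame with one row per pair and columns
    ``image_i, image_j, metric, coefficient, threshold`` (NaN coefficient and a
    ``note`` where a pair is undefined).
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if labels is None:
        labels = [
            Path(str(img)).name if isinstance(img, (str, Path)) else f"image_{i + 1}"
            for i, img in enumerate(images)
        ]
    if len(labels) != len(images):
        raise ValueError("labels length must match images")
    arrays = [
        _as_array(nib.load(img) if isinstance(img, (str, Path)) else img) for img in images
    ]
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
        res = image_similarity(
            a, b, mask=mask, threshold=threshold, metric=metric,
            labels=(labels[i], labels[j]),
        )
        rows.append(
            {
                "image_i": labels[i],
                "image_j": labels[j],
                "metric": metric,
                "coefficient": res.coefficient,
                "threshold": res.threshold_used,
                "note": res.note,
            }
        )
    return pd.DataFrame(rows)
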