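"""Synthetic subject x occasion volumes with known variance components.

The generator draws voxel data from the additive random-effects model that
underlies the ICC:

    y_ijv = mu_v + b_iv + s_j + e_ijv

with subject effects ``b_iv ~ N(0, sigma2_between(v))``, residual noise
``e_ijv ~ N(0, sigma2_within(v))`` and a *fixed* per-occasion additive bias
``s_j`` (a session/practice effect). Under this model the true consistency
ICC(3,1) at voxel ``v`` is ``sigma2_between / (sigma2_between +
sigma2_within)``; the occasion bias lowers absolute agreement (ICC(2,1)) but
not consistency.

Every draw is deterministic given the spec's seed. By default voxels are
independent; an optional Gaussian smoothing (variance-preserving) induces
spatially correlated fields for smoothing-sensitivity demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .maps import BrainMask, VolumeSet

__all__ = [
    "SimulationSpec",
    "TruthBundle",
    "simulate_dataset",
    "worked_example_volumes",
    "make_masks",
    "WORKED_EXAMPLE_A",
    "WORKED_EXAMPLE_B",
]

#: the five-subject, two-occasion demonstration values (occasion B = 3 x A):
#: perfectly correlated occasions whose consistency ICC(3,1) is nevertheless 0.60
WORKED_EXAMPLE_A = (1.0, 3.0, 6.0, 9.0, 12.0)
WORKED_EXAMPLE_B = (3.0, 9.0, 18.0, 27.0, 36.0)

DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic grid


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the generative model.

    ``sigma2_between`` / ``sigma2_within`` / ``grand_mean`` may be scalars or
    3D maps on ``grid_dims``. ``occasion_bias`` is a length-k vector of fixed
    additive shifts (defaults to zero). ``mask_fraction`` is the fraction of
    the grid treated as in-brain. ``smooth_sigma_vox`` > 0 smooths the random
    fields with a Gaussian kernel (in voxels) while preserving their marginal
    variance.
    """

    n_subjects: int
    n_occasions: int = 2
    grid_dims: Tuple[int, int, int] = (8, 8, 8)
    mask_fraction: float = 1.0
    grand_mean: Union[float, np.ndarray] = 0.0
    sigma2_between: Union[float, np.ndarray] = 1.0
    sigma2_within: Union[float, np.ndarray] = 1.0
    occasion_bias: Optional[Sequence[float]] = None
    smooth_sigma_vox: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_occasions < 2:
            raise ValueError("need >= 2 subjects and >= 2 occasions")
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 2 for d in dims):
            raise ValueError("grid_dims must be three ints >= 2")
        object.__setattr__(self, "grid_dims", dims)
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must lie in (0, 1]")
        for name in ("sigma2_between", "sigma2_within"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val < 0):
                raise ValueError(f"{name} must be >= 0")
            if val.ndim not in (0, 3):
                raise ValueError(f"{name} must be scalar or a 3-D map")
            if val.ndim == 3 and val.shape != dims:
                raise ValueError(f"{name} map shape {val.shape} != grid {dims}")
        bias = self.occasion_bias
        if bias is not None:
            bias = tuple(float(b) for b in bias)
            if len(bias) != self.n_occasions:
                raise ValueError("occasion_bias length must equal n_occasions")
        object.__setattr__(self, "occasion_bias", bias)


@dataclass(frozen=True)
class TruthBundle:
    """Generated volumes plus the ground-truth maps they were drawn from."""

    volume_set: VolumeSet
    brain_mask: BrainMask
    supra_mask: BrainMask
    sub_mask: BrainMask
    true_icc3: np.ndarray
    true_bs: np.ndarray
    true_ws: np.ndarray
    spec: SimulationSpec


def _smooth_preserving_variance(field: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth the trailing 3 axes, rescaling to keep unit-noise variance."""
    if sigma <= 0:
        return field
    # periodic boundaries: every voxel sees the same kernel mass, so one
    # rescaling restores the marginal variance at every voxel exactly
    out = gaussian_filter(field, sigma=(0,) * (field.ndim - 3) + (sigma,) * 3, mode="wrap")
    delta = np.zeros(field.shape[-3:])
    delta[tuple(d // 2 for d in delta.shape)] = 1.0
    factor = np.sqrt((gaussian_filter(delta, sigma, mode="wrap") ** 2).sum())
    return out / factor


def make_masks(
    grid_dims: Tuple[int, int, int],
    supra_fraction: float,
    seed: int = 0,
    brain: Optional[BrainMask] = None,
    affine: Optional[np.ndarray] = None,
) -> Tuple[BrainMask, BrainMask]:
    """Split the in-brain voxels into disjoint supra-/subthreshold masks.

    ``supra_fraction`` of the in-brain voxels (rounded) are assigned to the
    suprathreshold mask, the rest to the subthreshold mask; the split is a
    seeded random draw standing in for thresholding an independent
    meta-analytic map.
    """
    if not 0.0 < supra_fraction < 1.0:
        raise ValueError("supra_fraction must lie strictly between 0 and 1")
    affine = DEFAULT_AFFINE if affine is None else affine
    if brain is None:
        brain_arr = np.ones(tuple(grid_dims), dtype=bool)
    else:
        brain_arr = brain.data
        affine = brain.affine
    idx = np.flatnonzero(brain_arr.ravel())
    n_supra = int(round(supra_fraction * idx.size))
    if n_supra < 1 or n_supra >= idx.size:
        raise ValueError("supra_fraction leaves an empty mask on this grid")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    chosen = rng.choice(idx, size=n_supra, replace=False)
    supra = np.zeros(brain_arr.shape, dtype=bool)
    supra.ravel()[chosen] = True
    sub = brain_arr & ~supra
    return BrainMask(supra, affine), BrainMask(sub, affine)


def simulate_dataset(spec: SimulationSpec, supra_fraction: float = 0.25) -> TruthBundle:
    """Draw a subject x occasion volume set from the additive variance model.

    Returns the generated :class:`VolumeSet`, the brain mask, disjoint
    supra-/subthreshold masks, and the true ICC(3,1) / between-subject /
    within-subject variance maps implied by the spec.
    """
    dims = spec.grid_dims
    n, k = spec.n_subjects, spec.n_occasions
    s2b = np.broadcast_to(np.asarray(spec.sigma2_between, dtype=float), dims)
    s2w = np.broadcast_to(np.asarray(spec.sigma2_within, dtype=float), dims)
    mu = np.broadcast_to(np.asarray(spec.grand_mean, dtype=float), dims)
    bias = np.asarray(
        spec.occasion_bias if spec.occasion_bias is not None else np.zeros(k), dtype=float
    )

    master = np.random.SeedSequence(entropy=spec.seed)
    rng_b, rng_e, rng_m = (np.random.default_rng(s) for s in master.spawn(3))

    b = rng_b.standard_normal((n,) + dims)
    e = rng_e.standard_normal((n, k) + dims)
    if spec.smooth_sigma_vox > 0:
        b = _smooth_preserving_variance(b, spec.smooth_sigma_vox)
        e = _smooth_preserving_variance(e, spec.smooth_sigma_vox)
    b = b * np.sqrt(s2b)
    e = e * np.sqrt(s2w)
    data = mu + b[:, None] + bias.reshape(1, k, 1, 1, 1) + e

    if spec.mask_fraction < 1.0:
        flat = np.zeros(int(np.prod(dims)), dtype=bool)
        n_in = max(1, int(round(spec.mask_fraction * flat.size)))
        flat[rng_m.choice(flat.size, size=n_in, replace=False)] = True
        brain_arr = flat.reshape(dims)
    else:
        brain_arr = np.ones(dims, dtype=bool)
    brain = BrainMask(brain_arr, DEFAULT_AFFINE)
    supra, sub = make_masks(dims, supra_fraction, seed=spec.seed, brain=brain)

    with np.errstate(divide="ignore", invalid="ignore"):
        true_icc3 = np.where(s2b + s2w > 0, s2b / (s2b + s2w), np.nan)

    vs = VolumeSet(data, DEFAULT_AFFINE)
    return TruthBundle(
        volume_set=vs,
        brain_mask=brain,
        supra_mask=supra,
        sub_mask=sub,
        true_icc3=true_icc3,
        true_bs=np.array(s2b, dtype=float),
        true_ws=np.array(s2w, dtype=float),
        spec=spec,
    )


def worked_example_volumes(grid_dims: Tuple[int, int, int] = (4, 4, 4)) -> VolumeSet:
    """Five-subject, two-occasion volumes carrying the demonstration values.

    Every voxel of subject ``i`` holds ``WORKED_EXAMPLE_A[i]`` on occasion 1
    and ``WORKED_EXAMPLE_B[i] = 3 * A[i]`` on occasion 2: the occasions are
    perfectly correlated (r = 1.0) yet the voxel-wise ICC(3,1) is 0.60
    everywhere, the classic illustration that consistency is not correlation.
    """
    dims = tuple(int(d) for d in grid_dims)
    vals = np.array([WORKED_EXAMPLE_A, WORKED_EXAMPLE_B]).T  # (5, 2)
    data = np.broadcast_to(
        vals[:, :, None, None, None], (5, 2) + dims
    ).copy()
    return VolumeSet(data, DEFAULT_AFFINE)
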