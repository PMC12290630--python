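"""Bootstrap sample-size stability of median reliability estimates.

For each sample size ``n`` on a grid, subjects are resampled with replacement
(paired across occasions, so a subject keeps its own repeated measurements),
the voxel-wise ICC is recomputed, and the masked medians of the estimate and
of the between-/within-subject variance maps are recorded. Repeating this
many times per ``n`` yields an empirical stabilization curve: the spread of
the median estimate shrinks as ``n`` grows.

The default grid — 25 to 525 subjects in steps of 50, 100 iterations per
step — matches the common practice of probing correlation stability on large
consortium samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .maps import BrainMask, VolumeSet, _grids_match
from .stats import ICC_TYPES, ReliabilityError, _icc_point, _twoway_tables

__all__ = ["StabilityGrid", "StabilityCurve", "subsample_stability"]

DEFAULT_N_VALUES = tuple(range(25, 526, 50))


@dataclass(frozen=True)
class StabilityGrid:
    """Sample sizes, iteration count and master seed for the bootstrap."""

    n_values: Tuple[int, ...] = DEFAULT_N_VALUES
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        ns = tuple(int(v) for v in self.n_values)
        if len(ns) == 0 or any(v < 2 for v in ns):
            raise ValueError("n_values must contain sample sizes >= 2")
        if list(ns) != sorted(set(ns)):
            raise ValueError("n_values must be strictly increasing")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        object.__setattr__(self, "n_values", ns)


@dataclass(frozen=True)
class StabilityCurve:
    """Per-draw medians and per-n summaries of the bootstrap."""

    draws: pd.DataFrame     # columns: n, iteration, median_icc, median_bs, median_ws
    summary: pd.DataFrame   # per n: mean / lower / upper for each statistic
    icc_type: str
    grid: StabilityGrid


def _rng_for(seed: int, n: int, iteration: int) -> np.random.Generator:
    # one substream per (n, iteration): extending the grid never changes
    # draws already taken at other grid points
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n, iteration))
    )


def subsample_stability(
    vs: VolumeSet,
    mask: BrainMask,
    icc_type: str = "icc_3",
    grid: StabilityGrid = StabilityGrid(),
) -> StabilityCurve:
    """Bootstrap stabilization curve of median ICC / BS / WS versus sample size.

    Subjects are drawn with replacement; a subject drawn twice contributes two
    identical rows. Deterministic given ``grid.seed``.
    """
    if icc_type not in ICC_TYPES:
        raise ValueError(f"unknown icc_type {icc_type!r}")
    if vs.grid_dims != mask.data.shape or not _grids_match(vs.affine, mask.affine):
        raise ValueError("mask grid does not match volume grid")
    n_avail = vs.n_subjects
    if max(grid.n_values) > n_avail:
        raise ReliabilityError(
            f"grid requests up to {max(grid.n_values)} subjects but only {n_avail} available"
        )

    flat = vs.data.reshape(n_avail, vs.k_occasions, -1)[:, :, mask.data.ravel()]
    rows = []
    for n in grid.n_values:
        for it in range(grid.n_iterations):
            rng = _rng_for(grid.seed, n, it)
            idx = rng.integers(0, n_avail, size=n)
            t = _twoway_tables(flat[idx])
            est, s2b, s2w, _, degen = _icc_point(t, icc_type)
            est = np.where(degen, np.nan, est)
            rows.append(
                {
                    "n": n,
                    "iteration": it,
                    "median_icc": float(np.nanmedian(est)),
                    "median_bs": float(np.nanmedian(np.where(degen, np.nan, s2b))),
                    "median_ws": float(np.nanmedian(np.where(degen, np.nan, s2w))),
                }
            )
    draws = pd.DataFrame(rows)

    summaries = []
    for n, g in draws.groupby("n"):
        row = {"n": n}
        for stat in ("median_icc", "median_bs", "median_ws"):
            vals = g[stat].to_numpy()
            row[f"{stat}_mean"] = float(np.mean(vals))
            # 95% empirical interval across iterations
            row[f"{stat}_lower"] = float(np.percentile(vals, 2.5))
            row[f"{stat}_upper"] = float(np.percentile(vals, 97.5))
        summaries.append(row)
    summary = pd.DataFrame(summaries).sort_values("n").reset_index(drop=True)
    return StabilityCurve(draws=draws, summary=summary, icc_type=icc_type, grid=grid)
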