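"""Analytic-decision grid enumeration and specification-curve construction.

A "multiverse" run repeats the same reliability analysis under every
combination of first-level modeling decisions. The decision grid mirrors the
four categories of a task-fMRI first-level pipeline:

* smoothing kernel (FWHM as a multiple of voxel size; 5 ordinal levels),
* motion correction (none / regressors / +aCompCor / +censoring; the full
  design adds two mean-FD exclusion variants for a 6-level grid),
* task model parameterization (cue, fixation, or anticipation window), and
* task contrast (large/small gain versus implicit baseline or neutral cue).

The restricted 5 x 4 x 3 x 4 grid yields 240 pipelines; the full 6-level
motion grid yields 360. Per-pipeline summary estimates (e.g., the masked
median ICC for each sample) are aggregated into a specification curve:
pipelines ordered by their across-sample mean with a 95% interval and a
significance class versus a null value, plus the decision-panel indicator
matrix that shows which options produced each estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maps import BrainMask, ReliabilityMaps, masked_median

__all__ = [
    "FWHM_LEVELS",
    "MOTION_LEVELS",
    "MOTION_LEVELS_FULL",
    "MODEL_LEVELS",
    "CONTRAST_LEVELS",
    "PipelineOptions",
    "EstimateRecord",
    "SpecificationCurve",
    "enumerate_pipelines",
    "build_specification_curve",
    "summarize_multiverse",
]

FWHM_LEVELS = ("1.5x", "2x", "2.5x", "3x", "3.5x")
#: motion options retained in the restricted grid (no usable high-mean-FD strata)
MOTION_LEVELS = ("none", "reg", "reg+acompcor", "reg+acompcor+censor")
#: original 6-option design including mean-FD exclusion variants
MOTION_LEVELS_FULL = MOTION_LEVELS + ("reg+acompcor+excl", "reg+acompcor+censor+excl")
MODEL_LEVELS = ("CueMod", "FixMod", "AntMod")
CONTRAST_LEVELS = ("LgainNeut", "LgainBase", "SgainNeut", "SgainBase")

STATISTICS = ("median_icc", "median_bs", "median_ws", "jaccard", "spearman")
OPTION_FIELDS = ("fwhm", "motion", "model", "contrast")


@dataclass(frozen=True, order=True)
class PipelineOptions:
    """One cell of the analytic-decision grid."""

    fwhm: str
    motion: str
    model: str
    contrast: str

    def __post_init__(self):
        vocab = {
            "fwhm": FWHM_LEVELS,
            "motion": MOTION_LEVELS_FULL,
            "model": MODEL_LEVELS,
            "contrast": CONTRAST_LEVELS,
        }
        for fld, allowed in vocab.items():
            if getattr(self, fld) not in allowed:
                raise ValueError(
                    f"unknown {fld} option {getattr(self, fld)!r}; expected one of {allowed}"
                )

    @property
    def label(self) -> str:
        return f"fwhm-{self.fwhm}_mot-{self.motion}_mod-{self.model}_con-{self.contrast}"


@dataclass(frozen=True)
class EstimateRecord:
    """One summary estimate for one (sample, pipeline, statistic) cell."""

    sample_id: str
    options: PipelineOptions
    statistic: str
    value: float
    mask: str = ""

    def __post_init__(self):
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )


@dataclass(frozen=True)
class SpecificationCurve:
    """Ordered pipeline estimates with interval and significance class.

    ``table`` rows are sorted ascending by the across-sample point estimate
    (ties broken by lexicographic option labels); ``panel`` is the matching
    one-hot decision matrix (same row order) for the classic two-panel plot.
    """

    table: pd.DataFrame
    panel: pd.DataFrame
    null_value: float
    statistic: str = ""


def enumerate_pipelines(full_motion_grid: bool = False):
    """All pipeline combinations in deterministic (grid) order.

    240 combinations by default; 360 with ``full_motion_grid=True`` (the
    original 6-option motion design).
    """
    motion = MOTION_LEVELS_FULL if full_motion_grid else MOTION_LEVELS
    return [
        PipelineOptions(f, m, mod, con)
        for f, m, mod, con in itertools.product(
            FWHM_LEVELS, motion, MODEL_LEVELS, CONTRAST_LEVELS
        )
    ]


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        needed = {"sample_id", "fwhm", "motion", "model", "contrast", "value"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"records frame is missing columns: {sorted(missing)}")
    else:
        records = list(records)
        if not records:
            raise ValueError("no records given")
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "fwhm": [r.options.fwhm for r in records],
                "motion": [r.options.motion for r in records],
                "model": [r.options.model for r in records],
                "contrast": [r.options.contrast for r in records],
                "statistic": [r.statistic for r in records],
                "value": [r.value for r in records],
            }
        )
    # validates the vocabulary of every row
    for _, row in df[list(OPTION_FIELDS)].drop_duplicates().iterrows():
        PipelineOptions(row.fwhm, row.motion, row.model, row.contrast)
    return df


def build_specification_curve(
    records, null_value: float = 0.0, statistic: Optional[str] = None
) -> SpecificationCurve:
    """Aggregate per-sample pipeline estimates into a specification curve.

    For each pipeline the across-sample mean and a 95% t-interval
    (``mean +/- t_{.975, s-1} * SE``; degenerate to the point estimate for a
    single sample) are computed, pipelines are sorted ascending by the mean,
    and each is classed against ``null_value``:

    * ``null_gray`` -- interval spans the null,
    * ``positive_blue`` -- entire interval above the null,
    * ``negative_red`` -- entire interval below the null.
    """
    df = _records_to_frame(records)
    if statistic is not None and "statistic" in df.columns:
        df = df[df["statistic"] == statistic]
        if df.empty:
            raise ValueError(f"no records for statistic {statistic!r}")
    rows = []
    for opts, g in df.groupby(list(OPTION_FIELDS), sort=False):
        vals = g["value"].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        s = len(vals)
        if s > 1:
            half = float(sps.t.ppf(0.975, s - 1) * np.std(vals, ddof=1) / np.sqrt(s))
        else:
            half = 0.0
        lower, upper = mean - half, mean + half
        if lower > null_value:
            sig = "positive_blue"
        elif upper < null_value:
            sig = "negative_red"
        else:
            sig = "null_gray"
        rows.append(
            dict(
                zip(OPTION_FIELDS, opts),
                estimate=mean,
                lower=lower,
                upper=upper,
                n_samples=s,
                significance_class=sig,
            )
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["estimate", *OPTION_FIELDS], kind="mergesort")
        .reset_index(drop=True)
    )
    table.index.name = "rank"
    panel = pd.get_dummies(table[list(OPTION_FIELDS)], prefix_sep="=").astype(int)
    stat = statistic or (
        df["statistic"].iloc[0] if "statistic" in df.columns and df["statistic"].nunique() == 1 else ""
    )
    return SpecificationCurve(table=table, panel=panel, null_value=null_value, statistic=stat)


def summarize_multiverse(
    results: Mapping[PipelineOptions, Union[ReliabilityMaps, Mapping[str, float]]],
    supra_mask: BrainMask,
    sub_mask: BrainMask,
    sample_id: str = "sample-1",
) -> pd.DataFrame:
    """Masked-median summary records per pipeline, stratified by mask.

    ``results`` maps pipeline options either to :class:`ReliabilityMaps`
    (summarized to median ICC / BS / WS within each mask) or to an already
    computed ``{statistic: value}`` mapping (e.g., ``{"jaccard": .7}``, copied
    to both mask strata). The supra- and subthreshold masks must be disjoint.
    """
    if (supra_mask.data & sub_mask.data).any():
        raise ValueError("supra- and subthreshold masks overlap")
    rows = []
    for opts, res in results.items():
        if not isinstance(opts, PipelineOptions):
            raise ValueError("results keys must be PipelineOptions")
        for mask_name, mask in (("supra", supra_mask), ("sub", sub_mask)):
            if isinstance(res, ReliabilityMaps):
                stats_map = {
                    "median_icc": masked_median(res.estimate, mask),
                    "median_bs": masked_median(res.between_subject_var, mask),
                    "median_ws": masked_median(res.within_subject_var, mask),
                }
            else:
                stats_map = dict(res)
            for stat, value in stats_map.items():
                if stat not in STATISTICS:
                    raise ValueError(f"unknown statistic {stat!r}")
                rows.append(
                    {
                        "sample_id": sample_id,
                        "fwhm": opts.fwhm,
                        "motion": opts.motion,
                        "model": opts.model,
                        "contrast": opts.contrast,
                        "mask": mask_name,
                        "statistic": stat,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)
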