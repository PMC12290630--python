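"""Manifest-driven NIfTI loading and TSV/provenance output.

Manifests are explicit ordered TSV files (columns ``subject``, ``occasion``,
``path``) rather than glob patterns, so the subject pairing across occasions
is auditable. All tables are UTF-8 TSV with a header row; missing values are
written as ``NA``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .maps import BrainMask, VolumeSet
from .simulate import TruthBundle
from .stats import InvalidDesignError

__all__ = [
    "load_volume_set",
    "write_manifest",
    "write_table",
    "write_volume_set",
    "write_provenance",
]

NA_REP = "NA"


def load_volume_set(manifest: "str | Path | pd.DataFrame") -> VolumeSet:
    """Load a grid-checked :class:`VolumeSet` from an ordered manifest.

    Subject order is taken from first appearance in the manifest and must be
    identical for every occasion (a complete crossing). Grid mismatches raise
    an error naming the offending file.
    """
    if isinstance(manifest, (str, Path)):
        df = pd.read_csv(manifest, sep="\t", dtype=str)
    else:
        df = manifest.copy()
    needed = {"subject", "occasion", "path"}
    if not needed.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(needed)}, got {list(df.columns)}")
    if df.empty:
        raise InvalidDesignError("manifest is empty")
    occasions = list(dict.fromkeys(df["occasion"]))
    subjects = list(dict.fromkeys(df["subject"]))
    if len(occasions) < 2:
        raise InvalidDesignError("manifest lists fewer than 2 occasions")
    per_occ = []
    for occ in occasions:
        g = df[df["occasion"] == occ]
        if list(g["subject"]) != subjects:
            raise InvalidDesignError(
                f"occasion {occ!r} does not list the same subjects in the same order "
                f"as occasion {occasions[0]!r}"
            )
        per_occ.append(list(g["path"]))
    return VolumeSet.from_images(
        per_occ, subject_ids=tuple(subjects), occasion_ids=tuple(occasions)
    )


def write_manifest(rows: pd.DataFrame, path) -> Path:
    path = Path(path)
    rows.to_csv(path, sep="\t", index=False, na_rep=NA_REP)
    return path


def write_table(df: pd.DataFrame, path) -> Path:
    """UTF-8 TSV with header; NaN encoded as NA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)
    return path


def write_volume_set(bundle: TruthBundle, outdir) -> pd.DataFrame:
    """Write a simulated dataset as per-subject NIfTI volumes + manifest + truth.

    Layout: ``sub-XX_ses-Y_stat.nii.gz`` plus ``mask.nii.gz``,
    ``supra_mask.nii.gz``, ``sub_mask.nii.gz``, ``manifest.tsv`` and
    ``truth.tsv`` (voxel-wise true ICC(3,1), BS and WS for in-brain voxels).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = bundle.volume_set
    rows = []
    for j, occ in enumerate(vs.occasion_ids):
        for i, sub in enumerate(vs.subject_ids):
            fname = f"{sub}_{occ}_stat.nii.gz"
            nib.save(
                nib.Nifti1Image(vs.data[i, j].astype(np.float64), vs.affine),
                outdir / fname,
            )
            rows.append({"subject": sub, "occasion": occ, "path": str(outdir / fname)})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.tsv")
    nib.save(bundle.brain_mask.to_image(), outdir / "mask.nii.gz")
    nib.save(bundle.supra_mask.to_image(), outdir / "supra_mask.nii.gz")
    nib.save(bundle.sub_mask.to_image(), outdir / "sub_mask.nii.gz")
    sel = bundle.brain_mask.data
    ijk = np.argwhere(sel)
    truth = pd.DataFrame(
        {
            "i": ijk[:, 0],
            "j": ijk[:, 1],
            "k": ijk[:, 2],
            "true_icc3": bundle.true_icc3[sel],
            "true_bs": bundle.true_bs[sel],
            "true_ws": bundle.true_ws[sel],
        }
    )
    write_table(truth, outdir / "truth.tsv")
    return manifest


def write_provenance(outdir, command: str, params: dict, seed: Optional[int] = None) -> Path:
    """Machine-readable record sufficient to reproduce a run."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "relimap",
        "version": __version__,
        "command": command,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "nibabel": nib.__version__,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    path = outdir / f"{command}_provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
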