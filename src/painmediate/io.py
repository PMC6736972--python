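"""File formats: tidy trial TSVs, NIfTI volumes, JSON sidecars.

Trial tables are written one TSV per subject with a documented column
dictionary; brain data as 4-D NIfTI with trials along the fourth axis,
alongside a 3-D mask and (for synthetic data) a ground-truth label
image; generative parameters and seeds go into a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials_tsv",
    "read_trials_tsv",
    "write_volume",
    "read_volume",
    "write_beta_series",
    "read_beta_series",
    "write_json",
    "sha256_of",
]

#: column dictionary for trial tables
TRIAL_COLUMNS = {
    "subject": "subject id (1-based)",
    "run": "run number (1-based)",
    "trial": "trial index within subject (1-based)",
    "social": "social cue code (-1 low, +1 high)",
    "cs": "conditioned-stimulus code (-1 low, +1 high)",
    "temperature": "stimulus temperature (degC)",
    "expectation": "expectation rating (0-100)",
    "pain": "pain rating (0-100)",
    "scr": "single-trial skin-conductance amplitude (a.u.)",
}


def write_trials_tsv(trials: pd.DataFrame, out_dir: str | Path,
                     stem: str = "trials") -> list[Path]:
    """One TSV per subject plus a column-dictionary JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for subj, grp in trials.groupby("subject"):
        p = out_dir / f"sub-{int(subj):02d}_{stem}.tsv"
        grp.to_csv(p, sep="\t", index=False)
        paths.append(p)
    write_json(out_dir / f"{stem}_columns.json",
               {c: TRIAL_COLUMNS.get(c, "") for c in trials.columns})
    return paths


def read_trials_tsv(paths) -> pd.DataFrame:
    frames = [pd.read_csv(p, sep="\t") for p in sorted(map(str, paths))]
    return pd.concat(frames, ignore_index=True)


def write_volume(path: str | Path, data: np.ndarray,
                 affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_beta_series(path: str | Path, data: np.ndarray,
                      mask: np.ndarray, affine: np.ndarray) -> Path:
    """(n_trials, n_voxels) in-mask matrix -> 4-D NIfTI (x, y, z, trial)."""
    vol = np.zeros(mask.shape + (data.shape[0],), dtype=np.float32)
    vol[mask, :] = np.asarray(data, np.float32).T
    return write_volume(path, vol, affine)


def read_beta_series(path: str | Path,
                     mask: np.ndarray) -> np.ndarray:
    vol, _ = read_volume(path)
    return np.asarray(vol[mask, :], float).T


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: getattr(o, f.name)
                    for f in dataclasses.fields(o)
                    if not callable(getattr(o, f.name))}
        if callable(o):
            return getattr(o, "__name__", str(o))
        return super().default(o)


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_Encoder) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
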