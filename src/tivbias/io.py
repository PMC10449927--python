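"""Reading and writing subject tables, feature matrices and pair lists.

Subject tables are tab-separated text with the fixed header
``id site sex gender_group age tiv total_gmv``.  Feature matrices are stored
either as an HDF5 container (datasets ``features`` and ``ids``) or as a wide
TSV whose first column is the subject id; the format is chosen by file
extension (``.h5``/``.hdf5`` vs anything else).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import SUBJECT_COLUMNS, FeatureMatrix

__all__ = [
    "read_subjects",
    "write_subjects",
    "read_features",
    "write_features",
    "write_pairs",
    "read_pairs",
]

_HDF5_EXT = {".h5", ".hdf5"}


def write_subjects(subjects: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    subjects[SUBJECT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "site": str, "sex": str, "gender_group": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: subject table missing columns: {missing}")
    bad = set(df["sex"].unique()) - {"F", "M"}
    if bad:
        raise ValueError(f"{path}: sex must be coded F/M, found {sorted(bad)}")
    return df


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in _HDF5_EXT:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=features.values)
            f.create_dataset("ids", data=np.array(features.ids, dtype="S"))
    else:
        df = pd.DataFrame(features.values, columns=[f"f{i}" for i in range(features.n_features)])
        df.insert(0, "id", features.ids)
        df.to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if path.suffix.lower() in _HDF5_EXT:
        with h5py.File(path, "r") as f:
            values = np.asarray(f["features"])
            ids = [s.decode() for s in f["ids"][()]]
    else:
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        ids = df["id"].tolist()
        values = df.drop(columns="id").to_numpy(dtype=float)
    return FeatureMatrix(ids=ids, values=values)


PAIR_COLUMNS = ["woman_id", "man_id", "site", "age_diff", "tiv_diff_frac", "role"]


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"woman_id": str, "man_id": str, "site": str, "role": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pair table missing columns: {missing}")
    return df
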