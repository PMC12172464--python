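"""Readers and writers for count tables, cubes, and fitted models.

Supported inputs: long-format TSV/CSV (sample, subject, time, taxon, count),
a wide count matrix (samples x taxa) with a sample map, and BIOM 2.1 (via
the optional ``biom-format`` dependency).  Models are exported as one
delimited loading table per mode plus a key-value summary; the writer/reader
pair round-trips losslessly at the chosen decimal precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import DataCube, SampleTable
from .parafac import ParafacModel

__all__ = [
    "read_long_table",
    "read_wide_table",
    "read_biom_table",
    "export_model",
    "read_model",
    "export_cube",
]

_LONG_COLUMNS = {"subject": "subject", "time": "time", "taxon": "feature",
                 "count": "count"}


def read_long_table(
    counts_path, metadata_path=None, sep: str | None = None, column_map=None
) -> SampleTable:
    """Read a long-format count file (and optional subject metadata file).

    The counts file needs header columns subject/time/taxon/count (a
    ``column_map`` may rename them); the metadata file needs a ``subject``
    column used as index.  The delimiter is inferred from the extension
    unless given.
    """
    counts_path = Path(counts_path)
    if sep is None:
        sep = "," if counts_path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(counts_path, sep=sep)
    rename = dict(_LONG_COLUMNS)
    if column_map:
        rename.update({v: k for k, v in column_map.items()})
    df = df.rename(columns={c: rename.get(c, c) for c in df.columns})
    metadata = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        msep = "," if metadata_path.suffix.lower() == ".csv" else "\t"
        metadata = pd.read_csv(metadata_path, sep=msep)
        if "subject" not in metadata.columns:
            raise ValueError("metadata file needs a 'subject' column")
        metadata = metadata.set_index("subject")
    return SampleTable(counts=df[["subject", "time", "feature", "count"]],
                       metadata=metadata)


def read_wide_table(matrix_path, sample_map_path, metadata_path=None) -> SampleTable:
    """Read a wide samples x taxa count matrix plus a sample -> (subject, time) map."""
    matrix_path = Path(matrix_path)
    sep = "," if matrix_path.suffix.lower() == ".csv" else "\t"
    wide = pd.read_csv(matrix_path, sep=sep, index_col=0)
    map_path = Path(sample_map_path)
    msep = "," if map_path.suffix.lower() == ".csv" else "\t"
    smap = pd.read_csv(map_path, sep=msep, index_col=0)
    for col in ("subject", "time"):
        if col not in smap.columns:
            raise ValueError(f"sample map needs a {col!r} column")
    missing = set(wide.index) - set(smap.index)
    if missing:
        raise ValueError(f"samples without map entry: {sorted(map(str, missing))[:5]}")
    long = wide.stack().rename("count").reset_index()
    long.columns = ["sample", "feature", "count"]
    long["subject"] = long["sample"].map(smap["subject"])
    long["time"] = long["sample"].map(smap["time"])
    metadata = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        msep = "," if metadata_path.suffix.lower() == ".csv" else "\t"
        metadata = pd.read_csv(metadata_path, sep=msep).set_index("subject")
    return SampleTable(counts=long[["subject", "time", "feature", "count"]],
                       metadata=metadata)


def read_biom_table(biom_path, sample_map: pd.DataFrame,
                    metadata: pd.DataFrame | None = None) -> SampleTable:
    """Read a BIOM 2.1 observation matrix; ``sample_map`` maps sample id to
    subject and time."""
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "BIOM input requires the 'biom-format' package "
            "(pip install microtensor[biom])"
        ) from exc
    table = biom.load_table(str(biom_path))
    wide = table.to_dataframe(dense=True).T  # samples x observations
    long = wide.stack().rename("count").reset_index()
    long.columns = ["sample", "feature", "count"]
    long = long[long["count"] > 0].copy()
    long["count"] = long["count"].astype(int)
    long["subject"] = long["sample"].map(sample_map["subject"])
    long["time"] = long["sample"].map(sample_map["time"])
    if long[["subject", "time"]].isna().any().any():
        raise ValueError("sample map does not cover all BIOM samples")
    return SampleTable(counts=long[["subject", "time", "feature", "count"]],
                       metadata=metadata)


_MODE_FILES = {"subject": "subject_loadings.tsv", "feature": "feature_loadings.tsv",
               "time": "time_loadings.tsv"}


def export_model(model: ParafacModel, cube: DataCube, destination) -> dict:
    """Write one loading table per mode plus a JSON summary.

    Returns the mapping of written paths.  Loadings are written at full
    (repr) precision so :func:`read_model` round-trips exactly.
    """
    if model.shape != cube.shape:
        raise ValueError(f"model shape {model.shape} != cube shape {cube.shape}")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    comp_cols = [f"component_{f + 1}" for f in range(model.n_components)]
    paths = {}
    for mode, matrix, ids in (
        ("subject", model.A, cube.subject_ids),
        ("feature", model.B, cube.feature_ids),
        ("time", model.C, cube.time_points),
    ):
        df = pd.DataFrame(matrix, columns=comp_cols)
        df.insert(0, "id", list(ids))
        path = destination / _MODE_FILES[mode]
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths[mode] = path
    summary = {
        "n_components": model.n_components,
        "weights": [float(w) for w in model.weights],
        "sse": float(model.sse),
        "variance_explained": float(model.variance_explained),
        "n_iterations": int(model.n_iterations),
        "converged": bool(model.converged),
        "init_method": model.init_method,
        "seed": int(model.seed),
    }
    spath = destination / "model_summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    paths["summary"] = spath
    return paths


def read_model(source) -> tuple[ParafacModel, dict]:
    """Read a model written by :func:`export_model`; returns (model, ids)."""
    source = Path(source)
    summary = json.loads((source / "model_summary.json").read_text())
    mats, ids = {}, {}
    for mode, fname in _MODE_FILES.items():
        df = pd.read_csv(source / fname, sep="\t", float_precision="round_trip")
        ids[mode] = df["id"].tolist()
        mats[mode] = df.drop(columns="id").to_numpy(dtype=float)
    model = ParafacModel(
        A=mats["subject"], B=mats["feature"], C=mats["time"],
        weights=np.asarray(summary["weights"], dtype=float),
        n_components=int(summary["n_components"]),
        sse=summary["sse"], variance_explained=summary["variance_explained"],
        n_iterations=summary["n_iterations"], converged=summary["converged"],
        init_method=summary["init_method"], seed=summary["seed"],
    )
    return model, ids


def export_cube(cube: DataCube, path) -> Path:
    """Write the cube as an unfolded measurement x feature table with subject
    and time index columns (missing fibers written as empty fields)."""
    path = Path(path)
    rows = []
    for i, sid in enumerate(cube.subject_ids):
        for k, t in enumerate(cube.time_points):
            row = {"subject": sid, "time": t}
            observed = cube.observed_mask[i, :, k]
            for j, fid in enumerate(cube.feature_ids):
                row[str(fid)] = cube.values[i, j, k] if observed[j] else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
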