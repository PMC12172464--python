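"""Three-way data cubes for longitudinal microbiome studies.

A longitudinal microbiome study measures the same subjects at the same set of
time points, yielding one count vector (over microbial features) per
(subject, time) measurement.  Stacking these measurements along a third axis
produces a subject x feature x time array — the :class:`DataCube` — which is
the input to trilinear (PARAFAC) modelling.  Measurements that were never
taken (a subject missing a visit) are kept as fully missing fibers so the
model can impute them; a feature simply not seen in a taken measurement is a
zero count, not missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DataCube", "SampleTable", "build_cube", "calculate_sparsity"]


@dataclass
class SampleTable:
    """Long-format count table plus per-subject metadata.

    ``counts`` has one row per (subject, time, feature) observation with
    columns ``subject``, ``time``, ``feature``, ``count``; ``metadata`` is
    indexed by subject id.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"subject", "time", "feature", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table lacks columns: {sorted(missing)}")
        c = self.counts["count"].to_numpy()
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(c != np.floor(c)):
            raise ValueError("counts must be integers")
        dup = self.counts.duplicated(subset=["subject", "time", "feature"])
        if dup.any():
            row = self.counts.loc[dup.idxmax()]
            raise ValueError(
                "duplicate (subject, time, feature) triple: "
                f"({row['subject']}, {row['time']}, {row['feature']})"
            )


@dataclass
class DataCube:
    """Subject x feature x time array with axis labels and missingness mask.

    ``values`` is float with NaN on missing entries; ``observed_mask`` is the
    boolean complement of missingness.  ``transform_log`` records every
    preprocessing step applied, in order.  When a transform changes the value
    scale (e.g. CLR), the raw counts may be retained in ``raw_counts`` so
    count-based operations (sparsity, relative abundance) remain possible.
    """

    values: np.ndarray
    subject_ids: list
    feature_ids: list
    time_points: list
    observed_mask: np.ndarray = None  # type: ignore[assignment]
    subject_metadata: pd.DataFrame | None = None
    feature_taxonomy: Mapping[Any, str] | None = None
    transform_log: list = field(default_factory=list)
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        I, J, K = len(self.subject_ids), len(self.feature_ids), len(self.time_points)
        if self.values.shape != (I, J, K):
            raise ValueError(
                f"values shape {self.values.shape} != labels ({I}, {J}, {K})"
            )
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape mismatch")
        if len(set(self.subject_ids)) != I:
            raise ValueError("duplicate subject ids")
        if len(set(self.feature_ids)) != J:
            raise ValueError("duplicate feature ids")
        if len(set(self.time_points)) != K:
            raise ValueError("duplicate time points")

    # -- basic properties ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def missing_fraction(self) -> float:
        """Fraction of cube entries that are missing."""
        return 1.0 - self.observed_mask.mean()

    def has_transform(self, name: str) -> bool:
        return any(step.get("name") == name for step in self.transform_log)

    def log_transform(self, name: str, **params: Any) -> None:
        self.transform_log.append({"name": name, **params})

    def copy(self) -> "DataCube":
        return DataCube(
            values=self.values.copy(),
            subject_ids=list(self.subject_ids),
            feature_ids=list(self.feature_ids),
            time_points=list(self.time_points),
            observed_mask=self.observed_mask.copy(),
            subject_metadata=(
                None if self.subject_metadata is None else self.subject_metadata.copy()
            ),
            feature_taxonomy=(
                None if self.feature_taxonomy is None else dict(self.feature_taxonomy)
            ),
            transform_log=[dict(s) for s in self.transform_log],
            raw_counts=None if self.raw_counts is None else self.raw_counts.copy(),
        )

    def subset_subjects(self, keep: Sequence[int]) -> "DataCube":
        """Return a cube retaining the subject rows at integer positions ``keep``."""
        keep = list(keep)
        out = self.copy()
        out.values = out.values[keep]
        out.observed_mask = out.observed_mask[keep]
        out.subject_ids = [self.subject_ids[i] for i in keep]
        if out.raw_counts is not None:
            out.raw_counts = out.raw_counts[keep]
        if out.subject_metadata is not None:
            out.subject_metadata = out.subject_metadata.loc[out.subject_ids]
        return out

    def subset_features(self, keep: Sequence[int]) -> "DataCube":
        """Return a cube retaining the feature columns at integer positions ``keep``."""
        keep = list(keep)
        out = self.copy()
        out.values = out.values[:, keep]
        out.observed_mask = out.observed_mask[:, keep]
        out.feature_ids = [self.feature_ids[j] for j in keep]
        if out.raw_counts is not None:
            out.raw_counts = out.raw_counts[:, keep]
        if out.feature_taxonomy is not None:
            out.feature_taxonomy = {
                f: out.feature_taxonomy[f]
                for f in out.feature_ids
                if f in out.feature_taxonomy
            }
        return out

    def group_labels(self, column: str) -> np.ndarray:
        """Per-subject labels for a metadata column, in cube subject order."""
        if self.subject_metadata is None:
            raise ValueError("cube carries no subject metadata")
        if column not in self.subject_metadata.columns:
            raise ValueError(f"metadata has no column {column!r}")
        labels = self.subject_metadata.loc[self.subject_ids, column]
        if labels.isna().any():
            bad = [s for s, v in zip(self.subject_ids, labels) if pd.isna(v)]
            raise ValueError(f"group labels missing for subjects: {bad[:5]}")
        return labels.to_numpy()


def build_cube(table: SampleTable, time_order: Sequence) -> DataCube:
    """Pivot a long-format :class:`SampleTable` into a :class:`DataCube`.

    A (subject, time) pair absent from the table becomes a fully missing
    fiber; a feature absent from a present measurement gets count 0.

    Parameters
    ----------
    table:
        Long-format counts with optional subject metadata.
    time_order:
        The time labels in their study order; must cover every label in the
        table.
    """
    df = table.counts
    time_order = list(time_order)
    present_times = set(df["time"].unique())
    unknown = present_times - set(time_order)
    if unknown:
        raise ValueError(f"time labels not in time_order: {sorted(map(str, unknown))}")

    subjects = list(pd.unique(df["subject"]))
    features = list(pd.unique(df["feature"]))
    I, J, K = len(subjects), len(features), len(time_order)

    si = {s: i for i, s in enumerate(subjects)}
    fj = {f: j for j, f in enumerate(features)}
    tk = {t: k for k, t in enumerate(time_order)}

    values = np.full((I, J, K), np.nan)
    ii = df["subject"].map(si).to_numpy()
    jj = df["feature"].map(fj).to_numpy()
    kk = df["time"].map(tk).to_numpy()

    # measurements that exist: zero-fill the whole fiber, then overwrite
    present = set(zip(ii.tolist(), kk.tolist()))
    for i, k in present:
        values[i, :, k] = 0.0
    values[ii, jj, kk] = df["count"].to_numpy(dtype=float)

    metadata = None
    if table.metadata is not None:
        metadata = table.metadata.loc[[s for s in subjects if s in table.metadata.index]]

    cube = DataCube(
        values=values,
        subject_ids=subjects,
        feature_ids=features,
        time_points=time_order,
        subject_metadata=metadata,
    )
    cube.raw_counts = cube.values.copy()
    cube.log_transform("build_cube", n_measurements=len(present))
    return cube


def calculate_sparsity(
    cube: DataCube, groups: np.ndarray | str | None = None
) -> pd.DataFrame:
    """Per-feature sparsity: the fraction of observed measurements with zero count.

    Missing fibers contribute neither to the numerator nor the denominator.
    With ``groups`` (an array of per-subject labels, or the name of a
    metadata column), one sparsity column is returned per group; otherwise a
    single ``overall`` column.

    Raises if the cube has been CLR-transformed, since sparsity is defined on
    counts only.
    """
    if cube.has_transform("clr") and cube.raw_counts is None:
        raise ValueError("sparsity requires raw counts; cube is CLR-transformed")
    counts = cube.raw_counts if cube.raw_counts is not None else cube.values
    mask = cube.observed_mask

    if isinstance(groups, str):
        groups = cube.group_labels(groups)

    def _sparsity(rows: np.ndarray) -> np.ndarray:
        m = mask[rows]  # (n, J, K)
        c = counts[rows]
        observed = m.sum(axis=(0, 2)).astype(float)  # per feature
        zeros = (m & (c == 0)).sum(axis=(0, 2))
        with np.errstate(invalid="ignore"):
            return np.where(observed > 0, zeros / observed, np.nan)

    I = len(cube.subject_ids)
    if groups is None:
        return pd.DataFrame(
            {"overall": _sparsity(np.arange(I))}, index=list(cube.feature_ids)
        )
    groups = np.asarray(groups)
    if len(groups) != I:
        raise ValueError("group labels must cover all subjects")
    out = {}
    for g in pd.unique(groups):
        out[str(g)] = _sparsity(np.where(groups == g)[0])
    return pd.DataFrame(out, index=list(cube.feature_ids))
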