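"""Compositional preprocessing of count cubes.

The modelling pipeline assumes residuals symmetric around zero, which raw
sequencing counts do not satisfy: they are compositional (only relative
information), zero-inflated, and heteroscedastic.  The standard remedy is a
four-step chain applied in a fixed order:

1. centered log-ratio (CLR) transform after adding a pseudo-count, per
   measurement (subject, time) over all features;
2. sparsity-based feature filtering, computed on the *counts* but applied to
   the CLR values;
3. centering across one mode (usually subjects, removing the average time
   trajectory per feature/time cell);
4. scaling within one mode (usually features, giving every feature slab unit
   root-mean-square over its observed entries).

All statistics use observed entries only; missing fibers stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import DataCube, calculate_sparsity

__all__ = [
    "ProcessConfig",
    "clr_transform",
    "filter_features",
    "center_cube",
    "scale_cube",
    "process_data_cube",
]

_PSEUDOCOUNT_STRATEGIES = ("constant", "uniform_random")


@dataclass
class ProcessConfig:
    """Settings for :func:`process_data_cube`.

    pseudocount_strategy:
        ``"constant"`` adds ``pseudocount`` to every count; ``"uniform_random"``
        replaces each zero with a Uniform(0, 1) draw (seeded) and leaves
        positive counts untouched.
    sparsity_threshold:
        Features with sparsity above this fraction are dropped.
    sparsity_scope:
        ``"overall"`` uses the whole-cube sparsity; ``"per_group_any"`` keeps a
        feature if its sparsity is below threshold in at least one group of
        ``group_column``.
    center_mode / scale_mode:
        Which mode to center across / scale within (or ``"none"``).
    """

    pseudocount: float = 1.0
    pseudocount_strategy: str = "constant"
    sparsity_threshold: float = 1.0
    sparsity_scope: str = "overall"
    group_column: str | None = None
    center_mode: str = "subject"
    scale_mode: str = "feature"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount_strategy not in _PSEUDOCOUNT_STRATEGIES:
            raise ValueError(f"unknown pseudocount strategy {self.pseudocount_strategy!r}")
        if self.pseudocount_strategy == "constant" and not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")
        if not 0.0 <= self.sparsity_threshold <= 1.0:
            raise ValueError("sparsity_threshold must lie in [0, 1]")
        if self.sparsity_scope not in ("overall", "per_group_any"):
            raise ValueError(f"unknown sparsity scope {self.sparsity_scope!r}")
        if self.center_mode not in ("subject", "feature", "time", "none"):
            raise ValueError(f"unknown center mode {self.center_mode!r}")
        if self.scale_mode not in ("subject", "feature", "none"):
            raise ValueError(f"unknown scale mode {self.scale_mode!r}")


def clr_transform(cube: DataCube, cfg: ProcessConfig | None = None) -> DataCube:
    """Centered log-ratio transform each observed measurement.

    For measurement (i, k), with pseudo-counted counts z_j = x_j + p:
    y_j = ln(z_j / g(z)) with g the geometric mean over all J features.  The
    transformed values of one measurement sum to zero.  Raw counts are
    retained on the cube so sparsity stays computable downstream.
    """
    cfg = cfg or ProcessConfig()
    if cube.has_transform("clr"):
        raise ValueError("cube is already CLR-transformed")
    out = cube.copy()
    counts = cube.values
    if cfg.pseudocount_strategy == "constant":
        z = counts + cfg.pseudocount
    else:
        rng = np.random.default_rng(cfg.seed)
        z = counts.copy()
        zeros = (counts == 0) & cube.observed_mask
        z[zeros] = rng.uniform(0.0, 1.0, size=int(zeros.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        logz = np.log(z)
    # geometric mean over features, per (subject, time) measurement
    gm = np.nanmean(np.where(cube.observed_mask, logz, np.nan), axis=1, keepdims=True)
    vals = np.where(cube.observed_mask, logz - gm, np.nan)
    out.values = vals
    if out.raw_counts is None:
        out.raw_counts = counts.copy()
    out.log_transform(
        "clr", pseudocount=cfg.pseudocount, strategy=cfg.pseudocount_strategy
    )
    return out


def filter_features(
    cube: DataCube, sparsity=None, cfg: ProcessConfig | None = None
) -> DataCube:
    """Drop features whose sparsity exceeds the configured threshold.

    ``sparsity`` is a DataFrame from :func:`calculate_sparsity` (one column
    overall, or one per group); if omitted it is computed from the cube's raw
    counts with the scope requested in ``cfg``.  Under ``per_group_any`` a
    feature survives if its sparsity in *any* group is within threshold.
    """
    cfg = cfg or ProcessConfig()
    if sparsity is None:
        groups = cfg.group_column if cfg.sparsity_scope == "per_group_any" else None
        sparsity = calculate_sparsity(cube, groups=groups)
    sp = sparsity.loc[list(cube.feature_ids)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep = np.nanmin(sp, axis=1) <= cfg.sparsity_threshold
    if not keep.any():
        raise ValueError(
            f"no feature passes sparsity threshold {cfg.sparsity_threshold}"
        )
    kept_idx = np.where(keep)[0]
    out = cube.subset_features(kept_idx)
    out.log_transform(
        "filter_features",
        threshold=cfg.sparsity_threshold,
        scope=cfg.sparsity_scope,
        kept=[cube.feature_ids[j] for j in kept_idx],
        discarded=[cube.feature_ids[j] for j in np.where(~keep)[0]],
    )
    return out


_MODE_AXIS = {"subject": 0, "feature": 1, "time": 2}


def center_cube(cube: DataCube, mode: str = "subject") -> DataCube:
    """Center across a mode: subtract, per cell of the other two modes, the
    mean over the centered mode's observed entries."""
    if mode not in _MODE_AXIS:
        raise ValueError(f"unknown center mode {mode!r}")
    axis = _MODE_AXIS[mode]
    out = cube.copy()
    vals = np.where(cube.observed_mask, cube.values, np.nan)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=axis, keepdims=True)
    out.values = np.where(cube.observed_mask, vals - means, np.nan)
    n_empty = int(np.isnan(means).sum())
    if n_empty:
        import warnings

        warnings.warn(
            f"{n_empty} slabs have no observed entries; left missing", stacklevel=2
        )
    out.log_transform("center", mode=mode)
    return out


def scale_cube(cube: DataCube, mode: str = "feature") -> DataCube:
    """Scale within a mode: divide each slab by its observed root-mean-square.

    Feature mode: slab j is divided by sqrt(mean over observed (i,k) of x²),
    so every feature ends with unit RMS.  Subject mode: analogous per subject
    slab over (j, k).
    """
    if mode not in ("subject", "feature"):
        raise ValueError(f"unknown scale mode {mode!r}")
    out = cube.copy()
    vals = np.where(cube.observed_mask, cube.values, np.nan)
    axes = (1, 2) if mode == "subject" else (0, 2)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.nanmean(vals**2, axis=axes))
    bad = ~(rms > 0)
    if bad.any():
        labels = cube.subject_ids if mode == "subject" else cube.feature_ids
        names = [labels[i] for i in np.where(bad)[0]]
        raise ValueError(f"zero-RMS {mode} slab(s), cannot scale: {names[:5]}")
    shape = [1, 1, 1]
    shape[_MODE_AXIS[mode]] = len(rms)
    out.values = np.where(cube.observed_mask, vals / rms.reshape(shape), np.nan)
    out.log_transform("scale", mode=mode)
    return out


def process_data_cube(cube: DataCube, cfg: ProcessConfig | None = None) -> DataCube:
    """Run the full preprocessing chain: CLR, filter, center, scale.

    The CLR geometric mean is computed over the *full* feature set; filtering
    then drops rows of the transformed cube, using sparsity computed from the
    raw counts (per group when configured).
    """
    cfg = cfg or ProcessConfig()
    groups = cfg.group_column if cfg.sparsity_scope == "per_group_any" else None
    sparsity = calculate_sparsity(cube, groups=groups)
    out = clr_transform(cube, cfg)
    out = filter_features(out, sparsity, cfg)
    if cfg.center_mode != "none":
        out = center_cube(out, cfg.center_mode)
    if cfg.scale_mode != "none":
        out = scale_cube(out, cfg.scale_mode)
    return out
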