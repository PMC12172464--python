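"""Jackknife stability assessment of a PARAFAC model order.

A model with the right number of components should describe the same
phenomena when individual subjects are left out.  Each jackknife iteration
removes one randomly chosen subject per group (one random subject overall
when no grouping is given), refits the model with deterministic SVD
initialisation — so all cross-iteration variation is attributable to the
removed subjects — aligns the refit to a full-data SVD-init reference, and
accumulates the aligned loadings.  The report carries the per-element mean
and standard deviation of every loading across iterations; small SDs
everywhere indicate a stable model order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import DataCube
from .diagnostics import align_model
from .parafac import FitConfig, ParafacModel, fit_parafac

__all__ = ["StabilityReport", "assess_model_stability"]


@dataclass
class StabilityReport:
    """Aligned jackknife loadings and their dispersion.

    ``feature_sd`` / ``time_sd`` are J x F / K x F DataFrames over all
    iterations; ``subject_sd`` (I x F) uses only iterations retaining the
    subject.  ``models`` holds the aligned per-iteration models and
    ``removed`` the removed-subject list per iteration.
    """

    reference: ParafacModel
    models: list
    removed: list
    subject_mean: pd.DataFrame
    subject_sd: pd.DataFrame
    feature_mean: pd.DataFrame
    feature_sd: pd.DataFrame
    time_mean: pd.DataFrame
    time_sd: pd.DataFrame
    settings: dict

    def median_loading_sd(self) -> float:
        """Median SD over all feature- and time-mode loading elements."""
        pool = np.concatenate(
            [self.feature_sd.to_numpy().ravel(), self.time_sd.to_numpy().ravel()]
        )
        return float(np.median(pool))


def _choose_removals(
    rng: np.random.Generator, groups: np.ndarray | None, I: int
) -> list[int]:
    """Indices of subjects to remove this iteration: one per group."""
    if groups is None:
        return [int(rng.integers(I))]
    removals = []
    for g in pd.unique(groups):
        members = np.where(groups == g)[0]
        if len(members) < 2:
            raise ValueError(
                f"group {g!r} has {len(members)} subject(s); removing one "
                "would empty it"
            )
        removals.append(int(rng.choice(members)))
    return removals


def assess_model_stability(
    cube: DataCube,
    F: int,
    group_variable: str | None = None,
    n_iterations: int | None = None,
    cfg: FitConfig | None = None,
) -> StabilityReport:
    """Jackknife a PARAFAC model of order ``F``.

    Parameters
    ----------
    cube:
        Preprocessed data cube.
    F:
        Number of components to assess.
    group_variable:
        Metadata column with subject groups; one subject per group is removed
        each iteration (balanced jackknife).  ``None`` removes one random
        subject per iteration.
    n_iterations:
        Defaults to the smallest group size (leave-each-out coverage), or the
        number of subjects when ungrouped, capped at 20.
    """
    base = cfg or FitConfig()
    I = len(cube.subject_ids)
    groups = cube.group_labels(group_variable) if group_variable else None
    if n_iterations is None:
        if groups is None:
            n_iterations = min(I, 20)
        else:
            n_iterations = min(int(pd.Series(groups).value_counts().min()), 20)
    svd_cfg = FitConfig(ctol=base.ctol, maxit=base.maxit, init_method="svd",
                        n_starts=1, seed=base.seed)
    reference = fit_parafac(cube, F, svd_cfg)

    rng = np.random.default_rng(base.seed)
    models, removed = [], []
    A_stack = np.full((n_iterations, I, F), np.nan)
    B_stack = np.empty((n_iterations, len(cube.feature_ids), F))
    C_stack = np.empty((n_iterations, len(cube.time_points), F))
    for it in range(n_iterations):
        drop = _choose_removals(rng, groups, I)
        keep = [i for i in range(I) if i not in drop]
        sub = cube.subset_subjects(keep)
        m = fit_parafac(sub, F, svd_cfg)
        # reference restricted to the retained subjects so modes agree
        ref_sub = ParafacModel(
            A=reference.A[keep], B=reference.B, C=reference.C,
            weights=reference.weights, n_components=F,
        )
        aligned = align_model(ref_sub, m)
        models.append(aligned)
        removed.append([cube.subject_ids[i] for i in drop])
        # loadings scaled by component weight so SDs are on the data scale
        A_stack[it, keep, :] = aligned.A * aligned.weights
        B_stack[it] = aligned.B
        C_stack[it] = aligned.C

    comp_cols = [f"component_{f + 1}" for f in range(F)]

    def _stats(stack, labels):
        mean = pd.DataFrame(np.nanmean(stack, axis=0), index=labels,
                            columns=comp_cols)
        sd = pd.DataFrame(np.nanstd(stack, axis=0, ddof=0), index=labels,
                          columns=comp_cols)
        return mean, sd

    with np.errstate(invalid="ignore"):
        a_mean, a_sd = _stats(A_stack, list(cube.subject_ids))
        b_mean, b_sd = _stats(B_stack, list(cube.feature_ids))
        c_mean, c_sd = _stats(C_stack, list(cube.time_points))

    return StabilityReport(
        reference=reference,
        models=models,
        removed=removed,
        subject_mean=a_mean,
        subject_sd=a_sd,
        feature_mean=b_mean,
        feature_sd=b_sd,
        time_mean=c_mean,
        time_sd=c_sd,
        settings={
            "n_components": F,
            "n_iterations": n_iterations,
            "group_variable": group_variable,
            "seed": base.seed,
        },
    )
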