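"""Model-order diagnostics for PARAFAC models.

Choosing the number of components is a judgement call informed by several
metrics computed over a grid of component numbers and random starts:

* sum of squared errors / variance explained (scree behaviour),
* iterations to convergence (correct orders converge quickly),
* the core consistency diagnostic, CORCONDIA (how superdiagonal the
  least-squares Tucker core of the model is; 100 means perfectly trilinear,
  values below ~50 indicate an inappropriate component number),
* Tucker congruence between loading vectors of the same mode (values above
  ~0.95 mean two components are essentially the same vector — a degeneracy
  signal).

Component matching across independently fitted models (needed because the
decomposition is only identified up to permutation and paired sign flips) is
solved exactly as a linear assignment problem on the product of per-mode
absolute congruences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cube import DataCube
from .parafac import FitConfig, ParafacModel, reconstruct

__all__ = [
    "corcondia",
    "tucker_congruence",
    "congruence_matrix",
    "match_components",
    "factor_match_score",
    "assess_model_quality",
    "ModelQualityReport",
]


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker congruence phi = <x, y> / (||x|| ||y||), in [-1, 1].

    Scale-invariant cosine similarity between two loading vectors.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def congruence_matrix(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pairwise congruences between the columns of two matrices."""
    un = u / np.linalg.norm(u, axis=0)
    vn = v / np.linalg.norm(v, axis=0)
    return un.T @ vn


def corcondia(model: ParafacModel, cube: DataCube | np.ndarray) -> float:
    """Core consistency diagnostic, <= 100 (can be negative).

    Solves the least-squares Tucker core G for the fixed loadings (weights
    absorbed into the subject mode so the target core is the unit
    superdiagonal) and measures its distance from that superdiagonal:

        100 * (1 - sum (g_def - t_def)^2 / F)

    Under missingness the EM-completed tensor (observed values, model
    reconstruction elsewhere) is used.
    """
    if isinstance(cube, DataCube):
        values, mask = cube.values, cube.observed_mask
    else:
        values = np.asarray(cube, dtype=float)
        mask = ~np.isnan(values)
    x = np.where(mask, values, reconstruct(model))
    F = model.n_components
    Aw = model.A * model.weights
    pinvs = []
    for M in (Aw, model.B, model.C):
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        if s[0] <= 0 or s[-1] / s[0] < 1e-12:
            raise ValueError(
                "loading matrix is rank deficient; core regression is "
                f"ill-posed (condition ~ {s[0] / max(s[-1], 1e-300):.2e})"
            )
        pinvs.append(vt.T @ np.diag(1.0 / s) @ u.T)
    pa, pb, pc = pinvs
    # G = X x1 pinv(A diag(lambda)) x2 pinv(B) x3 pinv(C)
    core = np.einsum("di,ijk->djk", pa, x)
    core = np.einsum("ej,djk->dek", pb, core)
    core = np.einsum("fk,dek->def", pc, core)
    t = np.zeros((F, F, F))
    idx = np.arange(F)
    t[idx, idx, idx] = 1.0
    return float(100.0 * (1.0 - np.sum((core - t) ** 2) / F))


def match_components(reference: ParafacModel, other: ParafacModel):
    """Align ``other``'s components to ``reference``'s.

    Solves the assignment maximising the summed product of absolute per-mode
    congruences exactly (Hungarian algorithm), then chooses sign flips so the
    A- and B-mode congruences are positive, giving C the compensating flip so
    every component's triple product is unchanged.  Returns
    ``(permutation, signs, matched_products)``: ``signs`` has one row per
    mode (A, B, C) and ``other.A[:, permutation] * signs[0]`` aligns with
    ``reference.A``.
    """
    if reference.n_components != other.n_components:
        raise ValueError("component counts differ")
    if reference.shape != other.shape:
        raise ValueError("mode dimensions differ")
    ca = congruence_matrix(reference.A, other.A)
    cb = congruence_matrix(reference.B, other.B)
    cc = congruence_matrix(reference.C, other.C)
    score = np.abs(ca) * np.abs(cb) * np.abs(cc)
    rows, cols = linear_sum_assignment(-score)
    perm = cols[np.argsort(rows)]
    products = score[np.arange(len(perm)), perm]
    # per-mode signs: flip each of A, B so its congruence is positive, then
    # give C the product of those flips so the reconstruction is unchanged
    sa = np.sign(ca[np.arange(len(perm)), perm])
    sb = np.sign(cb[np.arange(len(perm)), perm])
    sa[sa == 0] = 1.0
    sb[sb == 0] = 1.0
    signs = np.stack([sa, sb, sa * sb])  # rows: A, B, C
    return perm, signs, products


def align_model(reference: ParafacModel, other: ParafacModel) -> ParafacModel:
    """Return a copy of ``other`` permuted and sign-flipped onto ``reference``."""
    perm, signs, _ = match_components(reference, other)
    return ParafacModel(
        A=other.A[:, perm] * signs[0],
        B=other.B[:, perm] * signs[1],
        C=other.C[:, perm] * signs[2],
        weights=other.weights[perm],
        n_components=other.n_components,
        sse=other.sse,
        variance_explained=other.variance_explained,
        n_iterations=other.n_iterations,
        converged=other.converged,
        init_method=other.init_method,
        seed=other.seed,
    )


def factor_match_score(reference: ParafacModel, other: ParafacModel) -> float:
    """Mean over optimally matched components of |phi_A * phi_B * phi_C|.

    1 means the two models contain the same components up to the trivial
    scale/permutation/sign indeterminacies.
    """
    _, _, products = match_components(reference, other)
    return float(np.mean(products))


@dataclass
class ModelQualityReport:
    """Per-(n_components, start) diagnostics grid plus per-F summaries."""

    records: pd.DataFrame
    summary: pd.DataFrame
    models: dict  # F -> best ParafacModel

    def best_model(self, F: int) -> ParafacModel:
        return self.models[F]


def max_offdiag_congruence(model: ParafacModel) -> dict:
    """Largest absolute within-mode congruence between distinct components."""
    out = {}
    for name, M in (("subject", model.A), ("feature", model.B), ("time", model.C)):
        if model.n_components < 2:
            out[name] = 0.0
            continue
        cm = np.abs(congruence_matrix(M, M))
        np.fill_diagonal(cm, 0.0)
        out[name] = float(cm.max())
    return out


def _corcondia_or_nan(model: ParafacModel, cube) -> float:
    """CORCONDIA, or NaN when collapsed components make the core ill-posed."""
    try:
        return corcondia(model, cube)
    except ValueError:
        return float("nan")


def assess_model_quality(
    cube: DataCube | np.ndarray,
    F_range=range(1, 6),
    n_starts: int = 10,
    cfg: FitConfig | None = None,
) -> ModelQualityReport:
    """Fit a (components x random starts) grid and tabulate all diagnostics.

    For every F in ``F_range``: ``n_starts`` random-init ALS fits, each with
    SSE, variance explained, iteration count, convergence flag, CORCONDIA,
    and the maximum within-mode off-diagonal congruence.  Deterministic under
    ``cfg.seed``.
    """
    F_range = list(F_range)
    if not F_range:
        raise ValueError("F_range is empty")
    base = cfg or FitConfig()
    rows = []
    models = {}
    from .parafac import fit_parafac, start_seed

    for F in F_range:
        fitted = []
        for s in range(n_starts):
            scfg = FitConfig(ctol=base.ctol, maxit=base.maxit,
                             init_method="random", n_starts=1,
                             seed=start_seed(base.seed, s))
            m = fit_parafac(cube, F, scfg)
            fitted.append(m)
            offd = max_offdiag_congruence(m)
            rows.append(
                {
                    "n_components": F,
                    "start": s,
                    "sse": m.sse,
                    "variance_explained": m.variance_explained,
                    "n_iterations": m.n_iterations,
                    "converged": m.converged,
                    "corcondia": _corcondia_or_nan(m, cube),
                    "max_congruence_subject": offd["subject"],
                    "max_congruence_feature": offd["feature"],
                    "max_congruence_time": offd["time"],
                }
            )
        pool = [(i, m) for i, m in enumerate(fitted) if m.converged]
        pool = pool or list(enumerate(fitted))
        models[F] = max(pool, key=lambda im: (im[1].variance_explained, -im[0]))[1]
    records_df = pd.DataFrame(rows)
    g = records_df.groupby("n_components")
    summary = pd.DataFrame(
        {
            "mean_variance_explained": g["variance_explained"].mean(),
            "max_variance_explained": g["variance_explained"].max(),
            "min_sse": g["sse"].min(),
            "mean_iterations": g["n_iterations"].mean(),
            "share_converged": g["converged"].mean(),
            "share_corcondia_ge_50": g["corcondia"].apply(
                lambda s: float((s >= 50).mean())
            ),
            "max_offdiag_congruence": g[
                ["max_congruence_subject", "max_congruence_feature",
                 "max_congruence_time"]
            ].apply(lambda d: float(d.to_numpy().max())),
        }
    )
    return ModelQualityReport(records=records_df, summary=summary, models=models)
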