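"""Alternating-least-squares PARAFAC (CANDECOMP) with EM imputation.

The trilinear model approximates a three-way array X (I x J x K) by F
components, each an outer product of a subject, feature, and time loading
vector:

    x_ijk = sum_f  lambda_f * a_if * b_jf * c_kf + e_ijk

fitted by minimising the sum of squared residuals over the observed entries.
Each ALS sweep solves the exact least-squares problem for one loading matrix
with the other two fixed, via the Khatri-Rao normal equations.  Missing
entries are handled by expectation-maximisation: before every sweep they are
replaced by the current model reconstruction (initially 0, appropriate for
centered data), which keeps the observed-entry loss non-increasing.

The decomposition is unique up to component order, scale, and paired sign
flips; models are therefore normalised to a fixed convention (unit-norm
loading columns with scale absorbed into non-negative weights, components
ordered by decreasing weight, time-mode column sums non-negative) so that
independent fits are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cube import DataCube

__all__ = [
    "ParafacModel",
    "FitConfig",
    "fit_parafac",
    "reconstruct",
    "variance_explained",
    "multi_start_fit",
]


@dataclass
class FitConfig:
    """ALS fitting settings.

    ctol:
        Relative change in observed-entry SSE below which iteration stops.
    maxit:
        Hard cap on the number of ALS sweeps.
    init_method:
        ``"random"`` (standard-normal entries) or ``"svd"`` (leading left
        singular vectors of the mode unfoldings, deterministic).
    n_starts:
        Number of independent random initialisations for
        :func:`multi_start_fit`.
    """

    ctol: float = 1e-4
    maxit: int = 500
    init_method: str = "random"
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ctol > 0:
            raise ValueError("ctol must be positive")
        if self.maxit < 1:
            raise ValueError("maxit must be >= 1")
        if self.init_method not in ("random", "svd"):
            raise ValueError(f"unknown init method {self.init_method!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class ParafacModel:
    """A fitted PARAFAC model.

    ``A``, ``B``, ``C`` are the subject (I x F), feature (J x F) and time
    (K x F) loading matrices with unit-norm columns; ``weights`` carries the
    absorbed component scales (non-negative, decreasing).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    weights: np.ndarray
    n_components: int
    sse: float = np.nan
    variance_explained: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    init_method: str = "random"
    seed: int = 0
    sse_history: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])


def reconstruct(model: ParafacModel) -> np.ndarray:
    """Dense I x J x K reconstruction sum_f lambda_f a_f (x) b_f (x) c_f."""
    Aw = model.A * model.weights
    return np.einsum("if,jf,kf->ijk", Aw, model.B, model.C)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding; the remaining axes are flattened in C order (the
    later axis varies fastest), matching the Khatri-Rao factor order below."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product: (u ⊙ v)[:, f] = kron(u[:, f], v[:, f])."""
    n, F = u.shape
    m, _ = v.shape
    return (u[:, None, :] * v[None, :, :]).reshape(n * m, F)


def _ls_update(unfolded: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve min ||X_(n) - W (u ⊙ v)^T||_F for W given the two fixed factors."""
    kr = _khatri_rao(u, v)
    gram = (u.T @ u) * (v.T @ v)
    rhs = unfolded @ kr
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:  # pragma: no cover - singular gram
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("ill-conditioned ALS normal equations; adding ridge",
                      stacklevel=2)
        gram = gram + 1e-12 * np.eye(gram.shape[0])
    return np.linalg.solve(gram, rhs.T).T


def _init_factors(
    cube_values: np.ndarray, F: int, method: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial B (J x F) and C (K x F)."""
    _, J, K = cube_values.shape
    if method == "random":
        return rng.standard_normal((J, F)), rng.standard_normal((K, F))
    # svd: leading left singular vectors of the zero-filled mode unfoldings
    if J < F or K < F:
        raise ValueError(f"svd init needs every mode dimension >= F={F}")
    x = np.nan_to_num(cube_values)
    B = np.linalg.svd(_unfold(x, 1), full_matrices=False)[0][:, :F]
    C = np.linalg.svd(_unfold(x, 2), full_matrices=False)[0][:, :F]
    return B, C


def _normalize(A: np.ndarray, B: np.ndarray, C: np.ndarray):
    """Apply the fixed model convention; returns (A, B, C, weights)."""
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    scale = na * nb * nc
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(na > 0, A / na, A)
        B = np.where(nb > 0, B / nb, B)
        C = np.where(nc > 0, C / nc, C)
    # sign convention: time-mode column sums non-negative, flips in pairs
    c_sign = np.where(C.sum(axis=0) < 0, -1.0, 1.0)
    C = C * c_sign
    A = A * c_sign  # paired flip keeps the triple product unchanged
    # a second pairwise flip to keep weights non-negative is unnecessary:
    # scale is a product of norms, hence >= 0
    order = np.argsort(-scale, kind="stable")
    return A[:, order], B[:, order], C[:, order], scale[order]


def fit_parafac(cube: DataCube | np.ndarray, F: int, cfg: FitConfig | None = None,
                rng: np.random.Generator | None = None) -> ParafacModel:
    """Fit an F-component PARAFAC model by ALS with EM imputation.

    Missing entries (NaN / unobserved) are replaced by the current model
    reconstruction before every sweep, starting from 0.  Convergence is
    declared when the relative change in observed-entry SSE drops below
    ``cfg.ctol``.
    """
    cfg = cfg or FitConfig()
    if isinstance(cube, DataCube):
        values, mask = cube.values, cube.observed_mask
    else:
        values = np.asarray(cube, dtype=float)
        mask = ~np.isnan(values)
    if F < 1:
        raise ValueError("F must be >= 1")
    if not mask.any():
        raise ValueError("cube has no observed entries")
    observed_values = values[mask]
    if not np.all(np.isfinite(observed_values)):
        raise ValueError("observed entries must be finite")

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    B, C = _init_factors(values, F, cfg.init_method, rng)
    A = np.zeros((values.shape[0], F))

    x = np.where(mask, values, 0.0)  # initial fill: 0 (mode-mean for centered data)
    model = None
    ssx = float(np.sum(observed_values**2))
    sse_prev = np.inf
    sse_history: list[float] = []
    converged = False
    it = 0
    recon = None
    for it in range(1, cfg.maxit + 1):
        if recon is not None:
            x = np.where(mask, values, recon)  # E-step: impute with model
        A = _ls_update(_unfold(x, 0), B, C)
        B = _ls_update(_unfold(x, 1), A, C)
        C = _ls_update(_unfold(x, 2), A, B)
        recon = np.einsum("if,jf,kf->ijk", A, B, C)
        sse = float(np.sum((values[mask] - recon[mask]) ** 2))
        sse_history.append(sse)
        if sse_prev < np.inf:
            denom = sse_prev if sse_prev > 0 else 1.0
            if abs(sse_prev - sse) / denom < cfg.ctol:
                converged = True
                break
        sse_prev = sse
    An, Bn, Cn, w = _normalize(A, B, C)
    ve = 100.0 * (1.0 - sse / ssx) if ssx > 0 else np.nan
    model = ParafacModel(
        A=An, B=Bn, C=Cn, weights=w, n_components=F, sse=sse,
        variance_explained=ve, n_iterations=it, converged=converged,
        init_method=cfg.init_method, seed=cfg.seed, sse_history=sse_history,
    )
    return model


def variance_explained(model: ParafacModel, cube: DataCube | np.ndarray) -> float:
    """Percent of observed-entry sum of squares captured: 100 (1 - SSE/SSX)."""
    if isinstance(cube, DataCube):
        values, mask = cube.values, cube.observed_mask
    else:
        values = np.asarray(cube, dtype=float)
        mask = ~np.isnan(values)
    if values.shape != model.shape:
        raise ValueError(f"cube shape {values.shape} != model shape {model.shape}")
    ssx = float(np.sum(values[mask] ** 2))
    if ssx == 0:
        raise ValueError("cube has zero sum of squares")
    recon = reconstruct(model)
    sse = float(np.sum((values[mask] - recon[mask]) ** 2))
    return 100.0 * (1.0 - sse / ssx)


def start_seed(master_seed: int, start_index: int) -> int:
    """Deterministic per-start seed; stable in earlier starts when n_starts grows."""
    return int(
        np.random.SeedSequence([int(master_seed), int(start_index)]).generate_state(1)[0]
        % (2**31)
    )


def multi_start_fit(
    cube: DataCube | np.ndarray, F: int, cfg: FitConfig | None = None
):
    """Fit ``cfg.n_starts`` randomly initialised models; keep the best.

    The best model is the converged one with maximal variance explained
    (ties broken by lowest start index); if no start converges, the best
    non-converged model is returned with a warning.  Returns
    ``(best_model, records)`` where ``records`` is one dict per start.
    """
    cfg = cfg or FitConfig()
    records = []
    models = []
    for s in range(cfg.n_starts):
        scfg = FitConfig(
            ctol=cfg.ctol, maxit=cfg.maxit, init_method="random",
            n_starts=1, seed=start_seed(cfg.seed, s),
        )
        m = fit_parafac(cube, F, scfg)
        models.append(m)
        records.append(
            {
                "start": s,
                "seed": scfg.seed,
                "sse": m.sse,
                "variance_explained": m.variance_explained,
                "n_iterations": m.n_iterations,
                "converged": m.converged,
            }
        )
    pool = [(i, m) for i, m in enumerate(models) if m.converged]
    if not pool:
        warnings.warn("no ALS start converged; returning best non-converged model",
                      stacklevel=2)
        pool = list(enumerate(models))
    best = max(pool, key=lambda im: (im[1].variance_explained, -im[0]))[1]
    return best, records
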