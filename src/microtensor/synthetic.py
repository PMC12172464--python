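"""Synthetic data with the structure the pipeline assumes.

Two generators:

* :func:`simulate_trilinear` draws a low-rank trilinear tensor plus i.i.d.
  Gaussian noise on the latent (CLR-like) scale, returning the ground-truth
  loadings for recovery scoring.
* :func:`simulate_mock_counts` emulates a mock intervention study: two
  subject groups (cases and controls) measured over time on a small set of
  taxa, with group-specific dynamics — exponential growth of one taxon in
  cases, sigmoid growth of another in controls, one taxon flat — a
  per-subject random effect scaling the response magnitude, and counts drawn
  multinomially at a fixed sequencing depth.

:func:`apply_missingness` masks a random fraction of (subject, time) fibers,
mimicking missed study visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import DataCube, SampleTable

__all__ = ["SimSpec", "simulate_trilinear", "simulate_mock_counts",
           "apply_missingness"]


@dataclass
class SimSpec:
    """Parameters of the synthetic generators.

    For :func:`simulate_trilinear`: ``I, J, K, F, noise_sd, missing_fraction``.
    For :func:`simulate_mock_counts`: ``n_cases, n_controls, n_times, depth,
    effect_size`` (log-scale magnitude of the group-specific enrichment /
    depletion at the final time point) and ``subject_effect_range`` (the
    uniform range of the per-subject response multiplier).
    """

    I: int = 20
    J: int = 15
    K: int = 8
    F: int = 2
    noise_sd: float = 0.05
    missing_fraction: float = 0.0
    loading_style: str = "normal"  # or "structured"
    # count-layer parameters (mock intervention)
    n_cases: int = 25
    n_controls: int = 25
    n_times: int = 10
    depth: int = 10_000
    baseline_log_abundance: tuple = (0.0, 0.0, 0.0)
    effect_size: float = 2.0
    subject_effect_range: tuple = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be positive")


def simulate_trilinear(spec: SimSpec):
    """Draw a rank-``spec.F`` tensor with additive Gaussian noise.

    Returns ``(cube, truth)`` where ``truth`` is a dict with the generating
    ``A`` (I x F), ``B`` (J x F), ``C`` (K x F) and the noise-free tensor.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.F > min(spec.I, spec.J, spec.K):
        import warnings

        warnings.warn("F exceeds the smallest mode; components may be "
                      "unidentifiable", stacklevel=2)
    if spec.loading_style == "structured":
        # smooth time curves and group-offset subject loadings
        t = np.linspace(0, 1, spec.K)
        C = np.stack(
            [np.sin(np.pi * t * (f + 1)) + 0.2 for f in range(spec.F)], axis=1
        )
        A = rng.standard_normal((spec.I, spec.F))
        A[: spec.I // 2] += 1.0  # group offset in the first half of subjects
        B = rng.standard_normal((spec.J, spec.F))
    else:
        A = rng.standard_normal((spec.I, spec.F))
        B = rng.standard_normal((spec.J, spec.F))
        C = rng.standard_normal((spec.K, spec.F))
    signal = np.einsum("if,jf,kf->ijk", A, B, C)
    x = signal + spec.noise_sd * rng.standard_normal(signal.shape)
    cube = DataCube(
        values=x,
        subject_ids=[f"s{i + 1}" for i in range(spec.I)],
        feature_ids=[f"f{j + 1}" for j in range(spec.J)],
        time_points=list(range(1, spec.K + 1)),
    )
    cube.log_transform("simulate_trilinear", F=spec.F, noise_sd=spec.noise_sd,
                       seed=spec.seed)
    if spec.missing_fraction > 0:
        cube = apply_missingness(cube, spec.missing_fraction, seed=spec.seed + 1)
    return cube, {"A": A, "B": B, "C": C, "signal": signal}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_mock_counts(spec: SimSpec | None = None) -> SampleTable:
    """Mock intervention study on three taxa.

    Cases show exponential enrichment of Proteobacteria (and matching
    depletion of Actinobacteria) over time; controls show sigmoid enrichment
    of Actinobacteria (and depletion of Proteobacteria); Bacteroidetes is
    flat in both groups.  A per-subject multiplier drawn uniformly from
    ``subject_effect_range`` scales the response, and per-sample counts are
    multinomial at ``spec.depth``.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed)
    taxa = ["Actinobacteria", "Bacteroidetes", "Proteobacteria"]
    n = spec.n_cases + spec.n_controls
    subjects = [f"case{i + 1}" for i in range(spec.n_cases)] + [
        f"ctrl{i + 1}" for i in range(spec.n_controls)
    ]
    group = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    u = rng.uniform(*spec.subject_effect_range, size=n)

    tt = np.arange(spec.n_times, dtype=float)
    # time courses in [0, 1]: exponential ramp and sigmoid ramp
    expo = (np.exp(tt / (spec.n_times - 1) * 3) - 1) / (np.e**3 - 1)
    sigm = _sigmoid((tt - spec.n_times / 2) / (spec.n_times / 10))
    sigm = (sigm - sigm[0]) / (sigm[-1] - sigm[0])

    rows = []
    base = np.asarray(spec.baseline_log_abundance, dtype=float)
    for i, (sid, g) in enumerate(zip(subjects, group)):
        for k in range(spec.n_times):
            logab = base.copy()
            if g == "case":
                delta = spec.effect_size * u[i] * expo[k]
                logab[2] += delta  # Proteobacteria enriched
                logab[0] -= delta  # Actinobacteria depleted
            else:
                delta = spec.effect_size * u[i] * sigm[k]
                logab[0] += delta  # Actinobacteria enriched
                logab[2] -= delta  # Proteobacteria depleted
            probs = np.exp(logab)
            probs /= probs.sum()
            counts = rng.multinomial(spec.depth, probs)
            for j, taxon in enumerate(taxa):
                rows.append({"subject": sid, "time": k + 1, "feature": taxon,
                             "count": int(counts[j])})
    meta = pd.DataFrame({"group": group}, index=subjects)
    meta.index.name = "subject"
    return SampleTable(counts=pd.DataFrame(rows), metadata=meta)


def apply_missingness(cube: DataCube, fraction: float, seed: int = 0) -> DataCube:
    """Mask a random ``fraction`` of (subject, time) fibers as fully missing.

    Guarantees that no subject and no time point loses all of its fibers;
    raises when the requested fraction makes that guarantee impossible.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return cube.copy()
    I, _, K = cube.shape
    n_fibers = I * K
    n_mask = int(round(fraction * n_fibers))
    if n_fibers - n_mask < max(I, K):
        raise ValueError(
            f"masking {n_mask}/{n_fibers} fibers cannot leave every subject "
            "and time point with at least one observation"
        )
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        flat = rng.choice(n_fibers, size=n_mask, replace=False)
        keep = np.ones((I, K), dtype=bool)
        keep[flat // K, flat % K] = False
        if keep.any(axis=1).all() and keep.any(axis=0).all():
            break
    else:  # pragma: no cover - vanishingly unlikely at valid fractions
        raise ValueError("could not draw a mask satisfying the coverage guarantee")
    out = cube.copy()
    mask3 = np.repeat(keep[:, None, :], out.shape[1], axis=1)
    out.observed_mask &= mask3
    out.values = np.where(out.observed_mask, out.values, np.nan)
    out.log_transform("apply_missingness", fraction=fraction, seed=seed)
    return out
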