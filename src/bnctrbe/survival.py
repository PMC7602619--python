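"""LQ survival fitting, RMF-constrained fits, and synthetic survival data.

Fitting is done in log space: ln S = −αD − βD² is linear in (α, β), so the
weighted least-squares problem has a closed form; non-negativity of (α, β)
is enforced by bounded optimization when the unconstrained solution leaves
the feasible region.  The one-parameter RMF fit holds β_p fixed at
β_γ·RBE_DSB² (the high-dose limit) and fits only the intra-track term of
α_p, i.e. z̄F, which is also linear in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .rmf import LQParameters, PhotonReference, lq_from_rmf, survival

__all__ = [
    "SurvivalDataset",
    "fit_lq",
    "fit_zbarF_rmf",
    "synth_survival",
    "compare_prediction",
]


@dataclass
class SurvivalDataset:
    """Measured or synthetic clonogenic-survival points."""

    doses: np.ndarray  # Gy
    fractions: np.ndarray  # surviving fraction, (0, 1]
    se: np.ndarray | None = None  # standard error on the fraction
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        s = np.asarray(self.fractions, dtype=float)
        if d.shape != s.shape or d.ndim != 1:
            raise ValueError("doses and fractions must be 1-D and aligned")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if np.any((s <= 0) | (s > 1)):
            raise ValueError("surviving fractions must lie in (0, 1]")
        if self.se is not None:
            e = np.asarray(self.se, dtype=float)
            if e.shape != d.shape or np.any(e <= 0):
                raise ValueError("se must align with doses and be positive")
            self.se = e
        self.doses, self.fractions = d, s

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses).size)

    def _weights(self) -> np.ndarray:
        """Per-point weights on ln S: 1/SE(ln S)² with SE(ln S) ≈ SE(S)/S."""
        if self.se is None:
            return np.ones_like(self.doses)
        return (self.fractions / self.se) ** 2


def fit_lq(data: SurvivalDataset) -> tuple[LQParameters, np.ndarray]:
    """Weighted least-squares LQ fit of ln S on (D, D²) with α, β ≥ 0.

    Returns the estimates and their 2×2 covariance (from the weighted
    normal equations, scaled by the residual variance when no SEs are
    given).
    """
    if data.n_distinct_doses < 3:
        raise ValueError("need at least 3 distinct doses to fit α and β")
    d = data.doses
    y = -np.log(data.fractions)  # = αD + βD²
    w = data._weights()
    sw = np.sqrt(w)
    A = np.column_stack([d, d**2])
    Aw, yw = A * sw[:, None], y * sw
    # unconstrained solution is exact; fall back to bounded only if infeasible
    theta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    if np.any(theta < 0):
        theta = lsq_linear(Aw, yw, bounds=(0.0, np.inf), tol=1e-14).x
    resid = yw - Aw @ theta
    dof = max(len(y) - 2, 1)
    ata_inv = np.linalg.pinv(Aw.T @ Aw)
    scale = 1.0 if data.se is not None else float(resid @ resid) / dof
    cov = ata_inv * scale
    return LQParameters(max(theta[0], 0.0), max(theta[1], 0.0)), cov


def fit_zbarF_rmf(
    data: SurvivalDataset, ref: PhotonReference, rbe_dsb: float
) -> float:
    """One-parameter RMF fit of z̄F (Gy) to survival data.

    β_p is fixed by the high-dose limit (β_γ·RBE_DSB²) and α_p's DSB-yield
    term by α_γ·RBE_DSB; the remaining linear-in-dose effect is attributed to
    the intra-track term 2·β_γ·RBE_DSB²·z̄F·D, and z̄F is the weighted
    least-squares solution, clipped at the physical boundary z̄F ≥ 0.
    """
    if rbe_dsb <= 0:
        raise ValueError(f"rbe_dsb must be positive, got {rbe_dsb}")
    if ref.beta_gamma <= 0:
        raise ValueError("RMF z̄F fit requires beta_gamma > 0")
    d = data.doses
    y = -np.log(data.fractions)
    w = data._weights()
    base = ref.alpha_gamma * rbe_dsb * d + ref.beta_gamma * rbe_dsb**2 * d**2
    x = 2.0 * ref.beta_gamma * rbe_dsb**2 * d
    denom = float(np.sum(w * x**2))
    if denom <= 0:
        raise ValueError("degenerate design: all doses are zero")
    zbar = float(np.sum(w * x * (y - base)) / denom)
    return max(zbar, 0.0)


def synth_survival(
    lq: LQParameters,
    doses,
    noise_sigma: float = 0.0,
    reps: int = 1,
    seed: int = 0,
) -> SurvivalDataset:
    """Synthetic clonogenic-survival dataset from an LQ truth.

    Each replicate observes S = exp(−αD − βD² + ε) with ε ~ N(0, σ²) —
    multiplicative lognormal noise, the usual error model for colony counts —
    truncated above at 1 so fractions stay physical.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    d_all = np.repeat(d, reps)
    s = np.exp(-lq.alpha * d_all - lq.beta * d_all**2)
    if noise_sigma > 0:
        s = s * np.exp(rng.normal(0.0, noise_sigma, size=d_all.size))
    s = np.minimum(s, 1.0)
    return SurvivalDataset(
        doses=d_all, fractions=s,
        metadata={"alpha": lq.alpha, "beta": lq.beta,
                  "noise_sigma": noise_sigma, "reps": reps, "seed": seed})


def compare_prediction(
    data: SurvivalDataset, predicted: LQParameters, dose_grid
) -> dict:
    """Agreement between a predicted LQ curve and the LQ fit to the data.

    Returns the maximum and mean relative deviation of the predicted
    surviving fraction from the fitted one over the dose grid, plus the
    per-dose residuals.
    """
    grid = np.asarray(dose_grid, dtype=float)
    fitted, _ = fit_lq(data)
    s_fit = survival(fitted, grid)
    s_pred = survival(predicted, grid)
    rel = np.abs(s_pred - s_fit) / s_fit
    return {
        "max_rel_deviation": float(rel.max()),
        "mean_rel_deviation": float(rel.mean()),
        "dose_grid": grid,
        "residuals": s_pred - s_fit,
        "fitted": fitted,
    }
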