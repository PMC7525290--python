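"""Optimal proximal junctional angle for a patient under a trained model.

Because the FEM is linear, the stress field at any post-operative angle is
the unit-load field scaled by ``F = G cos(alpha)``: a single unit-load solve
per geometry gives the whole risk-vs-angle curve

    risk(alpha) = g(  (G cos(alpha) - G cos(alpha_pre)) * sigma_unit,
                      age, gender; W )

which is minimized over a bounded angle interval by a 0.1-degree grid scan
followed by Adam refinement from the best grid point, using the analytic
chain-rule gradient d(risk)/d(alpha) through the stress deltas.  Near-ties
are broken toward the patient's pre-operative angle: blindly minimizing the
angle is not clinically desirable, so among equally low-risk angles the one
closest to the status quo is preferred.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import SubregionStressSummary, build_feature_vector
from .model import RiskModel

__all__ = [
    "OptimizationProblem",
    "OptimizationResult",
    "features_at_alpha",
    "optimal_pja",
    "risk_of_alpha",
]


@dataclasses.dataclass(frozen=True)
class OptimizationProblem:
    """One patient's angle-optimization instance.

    ``unit_summary`` is the subregion stress summary of the patient's disc
    under a unit axial load (F = 1 N); G, the pre-operative angle, age and
    gender complete the feature map; the model is the trained risk network.
    """

    model: RiskModel
    unit_summary: SubregionStressSummary
    G: float  #: gravity load above the UIV, N
    pre_pja_deg: float
    age: float
    gender: str | float
    alpha_bounds: tuple[float, float] = (0.0, 45.0)
    risk_tolerance: float = 1e-3  #: ties within this risk range break toward pre-op

    def __post_init__(self) -> None:
        lo, hi = self.alpha_bounds
        if not (0.0 <= lo < hi < 90.0):
            raise ValueError(f"alpha bounds must satisfy 0 <= lo < hi < 90, got {self.alpha_bounds}")
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if not 0.0 <= self.pre_pja_deg < 90.0:
            raise ValueError("pre-operative PJA must lie in [0, 90)")


@dataclasses.dataclass
class OptimizationResult:
    alpha_hat_deg: float
    risk: float
    risk_curve: np.ndarray  #: (K, 2) sampled (alpha, risk) pairs, grid order
    diagnostics: dict


def features_at_alpha(problem: OptimizationProblem, alpha_deg: float) -> np.ndarray:
    """18-feature vector for a candidate post-operative angle.

    Uses the exact linear-scaling shortcut: stress deltas are the unit-load
    summaries scaled by ``G (cos(alpha_post) - cos(alpha_pre))``.
    """
    unit16 = problem.unit_summary.as_vector()
    factor = problem.G * (np.cos(np.deg2rad(alpha_deg)) - np.cos(np.deg2rad(problem.pre_pja_deg)))
    return build_feature_vector(unit16 * factor, problem.age, problem.gender).values


def risk_of_alpha(problem: OptimizationProblem, alpha_deg: float) -> float:
    """Predicted PJK risk at a candidate angle (within bounds)."""
    lo, hi = problem.alpha_bounds
    if not lo <= alpha_deg <= hi:
        raise ValueError(f"alpha {alpha_deg!r} outside bounds [{lo}, {hi}]")
    return problem.model.predict_one(features_at_alpha(problem, alpha_deg))


def _risk_gradient(problem: OptimizationProblem, alpha_deg: float) -> float:
    """d(risk)/d(alpha) in 1/degree via the chain rule through the deltas."""
    x = features_at_alpha(problem, alpha_deg)
    g_in = problem.model.input_gradient(x)[:16]
    dfactor = -problem.G * np.sin(np.deg2rad(alpha_deg)) * np.pi / 180.0
    return float(g_in @ (problem.unit_summary.as_vector() * dfactor))


def optimal_pja(
    problem: OptimizationProblem,
    grid_step_deg: float = 0.1,
    adam_steps: int = 200,
    adam_lr: float = 0.05,
) -> OptimizationResult:
    """Minimize the predicted risk over the angle interval.

    A coarse grid scan (``grid_step_deg``) locates the global basin; Adam
    refines from the best grid point with the analytic gradient.  The
    returned angle is never worse (in risk) than the best grid point, and
    among candidates within ``risk_tolerance`` of the minimum the angle
    closest to the pre-operative PJA is returned.  Fully deterministic.
    """
    lo, hi = problem.alpha_bounds
    n_grid = int(np.floor((hi - lo) / grid_step_deg)) + 1
    grid = np.minimum(lo + grid_step_deg * np.arange(n_grid), hi)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    risks = np.array([risk_of_alpha(problem, a) for a in grid])
    curve = np.column_stack([grid, risks])

    candidates = [(float(a), float(r)) for a, r in zip(grid, risks)]
    if lo <= problem.pre_pja_deg <= hi:
        candidates.append(
            (problem.pre_pja_deg, risk_of_alpha(problem, problem.pre_pja_deg))
        )

    # Adam refinement from the best grid point
    alpha = float(grid[int(np.argmin(risks))])
    b1, b2, eps = 0.9, 0.999, 1e-8
    m = v = 0.0
    for step in range(1, adam_steps + 1):
        g = _risk_gradient(problem, alpha)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        alpha -= adam_lr * (m / (1 - b1**step)) / (np.sqrt(v / (1 - b2**step)) + eps)
        alpha = float(np.clip(alpha, lo, hi))
    candidates.append((alpha, risk_of_alpha(problem, alpha)))

    best_risk = min(r for _, r in candidates)
    ties = [(a, r) for a, r in candidates if r <= best_risk + problem.risk_tolerance]
    alpha_hat, risk_hat = min(
        ties, key=lambda ar: (abs(ar[0] - problem.pre_pja_deg), ar[0])
    )

    flat = bool(risks.max() - risks.min() < problem.risk_tolerance)
    return OptimizationResult(
        alpha_hat_deg=alpha_hat,
        risk=risk_hat,
        risk_curve=curve,
        diagnostics={
            "flat": flat,
            "grid_best_risk": float(risks.min()),
            "refined_alpha": alpha,
            "n_grid": int(len(grid)),
        },
    )
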