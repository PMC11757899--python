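"""Overlap losses for imbalanced tubular segmentation and their gradient ratios.

Implements the Dice loss, the Tversky loss, and the sigmoid-adaptive
Tversky loss (STL), plus closed-form expressions for the *gradient
ratio*: the magnitude ratio of a foreground voxel's loss gradient to a
background voxel's.  When a sparse foreground (e.g. a one-voxel-thick
skeleton) is surrounded by background, a small gradient ratio lets the
background gradients erode the foreground signal; the STL counteracts
this by replacing the numerator likelihood ``p_i`` with
``sigmoid(gamma * (p_i - 0.5))``, which steepens gradients exactly where
the prediction is least confident.

Losses:

    L_D  = 1 - 2*sum(p*g) / (sum(p) + sum(g))
    L_T  = 1 - sum(p*g) / (alpha*sum(p) + beta*sum(g)),     alpha + beta = 1
    L_ST = 1 - sum(sigma(gamma*(p-0.5))*g) / (alpha*sum(p) + beta*sum(g))

Gradient ratios (exact for any foreground voxel; see docs/methods.md):

    R_D  = 2/(1 - L_D) - 1
    R_T  = (1/alpha) * 1/(1 - L_T) - 1
    R_ST = gamma*sigma'(z)/alpha * 1/(1 - L_ST) - 1,  z = gamma*(p_f - 0.5)

All reductions accumulate in double precision so the analytic forms
agree with finite differences to tight tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

from .volumes import LIKELIHOOD_EPS, VoxelGrid

__all__ = [
    "STLParams",
    "dice_loss",
    "tversky_loss",
    "stl_loss",
    "overall_loss",
    "gradient_ratio_dice",
    "gradient_ratio_tversky",
    "gradient_ratio_stl",
    "loss_curve_table",
    "dice_loss_grad",
    "tversky_loss_grad",
    "stl_loss_grad",
]


@dataclass(frozen=True)
class STLParams:
    """Hyper-parameters of the Tversky / STL family.

    ``alpha`` weights the predicted mass, ``beta`` the ground-truth mass
    (``alpha + beta = 1`` enforced); ``gamma`` sets the steepness of the
    STL's sigmoid reweighting around likelihood 0.5.
    """

    alpha: float = 0.01
    beta: float = 0.99
    gamma: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def _unwrap(a) -> np.ndarray:
    return a.values if isinstance(a, VoxelGrid) else np.asarray(a)


def _prepare(p, g) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(_unwrap(p), dtype=np.float64)
    g = np.asarray(_unwrap(g), dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    p = np.clip(p, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
    return p, g


def _degenerate(sp: float, sg: float) -> bool:
    # Σp never reaches 0 after clamping; the degenerate 0/0 pair can only
    # arise for empty arrays
    if sp == 0.0 and sg == 0.0:
        warnings.warn("both prediction and ground truth are empty; loss := 0",
                      stacklevel=3)
        return True
    return False


def dice_loss(p, g) -> float:
    """Dice loss ``1 - 2*sum(p*g)/(sum(p)+sum(g))``; 0 iff p == g exactly."""
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    if _degenerate(sp, sg):
        return 0.0
    return 1.0 - 2.0 * float((p * g).sum()) / (sp + sg)


def tversky_loss(p, g, params: STLParams) -> float:
    """Tversky loss; reduces to the Dice loss at alpha = beta = 0.5."""
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    if _degenerate(sp, sg):
        return 0.0
    return 1.0 - float((p * g).sum()) / (params.alpha * sp + params.beta * sg)


def stl_loss(p, g, params: STLParams) -> float:
    """Sigmoid-adaptive Tversky loss.

    Never reaches 0: at a perfect prediction the loss equals
    ``1 - sigmoid(gamma/2)`` (≈ 0.0293 at gamma = 7).
    """
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    if _degenerate(sp, sg):
        return 0.0
    num = float((_sigmoid(params.gamma * (p - 0.5)) * g).sum())
    return 1.0 - num / (params.alpha * sp + params.beta * sg)


def overall_loss(p, g, p_hat, g_hat, params: STLParams,
                 skel_weight: float = 1.0) -> float:
    """Training objective: Dice on the structure + weighted STL on the skeleton.

    The default weight 1 adds the two terms as-is; the weight is exposed
    because down-weighting the skeleton term is a natural lever against
    false positives.
    """
    if skel_weight < 0:
        raise ValueError("skel_weight must be >= 0")
    total = dice_loss(p, g)
    if skel_weight > 0:
        total += skel_weight * stl_loss(p_hat, g_hat, params)
    return total


def gradient_ratio_dice(l_d: float) -> float:
    """Foreground/background gradient-magnitude ratio of the Dice loss."""
    if not 0.0 <= l_d < 1.0:
        raise ValueError("Dice loss must lie in [0, 1)")
    return 2.0 / (1.0 - l_d) - 1.0


def gradient_ratio_tversky(l_t: float, alpha: float) -> float:
    """Gradient ratio of the Tversky loss at a given loss value and alpha."""
    if not 0.0 <= l_t < 1.0:
        raise ValueError("Tversky loss must lie in [0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return (1.0 / alpha) / (1.0 - l_t) - 1.0


def gradient_ratio_stl(l_st: float, p_f: float, params: STLParams) -> float:
    """Gradient ratio of the STL for a foreground voxel with likelihood p_f.

    Unlike the Dice/Tversky ratios this is voxel-adaptive: the factor
    ``gamma * sigma'(gamma*(p_f - 0.5))`` is largest at p_f = 0.5, so
    low-confidence foreground voxels receive the steepest gradients.
    """
    if not 0.0 <= l_st < 1.0:
        raise ValueError("STL loss must lie in [0, 1)")
    if not 0.0 < p_f < 1.0:
        raise ValueError("p_f must lie in (0, 1)")
    z = params.gamma * (p_f - 0.5)
    s = float(_sigmoid(z))
    return params.gamma * s * (1.0 - s) / params.alpha / (1.0 - l_st) - 1.0


def loss_curve_table(family: str, params: STLParams,
                     grid=None, n_background: int = 26,
                     background_p: float = 0.1) -> np.ndarray:
    """Loss-vs-likelihood curve in the single-foreground-voxel scenario.

    One foreground voxel carries likelihood ``p`` swept over ``grid``;
    ``n_background`` background voxels are fixed at ``background_p``.
    Returns an array of rows ``(p, loss)``.  The default grid spans
    0.05..0.95, inside the clamped likelihood range.
    """
    if grid is None:
        grid = np.linspace(0.05, 0.95, 19)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("grid values must lie in (0, 1)")
    fns = {
        "dice": lambda p, g: dice_loss(p, g),
        "tversky": lambda p, g: tversky_loss(p, g, params),
        "stl": lambda p, g: stl_loss(p, g, params),
    }
    try:
        fn = fns[family]
    except KeyError:
        raise ValueError(f"unknown loss family {family!r}") from None
    g = np.zeros(1 + n_background)
    g[0] = 1.0
    rows = []
    for p_val in grid:
        p = np.full(1 + n_background, background_p)
        p[0] = p_val
        rows.append((float(p_val), fn(p, g)))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# analytic gradients w.r.t. the likelihood map (used by the trainer)

def dice_loss_grad(p, g) -> np.ndarray:
    """d(dice_loss)/dp, elementwise."""
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    denom = sp + sg
    if denom == 0.0:
        return np.zeros_like(p)
    spg = float((p * g).sum())
    return (2.0 * spg - 2.0 * g * denom) / denom**2


def tversky_loss_grad(p, g, params: STLParams) -> np.ndarray:
    """d(tversky_loss)/dp, elementwise."""
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    den = params.alpha * sp + params.beta * sg
    if den == 0.0:
        return np.zeros_like(p)
    num = float((p * g).sum())
    return -(g * den - num * params.alpha) / den**2


def stl_loss_grad(p, g, params: STLParams) -> np.ndarray:
    """d(stl_loss)/dp, elementwise."""
    p, g = _prepare(p, g)
    sp, sg = float(p.sum()), float(g.sum())
    den = params.alpha * sp + params.beta * sg
    if den == 0.0:
        return np.zeros_like(p)
    s = _sigmoid(params.gamma * (p - 0.5))
    num = float((s * g).sum())
    return -(params.gamma * s * (1.0 - s) * g * den - num * params.alpha) / den**2
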