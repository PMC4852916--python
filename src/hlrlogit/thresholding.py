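"""Closed-form univariate update operators for sparse penalties.

This module is the mathematical core of the package: the univariate
thresholding rules that coordinate descent applies to one coefficient at a
time.  The centrepiece is the *half-thresholding operator* for the L1/2
penalty, which has a hard dead zone of radius (3/4)·λ^(2/3) and a
trigonometric shrinkage formula outside it; unlike soft thresholding it is
asymptotically unbiased (the curve approaches the identity for large |ω|).

The hybrid L1/2+L2 (HLR) update composes half-thresholding with ridge
shrinkage::

    β ← Half(ω, λα) / (1 + λ(1-α))

where α ∈ [0, 1] mixes the sparsity-inducing L1/2 part against the
grouping-inducing L2 part.  Soft-threshold analogues (Lasso, Elastic net)
are provided so the same machinery covers the standard convex baselines.

Boundary convention: |ω| exactly equal to the dead-zone radius maps to 0.
π is used at machine precision throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Family",
    "PenaltySpec",
    "half_threshold",
    "soft_threshold",
    "hlr_update",
    "orthogonal_path",
    "half_threshold_radius",
]


class Family(str, Enum):
    """Penalty family: pure L1 / L2 / L1/2, or the two-parameter hybrids."""

    L1 = "l1"
    L2 = "l2"
    HALF = "half"
    HLR = "hlr"
    EN = "en"


#: Families whose univariate update is the half-thresholding operator.
_HALF_FAMILIES = frozenset({Family.HALF, Family.HLR, Family.L2})
#: Families whose univariate update is the soft-thresholding operator.
_SOFT_FAMILIES = frozenset({Family.L1, Family.EN})


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family together with overall strength ``lam`` and mix ``alpha``.

    ``alpha`` is the weight of the sparsity-inducing part (L1/2 for HLR,
    L1 for the elastic net); ``1 - alpha`` weights the ridge part.  It is
    ignored for the single-penalty families: ``HALF`` behaves identically
    to ``HLR`` with ``alpha=1`` and ``L2`` to ``HLR`` with ``alpha=0``.
    """

    family: Family
    lam: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")
        if not np.isfinite(self.alpha) or not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def lam1(self) -> float:
        """Strength of the sparsity term (λ1 = λ·α in the hybrid families)."""
        if self.family in (Family.L1, Family.HALF):
            return self.lam
        if self.family is Family.L2:
            return 0.0
        return self.lam * self.alpha

    @property
    def lam2(self) -> float:
        """Strength of the ridge term (λ2 = λ·(1-α) in the hybrid families)."""
        if self.family in (Family.L1, Family.HALF):
            return 0.0
        if self.family is Family.L2:
            return self.lam
        return self.lam * (1.0 - self.alpha)

    @property
    def delta(self) -> float:
        """Gram-shrinkage weight δ = λ2/(1+λ2) toward the identity matrix."""
        l2 = self.lam2
        return l2 / (1.0 + l2)

    @classmethod
    def from_lam12(cls, lam1: float, lam2: float, family: Family = Family.HLR) -> "PenaltySpec":
        """Build a spec from the two-parameter form λ1·P_sparse + λ2·P_ridge.

        Uses the identification λ1 = λ·α, λ2 = λ·(1-α), i.e. λ = λ1+λ2 and
        α = λ1/(λ1+λ2); this is the only identification consistent with the
        hybrid coordinate update.
        """
        if lam1 < 0 or lam2 < 0:
            raise ValueError("lam1 and lam2 must be non-negative")
        lam = lam1 + lam2
        alpha = 1.0 if lam == 0 else lam1 / lam
        return cls(family=family, lam=lam, alpha=alpha)

    @property
    def uses_half(self) -> bool:
        return self.family in _HALF_FAMILIES


def half_threshold_radius(lam: float) -> float:
    """Dead-zone radius of the half-thresholding operator, (3/4)·λ^(2/3)."""
    return 0.75 * lam ** (2.0 / 3.0)


def _check_scalar(omega: float, lam: float) -> None:
    if not np.isfinite(omega):
        raise ValueError(f"omega must be finite, got {omega}")
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"lam must be finite and >= 0, got {lam}")


def half_threshold(omega: float, lam: float) -> float:
    """Half-thresholding operator for the L1/2 penalty.

    Returns ``(2/3)·ω·(1 + cos(2(π - φ_λ(ω))/3))`` with
    ``φ_λ(ω) = arccos((λ/8)·(|ω|/3)^(-3/2))`` when ``|ω|`` exceeds the
    dead-zone radius ``(3/4)·λ^(2/3)``, and 0 otherwise (boundary included).

    The nonzero branch is the largest stationary point of the univariate
    half-penalized least squares objective ``(β-ω)² + λ|β|^(1/2)``; the
    output preserves the sign of ω and never exceeds |ω| in magnitude.
    """
    _check_scalar(omega, lam)
    if lam == 0.0:
        return float(omega)
    if abs(omega) <= half_threshold_radius(lam):
        return 0.0
    arg = (lam / 8.0) * (abs(omega) / 3.0) ** -1.5
    # |omega| above the radius implies arg <= 1; clip guards the boundary.
    phi = math.acos(min(1.0, max(-1.0, arg)))
    return (2.0 / 3.0) * omega * (1.0 + math.cos(2.0 * (math.pi - phi) / 3.0))


def soft_threshold(omega: float, lam: float) -> float:
    """Soft-thresholding operator sign(ω)·max(|ω| - λ, 0) (Lasso update)."""
    _check_scalar(omega, lam)
    if omega > lam:
        return float(omega - lam)
    if omega < -lam:
        return float(omega + lam)
    return 0.0


def hlr_update(omega: float, spec: PenaltySpec) -> float:
    """Univariate coordinate update for any supported penalty family.

    Half families (HALF, HLR, L2): ``Half(ω, λα) / (1 + λ(1-α))``.
    Soft families (L1, EN): ``Soft(ω, λα) / (1 + λ(1-α))`` (for L1 this is
    plain ``Soft(ω, λ)``).
    """
    if not isinstance(spec, PenaltySpec):
        raise ValueError("spec must be a PenaltySpec")
    if spec.uses_half:
        return half_threshold(omega, spec.lam1) / (1.0 + spec.lam2)
    return soft_threshold(omega, spec.lam1) / (1.0 + spec.lam2)


def orthogonal_path(penalty: PenaltySpec, ols_values) -> np.ndarray:
    """Exact penalized solutions in an orthogonal design.

    With orthonormal predictors the penalized problem decouples and each
    coordinate of the OLS estimate maps through the univariate update;
    evaluating on a dense grid of OLS values regenerates the classical
    solution curves (soft thresholding's constant bias, the half
    threshold's dead zone and asymptotic unbiasedness).
    """
    values = np.asarray(ols_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("ols_values must be finite")
    out = np.empty_like(values, dtype=float)
    flat = values.ravel()
    res = out.ravel()
    for i, w in enumerate(flat):
        res[i] = hlr_update(float(w), penalty)
    return out
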