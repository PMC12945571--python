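"""Precision profile and uncertainty-budget allocation.

A precision profile (CLSI EP17 style) relates the relative uncertainty of
the INR to its level.  Here %ru is modelled as a power function of INR,

    ru(INR) = a * INR^b,

fitted by ordinary least squares on the log-log transformed points — the
standard, closed-form way to fit a power law.  Prediction is endorsed only
inside the fitted INR domain (default [1.0, 4.0]).

The uncertainty budget of the INR traceability chain caps the total
standard uncertainty (as a CV) at 10% at the end-user level.  Two linear
sharing schemes are provided: the rule-of-thumb equal thirds (calibration
laboratories / IVD manufacturers / end users, 3.3% each) and the pragmatic
alternative giving the primary+secondary reference thromboplastins half of
the budget.  Sharing is linear (shares sum to the total), the convention
used when the budget is stated as a CV ceiling per tier; the quadrature
combination of the shares is available separately for context.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DomainError",
    "PrecisionProfile",
    "BudgetAllocation",
    "BudgetCheck",
    "fit_power_profile",
    "predict_ru",
    "allocate_budget",
    "check_budget",
    "quadrature_total",
]

DEFAULT_INR_DOMAIN = (1.0, 4.0)


class DomainError(ValueError):
    """Evaluation requested outside the profile's validated INR domain."""


@dataclass(frozen=True)
class PrecisionProfile:
    """Fitted power-law precision profile ru(INR) = a * INR^b."""

    coefficient_a: float
    exponent_b: float
    inr_domain: tuple[float, float] = DEFAULT_INR_DOMAIN
    fit_points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.coefficient_a > 0:
            raise ValueError(f"coefficient_a must be positive, got {self.coefficient_a}")
        lo, hi = self.inr_domain
        if not lo < hi:
            raise ValueError(f"inr_domain lower bound must be below upper, got {self.inr_domain}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "ru_percent = a * inr^b",
                "a": self.coefficient_a,
                "b": self.exponent_b,
                "inr_domain": list(self.inr_domain),
                "points": [list(p) for p in self.fit_points],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PrecisionProfile":
        obj = json.loads(text)
        return cls(
            coefficient_a=float(obj["a"]),
            exponent_b=float(obj["b"]),
            inr_domain=tuple(obj.get("inr_domain", DEFAULT_INR_DOMAIN)),
            fit_points=tuple(tuple(p) for p in obj.get("points", [])),
        )


def fit_power_profile(
    points: Sequence[tuple[float, float]],
    domain: tuple[float, float] = DEFAULT_INR_DOMAIN,
) -> PrecisionProfile:
    """Least-squares power-law fit of %ru against INR.

    Fits ln(ru) = ln(a) + b*ln(inr) by OLS; with exactly two points this is
    the interpolating power law.  Points exactly on a power law are
    recovered to machine precision.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points to fit, got {len(pts)}")
    for x, y in pts:
        if not (x > 0 and y > 0):
            raise ValueError(f"power-law fit requires positive coordinates, got ({x}, {y})")
    lx = np.log([p[0] for p in pts])
    ly = np.log([p[1] for p in pts])
    # closed-form simple linear regression on the log-log scale
    b, log_a = np.polyfit(lx, ly, 1)
    return PrecisionProfile(
        coefficient_a=float(np.exp(log_a)),
        exponent_b=float(b),
        inr_domain=(float(domain[0]), float(domain[1])),
        fit_points=tuple(pts),
    )


def predict_ru(
    profile: PrecisionProfile, inr: float, extrapolate: bool = False
) -> float:
    """Evaluate the profile at an INR value.

    Raises outside the fitted domain unless ``extrapolate=True``: the
    power-law shape is only validated inside the domain.
    """
    if not inr > 0:
        raise ValueError(f"inr must be positive, got {inr}")
    lo, hi = profile.inr_domain
    if not extrapolate and not (lo <= inr <= hi):
        raise DomainError(
            f"INR {inr} outside the profile domain [{lo}, {hi}]; "
            "pass extrapolate=True to override"
        )
    return profile.coefficient_a * inr**profile.exponent_b


@dataclass(frozen=True)
class BudgetAllocation:
    """Linear split of the total INR uncertainty budget across tiers."""

    total_ru_percent: float
    tier_shares: tuple[tuple[str, float], ...]
    scheme: str

    def __post_init__(self) -> None:
        if not self.total_ru_percent > 0:
            raise ValueError("total budget must be positive")
        if any(s <= 0 for _, s in self.tier_shares):
            raise ValueError("all shares must be positive")
        if abs(sum(s for _, s in self.tier_shares) - self.total_ru_percent) > 1e-9:
            raise ValueError("shares do not sum to the total budget")

    def share(self, tier_name: str) -> float:
        for name, s in self.tier_shares:
            if name == tier_name:
                return s
        raise KeyError(tier_name)


def allocate_budget(
    total_ru_percent: float = 10.0, scheme: str = "thirds"
) -> BudgetAllocation:
    """Split the total standard-uncertainty budget across the chain.

    ``thirds``: equal shares for calibration laboratories, IVD
    manufacturers and end users (10/3 ~ 3.3% each — the rule of thumb).
    ``half_reference``: half to the primary+secondary reference
    thromboplastins combined, half to industry and end users combined.
    """
    if not total_ru_percent > 0:
        raise ValueError(f"total budget must be positive, got {total_ru_percent}")
    if scheme == "thirds":
        s = total_ru_percent / 3.0
        shares = (
            ("calibration_labs", s),
            ("ivd_manufacturers", s),
            ("end_users", s),
        )
    elif scheme == "half_reference":
        s = total_ru_percent / 2.0
        shares = (
            ("reference_thromboplastins", s),
            ("industry_and_end_users", s),
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'thirds' or 'half_reference'")
    return BudgetAllocation(total_ru_percent, shares, scheme)


@dataclass(frozen=True)
class BudgetCheck:
    ru_percent: float
    budget_share: float
    passed: bool
    margin: float


def check_budget(ru_percent: float, budget_share: float) -> BudgetCheck:
    """Check a measured %ru against a tier's budget share.

    Passing requires strict inequality (the budget is stated as "< share");
    the margin is share - ru and may be negative on failure.
    """
    if not budget_share > 0:
        raise ValueError(f"budget_share must be positive, got {budget_share}")
    return BudgetCheck(
        ru_percent=ru_percent,
        budget_share=budget_share,
        passed=ru_percent < budget_share,
        margin=budget_share - ru_percent,
    )


def quadrature_total(shares: Sequence[float]) -> float:
    """Root-sum-of-squares combination of independent CV shares (context
    figure only — the budget allocation itself is linear)."""
    return math.sqrt(sum(float(s) ** 2 for s in shares))
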