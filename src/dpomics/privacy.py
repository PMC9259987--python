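"""Rényi differential privacy (RDP) bookkeeping.

The whole privacy contract of the package rests on three facts about the
Gaussian mechanism at a fixed Rényi order ``alpha > 1``:

* releasing ``Q(D) + Normal(0, sigma^2 I)`` for a query with l2 sensitivity
  ``delta_2`` satisfies (alpha, eps)-RDP with ``eps = alpha * delta_2**2 / (2 * sigma**2)``;
* inverting that bound, a requested budget ``eps`` is met by
  ``sigma = sqrt(alpha * delta_2**2 / (2 * eps))``;
* RDP composes additively at fixed order: running mechanisms with budgets
  ``eps_1, ..., eps_T`` costs ``sum(eps_t)`` in total.

Training therefore splits a total budget uniformly over the planned number of
noisy gradient steps, calibrates one per-step noise scale, and an
:class:`AccountantState` ledger counts the steps actually taken.  Overspending
is a hard :class:`BudgetExhaustedError`, never a warning: a published model's
privacy claim is only as good as this ledger.

No (eps, delta)-DP conversion is performed; budgets are reported in
(alpha, eps)-RDP form throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: absolute tolerance for all budget identities (conservation, round trips)
BUDGET_ATOL = 1e-9


class PrivacyParameterError(ValueError):
    """A privacy parameter is outside its mathematical domain."""


class BudgetExhaustedError(RuntimeError):
    """A noisy step was attempted beyond the planned schedule; training must abort."""


@dataclass(frozen=True)
class RDPParams:
    """An (alpha, epsilon)-RDP budget at a single Rényi order."""

    alpha: float
    epsilon: float

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise PrivacyParameterError(f"Renyi order alpha must exceed 1, got {self.alpha}")
        if self.epsilon < 0:
            raise PrivacyParameterError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class GaussianMechanism:
    """Gaussian noise of scale ``sigma`` applied to a query of l2 sensitivity ``sensitivity``."""

    sigma: float
    sensitivity: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise PrivacyParameterError(f"sigma must be positive, got {self.sigma}")
        if self.sensitivity < 0:
            raise PrivacyParameterError(f"sensitivity must be non-negative, got {self.sensitivity}")

    def epsilon(self, alpha: float) -> float:
        return rdp_epsilon(self.sigma, self.sensitivity, alpha)


def rdp_epsilon(sigma: float, sensitivity: float, alpha: float) -> float:
    """RDP budget of one Gaussian-mechanism release: ``alpha * sensitivity**2 / (2 sigma**2)``.

    Monotone decreasing in ``sigma``, increasing in ``alpha`` and ``sensitivity``.
    """
    if not sigma > 0:
        raise PrivacyParameterError(f"sigma must be positive, got {sigma}")
    if sensitivity < 0:
        raise PrivacyParameterError(f"sensitivity must be non-negative, got {sensitivity}")
    if not alpha > 1:
        raise PrivacyParameterError(f"Renyi order alpha must exceed 1, got {alpha}")
    return alpha * sensitivity**2 / (2.0 * sigma**2)


def calibrate_sigma(epsilon: float, sensitivity: float, alpha: float) -> float:
    """Smallest noise scale achieving (alpha, epsilon)-RDP: ``sqrt(alpha sensitivity^2 / (2 eps))``."""
    if not epsilon > 0:
        raise PrivacyParameterError(
            f"epsilon must be strictly positive (epsilon={epsilon} would require infinite noise)"
        )
    if not sensitivity > 0:
        raise PrivacyParameterError(f"sensitivity must be positive, got {sensitivity}")
    if not alpha > 1:
        raise PrivacyParameterError(f"Renyi order alpha must exceed 1, got {alpha}")
    return math.sqrt(alpha * sensitivity**2 / (2.0 * epsilon))


def compose(budgets: Sequence[RDPParams], alpha: float | None = None) -> RDPParams:
    """Additive composition of RDP budgets sharing one order.

    The empty composition is the identity (epsilon = 0); its order cannot be
    inferred from the (empty) list, so ``alpha`` must then be supplied.
    Mixing orders is rejected: cross-order composition is not defined here.
    """
    budgets = list(budgets)
    if not budgets:
        if alpha is None:
            raise PrivacyParameterError("empty composition requires an explicit alpha")
        return RDPParams(alpha=alpha, epsilon=0.0)
    alphas = {b.alpha for b in budgets}
    if len(alphas) != 1:
        raise PrivacyParameterError(f"cannot compose budgets at mixed Renyi orders: {sorted(alphas)}")
    (shared,) = alphas
    if alpha is not None and alpha != shared:
        raise PrivacyParameterError(f"alpha={alpha} disagrees with the budgets' order {shared}")
    return RDPParams(alpha=shared, epsilon=float(sum(b.epsilon for b in budgets)))


@dataclass
class AccountantState:
    """Ledger for a uniform per-step budget schedule.

    ``spent() = steps_taken * per_step_epsilon`` can never exceed
    ``total_epsilon`` (up to :data:`BUDGET_ATOL`): :func:`record_step` refuses
    the step that would overdraw.
    """

    alpha: float
    total_epsilon: float
    per_step_epsilon: float
    planned_steps: int
    sigma: float
    clip_norm: float
    steps_taken: int = 0

    def __post_init__(self) -> None:
        if self.planned_steps < 0 or self.steps_taken < 0:
            raise PrivacyParameterError("step counts must be non-negative")
        if self.steps_taken > self.planned_steps:
            raise PrivacyParameterError("steps_taken cannot exceed planned_steps")
        if self.per_step_epsilon * self.planned_steps > self.total_epsilon + BUDGET_ATOL:
            raise PrivacyParameterError("schedule would overdraw the total budget")

    def spent(self) -> float:
        return self.steps_taken * self.per_step_epsilon

    def remaining_steps(self) -> int:
        return self.planned_steps - self.steps_taken

    def as_record(self) -> dict:
        """Privacy record embedded in every published model manifest."""
        return {
            "private": True,
            "alpha": self.alpha,
            "total_epsilon": self.total_epsilon,
            "per_step_epsilon": self.per_step_epsilon,
            "planned_steps": self.planned_steps,
            "steps_taken": self.steps_taken,
            "spent_epsilon": self.spent(),
            "sigma": self.sigma,
            "clip_norm": self.clip_norm,
        }


def plan_schedule(total: RDPParams, clip_norm: float, planned_steps: int) -> AccountantState:
    """Split ``total`` uniformly over ``planned_steps`` noisy steps.

    Each step is a Gaussian mechanism on a sum of gradients clipped to l2 norm
    ``clip_norm`` (so the step's sensitivity is ``clip_norm``), with noise scale
    calibrated to the per-step budget ``total.epsilon / planned_steps``.
    Composing the full schedule recovers ``total`` exactly.
    """
    if planned_steps < 1:
        raise PrivacyParameterError(f"planned_steps must be >= 1, got {planned_steps}")
    if not clip_norm > 0:
        raise PrivacyParameterError(f"clip_norm must be positive, got {clip_norm}")
    if not total.epsilon > 0:
        raise PrivacyParameterError("cannot schedule a zero total budget")
    per_step = total.epsilon / planned_steps
    sigma = calibrate_sigma(per_step, clip_norm, total.alpha)
    return AccountantState(
        alpha=total.alpha,
        total_epsilon=total.epsilon,
        per_step_epsilon=per_step,
        planned_steps=planned_steps,
        sigma=sigma,
        clip_norm=clip_norm,
    )


def record_step(state: AccountantState) -> AccountantState:
    """Charge one noisy step to the ledger; hard error once the schedule is exhausted."""
    if state.steps_taken >= state.planned_steps:
        raise BudgetExhaustedError(
            f"privacy budget exhausted: all {state.planned_steps} planned steps already taken "
            f"(spent epsilon={state.spent():.6g} of {state.total_epsilon:.6g})"
        )
    state.steps_taken += 1
    return state
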