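"""Resolution of withdrawal events into switch-or-discontinue outcomes.

Withdrawal from an interferon-beta product (side effects, perceived lack of
efficacy, or other causes) is resolved by a small decision tree: during the
early switch window a patient who has never switched may move once to a
same-price-class alternative product, otherwise all withdrawal mass goes to
symptom management, which is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ProductSpec, SwitchingPolicy, ValidationError
from .states import (
    OFF_TREATMENT,
    HealthState,
    StatusKind,
    TreatmentStatus,
)

__all__ = ["WithdrawalResolution", "resolve_withdrawal"]


@dataclass(frozen=True)
class WithdrawalResolution:
    """Distribution over next treatment statuses, conditional on withdrawing."""

    outcomes: tuple[tuple[TreatmentStatus, float], ...]

    def validate(self) -> None:
        total = sum(p for _, p in self.outcomes)
        if abs(total - 1.0) > 1e-9 or any(p < 0 for _, p in self.outcomes):
            raise ValidationError(
                f"withdrawal resolution probabilities sum to {total!r}"
            )

    @property
    def p_off(self) -> float:
        return sum(p for s, p in self.outcomes if not s.on_treatment)


def resolve_withdrawal(
    product: ProductSpec,
    state: HealthState,
    cycle: int,
    policy: SwitchingPolicy,
    ever_switched: bool = False,
) -> WithdrawalResolution:
    """Destination statuses for a patient withdrawing from ``product``.

    Within the switch window (cycles 1..``policy.switch_window_cycles``) a
    never-switched patient follows the policy's split over the permitted
    same-price-class alternatives and off-treatment; afterwards, or after the
    one permitted switch has been used, all withdrawal mass discontinues.
    """
    if not state.ifn_eligible:
        raise ValidationError(
            f"cannot withdraw from treatment in state {state.value!r} "
            "(not interferon-eligible)"
        )
    if ever_switched or cycle > policy.switch_window_cycles:
        return WithdrawalResolution(((OFF_TREATMENT, 1.0),))
    try:
        targets, probs, p_off = policy.split[product.id]
    except KeyError:
        raise ValidationError(
            f"switching policy has no entry for product {product.id!r}"
        ) from None
    if not targets:
        return WithdrawalResolution(((OFF_TREATMENT, 1.0),))
    outcomes = tuple(
        (TreatmentStatus(StatusKind.SWITCHED, t), p) for t, p in zip(targets, probs)
    ) + ((OFF_TREATMENT, p_off),)
    res = WithdrawalResolution(outcomes)
    res.validate()
    return res
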