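"""Health states and treatment statuses of the disability-progression model.

The disease course is discretised into five living states — relapsing-remitting
MS (RRMS) and secondary progressive MS (SPMS), each banded by the Kurtzke
Expanded Disability Status Scale (EDSS) — plus an absorbing Death state:

* RRMS EDSS 1-3.5   — no or few limitations in mobility
* RRMS EDSS 4-6     — moderate limitations in mobility
* RRMS EDSS 6.5-9.5 — walking aid / wheelchair required, or bedridden
* SPMS EDSS 4-6
* SPMS EDSS 6.5-9.5
* Death

Withdrawal from interferon-beta therapy is tracked as a *treatment status*
orthogonal to the health state, not as a separate health compartment: a
patient is on the initially assigned product, on a once-switched product, or
off treatment (symptom management only). Patients with EDSS above 6 are not
eligible for interferon-beta and always carry off-treatment status.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class HealthState(enum.Enum):
    RRMS_MILD = "rrms_mild"    # RRMS EDSS 1-3.5
    RRMS_MOD = "rrms_mod"      # RRMS EDSS 4-6
    RRMS_SEV = "rrms_sev"      # RRMS EDSS 6.5-9.5
    SPMS_MOD = "spms_mod"      # SPMS EDSS 4-6
    SPMS_SEV = "spms_sev"      # SPMS EDSS 6.5-9.5
    DEATH = "death"

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEATH

    @property
    def ms_type(self) -> str | None:
        """``"rrms"`` or ``"spms"`` for living states, ``None`` for Death."""
        if self in (HealthState.RRMS_MILD, HealthState.RRMS_MOD, HealthState.RRMS_SEV):
            return "rrms"
        if self in (HealthState.SPMS_MOD, HealthState.SPMS_SEV):
            return "spms"
        return None

    @property
    def edss_band(self) -> str | None:
        """``"mild"`` (1-3.5), ``"mod"`` (4-6) or ``"sev"`` (6.5-9.5)."""
        if self is HealthState.RRMS_MILD:
            return "mild"
        if self in (HealthState.RRMS_MOD, HealthState.SPMS_MOD):
            return "mod"
        if self in (HealthState.RRMS_SEV, HealthState.SPMS_SEV):
            return "sev"
        return None

    @property
    def ifn_eligible(self) -> bool:
        """Interferon-beta is licensed only up to EDSS 6 (mild/moderate bands)."""
        return self.is_alive and self.edss_band in ("mild", "mod")


#: Living states, in canonical order.
LIVING_STATES: tuple[HealthState, ...] = (
    HealthState.RRMS_MILD,
    HealthState.RRMS_MOD,
    HealthState.RRMS_SEV,
    HealthState.SPMS_MOD,
    HealthState.SPMS_SEV,
)


class StatusKind(enum.Enum):
    INITIAL = "initial"      # on the initially assigned product
    SWITCHED = "switched"    # on the once-only alternative product
    OFF = "off"              # symptom management only (absorbing)


@dataclass(frozen=True)
class TreatmentStatus:
    """On-treatment/off-treatment status, with the product currently taken.

    ``product_id`` is ``None`` exactly for the off-treatment status.  A
    ``SWITCHED`` status implies the once-only switch has been used, so no
    further switching is permitted from it.
    """

    kind: StatusKind
    product_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind is StatusKind.OFF and self.product_id is not None:
            raise ValueError("off-treatment status carries no product")
        if self.kind is not StatusKind.OFF and self.product_id is None:
            raise ValueError(f"{self.kind.value} status requires a product id")

    @property
    def on_treatment(self) -> bool:
        return self.kind is not StatusKind.OFF

    @property
    def ever_switched(self) -> bool:
        return self.kind is StatusKind.SWITCHED

    def __repr__(self) -> str:  # compact, for trace column labels
        if self.kind is StatusKind.OFF:
            return "off"
        return f"{self.kind.value}:{self.product_id}"


OFF_TREATMENT = TreatmentStatus(StatusKind.OFF)


@dataclass(frozen=True)
class ModelState:
    """A (health state, treatment status) pair of the expanded state space.

    Treatment-bearing statuses are valid only in interferon-eligible health
    states (EDSS <= 6); severe-band and Death states carry off-treatment
    status only.
    """

    health: HealthState
    status: TreatmentStatus

    def __post_init__(self) -> None:
        if self.status.on_treatment and not self.health.ifn_eligible:
            raise ValueError(
                f"state {self.health.value} is not interferon-eligible and "
                "cannot carry an on-treatment status"
            )

    @property
    def label(self) -> str:
        return f"{self.health.value}|{self.status!r}"

    def __repr__(self) -> str:
        return self.label
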