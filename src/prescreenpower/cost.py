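"""Study-cost model: behavioral prescreening vs. scanning more participants.

A behavioral-only participant costs one behavioral session's reimbursement;
a scanned participant additionally costs the booked scanner time at the
facility rate plus reimbursement for that time.  Staff costs are excluded
by default; currency is a label, not a computation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostSpec", "DesignCost", "design_cost", "cost_ratio"]


@dataclass(frozen=True)
class CostSpec:
    """Session durations (hours) and hourly rates (currency/hour)."""

    behav_hours: float = 1.0
    scan_booking_hours: float = 2.0
    participant_fee: float = 8.0
    scanner_fee: float = 150.0

    def __post_init__(self) -> None:
        for name in ("behav_hours", "scan_booking_hours", "participant_fee", "scanner_fee"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DesignCost:
    """Total cost of a design with given behavioral-only and scanned counts."""

    n_behavioral: int
    n_scanned: int
    total: float


def design_cost(spec: CostSpec, n_behavioral: int, n_scanned: int) -> DesignCost:
    """Total study cost.

    ``n_behavioral`` participants are tested behaviorally only;
    ``n_scanned`` are tested behaviorally *and* scanned (reimbursed for both
    sessions, plus the scanner booking fee).
    """
    if n_behavioral < 0 or n_scanned < 0:
        raise ValueError("participant counts must be >= 0")
    per_behav = spec.behav_hours * spec.participant_fee
    per_scan = per_behav + spec.scan_booking_hours * (spec.participant_fee + spec.scanner_fee)
    total = n_behavioral * per_behav + n_scanned * per_scan
    return DesignCost(n_behavioral=n_behavioral, n_scanned=n_scanned, total=total)


def cost_ratio(option_a: DesignCost, option_b: DesignCost) -> float:
    """Cost of option A as a proportion of option B."""
    if option_b.total <= 0:
        raise ValueError("option_b must have positive total cost")
    return option_a.total / option_b.total
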