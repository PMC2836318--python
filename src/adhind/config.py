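"""Methodology constants for the adherence-indicator pipeline.

All thresholds that define the indicator set live in :class:`SummaryConfig`
so that a single object pins down the methodology: the retrospective
observation window, the treatment-gap threshold, the appointment
punctuality windows, the coverage target, the confidence-interval
multiplier, and the benchmark percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

CARRYOVER_POLICIES = ("stockpile", "truncate")
GAP_SCOPES = ("include_trailing", "between_fills_only")


@dataclass(frozen=True)
class ObservationWindow:
    """A half-open retrospective observation period ``[start, start + length)``.

    Days are indexed 0 .. length_days-1 relative to ``start_date`` (the
    cohort-entry / index visit). "Six months" is 180 days, "a year" 365.
    """

    start_date: date
    length_days: int = 180

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError(f"length_days must be positive, got {self.length_days}")

    @property
    def end_date(self) -> date:
        """First day *after* the window."""
        return self.start_date + timedelta(days=self.length_days)

    def day_offset(self, d: date) -> int:
        """Integer day offset of ``d`` from the window start (may be out of range)."""
        return (d - self.start_date).days

    def contains_offset(self, offset: int) -> bool:
        return 0 <= offset < self.length_days


@dataclass(frozen=True)
class SummaryConfig:
    """All tunable methodology constants.

    Parameters
    ----------
    window_days : int
        Length W of the retrospective dispensing window (days). 180 by default.
    gap_threshold_days : int
        Minimum run of consecutive uncovered days that counts as a
        treatment gap (G). 30 by default.
    punctuality_windows_days : tuple of int
        Maximum days after the scheduled date for a visit to count as
        attended "on time", "within 3 days", "within 30 days".
    coverage_target_pct : float
        Adherence target: a patient "meets target" when their percentage
        of days covered is at least this value. 95 by default.
    ci_multiplier : float
        z multiplier for normal-approximation binomial confidence
        intervals (1.96 for 95% CIs).
    benchmark_percentiles : tuple of float
        Cross-facility percentiles reported in the benchmark table.
    carryover_policy : {"stockpile", "truncate"}
        How supply from an early refill is credited; see
        :func:`adhind.indicators.coverage`.
    gap_scope : {"include_trailing", "between_fills_only"}
        Whether the uncovered run after the last fill (up to the window
        end) can count as a gap. ``include_trailing`` keeps patients lost
        to follow-up visible to the gap indicator.
    """

    window_days: int = 180
    gap_threshold_days: int = 30
    punctuality_windows_days: tuple[int, ...] = (0, 3, 30)
    coverage_target_pct: float = 95.0
    ci_multiplier: float = 1.96
    benchmark_percentiles: tuple[float, ...] = (5, 10, 25, 50, 75, 90)
    carryover_policy: str = "stockpile"
    gap_scope: str = "include_trailing"

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window_days must be positive")
        if self.gap_threshold_days < 1:
            raise ValueError("gap_threshold_days must be positive")
        if not 0 < self.coverage_target_pct <= 100:
            raise ValueError("coverage_target_pct must be in (0, 100]")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be positive")
        if any(not 0 < p < 100 for p in self.benchmark_percentiles):
            raise ValueError("benchmark_percentiles must lie in (0, 100)")
        if tuple(sorted(self.punctuality_windows_days)) != tuple(self.punctuality_windows_days):
            raise ValueError("punctuality_windows_days must be sorted ascending")
        if self.carryover_policy not in CARRYOVER_POLICIES:
            raise ValueError(f"carryover_policy must be one of {CARRYOVER_POLICIES}")
        if self.gap_scope not in GAP_SCOPES:
            raise ValueError(f"gap_scope must be one of {GAP_SCOPES}")

    def with_(self, **kwargs) -> "SummaryConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
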