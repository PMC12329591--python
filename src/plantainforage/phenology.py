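"""Phenological development: germination, emergence and the perennial
vegetative/reproductive cycle.

The plant moves through unsown -> germinating -> emerging -> vegetative,
then cycles vegetative <-> reproductive for the rest of its life.
Germination happens one day after sowing if the sowing layer holds any
plant-available water (100 % germination assumed).  Emergence completes
when accumulated thermal time reaches a target that grows with sowing
depth.  The vegetative phase ends after a configured number of long days
(photoperiod above a threshold, 11.5 h by default) have accumulated, and
the reproductive phase ends the same way with short days, resetting to
vegetative.  Defoliation never changes phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum


class Phase(str, Enum):
    UNSOWN = "unsown"
    GERMINATING = "germinating"
    EMERGING = "emerging"
    VEGETATIVE = "vegetative"
    REPRODUCTIVE = "reproductive"


def emergence_target_tt(sowing_depth_mm: float) -> float:
    """Thermal time (degCd) required to complete emergence.

    Linear in sowing depth: 15 degCd for a surface-sown seed plus
    10 degCd per mm of depth.  Depths above 10 mm are agronomically
    inadvisable for the small plantain seed and raise a warning.
    """
    if sowing_depth_mm < 0:
        raise ValueError(f"sowing depth must be >= 0 mm, got {sowing_depth_mm}")
    if sowing_depth_mm > 10:
        warnings.warn(
            f"sowing depth {sowing_depth_mm} mm exceeds the recommended 10 mm",
            stacklevel=2,
        )
    return 15.0 + 10.0 * sowing_depth_mm


@dataclass(frozen=True)
class PhenologyParams:
    """Photoperiod triggers of the vegetative/reproductive cycle."""

    long_day_threshold_h: float = 11.5  # photoperiod above this counts toward induction
    short_day_threshold_h: float = 11.5  # photoperiod below this counts toward reset
    induction_day_count: int = 21  # accumulated long days ending the vegetative phase
    reset_day_count: int = 21  # accumulated short days ending the reproductive phase


@dataclass
class PhenologyState:
    """Current phase plus the accumulators that drive transitions."""

    phase: Phase = Phase.UNSOWN
    tt_in_phase: float = 0.0  # degCd accumulated in the current phase
    long_day_count: int = 0
    short_day_count: int = 0
    sowing_depth_mm: float = 0.0
    emergence_target: float = field(default=0.0)
    days_since_sowing: int = 0
    days_since_emergence: int = 0

    def sow(self, sowing_depth_mm: float) -> None:
        if self.phase is not Phase.UNSOWN:
            raise ValueError(f"cannot sow in phase {self.phase.value}")
        self.phase = Phase.GERMINATING
        self.sowing_depth_mm = sowing_depth_mm
        self.emergence_target = emergence_target_tt(sowing_depth_mm)
        self.tt_in_phase = 0.0
        self.days_since_sowing = 0

    @property
    def emerged(self) -> bool:
        return self.phase in (Phase.VEGETATIVE, Phase.REPRODUCTIVE)

    @property
    def vegetative_only(self) -> bool:
        """True when only vegetative organs (leaf, taproot, root) may grow."""
        return self.phase is not Phase.REPRODUCTIVE


def germination_check(state: PhenologyState, soil_moisture: float) -> PhenologyState:
    """Advance germinating -> emerging one day after sowing if the sowing
    layer holds plant-available water; otherwise keep waiting."""
    if state.phase is not Phase.GERMINATING:
        raise ValueError(f"germination_check requires germinating phase, got {state.phase.value}")
    if state.days_since_sowing >= 1 and soil_moisture > 0:
        state.phase = Phase.EMERGING
        state.tt_in_phase = 0.0
    return state


def advance_phase(
    state: PhenologyState,
    tt_today: float,
    photoperiod_h: float,
    params: PhenologyParams | None = None,
    soil_moisture: float = 1.0,
) -> PhenologyState:
    """One daily phenology step (mutates and returns ``state``).

    Counting of qualifying long/short days is cumulative within the
    phase (not consecutive); counters reset on every transition.
    """
    p = params or PhenologyParams()
    if state.phase is Phase.UNSOWN:
        return state
    if state.emerged:
        state.days_since_emergence += 1
    state.tt_in_phase += tt_today

    if state.phase is Phase.GERMINATING:
        germination_check(state, soil_moisture)
    elif state.phase is Phase.EMERGING:
        if state.tt_in_phase >= state.emergence_target:
            state.phase = Phase.VEGETATIVE
            state.tt_in_phase = 0.0
            state.long_day_count = 0
            state.days_since_emergence = 0
    elif state.phase is Phase.VEGETATIVE:
        if photoperiod_h > p.long_day_threshold_h:
            state.long_day_count += 1
        if state.long_day_count >= p.induction_day_count:
            state.phase = Phase.REPRODUCTIVE
            state.tt_in_phase = 0.0
            state.long_day_count = 0
            state.short_day_count = 0
    elif state.phase is Phase.REPRODUCTIVE:
        if photoperiod_h < p.short_day_threshold_h:
            state.short_day_count += 1
        if state.short_day_count >= p.reset_day_count:
            # "GotoPhase" reset of the perennial cycle
            state.phase = Phase.VEGETATIVE
            state.tt_in_phase = 0.0
            state.long_day_count = 0
            state.short_day_count = 0
    state.days_since_sowing += 1  # counts completed days since sowing
    return state
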