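"""Trial-aligned spike data containers.

The universal input of the pipeline is a :class:`TrialAlignedSession`: a set of
units, a set of trials, and per-(unit, trial) spike-time arrays on a common time
axis with t = 0 at the auditory go cue.  Epochs (presample, sample, delay,
response) are expressed as offsets relative to the go cue, which lets the same
container describe tasks with different delay durations (1.3 s or 1.7 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "CellClass",
    "Layer",
    "Unit",
    "Trial",
    "TrialAlignedSession",
    "EpochWindows",
    "classify_cell_type",
    "assign_layer",
    "SessionValidationError",
    "DEFAULT_LAYER_BOUNDARIES_UM",
    "SAMPLE_DURATION_S",
    "RESPONSE_DURATION_S",
    "PRESAMPLE_DURATION_S",
]

#: Task epoch durations in seconds.  The sample epoch (pole presentation) lasts
#: 1.3 s; the analysed response window after the go cue is 1.3 s; the baseline
#: ("presample") epoch is the 500 ms immediately before the sample epoch.
SAMPLE_DURATION_S = 1.3
RESPONSE_DURATION_S = 1.3
PRESAMPLE_DURATION_S = 0.5

#: Mean cortical-layer boundaries (µm below pia): L1|L2/3, L2/3|L5, L5|L6.
DEFAULT_LAYER_BOUNDARIES_UM = (110.0, 378.3, 771.7)

#: Spike-width classification thresholds (trough-to-peak, ms).
FAST_SPIKING_MAX_MS = 0.35
PYRAMIDAL_MIN_MS = 0.45


class CellClass(str, Enum):
    FAST_SPIKING = "fast_spiking"
    PYRAMIDAL = "pyramidal"
    EXCLUDED_INTERMEDIATE = "excluded_intermediate"


class Layer(str, Enum):
    L1 = "L1"
    L23 = "L2/3"
    L5 = "L5"
    L6 = "L6"


class InstructedType(str, Enum):
    LICK_RIGHT = "lick_right"  # posterior pole position
    LICK_LEFT = "lick_left"  # anterior pole position


class Response(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class Correctness(str, Enum):
    CORRECT = "correct"
    ERROR = "error"
    IGNORE = "ignore"
    EARLY_LICK = "early_lick"


#: Condition labels.  The letter after C/E refers to the *instructed* lick
#: direction: ER is a posterior-pole (lick-right instructed) trial in which the
#: mouse licked left; EL is an anterior-pole trial in which it licked right.
CONDITION_LABELS = ("CR", "CL", "ER", "EL", "ignore", "early_lick")


class SessionValidationError(ValueError):
    """Raised when a session or one of its records violates an invariant."""


def classify_cell_type(spike_width_ms: float) -> CellClass:
    """Classify a unit from its trough-to-peak spike width.

    Widths below 0.35 ms are fast-spiking (putative interneurons), widths above
    0.45 ms putative pyramidal neurons; intermediate widths (0.35–0.45 ms
    inclusive) are excluded from analysis.
    """
    if not np.isfinite(spike_width_ms) or spike_width_ms <= 0:
        raise ValueError(f"spike_width_ms must be positive, got {spike_width_ms!r}")
    if spike_width_ms < FAST_SPIKING_MAX_MS:
        return CellClass.FAST_SPIKING
    if spike_width_ms > PYRAMIDAL_MIN_MS:
        return CellClass.PYRAMIDAL
    return CellClass.EXCLUDED_INTERMEDIATE


def assign_layer(
    depth_um: float,
    boundaries_um: tuple[float, float, float] = DEFAULT_LAYER_BOUNDARIES_UM,
) -> Layer:
    """Assign a cortical layer from recording depth below pia.

    Boundaries are half-open ``[lower, upper)``; they default to the mean
    L1|L2/3, L2/3|L5 and L5|L6 boundaries but can be overridden per dataset.
    """
    if depth_um < 0:
        raise ValueError(f"depth_um must be >= 0, got {depth_um!r}")
    b1, b2, b3 = boundaries_um
    if depth_um < b1:
        return Layer.L1
    if depth_um < b2:
        return Layer.L23
    if depth_um < b3:
        return Layer.L5
    return Layer.L6


@dataclass(frozen=True)
class Unit:
    unit_id: str
    mouse_id: str
    session_id: str
    depth_um: float
    spike_width_ms: float
    cell_class: CellClass = field(init=False)
    layer: Layer = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_class", classify_cell_type(self.spike_width_ms))
        object.__setattr__(self, "layer", assign_layer(self.depth_um))


def condition_label(
    instructed_type: InstructedType, response: Response, correctness: Correctness
) -> str:
    if correctness is Correctness.IGNORE:
        return "ignore"
    if correctness is Correctness.EARLY_LICK:
        return "early_lick"
    side = "R" if instructed_type is InstructedType.LICK_RIGHT else "L"
    return ("C" if correctness is Correctness.CORRECT else "E") + side


@dataclass(frozen=True)
class Trial:
    trial_id: int
    instructed_type: InstructedType
    response: Response
    correctness: Correctness
    sample_start_s: float
    delay_start_s: float
    go_cue_time_s: float = 0.0
    reaction_time_ms: float | None = None
    photostim: "PhotostimCondition | None" = None

    def __post_init__(self) -> None:
        if not (self.sample_start_s < self.delay_start_s < 0):
            raise SessionValidationError(
                f"trial {self.trial_id}: require sample_start_s < delay_start_s < 0, "
                f"got {self.sample_start_s}, {self.delay_start_s}"
            )
        if self.correctness is Correctness.CORRECT:
            want = (
                Response.RIGHT
                if self.instructed_type is InstructedType.LICK_RIGHT
                else Response.LEFT
            )
            if self.response is not want:
                raise SessionValidationError(
                    f"trial {self.trial_id}: correct trial response inconsistent "
                    f"with instruction"
                )
        if self.correctness is Correctness.ERROR:
            want = (
                Response.LEFT
                if self.instructed_type is InstructedType.LICK_RIGHT
                else Response.RIGHT
            )
            if self.response is not want:
                raise SessionValidationError(
                    f"trial {self.trial_id}: error trial must have the "
                    f"counter-instructed response"
                )
        if self.reaction_time_ms is not None and not self.reaction_time_ms > 0:
            raise SessionValidationError(
                f"trial {self.trial_id}: reaction_time_ms must be > 0 when present"
            )

    @property
    def condition(self) -> str:
        return condition_label(self.instructed_type, self.response, self.correctness)


@dataclass(frozen=True)
class PhotostimCondition:
    target: str  # e.g. "S1S2", "cALM", "thal"
    epoch: str  # "sample" | "delay" | "response"
    power_mW: float = 0.0


@dataclass(frozen=True)
class EpochWindows:
    """Contiguous task-epoch windows in go-cue-aligned seconds."""

    delay_duration_s: float
    sample_duration_s: float = SAMPLE_DURATION_S
    response_duration_s: float = RESPONSE_DURATION_S
    presample_duration_s: float = PRESAMPLE_DURATION_S

    @property
    def sample_start(self) -> float:
        return -(self.sample_duration_s + self.delay_duration_s)

    @property
    def delay_start(self) -> float:
        return -self.delay_duration_s

    @property
    def presample(self) -> tuple[float, float]:
        return (self.sample_start - self.presample_duration_s, self.sample_start)

    @property
    def sample(self) -> tuple[float, float]:
        return (self.sample_start, self.delay_start)

    @property
    def delay(self) -> tuple[float, float]:
        return (self.delay_start, 0.0)

    @property
    def response(self) -> tuple[float, float]:
        return (0.0, self.response_duration_s)

    @property
    def trial_window(self) -> tuple[float, float]:
        return (self.presample[0], self.response[1])

    def window(self, name: str) -> tuple[float, float]:
        try:
            return {
                "presample": self.presample,
                "baseline": self.presample,
                "sample": self.sample,
                "delay": self.delay,
                "response": self.response,
            }[name]
        except KeyError:
            raise KeyError(f"unknown epoch {name!r}") from None

    def epoch_of(self, t: float) -> str:
        if t < self.sample_start:
            return "presample"
        if t < self.delay_start:
            return "sample"
        if t < 0:
            return "delay"
        return "response"


@dataclass
class TrialAlignedSession:
    """Units, trials and go-cue-aligned spike times for one (pseudo-)session."""

    units: list[Unit]
    trials: list[Trial]
    spikes: Mapping[tuple[str, int], np.ndarray]
    delay_duration_s: float
    name: str = "session"

    def __post_init__(self) -> None:
        self.validate(repair=True)

    # -- lookups -----------------------------------------------------------
    @property
    def epochs(self) -> EpochWindows:
        return EpochWindows(self.delay_duration_s)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> Unit:
        return self._unit_index[unit_id]

    def trial(self, trial_id: int) -> Trial:
        return self._trial_index[trial_id]

    def trials_of(self, *conditions: str, photostim: bool | None = None) -> list[Trial]:
        """Trials matching any of the given condition labels.

        ``photostim=False`` restricts to control trials, ``True`` to
        photostimulation trials, ``None`` imposes no restriction.
        """
        out = []
        for tr in self.trials:
            if conditions and tr.condition not in conditions:
                continue
            if photostim is True and tr.photostim is None:
                continue
            if photostim is False and tr.photostim is not None:
                continue
            out.append(tr)
        return out

    def spike_times(self, unit_id: str, trial_id: int) -> np.ndarray:
        return self.spikes.get((unit_id, trial_id), _EMPTY)

    # -- validation --------------------------------------------------------
    def validate(self, repair: bool = False) -> None:
        self._unit_index = {u.unit_id: u for u in self.units}
        self._trial_index = {t.trial_id: t for t in self.trials}
        if len(self._unit_index) != len(self.units):
            raise SessionValidationError("duplicate unit_id")
        if len(self._trial_index) != len(self.trials):
            raise SessionValidationError("duplicate trial_id")
        spikes = dict(self.spikes)
        for (uid, tid), st in spikes.items():
            if uid not in self._unit_index:
                raise SessionValidationError(f"spikes reference unknown unit {uid!r}")
            if tid not in self._trial_index:
                raise SessionValidationError(f"spikes reference unknown trial {tid!r}")
            st = np.asarray(st, dtype=float)
            if st.ndim != 1:
                raise SessionValidationError(f"spike times for {(uid, tid)} not 1-D")
            if st.size > 1 and np.any(np.diff(st) < 0):
                if not repair:
                    raise SessionValidationError(
                        f"spike times for {(uid, tid)} are not sorted"
                    )
                warnings.warn(
                    f"unsorted spike times for unit {uid!r}, trial {tid}: sorting",
                    stacklevel=2,
                )
                st = np.sort(st)
            spikes[(uid, tid)] = st
        self.spikes = spikes


_EMPTY = np.array([], dtype=float)
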