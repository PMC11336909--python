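"""Timing model of the interleaved ultrafast-ultrasound / multispectral
photoacoustic acquisition sequences.

The imaging platform alternates two data blocks inside every combined frame:

* a multispectral photoacoustic (MSPA) block — single-wavelength photoacoustic
  frames fired at the laser pulse-repetition rate while the optical parametric
  oscillator cycles through a short wavelength list (750/800/850 nm), plus one
  spare frame to absorb trigger-synchronization frame loss;
* an ultrafast ultrasound (UFUS) block — tilted plane waves coherently
  compounded into one frame per pass over the angle list, repeated to build a
  slow-time ensemble for Doppler processing.

Microbubble (ULM) sessions reuse the UFUS sequence with a longer inter-angle
interval and more compounded frames per sequence, repeated many times.

All durations are represented in **integer microseconds** so that quantities
such as a 525 us compounded-frame period or a 78.75 ms ensemble window are
exact; seconds are exposed as derived float views only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConfigurationError",
    "UfusSequenceParams",
    "MspaSequenceParams",
    "FrameSchedule",
    "plan_ufus_block",
    "plan_mspa_block",
    "plan_ulm_session",
    "plan_fuspa_frame",
]

US_PER_S = 1_000_000


class ConfigurationError(ValueError):
    """Raised for sequence parameters that violate their invariants."""


@dataclass(frozen=True)
class UfusSequenceParams:
    """Plane-wave compounding sequence parameters.

    ``angles_deg`` is the tilt-angle list of one compounding pass;
    ``inter_angle_interval_us`` the time between successive plane-wave
    transmissions; ``n_compound_frames`` the slow-time ensemble length;
    ``transfer_time_us`` the host data-transfer dead time after the ensemble.
    """

    angles_deg: tuple = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)
    inter_angle_interval_us: int = 75
    n_compound_frames: int = 150
    transfer_time_us: int = 1_100_000

    def __post_init__(self) -> None:
        if len(self.angles_deg) == 0:
            raise ConfigurationError("angle list must not be empty")
        if self.inter_angle_interval_us <= 0:
            raise ConfigurationError("inter_angle_interval_us must be > 0")
        if self.n_compound_frames < 1:
            raise ConfigurationError("n_compound_frames must be >= 1")
        if self.transfer_time_us < 0:
            raise ConfigurationError("transfer_time_us must be >= 0")

    @property
    def compound_frame_period_us(self) -> int:
        return len(self.angles_deg) * self.inter_angle_interval_us

    @property
    def prf_c_hz(self) -> float:
        """Compounded frame rate in Hz."""
        return US_PER_S / self.compound_frame_period_us


@dataclass(frozen=True)
class MspaSequenceParams:
    """Multispectral photoacoustic block parameters.

    ``n_sets`` complete passes over ``wavelengths_nm`` are acquired at the
    laser pulse-repetition frequency, followed by ``n_spare_frames`` extra
    frames kept as insurance against trigger-synchronization frame loss.
    """

    laser_prf_hz: float = 10.0
    wavelengths_nm: tuple = (750.0, 800.0, 850.0)
    n_sets: int = 5
    n_spare_frames: int = 1
    transfer_time_us: int = 300_000

    def __post_init__(self) -> None:
        if self.laser_prf_hz <= 0:
            raise ConfigurationError("laser_prf_hz must be > 0")
        if len(set(self.wavelengths_nm)) != len(self.wavelengths_nm):
            raise ConfigurationError("wavelengths must be distinct")
        if len(self.wavelengths_nm) == 0:
            raise ConfigurationError("wavelength list must not be empty")
        if self.n_sets < 1:
            raise ConfigurationError("n_sets must be >= 1")
        if self.n_spare_frames < 0:
            raise ConfigurationError("n_spare_frames must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_sets * len(self.wavelengths_nm) + self.n_spare_frames

    @property
    def frame_period_us(self) -> int:
        period = US_PER_S / self.laser_prf_hz
        rounded = round(period)
        if abs(period - rounded) > 1e-6:
            raise ConfigurationError(
                "laser frame period must be an integer number of microseconds"
            )
        return int(rounded)


@dataclass(frozen=True)
class FrameSchedule:
    """A planned block: event list plus exact integer-microsecond durations.

    ``acquisition_window_us`` covers the live acquisition only;
    ``block_duration_us`` adds dead time (data transfer, trigger idle).
    """

    compound_frame_period_us: int
    acquisition_window_us: int
    block_duration_us: int
    event_times: tuple = field(default_factory=tuple)  # ((label, t_us), ...)

    def __post_init__(self) -> None:
        if self.acquisition_window_us < 0 or self.block_duration_us < 0:
            raise ConfigurationError("durations must be non-negative")
        times = [t for _, t in self.event_times]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigurationError("event times must be strictly increasing")

    @property
    def compound_frame_period_s(self) -> float:
        return self.compound_frame_period_us / US_PER_S

    @property
    def acquisition_window_s(self) -> float:
        return self.acquisition_window_us / US_PER_S

    @property
    def block_duration_s(self) -> float:
        return self.block_duration_us / US_PER_S

    def to_rows(self):
        """Event table as (label, time_s) rows, for CSV export."""
        return [(label, t / US_PER_S) for label, t in self.event_times]


def plan_ufus_block(params: UfusSequenceParams) -> FrameSchedule:
    """Plan one UFUS ensemble.

    The compounded-frame period is ``len(angles) * inter_angle_interval``
    (7 angles at 75 us -> 525 us, i.e. 1904.76 Hz), the acquisition window is
    ``n_compound_frames`` periods (150 frames -> 78.75 ms), and the block
    duration appends the transfer time.
    """
    period = params.compound_frame_period_us
    window = params.n_compound_frames * period
    events = tuple(
        (f"compound_frame_{i}", i * period) for i in range(params.n_compound_frames)
    )
    return FrameSchedule(
        compound_frame_period_us=period,
        acquisition_window_us=window,
        block_duration_us=window + params.transfer_time_us,
        event_times=events,
    )


def plan_mspa_block(params: MspaSequenceParams) -> FrameSchedule:
    """Plan one MSPA block.

    Frames fire at the laser PRF while the wavelength cycles through the
    configured list; spare frames continue the cycle. 5 sets of 3 wavelengths
    plus 1 spare at 10 Hz gives 16 frames in 1.6 s.
    """
    period = params.frame_period_us
    n_frames = params.n_frames
    window = n_frames * period
    n_wl = len(params.wavelengths_nm)
    events = tuple(
        (f"pa_frame_{i}_wl_{params.wavelengths_nm[i % n_wl]:g}nm", i * period)
        for i in range(n_frames)
    )
    return FrameSchedule(
        compound_frame_period_us=period,
        acquisition_window_us=window,
        block_duration_us=window + params.transfer_time_us,
        event_times=events,
    )


def plan_ulm_session(params: UfusSequenceParams, n_sequences: int) -> FrameSchedule:
    """Plan a microbubble-accumulation session of repeated UFUS sequences.

    ``acquisition_window_us`` is the total accumulation time (live acquisition
    only; 300 sequences of 400 frames at 1.4 ms -> 168 s) while
    ``block_duration_us`` is the wall-clock session time including the
    inter-sequence transfer gaps.
    """
    if n_sequences < 1:
        raise ConfigurationError("n_sequences must be >= 1")
    per_seq = params.n_compound_frames * params.compound_frame_period_us
    accumulation = n_sequences * per_seq
    session = n_sequences * (per_seq + params.transfer_time_us)
    events = tuple(
        (f"sequence_{i}", i * (per_seq + params.transfer_time_us))
        for i in range(n_sequences)
    )
    return FrameSchedule(
        compound_frame_period_us=params.compound_frame_period_us,
        acquisition_window_us=accumulation,
        block_duration_us=session,
        event_times=events,
    )


def plan_fuspa_frame(
    ufus: UfusSequenceParams,
    mspa: MspaSequenceParams,
    sync_slack_us: int = 200_000,
) -> FrameSchedule:
    """Plan one combined frame: MSPA block, then UFUS block, then trigger idle.

    With the default parameters this reproduces the ~3.3 s combined frame
    period (1.9 s MSPA incl. transfer + ~1.2 s UFUS incl. transfer + ~0.2 s
    trigger-synchronization slack). The slack is configurable because the
    hardware idle is only known approximately.
    """
    if sync_slack_us < 0:
        raise ConfigurationError("sync_slack_us must be >= 0")
    mspa_sched = plan_mspa_block(mspa)
    ufus_sched = plan_ufus_block(ufus)
    offset = mspa_sched.block_duration_us
    events = mspa_sched.event_times + tuple(
        (label, t + offset) for label, t in ufus_sched.event_times
    )
    total = mspa_sched.block_duration_us + ufus_sched.block_duration_us + sync_slack_us
    return FrameSchedule(
        compound_frame_period_us=ufus_sched.compound_frame_period_us,
        acquisition_window_us=(
            mspa_sched.acquisition_window_us + ufus_sched.acquisition_window_us
        ),
        block_duration_us=total,
        event_times=events,
    )
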