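"""Small protocol helpers."""

from __future__ import annotations

from .errors import InvalidArgumentError


def photoperiod_hours(lights_on: str, lights_off: str) -> float:
    """Photoperiod length in hours from 'HH:MM' on/off clock times.

    An off time earlier than the on time wraps past midnight.
    """

    def minutes(hhmm: str) -> int:
        try:
            hh, mm = hhmm.split(":")
            h, m = int(hh), int(mm)
        except ValueError as exc:
            raise InvalidArgumentError(f"bad clock time {hhmm!r}") from exc
        if not (0 <= h < 24 and 0 <= m < 60):
            raise InvalidArgumentError(f"bad clock time {hhmm!r}")
        return 60 * h + m

    span = minutes(lights_off) - minutes(lights_on)
    if span <= 0:
        span += 24 * 60
    return span / 60.0


def frame_frequency_hz(frame_interval_min: float) -> float:
    """Acquisition frequency (Hz) of a time-lapse with the given frame interval."""
    if frame_interval_min <= 0:
        raise InvalidArgumentError("frame interval must be positive")
    return 1.0 / (frame_interval_min * 60.0)
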