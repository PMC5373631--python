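"""Time- and region-dependent modulation of kinetic parameters.

A :class:`StimulusProtocol` scales one rate constant by a relative amplitude
with a prescribed time profile:

* ``step``  — ramp from 0 to the peak over ``rise`` and hold indefinitely
  (an instantaneous jump when ``rise == 0``), until an optional ``offset``
  time at which the parameter ramps back over ``fall``.
* ``pulse`` — trapezoid: ramp up over ``rise``, hold for ``hold``, ramp back
  down over ``fall``.

The modulated value is ``base * (1 + amplitude * profile(t))`` with
``profile`` in [0, 1], so ``amplitude`` is the peak relative change
(e.g. peak Δα_f/α_f); negative amplitudes model inhibition.  ``region``
optionally restricts the modulation to a set of cells/compartments and is
interpreted by the spatial solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence


@dataclass(frozen=True)
class StimulusProtocol:
    param: str = "alpha_f"
    shape: str = "pulse"  # "step" or "pulse"
    onset: float = 40.0
    rise: float = 10.0
    hold: float = 30.0
    fall: float = 10.0
    amplitude: float = 1.0  # peak relative change of the target rate
    offset: float | None = None  # step-only: time of reversal
    region: Sequence[int] | None = None  # cell/compartment ids; None = global

    def __post_init__(self) -> None:
        if self.shape not in ("step", "pulse"):
            raise ValueError(f"unknown protocol shape {self.shape!r}")
        if self.rise < 0 or self.fall < 0 or self.hold < 0:
            raise ValueError("rise/hold/fall times must be >= 0")
        if self.offset is not None and self.offset < self.onset:
            raise ValueError("offset must come after onset")

    def profile(self, t: float) -> float:
        """Dimensionless time profile in [0, 1]."""
        u = t - self.onset
        if u < 0:
            return 0.0
        if self.shape == "step":
            up = min(u / self.rise, 1.0) if self.rise > 0 else 1.0
            if self.offset is None or t < self.offset:
                return up
            d = t - self.offset
            return up * max(1.0 - d / self.fall, 0.0) if self.fall > 0 else 0.0
        # pulse (trapezoid)
        if u < self.rise:
            return u / self.rise if self.rise > 0 else 1.0
        u -= self.rise
        if u < self.hold:
            return 1.0
        u -= self.hold
        if self.fall > 0 and u < self.fall:
            return 1.0 - u / self.fall
        return 0.0

    def breakpoints(self) -> list[float]:
        """Times where the profile is non-smooth (integration restarts)."""
        pts = [self.onset]
        if self.shape == "step":
            if self.rise > 0:
                pts.append(self.onset + self.rise)
            if self.offset is not None:
                pts.append(self.offset)
                if self.fall > 0:
                    pts.append(self.offset + self.fall)
        else:
            u = self.onset
            for d in (self.rise, self.hold, self.fall):
                u += d
                pts.append(u)
        return pts

    def value(self, base: float, t: float) -> float:
        return base * (1.0 + self.amplitude * self.profile(t))

    def apply(self, params, t: float):
        """Return ``params`` with the target rate modulated at time ``t``."""
        base = getattr(params, self.param)
        return params.replace(**{self.param: self.value(base, t)})

    def replace(self, **kwargs) -> "StimulusProtocol":
        return replace(self, **kwargs)


def step_protocol(param: str, amplitude: float, onset: float = 40.0,
                  offset: float | None = None) -> StimulusProtocol:
    """Sudden sustained change of one rate (optionally reverted at offset)."""
    return StimulusProtocol(param=param, shape="step", onset=onset, rise=0.0,
                            fall=0.0, amplitude=amplitude, offset=offset)


def pulse_protocol(param: str, amplitude: float, onset: float = 40.0,
                   rise: float = 10.0, hold: float = 30.0,
                   fall: float = 10.0,
                   region: Sequence[int] | None = None) -> StimulusProtocol:
    """Transient trapezoid stimulus on one rate."""
    return StimulusProtocol(param=param, shape="pulse", onset=onset,
                            rise=rise, hold=hold, fall=fall,
                            amplitude=amplitude, region=region)
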