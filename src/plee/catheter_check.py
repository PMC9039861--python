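"""Occlusion-manoeuvre validity check for oesophageal catheter position.

With the airway occluded at end-expiration and the chest gently compressed,
airway and oesophageal pressure should swing together: the balloon then
transmits pleural pressure faithfully and the ratio of the oesophageal to
the airway pressure swing (ΔPes/ΔPaw) should lie between 0.8 and 1.2.
A ratio outside that band indicates balloon malposition or inappropriate
filling volume, and the recording should not be used for transpulmonary
pressure work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import NoOcclusionSwingError, ValidationError
from .fluxmed_io import SignalRecording


@dataclass(frozen=True)
class OcclusionResult:
    """Pressure swings during an occlusion manoeuvre and their ratio."""

    delta_pes: float
    delta_paw: float

    @property
    def ratio(self) -> float:
        return self.delta_pes / self.delta_paw

    @property
    def valid(self) -> bool:
        """Catheter position acceptable: ratio within [0.8, 1.2], inclusive."""
        return 0.8 <= self.ratio <= 1.2


def occlusion_ratio(
    rec: SignalRecording,
    window: tuple[float, float],
    method: Literal["amplitude", "regression"] = "amplitude",
    min_delta_paw: float = 1.0,
) -> OcclusionResult:
    """Evaluate the ΔPes/ΔPaw ratio over an occlusion window.

    Parameters
    ----------
    rec
        Recording with both paw and pes channels.
    window
        (start, end) in recording seconds, covering the occlusion
        manoeuvre; must span at least 0.5 s of samples.
    method
        "amplitude" (default): Δ is the peak-to-trough amplitude of each
        channel within the window.  "regression": Δpes/Δpaw is the
        least-squares slope of Pes on Paw, with Δpaw the Paw amplitude —
        an alternative reading of the swing ratio for sensitivity analysis.
    min_delta_paw : cmH2O
        Below this airway swing the manoeuvre did not produce a usable
        occlusion and the ratio is undefined.
    """
    if rec.pes is None:
        raise ValidationError("occlusion check needs a Pes channel")
    start, end = window
    if end <= start:
        raise ValueError("window end must be after window start")
    if start < rec.time[0] or end > rec.time[-1]:
        raise ValueError(
            f"window [{start:g}, {end:g}] s outside recording "
            f"[{rec.time[0]:g}, {rec.time[-1]:g}] s"
        )
    mask = (rec.time >= start) & (rec.time <= end)
    if mask.sum() < 0.5 * rec.sampling_hz:
        raise ValueError("occlusion window must span at least 0.5 s of samples")

    paw = rec.paw[mask]
    pes = rec.pes[mask]
    delta_paw = float(np.ptp(paw))
    if delta_paw < min_delta_paw:
        raise NoOcclusionSwingError(
            f"airway swing {delta_paw:.2f} cmH2O below {min_delta_paw:g} cmH2O: "
            "no usable occlusion in the window"
        )
    if method == "amplitude":
        delta_pes = float(np.ptp(pes))
    elif method == "regression":
        slope = float(np.polyfit(paw, pes, 1)[0])
        delta_pes = slope * delta_paw
    else:
        raise ValueError(f"unknown method {method!r}")
    return OcclusionResult(delta_pes=delta_pes, delta_paw=delta_paw)
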