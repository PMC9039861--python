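"""Synthetic ventilator and oesophageal pressure waveforms with known truth.

Single-compartment respiratory mechanics drive the generator: with volume
V(t) above the end-expiratory lung volume, flow V'(t), total respiratory
elastance E = E_lung + E_cw and airway resistance R,

    Paw(t) = PEEP + E * V(t) + R * V'(t)
    Pes(t) = Pes_baseline + E_cw * V(t) + cardiac oscillation + noise
    P_L(t) = Paw(t) - Pes(t)

so at relaxed end-expiration (V = 0, V' = 0, no artifact) the
transpulmonary pressure equals exactly ``set_peep - pes_baseline`` — the
generator's ground truth against which the extraction pipeline is scored.

Volume control delivers a constant inspiratory flow; expiration is passive
with time constant tau = R/E, which is what produces the near-zero
end-expiratory flow window the extraction filters rely on.  Pressure
control applies a square driving pressure above PEEP instead.  The cardiac
oscillation is a sinusoid at the heart rate with a seeded random phase;
optional artifacts model oesophageal contractions (raised-cosine pressure
bump) and surgical manipulation (pressure step).

:func:`export_project` writes simulated multi-PEEP recordings in the
monitor's file dialect, in the standardized project layout, together with a
CRF and a ground-truth table — everything the rest of the package needs for
end-to-end testing without any recorded data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fluxmed_io import DialectOptions, SignalRecording, write_signal_file

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BreathModelParams:
    """Ground-truth parameters of one simulated recording segment.

    Defaults describe an anaesthetized, paralysed, normal-weight adult on
    volume control: tidal volume 500 mL at 12 breaths/min (I:E 1:2), lung
    elastance 12 and chest-wall elastance 8 cmH2O/L (compliance
    50 mL/cmH2O), airway resistance 10 cmH2O/(L/s), oesophageal baseline
    5 cmH2O, cardiac oscillation 2 cmH2O at 72 bpm, Gaussian sensor noise
    0.3 cmH2O, 7 minutes recorded at 256 Hz.
    """

    mode: Literal["volume_control", "pressure_control"] = "volume_control"
    set_peep: float = 5.0
    tidal_volume_ml: float = 500.0
    driving_pressure: float | None = None  # cmH2O, pressure control only
    resp_rate: float = 12.0  # breaths/min
    i_to_e: float = 0.5  # inspiratory:expiratory time ratio (1:2)
    e_lung: float = 12.0  # cmH2O/L
    e_cw: float = 8.0  # cmH2O/L
    r_aw: float = 10.0  # cmH2O/(L/s)
    pes_baseline: float = 5.0  # cmH2O
    cardiac_amplitude: float = 2.0  # cmH2O
    heart_rate_bpm: float = 72.0
    noise_sd: float = 0.3  # cmH2O (also L/min on the flow channel)
    pause_fraction: float = 0.0  # end-inspiratory hold, fraction of the breath
    sampling_hz: float = 256.0
    duration_s: float = 420.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.e_lung, self.e_cw, self.r_aw, self.i_to_e) <= 0:
            raise ConfigError("mechanics parameters must be > 0")
        if not 4.0 <= self.resp_rate <= 60.0:
            raise ConfigError("resp_rate outside physiologic range (4-60/min)")
        if not 30.0 <= self.heart_rate_bpm <= 220.0:
            raise ConfigError("heart_rate_bpm outside physiologic range")
        if self.cardiac_amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.mode == "pressure_control" and self.driving_pressure is None:
            raise ConfigError("pressure_control requires driving_pressure")
        i_frac = self.i_to_e / (1.0 + self.i_to_e)
        if not 0.0 <= self.pause_fraction < i_frac:
            raise ConfigError("pause_fraction must leave time for inspiratory flow")

    @property
    def breath_period_s(self) -> float:
        return 60.0 / self.resp_rate

    @property
    def e_total(self) -> float:
        return self.e_lung + self.e_cw

    @property
    def true_plee(self) -> float:
        """Ground-truth end-expiratory transpulmonary pressure, cmH2O."""
        return self.set_peep - self.pes_baseline


@dataclass(frozen=True)
class ArtifactSpec:
    """A transient disturbance added to the oesophageal pressure.

    ``oesophageal_contraction``: raised-cosine pressure bump (smooth onset
    and offset, peak ``amplitude``).  ``surgical_step``: rectangular
    pressure offset for the given duration.
    """

    kind: Literal["oesophageal_contraction", "surgical_step"]
    onset_s: float
    duration_s: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude == 0:
            raise ConfigError("artifact amplitude must be nonzero")
        if self.onset_s < 0 or self.duration_s <= 0:
            raise ConfigError("artifact onset/duration invalid")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Artifact pressure contribution (cmH2O) on local time grid t."""
        out = np.zeros_like(t)
        inside = (t >= self.onset_s) & (t < self.onset_s + self.duration_s)
        if self.kind == "oesophageal_contraction":
            phase = (t[inside] - self.onset_s) / self.duration_s
            out[inside] = 0.5 * self.amplitude * (1 - np.cos(2 * np.pi * phase))
        else:  # surgical_step
            out[inside] = self.amplitude
        return out


#: Volume clamp (L): below this residual, expiration is treated as complete
#: so every breath carries true zero-flow end-expiratory samples.
_VOLUME_CLAMP_L = 0.001


def _breath_waveforms(
    params: BreathModelParams, t_local: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Volume (L) and flow (L/s) on the local time grid, by breath phase.

    Each breath is inspiratory flow, an optional end-inspiratory hold
    (``pause_fraction`` of the period, volume held with zero flow — the
    plateau phase), then passive exponential expiration.
    """
    period = params.breath_period_s
    t_insp = period * params.i_to_e / (1.0 + params.i_to_e)
    t_flow = t_insp - params.pause_fraction * period
    tau = params.r_aw / params.e_total
    phase = np.mod(t_local, period)
    insp = phase < t_flow
    hold = (phase >= t_flow) & (phase < t_insp)

    v = np.empty_like(t_local)
    vdot = np.empty_like(t_local)
    if params.mode == "volume_control":
        vt = params.tidal_volume_ml / 1000.0
        v[insp] = vt * phase[insp] / t_flow
        vdot[insp] = vt / t_flow
    else:
        dp = float(params.driving_pressure)  # validated non-None
        v[insp] = (dp / params.e_total) * (1.0 - np.exp(-phase[insp] / tau))
        vdot[insp] = (dp - params.e_total * v[insp]) / params.r_aw
        vt = (dp / params.e_total) * (1.0 - np.exp(-t_flow / tau))
    v[hold] = vt
    vdot[hold] = 0.0
    exp_ = phase >= t_insp
    t_exp = phase[exp_] - t_insp
    v[exp_] = vt * np.exp(-t_exp / tau)
    vdot[exp_] = -v[exp_] / tau
    done = exp_ & (v <= _VOLUME_CLAMP_L)
    v[done] = 0.0
    vdot[done] = 0.0
    return v, vdot


def simulate_recording(
    params: BreathModelParams,
    artifacts: Sequence[ArtifactSpec] = (),
    t_offset: float = 0.0,
    source_id: str | None = None,
) -> tuple[SignalRecording, float]:
    """Simulate one recording segment; returns (recording, true P_Lee).

    The time channel starts at ``t_offset`` (used when concatenating PEEP
    steps into one monitor file); breath and cardiac phases run on local
    time so segments are individually reproducible.  Identical parameters
    and seed give bitwise-identical output.
    """
    fs = params.sampling_hz
    n = int(round(params.duration_s * fs))
    if params.duration_s < params.breath_period_s:
        raise ConfigError("duration must cover at least one breath")
    rng = np.random.default_rng(params.seed)
    cardiac_phase = rng.uniform(0.0, 2 * np.pi)

    t_local = np.arange(n) / fs
    v, vdot = _breath_waveforms(params, t_local)

    paw = params.set_peep + params.e_total * v + params.r_aw * vdot
    pes = params.pes_baseline + params.e_cw * v
    if params.cardiac_amplitude > 0:
        f_c = params.heart_rate_bpm / 60.0
        pes = pes + params.cardiac_amplitude * np.sin(
            2 * np.pi * f_c * t_local + cardiac_phase
        )
    for art in artifacts:
        pes = pes + art.waveform(t_local)
    flow_lpm = vdot * 60.0
    if params.noise_sd > 0:
        paw = paw + rng.normal(0.0, params.noise_sd, n)
        pes = pes + rng.normal(0.0, params.noise_sd, n)
        flow_lpm = flow_lpm + rng.normal(0.0, params.noise_sd, n)

    rec = SignalRecording(
        time=t_offset + t_local,
        flow=flow_lpm,
        volume=v * 1000.0,
        paw=paw,
        pes=pes,
        pl=paw - pes,
        sampling_hz=fs,
        source_id=source_id,
    )
    return rec, params.true_plee


def _zero_segment(duration_s: float, fs: float) -> dict[str, np.ndarray]:
    """A dead lead-in: monitor running, circuit not yet connected."""
    n = int(round(duration_s * fs))
    z = np.zeros(n)
    return {k: z.copy() for k in ("flow", "volume", "paw", "pes", "pl")}


def _concatenate(
    segments: list[dict[str, np.ndarray]], fs: float, source_id: str
) -> SignalRecording:
    chans = {
        k: np.concatenate([seg[k] for seg in segments])
        for k in ("flow", "volume", "paw", "pes", "pl")
    }
    n = len(chans["flow"])
    return SignalRecording(
        time=np.arange(n) / fs, sampling_hz=fs, source_id=source_id, **chans
    )


@dataclass
class ProjectExport:
    """Paths and ground truth of an exported synthetic project."""

    root: Path
    crf_path: Path
    truth_path: Path
    truth: pd.DataFrame = field(repr=False)


def export_project(
    out_dir: str | Path,
    n_participants: int = 5,
    peep_levels: Sequence[float] = (15.0, 10.0, 5.0),
    base_params: BreathModelParams | None = None,
    artifacts_by_id: dict[str, Sequence[ArtifactSpec]] | None = None,
    seed: int = 42,
    lead_in_s: float = 20.0,
) -> ProjectExport:
    """Write a synthetic multi-participant project in the monitor dialect.

    Mirrors the study layout: one folder per participant holding a single
    ``signals.txt`` that concatenates a dead lead-in (before the experiment
    starts) and one segment per PEEP level, in the given order.  ``CRF.csv``
    carries the per-participant ``datastart`` (the lead-in length) and
    ``truth.csv`` the ground-truth P_Lee per (id, setPEEP) for recovery
    tests.

    Participants differ in oesophageal baseline pressure (uniform
    2–8 cmH2O), airway resistance (8–10 cmH2O/(L/s)), heart rate
    (60–90 bpm) and all random phases/noise, each drawn from a child of
    ``seed`` — the tree of files is bit-identical across runs for a fixed
    seed.
    """
    base = base_params or BreathModelParams()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    dialect = DialectOptions(decimal_separator="comma")
    fs = base.sampling_hz

    crf_rows: list[dict] = []
    truth_rows: list[dict] = []
    children = np.random.SeedSequence(seed).spawn(max(n_participants, 1))
    for i in range(n_participants):
        pid = f"Participant{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        pes_baseline = float(rng.uniform(2.0, 8.0))
        r_aw = float(rng.uniform(8.0, 10.0))
        heart_rate = float(rng.uniform(60.0, 90.0))
        segments = [_zero_segment(lead_in_s, fs)] if lead_in_s > 0 else []
        arts = (artifacts_by_id or {}).get(pid, ())
        for peep in peep_levels:
            params = replace(
                base,
                set_peep=float(peep),
                pes_baseline=pes_baseline,
                r_aw=r_aw,
                heart_rate_bpm=heart_rate,
                seed=int(rng.integers(2**31)),
            )
            rec, true_plee = simulate_recording(params, artifacts=arts)
            segments.append(
                {k: getattr(rec, k) for k in ("flow", "volume", "paw", "pes", "pl")}
            )
            truth_rows.append(
                {"id": pid, "setPEEP": float(peep), "true_plee": true_plee}
            )
        full = _concatenate(segments, fs, pid)
        folder = root / pid
        folder.mkdir(exist_ok=True)
        write_signal_file(full, folder / "signals.txt", dialect)
        crf_rows.append({"id": pid, "datastart": lead_in_s})
        logger.info("wrote %s (%d samples)", folder / "signals.txt", len(full))

    crf_path = root / "CRF.csv"
    pd.DataFrame(crf_rows, columns=["id", "datastart"]).to_csv(crf_path, index=False)
    truth_path = root / "truth.csv"
    truth = pd.DataFrame(truth_rows, columns=["id", "setPEEP", "true_plee"])
    truth.to_csv(truth_path, index=False)
    return ProjectExport(root=root, crf_path=crf_path, truth_path=truth_path, truth=truth)
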