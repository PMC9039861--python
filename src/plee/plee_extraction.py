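"""Extraction of the median end-expiratory transpulmonary pressure (P_Lee).

Manual reading of transpulmonary pressure-time plots samples only a handful
of breaths and is prone to inter-observer bias.  The extraction implemented
here instead uses every representative sample of a recording:

1.  trim to the experiment window (drop samples before ``datastart`` and,
    optionally, after ``dataend``);
2.  keep only end-expiratory samples — airway pressure within a margin of
    the set PEEP (default ±1 cmH2O) and flow approximately zero (default
    ±10 L/min);
3.  remove nonsense values from the retained transpulmonary pressures with
    Tukey's fences (outside [Q1 - k·IQR, Q3 + k·IQR], k = 1.5), which
    discards oesophageal contractions, surgical manipulation and other
    transients in a single pass;
4.  summarise with the median, a robust measure of central tendency.

The same machinery, with the airway-pressure window replaced by
``paw > set PEEP + offset`` (inspiratory hold), extracts the transpulmonary
plateau pressure and hence the transpulmonary driving pressure
P_Lplat - P_Lee.

Set PEEP, not measured PEEP, parameterises the window: P_Lee is reported per
protocol PEEP step, which is how the quantity is used in research practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyWindowError,
    NoEndExpirationError,
    NoPlateauError,
    PleeError,
)
from .fluxmed_io import (
    CRFTable,
    DialectOptions,
    SignalRecording,
    discover_participants,
    parse_signal_file,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    """All tunable parameters of the P_Lee extraction.

    set_peep : cmH2O
        The ventilator's set PEEP for the step being extracted.
    paw_margin : cmH2O
        Half-width of the airway-pressure acceptance window around set PEEP;
        ±1 cmH2O absorbs measurement variation around the set level.
    flow_margin : L/min
        Acceptance half-width for "flow approximately zero"; ±10 L/min
        tolerates sensor noise while excluding active in/expiration.
    tukey_k : dimensionless
        Fence multiplier of Tukey's rule; 1.5 is the conventional value.
    plateau_offset : cmH2O
        Plateau filter keeps samples with paw > set_peep + plateau_offset.
    min_samples : count
        Below this many retained samples a low-sample warning is logged
        (the result is still returned).
    quartile_method
        "linear": interpolated order statistics (the common default of
        numerical environments); "hinges": Tukey's hinges.
    """

    set_peep: float
    paw_margin: float = 1.0
    flow_margin: float = 10.0
    tukey_k: float = 1.5
    plateau_offset: float = 2.0
    min_samples: int = 10
    quartile_method: Literal["linear", "hinges"] = "linear"

    def __post_init__(self) -> None:
        if self.paw_margin <= 0 or self.flow_margin <= 0:
            raise ValueError("margins must be > 0")
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be > 0")
        if self.plateau_offset <= 0:
            raise ValueError("plateau_offset must be > 0")

    @property
    def paw_window(self) -> tuple[float, float]:
        """Inclusive airway-pressure acceptance window [low, high] in cmH2O."""
        return (self.set_peep - self.paw_margin, self.set_peep + self.paw_margin)


@dataclass(frozen=True)
class PleeResult:
    """Median P_Lee for one (participant, set PEEP) with its audit trail.

    ``median_plee`` keeps full precision; :attr:`median_plee_rounded` is the
    1-decimal reporting convention of the output table.  The counts document
    how many samples each pipeline stage retained.
    """

    id: str
    set_peep: float
    median_plee: float
    n_total: int
    n_after_trim: int
    n_endexp: int
    n_outliers_removed: int
    pl_source: str = "exported"

    @property
    def median_plee_rounded(self) -> float:
        return round(self.median_plee, 1)

    @property
    def n_retained(self) -> int:
        return self.n_endexp - self.n_outliers_removed


@dataclass(frozen=True)
class DrivingPressureResult:
    """Transpulmonary driving pressure: plateau minus end-expiratory median."""

    id: str
    set_peep: float
    median_plplat: float
    median_plee: float

    @property
    def delta_pl(self) -> float:
        return self.median_plplat - self.median_plee


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def trim_to_experiment(
    rec: SignalRecording, datastart: float, dataend: float | None = None
) -> SignalRecording:
    """Drop samples recorded before the experiment started (or after it ended).

    ``datastart``/``dataend`` are seconds from the start of the monitor
    recording, as noted in the CRF.  ``dataend`` defaults to the end of the
    recording, since the minimal CRF only carries a start time.
    """
    if datastart < 0:
        raise ValueError("datastart must be >= 0")
    mask = rec.time >= datastart
    if dataend is not None:
        mask &= rec.time <= dataend
    if not mask.any():
        raise EmptyWindowError(
            f"{rec.source_id or 'recording'}: no samples at or after "
            f"datastart={datastart:g} s"
            + (f" and before dataend={dataend:g} s" if dataend is not None else "")
        )
    return rec.subset(mask)


def filter_end_expiratory(
    rec: SignalRecording, cfg: ExtractionConfig
) -> SignalRecording:
    """Keep only end-expiratory samples.

    At end-expiration the airway pressure sits close to the set PEEP and the
    flow is approximately zero; both bounds are inclusive.
    """
    low, high = cfg.paw_window
    mask = (
        (rec.paw >= low)
        & (rec.paw <= high)
        & (np.abs(rec.flow) <= cfg.flow_margin)
    )
    if not mask.any():
        raise NoEndExpirationError(
            f"{rec.source_id or 'recording'}: no sample has airway pressure in "
            f"[{low:g}, {high:g}] cmH2O with |flow| <= {cfg.flow_margin:g} L/min"
        )
    return rec.subset(mask)


def filter_plateau(rec: SignalRecording, cfg: ExtractionConfig) -> SignalRecording:
    """Keep inspiratory-hold (plateau) samples.

    Plateau pressure is read during a zero-flow inspiratory hold, when the
    airway pressure sits strictly above set PEEP: paw > set_peep +
    plateau_offset with |flow| within the usual margin.
    """
    mask = (rec.paw > cfg.set_peep + cfg.plateau_offset) & (
        np.abs(rec.flow) <= cfg.flow_margin
    )
    if not mask.any():
        raise NoPlateauError(
            f"{rec.source_id or 'recording'}: no sample has airway pressure above "
            f"{cfg.set_peep + cfg.plateau_offset:g} cmH2O with near-zero flow"
        )
    return rec.subset(mask)


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float]:
    if method == "linear":
        q1, q3 = np.quantile(values, [0.25, 0.75])
        return float(q1), float(q3)
    if method == "hinges":
        # Tukey's hinges: medians of the lower/upper halves, the overall
        # median included in both halves when n is odd.
        v = np.sort(values)
        n = v.size
        half = (n + 1) // 2
        return float(np.median(v[:half])), float(np.median(v[n - half:]))
    raise ValueError(f"unknown quartile method {method!r}")


def tukey_remove_outliers(
    values: Sequence[float] | np.ndarray,
    k: float = 1.5,
    quartile_method: str = "linear",
) -> tuple[np.ndarray, int]:
    """Remove values strictly outside Tukey's fences [Q1 - k·IQR, Q3 + k·IQR].

    The fences are computed once on the input — the rule is applied in a
    single pass, not iterated to convergence.  Sample order is preserved.
    A constant input has IQR 0 and is returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute fences of an empty sample")
    q1, q3 = _quartiles(v, quartile_method)
    iqr = q3 - q1
    keep = (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    return v[keep], int(v.size - keep.sum())


# ---------------------------------------------------------------------------
# End-to-end extraction
# ---------------------------------------------------------------------------


def median_plee(
    rec: SignalRecording,
    datastart: float,
    cfg: ExtractionConfig,
    dataend: float | None = None,
) -> PleeResult:
    """Median end-expiratory transpulmonary pressure for one recording.

    Composes trim -> end-expiratory filter -> Tukey outlier removal on the
    P_L samples -> median.  Raises :class:`EmptyWindowError` or
    :class:`NoEndExpirationError` when a stage retains nothing; logs a
    warning (but still returns) when fewer than ``cfg.min_samples`` samples
    survive.
    """
    n_total = len(rec)
    trimmed = trim_to_experiment(rec, datastart, dataend)
    endexp = filter_end_expiratory(trimmed, cfg)
    pl, source = endexp.pl_values()
    retained, n_removed = tukey_remove_outliers(pl, cfg.tukey_k, cfg.quartile_method)
    if retained.size < cfg.min_samples:
        logger.warning(
            "%s @ PEEP %g: only %d end-expiratory samples retained",
            rec.source_id, cfg.set_peep, retained.size,
        )
    result = PleeResult(
        id=rec.source_id or "",
        set_peep=cfg.set_peep,
        median_plee=float(np.median(retained)),
        n_total=n_total,
        n_after_trim=len(trimmed),
        n_endexp=len(endexp),
        n_outliers_removed=n_removed,
        pl_source=source,
    )
    logger.info(
        "%s @ PEEP %g: n_total=%d n_after_trim=%d n_endexp=%d n_outliers_removed=%d",
        result.id, result.set_peep, result.n_total, result.n_after_trim,
        result.n_endexp, result.n_outliers_removed,
    )
    return result


def driving_pressure(
    rec: SignalRecording,
    datastart: float,
    cfg: ExtractionConfig,
    dataend: float | None = None,
) -> DrivingPressureResult:
    """Transpulmonary driving pressure P_Lplat - P_Lee for one recording.

    The plateau median runs the same pipeline as P_Lee with the plateau
    filter (paw above set PEEP + offset, near-zero flow) in place of the
    end-expiratory window, including the Tukey step.
    """
    ee = median_plee(rec, datastart, cfg, dataend)
    trimmed = trim_to_experiment(rec, datastart, dataend)
    plat = filter_plateau(trimmed, cfg)
    pl, _ = plat.pl_values()
    retained, _ = tukey_remove_outliers(pl, cfg.tukey_k, cfg.quartile_method)
    return DrivingPressureResult(
        id=ee.id,
        set_peep=cfg.set_peep,
        median_plplat=float(np.median(retained)),
        median_plee=ee.median_plee,
    )


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["id", "setPEEP", "medianPLee"]
AUDIT_COLUMNS = RESULT_COLUMNS + [
    "n_total", "n_after_trim", "n_endexp", "n_outliers_removed", "error",
]


def batch_process(
    project_root: str | Path,
    crf: CRFTable,
    peep_levels: Sequence[float],
    cfg: ExtractionConfig | None = None,
    dialect: DialectOptions | None = None,
    signal_filename: str = "signals.txt",
) -> pd.DataFrame:
    """Extract median P_Lee for every (participant, set PEEP) combination.

    Iterates over the CRF rows in order and, per participant, over
    ``peep_levels`` in the given order.  Each participant's signal file is
    parsed once and re-filtered per PEEP level.  Failures (missing files,
    empty windows, no end-expiratory samples) become rows with a NaN median
    and the error message in the ``error`` column — they are never silently
    dropped.

    Returns a DataFrame with columns id, setPEEP, medianPLee (full
    precision) plus the audit counts; see :func:`write_results` for the
    rounded 3-column report.
    """
    base = cfg or ExtractionConfig(set_peep=0.0, )
    found = dict(discover_participants(project_root, signal_filename))
    rows: list[dict] = []
    for participant_id, datastart in crf:
        rec: SignalRecording | None = None
        load_error: str | None = None
        if participant_id not in found:
            load_error = f"no {signal_filename} under {project_root}/{participant_id}"
            logger.error(load_error)
        else:
            try:
                rec = parse_signal_file(found[participant_id], dialect)
            except PleeError as exc:
                load_error = str(exc)
                logger.error("%s: %s", participant_id, load_error)
        for peep in peep_levels:
            row: dict = {"id": participant_id, "setPEEP": peep}
            if rec is None:
                row.update(medianPLee=np.nan, error=load_error)
            else:
                level_cfg = replace(base, set_peep=float(peep))
                try:
                    res = median_plee(rec, datastart, level_cfg)
                    row.update(
                        medianPLee=res.median_plee,
                        n_total=res.n_total,
                        n_after_trim=res.n_after_trim,
                        n_endexp=res.n_endexp,
                        n_outliers_removed=res.n_outliers_removed,
                        error="",
                    )
                except PleeError as exc:
                    logger.error("%s @ PEEP %g: %s", participant_id, peep, exc)
                    row.update(medianPLee=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows, columns=AUDIT_COLUMNS)


def write_results(results: pd.DataFrame, path: str | Path, audit: bool = False) -> Path:
    """Write the output table (id, setPEEP, medianPLee) as CSV.

    The median is rounded to one decimal for reporting; pass ``audit=True``
    to include the per-stage sample counts and error column at full
    precision instead.
    """
    path = Path(path)
    if audit:
        results.to_csv(path, index=False)
    else:
        out = results[RESULT_COLUMNS].copy()
        out["medianPLee"] = out["medianPLee"].round(1)
        out["setPEEP"] = [
            int(v) if float(v).is_integer() else v for v in out["setPEEP"]
        ]
        out.to_csv(path, index=False)
    return path
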