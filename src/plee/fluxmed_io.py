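"""Reading and writing FluxMed/FluxView raw signal exports.

The FluxView acquisition software exports the sensor time series ("signals")
as tab-separated text: a short free-form preamble (title, "Signal file",
serial number, software version), a ``Sampling rate: N Hz`` line, a
column-name row (Time, Flow, Volume, Paw, Pes, PL, Pga, Ptdiaf, CO2), a
units row, and then one sample per row at the stated rate.  Numbers are
written with a decimal comma on the original system; this module handles
comma, dot and automatic dialect detection.

The module also reads the minimal case-report-form (CRF) table mapping each
participant identifier to the experiment start time, and discovers
per-participant signal files in the standardized project layout (one folder
per participant, each holding a ``signals.txt``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .errors import (
    EmptyRecordingError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Channel names in export column order, with their units.
CHANNELS = (
    ("time", "Sec"),
    ("flow", "l/min"),
    ("volume", "ml"),
    ("paw", "cmH2O"),
    ("pes", "cmH2O"),
    ("pl", "cmH2O"),
    ("pga", "cmH2O"),
    ("ptdiaf", "cmH2O"),
    ("co2", "mmHg"),
)

_EXPORT_HEADER_NAMES = {
    "time": "Time",
    "flow": "Flow",
    "volume": "Volume",
    "paw": "Paw",
    "pes": "Pes",
    "pl": "PL",
    "pga": "Pga",
    "ptdiaf": "Ptdiaf",
    "co2": "CO2",
}

_SAMPLING_RATE_RE = re.compile(r"Sampling rate:\s*([0-9]+(?:[.,][0-9]+)?)\s*Hz")

#: Short excerpt of a FluxView signals export recorded with the oesophageal,
#: gastric and CO2 channels not connected (those columns read zero).  Used in
#: documentation and tests; 13 samples at 256 Hz.
EXAMPLE_SIGNALS_TEXT = "\n".join(
    [
        "FluxView - FluxMed acquisition system",
        "Signal file",
        "Serial Number",
        "SW version: 1.33i-OX-CO2 | File version:1.15",
        "Sampling rate: 256 Hz",
        "Time\tFlow\tVolume\tPaw\tPes\tPL\tPga\tPtdiaf\tCO2",
        "Sec\tl/min\tml\tcmH2O\tcmH2O\tcmH2O\tcmH2O\tcmH2O\tmmHg",
        "0\t0\t0\t0\t0\t0\t0\t0\t0",
        "0,0039063\t-5,6\t0\t6,1\t0\t6,1\t0\t0\t0",
        "0,0078125\t-5,1\t-1\t6,3\t0\t6,3\t0\t0\t0",
        "0,0117188\t-4,8\t-1\t6,4\t0\t6,4\t0\t0\t0",
        "0,015625\t-4,4\t-1\t6,4\t0\t6,4\t0\t0\t0",
        "0,0195313\t-4,5\t-1\t6,1\t0\t6,1\t0\t0\t0",
        "0,0234375\t-5\t-1\t6,3\t0\t6,3\t0\t0\t0",
        "0,0273438\t-5,4\t-1\t6,4\t0\t6,4\t0\t0\t0",
        "0,03125\t-5,6\t-1\t6,4\t0\t6,4\t0\t0\t0",
        "0,0351563\t-5,6\t-2\t6,1\t0\t6,1\t0\t0\t0",
        "0,0390625\t-5,5\t-2\t6,1\t0\t6,1\t0\t0\t0",
        "0,0429688\t-5\t-2\t6,3\t0\t6,3\t0\t0\t0",
        "0,046875\t-4,5\t-2\t6,3\t0\t6,3\t0\t0\t0",
    ]
) + "\n"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DialectOptions:
    """How numbers and columns are laid out in a signal export.

    ``decimal_separator="auto"`` decides per file: if any numeric-looking
    token contains a comma and no token mixes comma and dot, the file is
    taken to use decimal commas.
    """

    decimal_separator: Literal["comma", "dot", "auto"] = "auto"
    delimiter: str = "\t"
    header_scan_limit: int = 30

    def __post_init__(self) -> None:
        if self.header_scan_limit < 6:
            raise ValueError("header_scan_limit must be >= 6")
        if self.decimal_separator not in ("comma", "dot", "auto"):
            raise ValueError(f"unknown decimal_separator {self.decimal_separator!r}")


@dataclass
class SignalRecording:
    """A uniformly sampled multichannel respiratory recording.

    Channels follow the monitor's conventions: ``time`` in seconds on a
    strictly increasing grid at ``sampling_hz``; ``flow`` in L/min;
    ``volume`` in mL; pressures in cmH2O (``pl`` is the transpulmonary
    pressure, airway minus oesophageal); ``co2`` in mmHg.  Channels that
    were not exported are ``None``; channels recorded but not connected
    are kept as recorded (see :func:`channel_activity`).
    """

    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    sampling_hz: float
    volume: np.ndarray | None = None
    pes: np.ndarray | None = None
    pl: np.ndarray | None = None
    pga: np.ndarray | None = None
    ptdiaf: np.ndarray | None = None
    co2: np.ndarray | None = None
    source_id: str | None = None

    def __len__(self) -> int:
        return len(self.time)

    def channel_names(self) -> list[str]:
        """Names of the channels present in this recording, export order."""
        return [name for name, _ in CHANNELS if getattr(self, name) is not None]

    def subset(self, mask: np.ndarray) -> "SignalRecording":
        """Recording restricted to the samples where ``mask`` is True.

        All channels stay aligned; metadata is carried over unchanged.
        """
        kwargs = {name: getattr(self, name)[mask] for name in self.channel_names()}
        return SignalRecording(
            sampling_hz=self.sampling_hz, source_id=self.source_id, **kwargs
        )

    def pl_values(self) -> tuple[np.ndarray, str]:
        """Transpulmonary pressure samples and which path produced them.

        Prefers the exported PL column; falls back to paw - pes when PL was
        not exported.  The path taken is logged, since a derived PL hides
        any on-monitor calibration of the exported channel.
        """
        if self.pl is not None:
            logger.debug("%s: using exported PL channel", self.source_id)
            return self.pl, "exported"
        if self.pes is not None:
            logger.info("%s: PL channel absent, deriving paw - pes", self.source_id)
            return self.paw - self.pes, "derived"
        raise ValidationError(
            f"{self.source_id or 'recording'}: no PL channel and no Pes to derive it"
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        n = len(self.time)
        if n < 1:
            raise ValidationError("recording has no samples")
        for name in self.channel_names():
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name} length differs from time")
        dt = np.diff(self.time)
        if n > 1:
            if not np.all(dt > 0):
                raise ValidationError("time is not strictly increasing")
            expected = 1.0 / self.sampling_hz
            if abs(float(np.median(dt)) - expected) > 0.01 * expected:
                raise ValidationError(
                    "median inter-sample interval disagrees with sampling rate"
                )
        if self.pl is not None and self.pes is not None and self.paw is not None:
            ok = np.abs(self.pl - (self.paw - self.pes)) <= 0.05
            if np.mean(ok) < 0.99:
                raise ValidationError("PL differs from paw - pes on > 1% of samples")

    def to_frame(self) -> pd.DataFrame:
        """Channels as a DataFrame in export column order."""
        return pd.DataFrame({name: getattr(self, name) for name in self.channel_names()})


@dataclass
class CRFTable:
    """Case-report-form table: participant id -> experiment start (seconds).

    ``datastart`` is the time at which the experiment started, measured from
    the start of the monitor recording.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not {"id", "datastart"} <= set(self.df.columns):
            raise FormatError("CRF must contain 'id' and 'datastart' columns")
        if self.df["id"].duplicated().any():
            dupes = self.df["id"][self.df["id"].duplicated()].tolist()
            raise ValidationError(f"duplicate participant ids in CRF: {dupes}")
        if (self.df["datastart"] < 0).any():
            raise ValidationError("datastart must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        for row in self.df.itertuples(index=False):
            yield str(row.id), float(row.datastart)

    def datastart_for(self, participant_id: str) -> float:
        sel = self.df.loc[self.df["id"] == participant_id, "datastart"]
        if sel.empty:
            raise KeyError(participant_id)
        return float(sel.iloc[0])


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _normalise_column(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.strip().lower())


def _detect_decimal(raw: pd.DataFrame) -> str:
    """Comma/dot detection on a sample of raw string cells."""
    sample = raw.head(200)
    has_comma = False
    for col in sample.columns:
        s = sample[col].dropna().astype(str)
        if s.str.contains(",", regex=False).any():
            has_comma = True
            if (s.str.contains(",", regex=False) & s.str.contains(".", regex=False)).any():
                return "dot"  # mixed separators: comma must be a thousands mark
    return "comma" if has_comma else "dot"


def _validate_time_grid(
    time: np.ndarray, sampling_hz: float, first_data_line: int
) -> np.ndarray:
    """Mask of samples consistent with a (nearly) uniform increasing grid.

    A sample is flagged when its step from the last accepted sample is not
    positive or exceeds 10 grid intervals — this catches corrupted stamps
    such as a decimal separator dropped during export, which still parse as
    numbers but jump off the grid.  ``first_data_line`` is the 1-based file
    line of the first sample, used for error reporting by the caller.
    """
    expected = 1.0 / sampling_hz
    ok = np.ones(time.size, dtype=bool)
    dt = np.diff(time)
    if time.size < 2 or (np.all(dt > 0) & np.all(dt <= 10 * expected)):
        return ok
    last_good = time[0]
    for i in range(1, time.size):
        step = time[i] - last_good
        if step <= 0 or step > 10 * expected:
            ok[i] = False
        else:
            last_good = time[i]
    return ok


def parse_signal_file(
    path: str | Path,
    dialect: DialectOptions | None = None,
    coerce: bool = False,
) -> SignalRecording:
    """Parse a FluxMed-style raw signal export.

    Parameters
    ----------
    path
        Signal file location.  The participant id is taken from the parent
        folder name, following the standardized project layout.
    dialect
        Delimiter / decimal-separator options; defaults to tab-separated
        with automatic decimal detection.
    coerce
        When True, rows with unparseable cells or off-grid time stamps are
        dropped (and logged) instead of raising :class:`ParseError`.
        Silent correction is deliberately not offered: a corrupt stamp may
        indicate an acquisition fault.

    Returns
    -------
    SignalRecording with ``sampling_hz`` read from the header.  Blank cells
    become NaN; the parser never invents values.
    """
    dialect = dialect or DialectOptions()
    path = Path(path)

    sampling_hz: float | None = None
    columns: list[str] | None = None
    n_skip = 0
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno > dialect.header_scan_limit:
                break
            m = _SAMPLING_RATE_RE.search(line)
            if m:
                sampling_hz = float(m.group(1).replace(",", "."))
            tokens = [t.strip() for t in line.rstrip("\n").split(dialect.delimiter)]
            if tokens and _normalise_column(tokens[0]) == "time":
                if sampling_hz is None:
                    raise FormatError(
                        f"{path}: no 'Sampling rate: N Hz' line before the column row"
                    )
                columns = [_normalise_column(t) for t in tokens]
                n_skip = lineno + 1  # the units row follows the column row
                break
    if sampling_hz is None:
        raise FormatError(f"{path}: no 'Sampling rate: N Hz' header line found")
    if columns is None:
        raise FormatError(f"{path}: no column row starting with 'Time' found")
    if "flow" not in columns:
        raise FormatError(f"{path}: column row lacks a Flow column")

    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        skiprows=n_skip,
        header=None,
        names=columns,
        dtype=str,
        engine="c",
    )
    if raw.empty:
        raise EmptyRecordingError(f"{path}: no data rows after the units row")

    decimal = dialect.decimal_separator
    if decimal == "auto":
        decimal = _detect_decimal(raw)

    first_data_line = n_skip + 1  # 1-based line number of the first sample
    data: dict[str, np.ndarray] = {}
    bad_rows = np.zeros(len(raw), dtype=bool)
    for col in columns:
        s = raw[col]
        stripped = s.str.strip() if s.dtype == object else s
        if decimal == "comma":
            stripped = stripped.str.replace(",", ".", regex=False)
        vals = pd.to_numeric(stripped, errors="coerce")
        bad = vals.isna() & s.notna() & (s.astype(str).str.strip() != "")
        if bad.any():
            if not coerce:
                idx = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: cannot parse {s.iloc[idx]!r} in column {col!r}",
                    line=first_data_line + idx,
                )
            bad_rows |= bad.to_numpy()
        data[col] = vals.to_numpy(dtype=float)

    if bad_rows.any():
        logger.warning(
            "%s: dropping %d rows with unparseable cells", path, int(bad_rows.sum())
        )
        data = {c: v[~bad_rows] for c, v in data.items()}

    if "time" in data:
        grid_ok = _validate_time_grid(data["time"], sampling_hz, first_data_line)
        if not grid_ok.all():
            if not coerce:
                idx = int(np.flatnonzero(~grid_ok)[0])
                raise ParseError(
                    f"{path}: time stamp {data['time'][idx]!r} breaks the "
                    f"{sampling_hz:g} Hz sample grid (corrupt decimal separator?)",
                    line=first_data_line + idx,
                )
            logger.warning(
                "%s: dropping %d rows with off-grid time stamps",
                path,
                int((~grid_ok).sum()),
            )
            data = {c: v[grid_ok] for c, v in data.items()}

    if len(data["time"]) < 1:
        raise EmptyRecordingError(f"{path}: all data rows were dropped")

    known = {name for name, _ in CHANNELS}
    kwargs = {c: v for c, v in data.items() if c in known}
    rec = SignalRecording(
        sampling_hz=sampling_hz,
        source_id=path.parent.name if path.parent.name not in ("", ".") else path.stem,
        **kwargs,
    )
    return rec


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_signal_file(
    rec: SignalRecording,
    path: str | Path,
    dialect: DialectOptions | None = None,
) -> Path:
    """Write a recording in the monitor's export dialect.

    The emitted file re-parses to a recording equal to ``rec`` channel-wise
    within 1e-6 per value.  ``decimal_separator="auto"`` writes commas, the
    dialect of the original system.
    """
    dialect = dialect or DialectOptions()
    path = Path(path)
    decimal = "," if dialect.decimal_separator in ("comma", "auto") else "."
    delim = dialect.delimiter

    names = rec.channel_names()
    units = dict(CHANNELS)
    rate = (
        f"{int(rec.sampling_hz)}" if float(rec.sampling_hz).is_integer()
        else f"{rec.sampling_hz:g}"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("FluxView - FluxMed acquisition system\n")
        fh.write("Signal file\n")
        fh.write("Serial Number\n")
        fh.write("SW version: plee | File version:1.15\n")
        fh.write(f"Sampling rate: {rate} Hz\n")
        fh.write(delim.join(_EXPORT_HEADER_NAMES[n] for n in names) + "\n")
        fh.write(delim.join(units[n] for n in names) + "\n")
        rec.to_frame().to_csv(
            fh,
            sep=delim,
            decimal=decimal,
            header=False,
            index=False,
            float_format="%.10g",
            na_rep="",
        )
    return path


# ---------------------------------------------------------------------------
# CRF and project layout
# ---------------------------------------------------------------------------


def parse_crf(path: str | Path) -> CRFTable:
    """Read the CRF table (CSV with at least ``id`` and ``datastart``)."""
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"id", "datastart"} <= set(df.columns):
        raise FormatError(f"{path}: CRF must have 'id' and 'datastart' columns")
    try:
        df["datastart"] = pd.to_numeric(df["datastart"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric datastart: {exc}") from exc
    df["id"] = df["id"].astype(str).str.strip()
    return CRFTable(df[["id", "datastart"]].reset_index(drop=True))


def discover_participants(
    project_root: str | Path, signal_filename: str = "signals.txt"
) -> list[tuple[str, Path]]:
    """Find per-participant signal files in the standardized project layout.

    Each participant has a dedicated folder named after their id, holding a
    raw signal export.  Folders without one are skipped with a warning.
    Entries come back in lexicographic folder order, so repeated runs over
    the same tree are deterministic.
    """
    root = Path(project_root)
    if not root.is_dir():
        raise FileNotFoundError(f"project root {root} does not exist")
    entries: list[tuple[str, Path]] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        candidate = sub / signal_filename
        if candidate.is_file():
            entries.append((sub.name, candidate))
        else:
            logger.warning("skipping %s: no %s", sub, signal_filename)
    return entries


def channel_activity(rec: SignalRecording, zero_fraction: float = 0.99) -> dict[str, str]:
    """Classify each present channel as active or inactive.

    A channel recorded while its sensor was not connected reads (almost)
    exactly zero; such channels are preserved as recorded but flagged here
    so downstream analyses do not mistake them for real signals.
    """
    report: dict[str, str] = {}
    for name in rec.channel_names():
        if name == "time":
            continue
        values = getattr(rec, name)
        frac_zero = float(np.mean(values == 0)) if len(values) else 1.0
        report[name] = "inactive" if frac_zero > zero_fraction else "active"
        logger.info("channel %s: %s (%.1f%% zero samples)", name, report[name], 100 * frac_zero)
    return report


def example_recording() -> SignalRecording:
    """The 13-sample documentation excerpt, parsed (see EXAMPLE_SIGNALS_TEXT)."""
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".txt", delete=False, encoding="utf-8"
    ) as fh:
        fh.write(EXAMPLE_SIGNALS_TEXT)
        name = fh.name
    try:
        return parse_signal_file(name)
    finally:
        Path(name).unlink(missing_ok=True)
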