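"""Reading and writing signal files and trial tables.

Native signal dialect: UTF-8 text, ``# key=value`` header lines followed by
one amplitude per line.  ``fs`` is the one mandatory header key; optional keys
are ``channel``, ``subject`` and the protocol triple ``current_mA``,
``frequency_Hz``, ``pulse_width_us`` (all three or none).  Amplitudes are
written with ``repr`` so write→read round-trips bit-exactly.

Trial tables are CSV with header
``subject_id,kind,path,current_mA,frequency_Hz,pulse_width_us`` where ``kind``
is ``voluntary`` or ``fes``; fes rows must carry a complete protocol.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SignalRecord, StimulationProtocol
from .exceptions import FormatError, InvalidSpecError

__all__ = ["read_signal", "write_signal", "TrialRow", "TrialTable",
           "read_trial_table", "write_trial_table"]

_PROTOCOL_KEYS = ("current_mA", "frequency_Hz", "pulse_width_us")
TRIAL_TABLE_COLUMNS = ["subject_id", "kind", "path",
                       "current_mA", "frequency_Hz", "pulse_width_us"]


def write_signal(record: SignalRecord, path) -> None:
    """Write ``record`` to ``path`` in the native text dialect."""
    if record.samples.size == 0:  # SignalRecord forbids this, but be defensive
        raise InvalidSpecError("cannot write a record with no samples")
    lines = [f"# fs={record.sampling_rate!r}",
             f"# channel={record.channel_label}"]
    if record.subject_id is not None:
        lines.append(f"# subject={record.subject_id}")
    if record.protocol is not None:
        p = record.protocol
        lines.append(f"# current_mA={p.current_amplitude!r}")
        lines.append(f"# frequency_Hz={p.frequency!r}")
        lines.append(f"# pulse_width_us={p.pulse_width!r}")
    lines.extend(repr(float(x)) for x in record.samples)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_signal(path) -> SignalRecord:
    """Parse a native-dialect signal file into a :class:`SignalRecord`."""
    header: dict[str, str] = {}
    samples: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, value = body.split("=", 1)
                header[key.strip()] = value.strip()
            else:
                try:
                    samples.append(float(line))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric sample {line!r}"
                    ) from None
    if "fs" not in header:
        raise FormatError(f"{path}: missing mandatory 'fs' header")
    try:
        fs = float(header["fs"])
    except ValueError:
        raise FormatError(f"{path}: non-numeric fs={header['fs']!r}") from None
    if fs <= 0:
        raise FormatError(f"{path}: sampling rate must be positive, got {fs}")
    if not samples:
        raise FormatError(f"{path}: file contains no samples")

    protocol = None
    present = [k for k in _PROTOCOL_KEYS if k in header]
    if present:
        if len(present) != len(_PROTOCOL_KEYS):
            missing = sorted(set(_PROTOCOL_KEYS) - set(present))
            raise FormatError(f"{path}: incomplete protocol header, missing {missing}")
        try:
            protocol = StimulationProtocol(
                current_amplitude=float(header["current_mA"]),
                frequency=float(header["frequency_Hz"]),
                pulse_width=float(header["pulse_width_us"]),
            )
        except (ValueError, InvalidSpecError) as exc:
            raise FormatError(f"{path}: invalid protocol header ({exc})") from exc

    return SignalRecord(
        samples=np.asarray(samples, dtype=np.float64),
        sampling_rate=fs,
        channel_label=header.get("channel", "EMG"),
        protocol=protocol,
        subject_id=header.get("subject"),
    )


@dataclass(frozen=True)
class TrialRow:
    """One trial-table row: where a trial's signal lives and how it was run."""

    subject_id: str
    kind: str  # "voluntary" | "fes"
    path: str
    protocol: StimulationProtocol | None = None


@dataclass
class TrialTable:
    """Validated collection of trial rows."""

    rows: list[TrialRow]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def voluntary(self) -> list[TrialRow]:
        return [r for r in self.rows if r.kind == "voluntary"]

    def fes(self) -> list[TrialRow]:
        return [r for r in self.rows if r.kind == "fes"]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            p = r.protocol
            recs.append({
                "subject_id": r.subject_id, "kind": r.kind, "path": r.path,
                "current_mA": p.current_amplitude if p else np.nan,
                "frequency_Hz": p.frequency if p else np.nan,
                "pulse_width_us": p.pulse_width if p else np.nan,
            })
        return pd.DataFrame(recs, columns=TRIAL_TABLE_COLUMNS)


def write_trial_table(table: TrialTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_trial_table(path) -> TrialTable:
    """Read and validate a trial-table CSV."""
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty trial table")
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "kind": str, "path": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: unreadable trial table ({exc})") from exc
    missing = [c for c in ("subject_id", "kind", "path") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: trial table has no rows")

    rows: list[TrialRow] = []
    for idx, row in df.iterrows():
        kind = str(row["kind"]).strip().lower()
        if kind not in ("voluntary", "fes"):
            raise FormatError(f"{path}: row {idx}: unknown trial kind {row['kind']!r}")
        protocol = None
        if kind == "fes":
            vals = [row.get(k, np.nan) for k in _PROTOCOL_KEYS]
            if any(pd.isna(v) for v in vals):
                raise FormatError(
                    f"{path}: row {idx}: fes trial missing protocol fields"
                )
            try:
                protocol = StimulationProtocol(*[float(v) for v in vals])
            except InvalidSpecError as exc:
                raise FormatError(f"{path}: row {idx}: {exc}") from exc
        rows.append(TrialRow(subject_id=str(row["subject_id"]), kind=kind,
                             path=str(row["path"]), protocol=protocol))
    return TrialTable(rows=rows)
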