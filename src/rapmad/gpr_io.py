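"""Reading and writing GenePix Result (GPR) tables in the ATF dialect.

A GPR file is an Axon Text File: a first line ``ATF<tab>1.0``, a second line
with the number of optional header records and of data columns, the quoted
``"Key=Value"`` header records, a quoted column-name row, and tab-separated
data rows.  Each data row quantifies one spot; the intensity used downstream
is the mean foreground intensity of the scan channel, without background
subtraction.  Windows and Unix line endings are both accepted and header
fields are stored verbatim.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from rapmad.errors import ConfigError, DataError, FormatError

log = logging.getLogger(__name__)

#: Default intensity columns: 635 nm incubation scan, 532 nm scatterlight scan.
DEFAULT_INTENSITY_COLUMN = "F635 Mean"
DEFAULT_SCATTERLIGHT_COLUMN = "F532 Mean"

#: Prefix applied to scatterlight columns when joined onto an incubation table.
SCATTERLIGHT_PREFIX = "SL "

_ID_COLUMNS = {"Block", "Row", "Column", "ID", "Name", "Flags"}


@dataclass
class SpotRecord:
    """One quantified spot."""

    block_id: int
    row_in_block: int
    col_in_block: int
    peptide_id: str
    raw_intensity: float
    flag: int = 0
    sequence: Optional[str] = None
    extra_features: dict = field(default_factory=dict)


class SpotTable:
    """A quantified slide scan: one record per spot plus the ATF header.

    Backed by a DataFrame with canonical columns ``block``, ``row``, ``col``,
    ``peptide_id``, ``raw_intensity``, ``flag`` (and ``sequence`` when the
    source had a Name column) followed by the remaining numeric result-file
    columns, preserved under their original names.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        channel: str = "635",
        header: Optional[dict] = None,
        intensity_column: str = DEFAULT_INTENSITY_COLUMN,
    ):
        required = {"block", "row", "col", "peptide_id", "raw_intensity", "flag"}
        missing = required - set(data.columns)
        if missing:
            raise DataError(f"SpotTable frame missing columns {sorted(missing)}")
        if (data["raw_intensity"] < 0).any():
            raise DataError("raw_intensity must be non-negative")
        dup = data.duplicated(subset=["block", "row", "col"])
        if dup.any():
            first = data.loc[dup.idxmax(), ["block", "row", "col"]]
            raise DataError(
                "duplicate spot address (block={}, row={}, col={})".format(*first.tolist())
            )
        self.data = data.reset_index(drop=True)
        self.channel = channel
        self.header = dict(header or {})
        self.intensity_column = intensity_column

    @property
    def extra_columns(self) -> list[str]:
        skip = {"block", "row", "col", "peptide_id", "sequence", "raw_intensity", "flag"}
        return [c for c in self.data.columns if c not in skip]

    @property
    def n_features(self) -> int:
        """Intensity plus extra feature columns."""
        return 1 + len(self.extra_columns)

    @property
    def records(self) -> list[SpotRecord]:
        extras = self.extra_columns
        has_seq = "sequence" in self.data.columns
        out = []
        for rec in self.data.itertuples(index=False):
            d = rec._asdict()
            out.append(
                SpotRecord(
                    block_id=int(d["block"]),
                    row_in_block=int(d["row"]),
                    col_in_block=int(d["col"]),
                    peptide_id=str(d["peptide_id"]),
                    raw_intensity=float(d["raw_intensity"]),
                    flag=int(d["flag"]),
                    sequence=(str(d["sequence"]) if has_seq and not pd.isna(d["sequence"]) else None),
                    extra_features={c: d[c] for c in extras},
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.data)

    def addresses(self) -> set[tuple[int, int, int]]:
        return set(zip(self.data["block"].astype(int), self.data["row"].astype(int), self.data["col"].astype(int)))


def _split_atf(text: str) -> tuple[dict, list[str], str]:
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty ATF source")
    first = lines[0].strip().split("\t")
    if len(first) < 2 or first[0].upper() != "ATF":
        raise FormatError(f"not an ATF file (first line {lines[0]!r})")
    if len(lines) < 3:
        raise FormatError("truncated ATF file")
    try:
        n_header, n_cols = (int(tok) for tok in lines[1].strip().split("\t")[:2])
    except ValueError as e:
        raise FormatError(f"malformed ATF count line {lines[1]!r}") from e
    if len(lines) < 2 + n_header + 1:
        raise FormatError("ATF header longer than file")
    header = {}
    for raw in lines[2 : 2 + n_header]:
        entry = raw.strip().strip('"')
        key, _, value = entry.partition("=")
        header[key] = value
    col_line = lines[2 + n_header]
    columns = [c.strip().strip('"') for c in col_line.split("\t")]
    if len(columns) != n_cols:
        log.warning("ATF declares %d columns, found %d", n_cols, len(columns))
    body = "\n".join(lines[3 + n_header :])
    return header, columns, body


def read_gpr(
    source: Union[str, os.PathLike, io.TextIOBase],
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
    channel: Optional[str] = None,
) -> SpotTable:
    """Parse a GPR/ATF file into a :class:`SpotTable`.

    ``raw_intensity`` is taken from ``intensity_column``; every other numeric
    column is preserved as an extra feature.  Non-numeric columns besides the
    identifiers (Block, Row, Column, ID, Name) are dropped with a notice.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        with open(source, "r", newline="") as fh:
            text = fh.read()
    header, columns, body = _split_atf(text)
    required = {"Block", "Row", "Column", "ID"}
    missing = required - set(columns)
    if missing:
        raise FormatError(f"GPR table lacks required columns {sorted(missing)}")
    if intensity_column not in columns:
        raise ConfigError(f"intensity column {intensity_column!r} not in file columns")
    df = pd.read_csv(io.StringIO(body), sep="\t", names=columns, quotechar='"') if body.strip() else pd.DataFrame(columns=columns)

    rename = {"Block": "block", "Row": "row", "Column": "col", "ID": "peptide_id"}
    out = pd.DataFrame(
        {
            "block": df["Block"].astype(int) if len(df) else pd.Series(dtype=int),
            "row": df["Row"].astype(int) if len(df) else pd.Series(dtype=int),
            "col": df["Column"].astype(int) if len(df) else pd.Series(dtype=int),
            "peptide_id": df["ID"].astype(str) if len(df) else pd.Series(dtype=str),
        }
    )
    if "Name" in columns:
        out["sequence"] = df["Name"].astype(str) if len(df) else pd.Series(dtype=str)
    out["raw_intensity"] = pd.to_numeric(df[intensity_column], errors="raise") if len(df) else pd.Series(dtype=float)
    if "Flags" in columns:
        out["flag"] = df["Flags"].astype(int) if len(df) else pd.Series(dtype=int)
    else:
        out["flag"] = 0
    for c in columns:
        if c in rename or c in ("Name", "Flags") or c == intensity_column:
            continue
        series = pd.to_numeric(df[c], errors="coerce") if len(df) else pd.Series(dtype=float)
        if len(df) and series.isna().all() and not df[c].isna().all():
            log.info("dropping non-numeric GPR column %r", c)
            continue
        out[c] = series
    if channel is None:
        digits = "".join(ch for ch in intensity_column if ch.isdigit())
        channel = digits or "unknown"
    return SpotTable(out, channel=channel, header=header, intensity_column=intensity_column)


def _fmt(value) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    f = float(value)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def write_gpr(table: SpotTable, destination: Union[str, os.PathLike, io.TextIOBase]) -> None:
    """Emit an ATF 1.0 file readable by :func:`read_gpr`.

    Column order is deterministic: Block, Row, Column, ID, (Name), Flags,
    the intensity column, then extra features in table order.  Floats are
    written in shortest round-trip representation, so read(write(t))
    reproduces the intensities bit-exactly.
    """
    cols = ["Block", "Row", "Column", "ID"]
    frame = {
        "Block": table.data["block"],
        "Row": table.data["row"],
        "Column": table.data["col"],
        "ID": table.data["peptide_id"],
    }
    if "sequence" in table.data.columns:
        cols.append("Name")
        frame["Name"] = table.data["sequence"]
    cols.append("Flags")
    frame["Flags"] = table.data["flag"]
    cols.append(table.intensity_column)
    frame[table.intensity_column] = table.data["raw_intensity"]
    for c in table.extra_columns:
        cols.append(c)
        frame[c] = table.data[c]

    lines = ["ATF\t1.0"]
    lines.append(f"{len(table.header)}\t{len(cols)}")
    for k, v in table.header.items():
        lines.append(f'"{k}={v}"')
    lines.append("\t".join(f'"{c}"' for c in cols))
    for i in range(len(table)):
        row = []
        for c in cols:
            v = frame[c].iloc[i]
            if c in ("Block", "Row", "Column", "Flags"):
                row.append(str(int(v)))
            elif c in ("ID", "Name"):
                row.append(str(v))
            else:
                row.append(_fmt(v))
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if isinstance(destination, io.TextIOBase):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def join_scans(incubation: SpotTable, scatterlight: SpotTable) -> SpotTable:
    """Append scatterlight QC features to the incubation table, per spot.

    The scatterlight intensity and extra columns are added under the
    ``SL `` prefix; the incubation intensity is retained.  Both tables must
    cover exactly the same spot addresses.
    """
    a, b = incubation.addresses(), scatterlight.addresses()
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise DataError(f"scan address sets differ at {diff[:10]}{'...' if len(diff) > 10 else ''}")
    keys = ["block", "row", "col"]
    sl = scatterlight.data[keys + ["raw_intensity"] + scatterlight.extra_columns].rename(
        columns={
            "raw_intensity": SCATTERLIGHT_PREFIX + scatterlight.intensity_column,
            **{c: SCATTERLIGHT_PREFIX + c for c in scatterlight.extra_columns},
        }
    )
    merged = incubation.data.merge(sl, on=keys, how="left", validate="one_to_one")
    return SpotTable(
        merged,
        channel=incubation.channel,
        header=incubation.header,
        intensity_column=incubation.intensity_column,
    )
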