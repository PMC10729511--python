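"""File I/O: wide-CSV spectra matrices, long-form reference tables, JCAMP-DX.

The canonical on-disk spectra format is a wide CSV: first column
``wavenumber_cm-1``, remaining column headers the acquisition times in
decimal hours, numeric body. Reference tables are long-form CSV with columns
``time_h, analyte, units, value``. JCAMP-DX (single block, AFFN-encoded
XYDATA or XYPOINTS) is supported read-only as the common exchange format for
single FT spectra.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .spectra import ReferenceTable, SpectraSet, Spectrum

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "read_jcamp",
]

WAVENUMBER_HEADER = "wavenumber_cm-1"


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide-format spectra matrix.

    The axis is stored descending regardless of file order; an ascending
    file is flipped (rows reversed consistently with the axis).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        ncol = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != ncol or any(c.strip() == "" for c in cells):
                raise FormatError(
                    f"{path.name} line {lineno}: expected {ncol} numeric cells, got "
                    f"{len([c for c in cells if c.strip() != ''])}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: non-numeric cell ({exc})") from None
    if header[0] != WAVENUMBER_HEADER:
        raise FormatError(
            f"first column header must be {WAVENUMBER_HEADER!r}, got {header[0]!r}"
        )
    try:
        times = np.array([float(h) for h in header[1:]], dtype=float)
    except ValueError:
        raise FormatError("time column headers must be decimal hours") from None
    if np.unique(times).size != times.size:
        raise ValidationError("duplicate acquisition-time headers")
    if times.size >= 2 and np.any(np.diff(times) < 0):
        raise ValidationError("acquisition-time headers must be non-decreasing")
    body = np.asarray(rows, dtype=float)
    if body.size == 0:
        raise FormatError(f"{path.name}: no data rows")
    wavenumbers = body[:, 0]
    intensities = body[:, 1:].T  # (n_spectra, n_channels)
    return SpectraSet(wavenumbers, intensities, times)


def write_spectra_csv(s: SpectraSet, path, precision: int = 10) -> None:
    """Write the wide CSV; round-trips with :func:`read_spectra_csv` at
    the declared precision."""
    path = Path(path)
    fmt = f"%.{precision}g"
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(WAVENUMBER_HEADER + "," + ",".join(fmt % t for t in s.times) + "\n")
        for j in range(s.n_channels):
            row = [fmt % s.wavenumbers[j]] + [fmt % v for v in s.intensities[:, j]]
            fh.write(",".join(row) + "\n")


def read_reference_csv(path) -> ReferenceTable:
    """Read a long-form reference table (time_h, analyte, units, value).

    An empty value cell marks a missing measurement.
    """
    df = pd.read_csv(path, dtype={"analyte": str, "units": str})
    required = {"time_h", "analyte", "units", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"reference CSV needs columns {sorted(required)}, got {list(df.columns)}")
    units_per = df.groupby("analyte")["units"].nunique()
    if (units_per > 1).any():
        bad = units_per[units_per > 1].index.tolist()
        raise ValidationError(f"inconsistent units for analytes: {bad}")
    wide = df.pivot_table(index="time_h", columns="analyte", values="value", aggfunc="first")
    analytes = list(wide.columns)
    units = [df.loc[df["analyte"] == a, "units"].iloc[0] for a in analytes]
    return ReferenceTable(
        timepoints=wide.index.to_numpy(dtype=float),
        analytes=analytes,
        units=units,
        values=wide.to_numpy(dtype=float),
    )


def write_reference_csv(ref: ReferenceTable, path) -> None:
    records = []
    for i, tp in enumerate(ref.timepoints):
        for j, analyte in enumerate(ref.analytes):
            v = ref.values[i, j]
            records.append(
                {
                    "time_h": tp,
                    "analyte": analyte,
                    "units": ref.units[j],
                    "value": "" if not np.isfinite(v) else v,
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# --- JCAMP-DX -------------------------------------------------------------
#
# Minimal single-block reader for AFFN (plain decimal) XYDATA / XYPOINTS.
# Compressed encodings (SQZ/DIF/DUP) are out of scope.

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")

_X_TO_CM1 = {
    "1/CM": lambda x: x,
    "CM-1": lambda x: x,
    "CM^-1": lambda x: x,
    "MICROMETERS": lambda x: 1e4 / x,
    "NANOMETERS": lambda x: 1e7 / x,
}


def _parse_numbers(text: str) -> list[float]:
    # AFFN numbers separated by spaces, commas or semicolons; exponents allowed
    toks = re.split(r"[,;\s]+", text.strip())
    return [float(t) for t in toks if t]


def read_jcamp(path) -> Spectrum:
    """Read a single-block JCAMP-DX file into a :class:`Spectrum`.

    The x axis is converted to cm^-1 when XUNITS declares micrometers or
    nanometers. FIRSTX/LASTX/NPOINTS consistency is enforced for XYDATA.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # 'XYDATA' | 'XYPOINTS'
    in_data = False
    n_titles = 0
    for raw in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            val = m.group(2).strip()
            if key == "TITLE":
                n_titles += 1
                if n_titles > 1:
                    raise FormatError("multi-block JCAMP-DX files are not supported")
            if key in ("XYDATA", "XYPOINTS"):
                mode = key
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            in_data = False
            labels[key] = val
        elif in_data:
            data_lines.append(line)
    if mode is None:
        raise FormatError("no XYDATA or XYPOINTS block found")
    if "BLOCKS" in labels:
        raise FormatError("multi-block JCAMP-DX files are not supported")

    xfactor = float(labels.get("XFACTOR", 1.0))
    yfactor = float(labels.get("YFACTOR", 1.0))
    xunits = labels.get("XUNITS", "1/CM").upper().replace(" ", "")
    convert = _X_TO_CM1.get(xunits)
    if convert is None:
        raise FormatError(f"unsupported XUNITS {labels.get('XUNITS')!r}")

    if mode == "XYPOINTS":
        nums = [v for line in data_lines for v in _parse_numbers(line)]
        if len(nums) % 2:
            raise FormatError("XYPOINTS block has an odd number of values")
        x = np.array(nums[0::2]) * xfactor
        y = np.array(nums[1::2]) * yfactor
    else:  # XYDATA, (X++(Y..Y)) layout: each line starts with an x value
        for key in ("FIRSTX", "LASTX", "NPOINTS"):
            if key not in labels:
                raise FormatError(f"XYDATA requires the {key} label")
        npoints = int(float(labels["NPOINTS"]))
        ys: list[float] = []
        for line in data_lines:
            nums = _parse_numbers(line)
            if not nums:
                continue
            ys.extend(nums[1:])  # leading value is the line's x checkpoint
        if len(ys) != npoints:
            raise FormatError(f"NPOINTS={npoints} but {len(ys)} ordinates were read")
        # FIRSTX/LASTX are in actual units; table x checkpoints are raw values
        # to be multiplied by XFACTOR.
        firstx, lastx = float(labels["FIRSTX"]), float(labels["LASTX"])
        first_raw = _parse_numbers(data_lines[0])[0] * xfactor
        spacing = abs(lastx - firstx) / max(npoints - 1, 1)
        if abs(first_raw - firstx) > max(spacing, 1e-6 * max(abs(firstx), 1.0)):
            raise FormatError(
                f"FIRSTX={firstx} inconsistent with first data checkpoint {first_raw}"
            )
        x = np.linspace(firstx, lastx, npoints)
        y = np.asarray(ys) * yfactor
    if mode == "XYPOINTS" and "NPOINTS" in labels and int(float(labels["NPOINTS"])) != x.size:
        raise FormatError(f"NPOINTS={labels['NPOINTS']} but {x.size} points were read")
    return Spectrum(convert(x), y)
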