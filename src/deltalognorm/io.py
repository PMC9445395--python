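"""One-column CSV input/output, the package's data interchange format.

A sample is stored as a single numeric column, optionally headed by a
label line (conventionally ``y``), comma-free, "." decimal, UTF-8.  Zeros
are preserved exactly; blank lines are skipped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_values", "write_values"]


def read_values(path: str | Path, has_header: bool = True) -> np.ndarray:
    """Read a one-column file of nonnegative values.

    Parameters
    ----------
    path : str or Path
    has_header : bool
        Skip the first non-blank line.

    Raises
    ------
    ValueError
        On a negative or non-numeric cell (naming the 1-based line number)
        or an empty file.
    """
    values: list[float] = []
    skipped_header = not has_header
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            cell = raw.strip()
            if not cell:
                continue
            if not skipped_header:
                skipped_header = True
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} on line {lineno}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}: negative value {v} on line {lineno}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no data values found")
    return np.asarray(values, dtype=float)


def write_values(path: str | Path, values, header: str | None = "y") -> None:
    """Write values as a one-column CSV, with an optional header line."""
    y = np.asarray(values, dtype=float).ravel()
    with open(path, "w", encoding="utf-8") as fh:
        if header is not None:
            fh.write(header + "\n")
        for v in y:
            fh.write(np.format_float_positional(v, trim="-") + "\n")
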