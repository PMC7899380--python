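"""Reading lifetime samples from plain-text and single-column CSV files."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .distribution import Sample
from .exceptions import DataValidationError

__all__ = ["read_sample"]


def read_sample(path) -> Sample:
    """Read a Sample from a one-value-per-line text file or a single-column
    CSV (a non-numeric first line is treated as a header).

    Blank lines are skipped.  Non-numeric tokens raise a parse error naming
    the line; non-positive values raise a validation error listing them.
    """
    p = Path(path)
    values: list[float] = []
    bad_lines: list[tuple[int, str]] = []
    with p.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip().rstrip(",")
            if not token:
                continue
            # tolerate a unicode minus from copy-pasted tables
            token = token.replace("−", "-")
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1 and not bad_lines:
                    continue  # CSV header
                bad_lines.append((lineno, token))
    if bad_lines:
        loc = "; ".join(f"line {ln}: {tok!r}" for ln, tok in bad_lines[:5])
        raise DataValidationError(f"non-numeric tokens in {p}: {loc}")
    if not values:
        raise DataValidationError(f"no numeric data found in {p}")
    arr = np.asarray(values)
    if np.any(arr <= 0):
        offenders = [
            f"line-order index {i + 1}: value {v}" for i, v in enumerate(arr) if v <= 0
        ][:5]
        raise DataValidationError(
            f"lifetimes must be > 0 in {p}: " + "; ".join(offenders)
        )
    return Sample(arr)
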