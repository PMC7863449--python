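"""CSV batch input and output.

Input format, one matrix per row::

    name,tp,fn,fp,tn
    classifier_a,100,1,5000,94900

Counts must be non-negative integers.  A relative-matrix file carries a
first comment line ``# relative=true`` and proportions instead of
counts.  Output panels serialize UNDEFINED as the literal string
``undefined``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .fixtures import NamedClassifierResult
from .matrix import ConfusionMatrix, RelativeConfusionMatrix
from .types import format_value

__all__ = ["read_matrices_csv", "write_panels_csv", "PANEL_COLUMNS"]

_INPUT_COLUMNS = ["name", "tp", "fn", "fp", "tn"]
PANEL_COLUMNS = _INPUT_COLUMNS + [
    "tpr", "tnr", "ppv", "npv", "mcc", "ba", "bm", "mk", "accuracy", "f1",
]

MatrixLike = Union[ConfusionMatrix, RelativeConfusionMatrix]


def _is_relative(path: Path) -> bool:
    with path.open() as handle:
        first = handle.readline().strip().lower()
    return first.startswith("#") and "relative=true" in first.replace(" ", "")


def read_matrices_csv(path) -> list[tuple[str, MatrixLike]]:
    """Read named matrices from CSV; count or relative format.

    Count files are validated strictly: negative or non-integer entries
    are rejected.
    """
    path = Path(path)
    relative = _is_relative(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _INPUT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: list[tuple[str, MatrixLike]] = []
    for row in frame.itertuples(index=False):
        cells = (row.tp, row.fn, row.fp, row.tn)
        if relative:
            matrix: MatrixLike = RelativeConfusionMatrix(*map(float, cells))
        else:
            for value in cells:
                if float(value) != int(value):
                    raise ValueError(
                        f"{path}: count matrix {row.name!r} has non-integer entry {value!r}"
                    )
            matrix = ConfusionMatrix(*(int(v) for v in cells))
        out.append((str(row.name), matrix))
    return out


def write_panels_csv(results: Sequence[NamedClassifierResult], path,
                     precision: int | None = None) -> None:
    """Write matrices and full metric panels, UNDEFINED as ``undefined``.

    With ``precision=None`` metric values are written at full double
    precision; otherwise rounded for display.
    """
    rows = []
    for result in results:
        row: dict[str, object] = {"name": result.name}
        row.update(zip(("tp", "fn", "fp", "tn"), result.cm.as_tuple()))
        for key in PANEL_COLUMNS[5:]:
            row[key] = format_value(result.panel[key], precision)
        rows.append(row)
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)
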