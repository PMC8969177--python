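"""Plate and electrode geometry for the two supported multiwell MEA layouts.

Two commercial plate formats are modelled: a 12-well plate with 64 recording
electrodes per well (8x8 grid) used for developmental time-point recordings,
and a 48-well plate with 16 electrodes per well (4x4 grid) used for
pharmacology.  Wells are labelled row-letter + column-number (``A1`` ... ``C4``
for the 3x4 12-well plate, ``A1`` ... ``F8`` for the 6x8 48-well plate);
electrodes are two-digit row-column strings (``11`` ... ``88`` or ``11`` ...
``44``).
"""

from __future__ import annotations

import string

PLATE_TYPES = (12, 48)

#: (rows, columns) of wells per plate type
_WELL_GRID = {12: (3, 4), 48: (6, 8)}
#: electrodes per well arranged on a square grid
_ELECTRODE_GRID = {12: 8, 48: 4}


def wells_for_plate(plate_type: int) -> list[str]:
    """Return all well labels of a plate type in row-major order."""
    _check_plate_type(plate_type)
    n_rows, n_cols = _WELL_GRID[plate_type]
    rows = string.ascii_uppercase[:n_rows]
    return [f"{r}{c}" for r in rows for c in range(1, n_cols + 1)]


def electrodes_for_plate(plate_type: int) -> list[str]:
    """Return all electrode labels of one well, row-major (``"11"`` first)."""
    _check_plate_type(plate_type)
    n = _ELECTRODE_GRID[plate_type]
    return [f"{r}{c}" for r in range(1, n + 1) for c in range(1, n + 1)]


def electrodes_per_well(plate_type: int) -> int:
    _check_plate_type(plate_type)
    return _ELECTRODE_GRID[plate_type] ** 2


def electrode_position(electrode: str) -> tuple[int, int]:
    """(row, column) grid position of an electrode label, 0-based."""
    if len(electrode) != 2 or not electrode.isdigit():
        raise ValueError(f"malformed electrode label {electrode!r}")
    return int(electrode[0]) - 1, int(electrode[1]) - 1


def validate_well(well: str, plate_type: int) -> None:
    if well not in wells_for_plate(plate_type):
        raise ValueError(f"well {well!r} is not valid for a {plate_type}-well plate")


def validate_electrode(electrode: str, plate_type: int) -> None:
    if electrode not in electrodes_for_plate(plate_type):
        raise ValueError(
            f"electrode {electrode!r} is not valid for a {plate_type}-well plate"
        )


def _check_plate_type(plate_type: int) -> None:
    if plate_type not in PLATE_TYPES:
        raise ValueError(f"plate_type must be one of {PLATE_TYPES}, got {plate_type!r}")
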