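"""Geometry of ICES statistical rectangles.

The ICES grid tiles the North-East Atlantic and adjacent seas with cells of
0.5 degrees latitude by 1 degree longitude.  A rectangle code is a two-digit
row, a column letter and a column digit, e.g. ``"44G6"``:

* rows are numbered ``01``, ``02``, ... northwards, row 01 spanning
  36.0-36.5 degrees N (so row 44 spans 57.5-58.0 degrees N);
* columns run eastwards from 44 degrees W in 10-degree letter blocks
  ``B0``-``B9`` (40-30 W), ``C0``-``C9`` (30-20 W), ..., each digit one
  degree wide.  The first block ``A0``-``A3`` is truncated to 44-40 W, and
  the letter ``I`` is skipped to avoid confusion with ``1``.

Only the centre coordinates of cells are used throughout the package: survey
quantities are reported per rectangle, with no within-cell positioning.
"""

from __future__ import annotations

import math
import re

from seascape.errors import RectangleCodeError

#: Column letters in grid order; ``I`` is unused by the coding standard.
COLUMN_LETTERS = "ABCDEFGHJKLM"

_CODE_RE = re.compile(r"([0-9]{2})([A-HJ-M])([0-9])")

#: Latitude of the southern edge of row 01.
_LAT_ORIGIN = 36.0


def rect_to_centre(code: str) -> tuple[float, float]:
    """Return the (lat, lon) centre of an ICES statistical rectangle.

    Parameters
    ----------
    code
        Rectangle code such as ``"44G6"``.  Case-insensitive; surrounding
        whitespace is ignored.

    Returns
    -------
    (lat, lon)
        Centre of the 0.5 x 1 degree cell, degrees N / degrees E.

    Raises
    ------
    RectangleCodeError
        If the code is malformed (wrong pattern, letter ``I``, row 00, or a
        digit outside the truncated ``A`` block).

    Examples
    --------
    >>> rect_to_centre("44G6")
    (57.75, 16.5)
    """
    if not isinstance(code, str):
        raise RectangleCodeError(f"rectangle code must be a string, got {code!r}")
    m = _CODE_RE.fullmatch(code.strip().upper())
    if m is None:
        raise RectangleCodeError(
            f"{code!r} is not a valid ICES rectangle code "
            "(expected two-digit row + column letter (no 'I') + digit)"
        )
    row = int(m.group(1))
    if row < 1:
        raise RectangleCodeError(f"{code!r}: row must be 01 or greater")
    letter, digit = m.group(2), int(m.group(3))
    idx = COLUMN_LETTERS.index(letter)
    if idx == 0:
        # A block is truncated: A0..A3 cover 44W..40W.
        if digit > 3:
            raise RectangleCodeError(f"{code!r}: column A only spans A0-A3 (44-40 W)")
        lon_west = -44.0 + digit
    else:
        lon_west = (idx - 5) * 10.0 + digit
    lat_south = _LAT_ORIGIN + (row - 1) * 0.5
    return lat_south + 0.25, lon_west + 0.5


def centre_to_rect(lat: float, lon: float) -> str:
    """Return the code of the rectangle containing the point (lat, lon).

    Inverse of :func:`rect_to_centre` on cell centres; any interior point of
    a cell maps to that cell's code.
    """
    row = math.floor((lat - _LAT_ORIGIN) / 0.5) + 1
    if not 1 <= row <= 99:
        raise RectangleCodeError(f"latitude {lat} outside the ICES grid")
    lon_west = math.floor(lon)
    if -44 <= lon_west <= -41:
        letter, digit = "A", lon_west + 44
    elif -40 <= lon_west <= 69:
        idx = (lon_west + 50) // 10
        letter = COLUMN_LETTERS[idx]
        digit = lon_west - (idx - 5) * 10
    else:
        raise RectangleCodeError(f"longitude {lon} outside the ICES grid")
    return f"{row:02d}{letter}{digit}"


def is_valid_rect(code: str) -> bool:
    """True if ``code`` parses as an ICES rectangle code."""
    try:
        rect_to_centre(code)
    except RectangleCodeError:
        return False
    return True
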