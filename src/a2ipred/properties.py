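"""The six RNA dinucleotide step parameters and their standardization.

Each of the 16 RNA dinucleotide steps carries three translational
descriptors (Shift, Slide, Rise; nm) and three angular descriptors
(Tilt, Roll, Twist; degrees). Before entering the encoder's correlation
function, each property column is z-scored over the 16 dinucleotides so
that all six contribute on a common scale with zero mean.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Fixed lexicographic dinucleotide order (A < C < G < U); frozen because
#: feature-vector layout and model serialization depend on it.
DINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b for a in "ACGU" for b in "ACGU"
)
DINUC_INDEX: dict[str, int] = {d: i for i, d in enumerate(DINUCLEOTIDES)}

PROPERTY_NAMES: tuple[str, ...] = ("Shift", "Slide", "Rise", "Tilt", "Roll", "Twist")

# Built-in 16 x 6 table of RNA dinucleotide structural parameters.
# Rows follow DINUCLEOTIDES order; columns follow PROPERTY_NAMES.
# Shift/Slide/Rise in nm, Tilt/Roll/Twist in degrees.
_BUILTIN_VALUES = np.array(
    [
        #  Shift  Slide  Rise   Tilt   Roll   Twist
        [-0.08, -1.27, 3.18, -0.80,  7.00, 31.00],  # AA
        [ 0.23, -1.43, 3.24,  0.80,  4.80, 32.00],  # AC
        [-0.04, -1.50, 3.30,  0.50,  8.50, 30.00],  # AG
        [-0.06, -1.36, 3.24,  1.10,  7.10, 33.00],  # AU
        [ 0.11, -1.46, 3.09,  1.00,  9.90, 31.00],  # CA
        [-0.01, -1.78, 3.32,  0.30,  8.70, 32.00],  # CC
        [ 0.30, -1.89, 3.30, -0.10, 12.10, 27.00],  # CG
        [-0.04, -1.50, 3.30,  0.50,  8.50, 30.00],  # CU
        [ 0.07, -1.70, 3.38,  1.30,  9.40, 32.00],  # GA
        [ 0.07, -1.39, 3.22,  0.00,  6.10, 35.00],  # GC
        [-0.01, -1.78, 3.32,  0.30, 12.10, 32.00],  # GG
        [ 0.23, -1.43, 3.24,  0.80,  4.80, 32.00],  # GU
        [-0.02, -1.45, 3.26, -0.20, 10.70, 32.00],  # UA
        [ 0.07, -1.70, 3.38,  1.30,  9.40, 32.00],  # UC
        [ 0.11, -1.46, 3.09,  1.00,  9.90, 31.00],  # UG
        [-0.08, -1.27, 3.18, -0.80,  7.00, 31.00],  # UU
    ]
)


class PropertyTableError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyTable:
    """A complete 16-dinucleotide x 6-property matrix.

    ``standardized`` distinguishes the raw printed values from their
    column-wise z-scores; the encoder only accepts the standardized form.
    """

    values: np.ndarray
    standardized: bool
    property_names: tuple[str, ...] = PROPERTY_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16, len(self.property_names)):
            raise PropertyTableError(
                f"property table must be 16 x {len(self.property_names)}; "
                f"got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise PropertyTableError("property table contains non-finite cells")
        object.__setattr__(self, "values", v)
        self.values.setflags(write=False)

    def lookup(self, dinucleotide: str, prop: str) -> float:
        return float(
            self.values[DINUC_INDEX[dinucleotide], self.property_names.index(prop)]
        )

    def row(self, dinucleotide: str) -> np.ndarray:
        return self.values[DINUC_INDEX[dinucleotide]]

    def fingerprint(self) -> str:
        """Stable checksum of the table contents, recorded in trained models."""
        h = hashlib.sha256()
        h.update(",".join(self.property_names).encode())
        h.update(self.values.tobytes())
        h.update(b"std" if self.standardized else b"raw")
        return h.hexdigest()[:16]


def builtin_property_table() -> PropertyTable:
    """The built-in raw table of six RNA dinucleotide structure parameters."""
    return PropertyTable(_BUILTIN_VALUES.copy(), standardized=False)


def standardize(table: PropertyTable, ddof: int = 0) -> PropertyTable:
    """Z-score each property column over the 16 dinucleotides.

    The 16 dinucleotides are the entire population, so the population
    standard deviation (``ddof=0``) is the default; ``ddof=1`` is exposed
    for sensitivity analysis only. A constant column cannot be standardized.
    """
    if table.standardized:
        # idempotent fixed point: columns already have mean 0, SD 1
        return table
    sd = table.values.std(axis=0, ddof=ddof)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        names = [table.property_names[i] for i in zero]
        raise PropertyTableError(
            f"cannot standardize constant property column(s): {names}"
        )
    z = (table.values - table.values.mean(axis=0)) / sd
    return PropertyTable(z, standardized=True, property_names=table.property_names)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a user-supplied raw property table from delimited text.

    Format: header row naming the properties, then one row per dinucleotide
    (first column the dinucleotide, T accepted for U); comma- or
    tab-separated. All 16 dinucleotides must be present exactly once.
    """
    text = Path(path).read_text().strip()
    if not text:
        raise PropertyTableError(f"empty property table file: {path}")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header = [c.strip() for c in lines[0].split(sep)]
    prop_names = tuple(header[1:])
    if len(prop_names) < 1:
        raise PropertyTableError("property table needs at least one property column")
    rows: dict[str, list[float]] = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(sep)]
        dinuc = cells[0].upper().replace("T", "U")
        if dinuc not in DINUC_INDEX:
            raise PropertyTableError(f"unknown dinucleotide row {cells[0]!r}")
        if dinuc in rows:
            raise PropertyTableError(f"duplicate dinucleotide row {dinuc!r}")
        if len(cells) - 1 != len(prop_names):
            raise PropertyTableError(
                f"row {dinuc!r} has {len(cells) - 1} values; expected {len(prop_names)}"
            )
        rows[dinuc] = [float(c) for c in cells[1:]]
    missing = [d for d in DINUCLEOTIDES if d not in rows]
    if missing:
        raise PropertyTableError(f"missing dinucleotide rows: {missing}")
    values = np.array([rows[d] for d in DINUCLEOTIDES])
    return PropertyTable(values, standardized=False, property_names=prop_names)
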