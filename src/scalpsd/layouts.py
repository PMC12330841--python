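"""Electrode geometry for the scalp array and the ECoG strip.

The scalp sensor is a forehead-placed hexagonal array of 29 Ag/AgCl
electrodes at 1-cm nearest-neighbour spacing, arranged in five staggered
rows labelled A (5 electrodes), B (6), C (7), D (6) and E (5).  The
invasive reference is a 1 x 6 ECoG strip placed on the cortical surface.

Positions are expressed in centimetres in the plane of the array.  Rows
are staggered by half the spacing and separated by ``spacing * sqrt(3)/2``
so every adjacent pair of electrodes — within a row or across rows — sits
exactly one spacing apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Channels of the study device that produced no usable signal.
DEFAULT_DEAD_SCALP = frozenset({"A2", "D1", "D6", "E1", "E2", "E3", "E4"})

_SCALP_ROWS = (("A", 5), ("B", 6), ("C", 7), ("D", 6), ("E", 5))


@dataclass(frozen=True)
class ElectrodeLayout:
    """2-D electrode positions with live/dead bookkeeping.

    Parameters
    ----------
    name
        Identifier, e.g. ``"scalp29"`` or ``"ecog6"``.
    positions
        Sequence of ``(label, x_cm, y_cm)`` tuples.
    spacing
        Nearest-neighbour electrode distance in cm.
    dead_labels
        Labels of channels known to carry no signal; must be a subset of
        the position labels.
    """

    name: str
    positions: tuple[tuple[str, float, float], ...]
    spacing: float = 1.0
    dead_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        labels = set(self.labels)
        if len(labels) != len(self.positions):
            raise ValueError("duplicate electrode labels")
        extra = set(self.dead_labels) - labels
        if extra:
            raise ValueError(f"dead_labels not in layout: {sorted(extra)}")

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.positions]

    @property
    def live_labels(self) -> list[str]:
        return [p[0] for p in self.positions if p[0] not in self.dead_labels]

    def coords(self, labels: list[str] | None = None) -> np.ndarray:
        """Return an ``(n, 2)`` array of x/y positions in cm."""
        lut = {p[0]: (p[1], p[2]) for p in self.positions}
        use = self.labels if labels is None else labels
        return np.array([lut[lab] for lab in use], dtype=float)

    def position_of(self, label: str) -> tuple[float, float]:
        for lab, x, y in self.positions:
            if lab == label:
                return (x, y)
        raise KeyError(label)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of all electrode centres, in cm."""
        xy = self.coords()
        return (
            float(xy[:, 0].min()),
            float(xy[:, 1].min()),
            float(xy[:, 0].max()),
            float(xy[:, 1].max()),
        )

    def with_dead(self, dead_labels) -> "ElectrodeLayout":
        return ElectrodeLayout(
            self.name, self.positions, self.spacing, frozenset(dead_labels)
        )


def scalp29_layout(
    spacing: float = 1.0, dead_labels=DEFAULT_DEAD_SCALP
) -> ElectrodeLayout:
    """Hexagonal 29-electrode forehead array.

    Row C (seven electrodes) is the longest and spans ``x = 0..6``;
    rows B/D are offset by half a spacing, rows A/E by a full spacing,
    giving a 6 x 2*sqrt(3) cm footprint at the default 1-cm spacing.
    """
    row_pitch = spacing * math.sqrt(3) / 2
    positions = []
    for i, (row, n) in enumerate(_SCALP_ROWS):
        # horizontal offset keeps every cross-row pair at one spacing
        offset = (7 - n) * spacing / 2
        y = i * row_pitch
        for j in range(n):
            positions.append((f"{row}{j + 1}", offset + j * spacing, y))
    return ElectrodeLayout(
        "scalp29", tuple(positions), spacing, frozenset(dead_labels)
    )


def ecog6_layout(spacing: float = 1.0) -> ElectrodeLayout:
    """Collinear 1 x 6 cortical strip, contacts labelled "1".."6"."""
    positions = tuple((str(i + 1), i * spacing, 0.0) for i in range(6))
    return ElectrodeLayout("ecog6", positions, spacing)


def write_layout_table(layout: ElectrodeLayout, path) -> None:
    """Save a layout as a plain-text table (label, x_cm, y_cm, dead)."""
    with open(path, "w") as fh:
        fh.write(f"# layout {layout.name} spacing_cm {layout.spacing}\n")
        fh.write("label\tx_cm\ty_cm\tdead\n")
        for lab, x, y in layout.positions:
            dead = int(lab in layout.dead_labels)
            fh.write(f"{lab}\t{x:.6g}\t{y:.6g}\t{dead}\n")


def read_layout_table(path) -> ElectrodeLayout:
    """Load a layout written by :func:`write_layout_table`."""
    name, spacing = "layout", 1.0
    positions: list[tuple[str, float, float]] = []
    dead: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if "layout" in parts:
                    name = parts[parts.index("layout") + 1]
                if "spacing_cm" in parts:
                    spacing = float(parts[parts.index("spacing_cm") + 1])
                continue
            if line.startswith("label"):
                continue
            lab, x, y, d = line.split("\t")
            positions.append((lab, float(x), float(y)))
            if int(d):
                dead.add(lab)
    return ElectrodeLayout(name, tuple(positions), spacing, frozenset(dead))
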