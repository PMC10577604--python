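"""Marker panels and the phenotype-label grammar.

A phenotype label is a conjunction of marker states written in the field's
usual shorthand, e.g. ``"CD8+FOXP3+"`` (CD8-positive AND FOXP3-positive,
other markers unconstrained) or ``"CD4-CD8+FOXP3-"``. The *canonical* label
of a cell lists its positive markers in panel order ("negative" if none),
so canonical labels partition a cell map while query labels may overlap.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

#: The four multiplexed-immunofluorescence panels, marker order fixed.
PANELS: dict[str, list[str]] = {
    "t_cell": ["CD4", "CD8", "FOXP3", "PD1"],
    "macrophage": ["CD68", "CD163", "CD206", "PDL1"],
    "myeloid": ["CD8", "CD11b", "CD14", "CD15"],
    "nkt": ["CD8", "GranzymeB", "Granulysin", "CD16", "CD56"],
}

_TOKEN = re.compile(r"([A-Za-z0-9]+)([+\-−‐‑])")


def parse_label(label: str) -> dict[str, bool]:
    """Parse a phenotype label into {marker: required state}.

    Raises ValueError if the label has trailing junk or no tokens.
    """
    if label == "negative":
        return {}
    constraints: dict[str, bool] = {}
    pos = 0
    for m in _TOKEN.finditer(label):
        if m.start() != pos:
            raise ValueError(f"cannot parse phenotype label {label!r}")
        constraints[m.group(1)] = m.group(2) == "+"
        pos = m.end()
    if pos != len(label) or not constraints:
        raise ValueError(f"cannot parse phenotype label {label!r}")
    return constraints


def canonical_label(positivity: dict[str, bool] | pd.Series, panel: list[str]) -> str:
    """Canonical label: positive markers joined in panel order, or 'negative'."""
    parts = [m + "+" for m in panel if bool(positivity.get(m, False))]
    return "".join(parts) if parts else "negative"


def phenotype_mask(cells: pd.DataFrame, label: str, panel: list[str] | None = None) -> np.ndarray:
    """Boolean mask of cells matching a (possibly partial) phenotype label.

    Markers mentioned with '+' must be positive, with '-' negative;
    unmentioned markers are unconstrained. The label "negative" matches
    cells negative for every marker of *panel*.
    """
    if label == "negative":
        if panel is None:
            panel = [c[:-4] for c in cells.columns if c.endswith("_pos")]
        mask = np.ones(len(cells), dtype=bool)
        for m in panel:
            mask &= ~cells[f"{m}_pos"].to_numpy(dtype=bool)
        return mask
    mask = np.ones(len(cells), dtype=bool)
    for marker, required in parse_label(label).items():
        col = f"{marker}_pos"
        if col not in cells.columns:
            raise KeyError(f"marker {marker!r} not in cell table")
        mask &= cells[col].to_numpy(dtype=bool) == required
    return mask
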