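"""Per-marker cell classification and cross-plane co-expression merging.

Each deconvoluted plane yields, per detected cell, a patch centred on the
centroid which a small VGG-style network classifies as marker-positive or
-negative (two-way softmax; a cell is called positive when
p_pos >= p_neg, so an exact tie goes to positive). Positive centroids from
the N marker planes are then mapped onto one coordinate frame and merged
into multi-marker cells — the co-expression step that produces phenotypes
such as CD8+FOXP3+ or CD4+CD8+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .matching import greedy_match
from .panels import PANELS, canonical_label, phenotype_mask

__all__ = [
    "ClassifierOutput",
    "PatchClassifier",
    "train_classifier",
    "extract_patches",
    "classify_cells",
    "merge_across_planes",
    "phenotype_fractions",
]


@dataclass
class ClassifierOutput:
    p_pos: float
    p_neg: float

    @property
    def predicted_class(self) -> str:
        # tie goes to positive
        return "positive" if self.p_pos >= self.p_neg else "negative"


class PatchClassifier:
    """VGG-style conv-conv-pool stack with a 2-way softmax head."""

    def __init__(self, seed: int = 0, patch_size: int = 28):
        if patch_size % 4 != 0:
            raise ValueError("patch_size must be divisible by 4 (two 2x2 pools)")
        rng = np.random.default_rng(seed)
        side = patch_size // 4
        self.patch_size = patch_size
        self.net = nn.Sequential(
            nn.Conv2d(2, 8, 3, rng), nn.ReLU(),
            nn.Conv2d(8, 8, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(8, 16, 3, rng), nn.ReLU(),
            nn.Conv2d(16, 16, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Flatten(),
            nn.Dense(16 * side * side, 32, rng), nn.ReLU(),
            nn.Dense(32, 2, rng),
        )
        self.history: list[float] = []

    def predict_proba(self, patches: np.ndarray, batch: int = 256) -> np.ndarray:
        """(N,2,s,s) patches -> (N,2) probabilities [p_neg, p_pos]."""
        out = []
        for i in range(0, len(patches), batch):
            out.append(nn.softmax(self.net.forward(patches[i:i + batch])))
        return np.vstack(out) if out else np.empty((0, 2))


def train_classifier(patches: np.ndarray, labels: np.ndarray,
                     hyperparams: dict | None = None) -> PatchClassifier:
    """Train the positive/negative patch classifier.

    `labels` are 0 (negative) / 1 (positive); both classes must be present.
    """
    hp = {"seed": 0, "epochs": 4, "lr": 1e-3, "batch": 32}
    hp.update(hyperparams or {})
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both positive and negative patches")
    model = PatchClassifier(seed=hp["seed"], patch_size=patches.shape[-1])
    opt = nn.Adam(model.net.parameters(), model.net.gradients(), lr=hp["lr"])
    rng = np.random.default_rng(hp["seed"] + 511)
    n = len(patches)
    for _ in range(hp["epochs"]):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i in range(0, n, hp["batch"]):
            idx = order[i:i + hp["batch"]]
            x, y = patches[idx], labels[idx]
            logits = model.net.forward(x)
            p = nn.softmax(logits)
            loss = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError("non-finite classifier loss")
            g = p.copy()
            g[np.arange(len(y)), y] -= 1.0
            model.net.backward(g / len(y))
            opt.step()
            epoch_loss += loss
            nb += 1
        model.history.append(epoch_loss / nb)
    return model


def extract_patches(image: np.ndarray, centroids_um: np.ndarray, um_per_pixel: float,
                    patch_size: int = 28) -> np.ndarray:
    """Zero-padded patches centred on each centroid (rounded half-up)."""
    c, h, w = image.shape
    half = patch_size // 2
    padded = np.pad(image, ((0, 0), (half, half), (half, half)))
    out = np.empty((len(centroids_um), c, patch_size, patch_size))
    for k, (x_um, y_um) in enumerate(np.asarray(centroids_um).reshape(-1, 2)):
        x = int(np.floor(x_um / um_per_pixel + 0.5))
        y = int(np.floor(y_um / um_per_pixel + 0.5))
        x = min(max(x, 0), w - 1)
        y = min(max(y, 0), h - 1)
        out[k] = padded[:, y:y + patch_size, x:x + patch_size]
    return out


def classify_cells(model: PatchClassifier, image: np.ndarray, centroids_um: np.ndarray,
                   um_per_pixel: float) -> pd.DataFrame:
    """One row per centroid: p_pos, p_neg, positive (p_pos >= p_neg)."""
    patches = extract_patches(image, centroids_um, um_per_pixel, model.patch_size)
    proba = model.predict_proba(patches)
    df = pd.DataFrame({"p_neg": proba[:, 0], "p_pos": proba[:, 1]})
    df["positive"] = df["p_pos"] >= df["p_neg"]
    return df


def merge_across_planes(plane_positives: dict[str, np.ndarray], merge_radius: float = 5.0,
                        panel: str | list[str] = "t_cell", d_min: float | None = None,
                        tile_id: str = "tile_0") -> pd.DataFrame:
    """Merge per-plane positive centroids into multi-marker cells.

    `plane_positives` maps marker name -> (n, 2) positive centroids in the
    shared tile frame. Centroids from different planes closer than
    `merge_radius` are merged greedily (ascending distance, one-to-one per
    plane pair) into single cells carrying the union of positivities;
    positions of merged cells are the running mean of their sources.
    Every input centroid ends up in exactly one output cell.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be > 0")
    markers = PANELS[panel] if isinstance(panel, str) else list(panel)
    d_min = merge_radius if d_min is None else d_min

    cells_xy: list[np.ndarray] = []  # running mean position
    cells_n: list[int] = []
    cells_markers: list[set[str]] = []

    for marker, pts in plane_positives.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        # intra-plane deduplication: drop the later of any pair closer than d_min
        if len(pts) > 1 and d_min > 0:
            from scipy.spatial.distance import cdist as _cdist

            d = _cdist(pts, pts)
            np.fill_diagonal(d, np.inf)
            removed: set[int] = set()
            ii, jj = np.nonzero(d < d_min)
            for i, j in sorted(zip(ii, jj), key=lambda p: d[p]):
                if i < j and i not in removed and j not in removed:
                    removed.add(j)
            if removed:
                warnings.warn(
                    f"{len(removed)} duplicate centroid(s) within plane {marker!r} "
                    f"closer than {d_min} μm removed"
                )
                pts = pts[[i for i in range(len(pts)) if i not in removed]]
        if len(cells_xy) == 0:
            matched: dict[int, int] = {}
        else:
            existing = np.array(cells_xy)
            pairs = greedy_match(pts, existing, merge_radius)
            matched = dict(pairs)
        for i, p in enumerate(pts):
            if i in matched:
                j = matched[i]
                k = cells_n[j]
                cells_xy[j] = (cells_xy[j] * k + p) / (k + 1)
                cells_n[j] += 1
                cells_markers[j].add(marker)
            else:
                cells_xy.append(p.copy())
                cells_n.append(1)
                cells_markers.append({marker})

    rows = []
    for i, (xy, ms) in enumerate(zip(cells_xy, cells_markers)):
        positivity = {m: m in ms for m in markers}
        rows.append((f"{tile_id}_m{i}", tile_id, xy[0], xy[1],
                     *[positivity[m] for m in markers],
                     canonical_label(positivity, markers)))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "tile_id", "x_um", "y_um", *[f"{m}_pos" for m in markers], "phenotype"],
    )


def save_classifier(model: PatchClassifier, path) -> None:
    """Write classifier weights and patch size to an .npz checkpoint."""
    np.savez(path, patch_size=model.patch_size,
             **{f"p{i}": p for i, p in enumerate(model.net.parameters())})


def load_classifier(path) -> PatchClassifier:
    state = np.load(path)
    model = PatchClassifier(patch_size=int(state["patch_size"]))
    for i, p in enumerate(model.net.parameters()):
        p[...] = state[f"p{i}"]
    return model


def phenotype_fractions(cell_map: pd.DataFrame, numerator: str, denominator_marker: str) -> float:
    """Percentage of `denominator_marker`-positive cells matching `numerator`.

    E.g. the share of CD8-expressing cells that are CD8+FOXP3+. Returns NaN
    when the denominator is empty.
    """
    denom = cell_map[f"{denominator_marker}_pos"].to_numpy(dtype=bool)
    if denom.sum() == 0:
        return float("nan")
    num = phenotype_mask(cell_map, numerator) & denom
    return 100.0 * num.sum() / denom.sum()
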