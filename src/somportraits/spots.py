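"""Detection of over-/under-expression spot modules on the metagene grid.

A *spot* is a connected grid region of concertedly over- (or under-)
expressed metagenes. Detection proceeds in three steps:

1. per sample, select the metagenes beyond the 98th (over) or 2nd (under)
   percentile of that sample's portrait;
2. transfer all per-sample selections into one summary ("master") map that
   keeps, per selected tile, the strongest value observed across samples;
3. threshold the summary map at the same percentile of its non-neutral
   values and split the supra-threshold tiles into 4-connected components.

Each component becomes one labeled spot ('A', 'B', …, assigned row-major by
centroid) collecting its member metagenes and, through the gene→metagene
assignment, its member genes. Spots are disjoint by construction and can be
read as distinct expression modules of the cohort.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .som import Portrait, SOMModel

OVER = "over"
UNDER = "under"

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Spot:
    label: str
    metagenes: tuple[int, ...]        # flat grid indices
    genes: tuple[str, ...]
    centroid: tuple[float, float]     # (row, col)


@dataclass
class SpotSet:
    polarity: str                     # "over" | "under"
    threshold: float
    spots: dict[str, Spot] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots.values())

    def membership(self, n_metagenes: int) -> np.ndarray:
        """Flat array mapping metagene index → spot label ('' outside spots)."""
        out = np.full(n_metagenes, "", dtype=object)
        for spot in self:
            for k in spot.metagenes:
                out[k] = spot.label
        return out


def _spot_labels(n: int) -> list[str]:
    """'A', 'B', …, 'Z', 'AA', 'AB', … — consecutive capital letters."""
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        if i < 26:
            labels.append(letters[i])
        else:
            labels.append(letters[i // 26 - 1] + letters[i % 26])
    return labels


def sample_spot_mask(portrait: Portrait, percentile: float = 98.0,
                     polarity: str = OVER) -> np.ndarray:
    """Boolean grid of this sample's extreme tiles.

    Over-expression keeps tiles at or above the sample's ``percentile``-th
    percentile; under-expression keeps tiles at or below the mirrored
    ``100 − percentile``-th percentile. A constant portrait is degenerate
    (the threshold would select everything) and yields an empty mask with a
    warning.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    if polarity not in (OVER, UNDER):
        raise ValueError(f"polarity must be 'over' or 'under', got {polarity!r}")
    grid = np.asarray(portrait.grid, dtype=float)
    if np.ptp(grid) < 1e-15:
        warnings.warn(
            f"constant portrait {portrait.sample_id!r}: no spot tiles selected",
            RuntimeWarning,
        )
        return np.zeros_like(grid, dtype=bool)
    if polarity == OVER:
        return grid >= np.percentile(grid, percentile)
    return grid <= np.percentile(grid, 100.0 - percentile)


def summary_map(model: SOMModel, polarity: str = OVER,
                percentile: float = 98.0) -> np.ndarray:
    """Master map collecting all per-sample spot tiles.

    A tile selected in at least one sample carries the strongest metadata
    value observed across samples (max for over-, min for under-expression);
    never-selected tiles stay neutral at 0.
    """
    rows, cols = model.config.rows, model.config.cols
    union = np.zeros((rows, cols), dtype=bool)
    for sid in model.sample_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            union |= sample_spot_mask(model.portrait(sid), percentile, polarity)
    if polarity == OVER:
        extreme = model.metadata.max(axis=1)
    else:
        extreme = model.metadata.min(axis=1)
    out = np.where(union, extreme.reshape(rows, cols), 0.0)
    return out


def segment_spots(summary: np.ndarray, model: SOMModel,
                  polarity: str = OVER,
                  secondary_percentile: float | None = None) -> SpotSet:
    """Split the summary map into disjoint, alphabetically labeled spots.

    Every non-neutral tile of the summary map already passed the per-sample
    percentile criterion in at least one portrait, so by default the global
    spots are simply the 4-connected components of the non-neutral tiles
    (4-connectivity keeps diagonal contact from bridging two modules). An
    optional ``secondary_percentile`` re-cuts the summary map at that
    percentile of its non-neutral values before segmentation, for stricter
    spot cores. An empty result is valid when nothing passes.
    """
    if polarity not in (OVER, UNDER):
        raise ValueError(f"polarity must be 'over' or 'under', got {polarity!r}")
    summary = np.asarray(summary, dtype=float)
    nonneutral = summary[summary != 0.0]
    if nonneutral.size == 0:
        return SpotSet(polarity=polarity, threshold=np.nan)
    if secondary_percentile is None:
        threshold = float(nonneutral.min() if polarity == OVER else nonneutral.max())
        passing = summary != 0.0
    elif polarity == OVER:
        threshold = float(np.percentile(nonneutral, secondary_percentile))
        passing = (summary != 0.0) & (summary >= threshold)
    else:
        threshold = float(np.percentile(nonneutral, 100.0 - secondary_percentile))
        passing = (summary != 0.0) & (summary <= threshold)
    labeled, n_components = ndimage.label(passing, structure=_FOUR_CONN)
    spots: list[Spot] = []
    for comp in range(1, n_components + 1):
        tiles = np.argwhere(labeled == comp)
        flat = tuple(int(r) * model.config.cols + int(c) for r, c in tiles)
        genes = tuple(model.genes_of_metagenes(flat))
        centroid = (float(tiles[:, 0].mean()), float(tiles[:, 1].mean()))
        spots.append(Spot(label="", metagenes=flat, genes=genes, centroid=centroid))
    spots.sort(key=lambda s: s.centroid)  # row-major: top-left first
    result = SpotSet(polarity=polarity, threshold=threshold)
    for label, spot in zip(_spot_labels(len(spots)), spots):
        spot.label = label
        result.spots[label] = spot
    return result


def detect_spots(model: SOMModel, percentile: float = 98.0,
                 polarity: str = OVER,
                 secondary_percentile: float | None = None) -> SpotSet:
    """Convenience wrapper: summary map + segmentation in one call."""
    return segment_spots(summary_map(model, polarity, percentile), model,
                         polarity, secondary_percentile)


def spot_profiles(model: SOMModel, spotset: SpotSet) -> pd.DataFrame:
    """Spots × samples matrix of mean member-metagene expression."""
    if len(spotset) == 0:
        raise ValueError("empty spot set has no profiles")
    rows = {}
    for spot in spotset:
        if not spot.metagenes:
            raise ValueError(f"spot {spot.label!r} has no member metagenes")
        rows[spot.label] = model.metadata[list(spot.metagenes)].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=model.sample_ids)


def write_spots_json(spotset: SpotSet, path) -> None:
    import json

    payload = {
        "polarity": spotset.polarity,
        "threshold": None if np.isnan(spotset.threshold) else spotset.threshold,
        "spots": {
            s.label: {
                "metagenes": list(s.metagenes),
                "genes": list(s.genes),
                "centroid": list(s.centroid),
            }
            for s in spotset
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_spots_json(path) -> SpotSet:
    import json

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    threshold = payload["threshold"]
    out = SpotSet(polarity=payload["polarity"],
                  threshold=np.nan if threshold is None else float(threshold))
    for label, d in payload["spots"].items():
        out.spots[label] = Spot(
            label=label,
            metagenes=tuple(int(k) for k in d["metagenes"]),
            genes=tuple(d["genes"]),
            centroid=(float(d["centroid"][0]), float(d["centroid"][1])),
        )
    return out


def spot_correlation(profiles: pd.DataFrame,
                     high: float = 0.7, moderate: float = 0.4,
                     anti: float = -0.6) -> pd.DataFrame:
    """Pearson r per unordered spot pair, with correlation-class flags.

    Flags follow the conventions used for spot co-expression maps: ``high``
    for r > 0.7, ``moderate`` for 0.4 < r ≤ 0.7, ``anti`` for r < −0.6, else
    ``none``. Pairs involving a zero-variance profile get ``r = NaN`` and the
    flag ``missing``.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two spot profiles")
    if profiles.shape[1] < 3:
        raise ValueError("need at least three samples")
    labels = list(profiles.index)
    values = profiles.to_numpy()
    sd = values.std(axis=1)
    records = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if sd[i] < 1e-15 or sd[j] < 1e-15:
                r, flag = np.nan, "missing"
            else:
                r = float(np.corrcoef(values[i], values[j])[0, 1])
                if r > high:
                    flag = "high"
                elif r > moderate:
                    flag = "moderate"
                elif r < anti:
                    flag = "anti"
                else:
                    flag = "none"
            records.append({"spot_a": labels[i], "spot_b": labels[j],
                            "r": r, "flag": flag})
    return pd.DataFrame.from_records(records)
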