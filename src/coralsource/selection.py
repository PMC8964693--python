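"""Classify reefs as predicted sources of heritable heat tolerance.

Applies fitted intrinsic-resistance envelopes to a reef-scale environmental
table: a reef qualifies for one model combination (life stage ×
purebred/hybrid × symbiont) when its metric value lies inside that model's
envelope, and the union across combinations gives the headline count and
fraction of candidate source reefs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .resistance import IntrinsicResistanceResults

__all__ = ["SelectionResult", "classify_reefs", "summarize_selection",
           "write_selection_csv", "write_selection_geojson"]


@dataclass
class SelectionResult:
    """Selected reefs for a set of envelope models under a combination rule."""

    selected: list  # reef ids under the combination rule
    per_model: dict  # model label -> list of reef ids inside that envelope
    rule: str
    total_reef_count: int
    catalogue: pd.DataFrame = field(repr=False, default=None)

    @property
    def count(self) -> int:
        return len(self.selected)

    @property
    def fraction(self) -> float:
        return self.count / self.total_reef_count


def _model_label(i: int, model: IntrinsicResistanceResults) -> str:
    return f"m{i}:{model.feature}"


def classify_reefs(catalogue: pd.DataFrame,
                   models: list[IntrinsicResistanceResults],
                   rule: str = "any",
                   total_reef_count: int | None = None) -> SelectionResult:
    """Select reefs whose metrics fall inside the model envelopes.

    ``rule="any"`` selects reefs inside at least one model's envelope
    (the union used for headline counts); ``"all"`` requires every envelope.
    Envelope bounds are closed, so values exactly at a polynomial root are
    selected. Missing metric columns raise an error naming the column.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"rule must be 'any' or 'all', got {rule!r}")
    if "reef_id" not in catalogue.columns:
        raise KeyError("catalogue must have a reef_id column")
    if catalogue["reef_id"].duplicated().any():
        raise ValueError("catalogue reef_id values must be unique")
    per_model = {}
    masks = []
    for i, model in enumerate(models):
        col = model.feature if model.feature in catalogue.columns else (
            "lat" if model.feature == "LAT" and "lat" in catalogue.columns else None)
        if col is None:
            raise KeyError(f"catalogue is missing metric column {model.feature!r}")
        inside = model.contains(catalogue[col].to_numpy(float))
        masks.append(inside)
        per_model[_model_label(i, model)] = catalogue.loc[inside, "reef_id"].tolist()
    if not masks:
        raise ValueError("no models given")
    combined = np.any(masks, axis=0) if rule == "any" else np.all(masks, axis=0)
    total = total_reef_count if total_reef_count is not None else len(catalogue)
    return SelectionResult(selected=catalogue.loc[combined, "reef_id"].tolist(),
                           per_model=per_model, rule=rule,
                           total_reef_count=total, catalogue=catalogue)


def summarize_selection(results: list[SelectionResult],
                        grid_snap: float | None = None) -> dict:
    """De-duplicated union of selected reefs across combinations.

    With ``grid_snap`` (degrees), closely adjacent selected locations are
    merged by snapping coordinates to a lat/lon grid of that cell size
    before counting — off by default, since any merging radius is a
    reporting choice rather than a property of the models.
    """
    if not results:
        raise ValueError("no selection results to summarize")
    union: set = set()
    for res in results:
        union.update(res.selected)
    total = max(res.total_reef_count for res in results)
    out = {"union": sorted(union), "count": len(union),
           "fraction": len(union) / total, "total_reef_count": total}
    if grid_snap:
        cat = next(r.catalogue for r in results if r.catalogue is not None)
        coords = cat.set_index("reef_id").loc[sorted(union), ["lat", "lon"]]
        cells = {(round(la / grid_snap), round(lo / grid_snap))
                 for la, lo in coords.itertuples(index=False)}
        out["snapped_count"] = len(cells)
        out["snapped_fraction"] = len(cells) / total
    return out


def write_selection_csv(result: SelectionResult, path) -> None:
    rows = []
    for label, reefs in result.per_model.items():
        for reef in reefs:
            rows.append({"model": label, "reef_id": reef})
    for reef in result.selected:
        rows.append({"model": f"combined({result.rule})", "reef_id": reef})
    pd.DataFrame(rows, columns=["model", "reef_id"]).to_csv(path, index=False)


def write_selection_geojson(result: SelectionResult, path) -> None:
    """Point features for selected reefs, tagged with qualifying models.

    Longitude is emitted as °E and latitude as negative degrees (the stored
    latitudes are positive °S).
    """
    cat = result.catalogue.set_index("reef_id")
    features = []
    for reef in result.selected:
        tags = [label for label, reefs in result.per_model.items() if reef in reefs]
        lat = float(cat.loc[reef, "lat"]) if "lat" in cat.columns else None
        lon = float(cat.loc[reef, "lon"]) if "lon" in cat.columns else None
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [lon, -lat if lat is not None else None]},
            "properties": {"reef_id": str(reef), "models": tags},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)
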