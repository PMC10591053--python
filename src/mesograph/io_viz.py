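"""Readers, writers and visualisation.

Detection tables round-trip through CSV and a QuPath-dialect GeoJSON
FeatureCollection; model checkpoints are self-describing JSON archives
(parameters + configuration + feature schema hash + standardisation
statistics); MesoGram histograms and blue-red score overlays render the
per-cell output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon, mapping, shape as shapely_shape

from .autodiff import Tensor
from .features import Standardizer
from .graphs import CoreGraph
from .model import MLPParams, ModelConfig, ModelParams, ScoreSet

__all__ = ["read_detections", "write_detections", "MesoGram", "mesogram",
           "score_overlay", "save_checkpoint", "load_checkpoint",
           "save_graph_bundle", "load_graph_bundle"]

_CSV_COLUMNS = ["core_id", "cell_id", "cx_um", "cy_um",
                "nucleus_wkt", "cell_wkt", "planted_class"]


def _check_polygon(wkt_text: str, cell_id) -> Polygon:
    try:
        poly = shapely_wkt.loads(wkt_text)
    except Exception as exc:
        raise ValueError(f"cell {cell_id}: malformed polygon WKT") from exc
    if poly.geom_type != "Polygon" or len(poly.exterior.coords) < 4:
        raise ValueError(
            f"cell {cell_id}: polygon needs at least 3 vertices")
    return poly


def write_detections(detections: pd.DataFrame, path: str | Path,
                     dialect: str = "csv") -> None:
    """Write a detection table as CSV or QuPath-dialect GeoJSON."""
    path = Path(path)
    if dialect == "csv":
        detections.to_csv(path, index=False)
    elif dialect == "geojson":
        features = []
        extra_cols = [c for c in detections.columns
                      if c not in ("nucleus_wkt", "cell_wkt")]
        for row in detections.itertuples(index=False):
            cell = shapely_wkt.loads(row.cell_wkt)
            nucleus = shapely_wkt.loads(row.nucleus_wkt)
            props = {
                "objectType": "cell",
                "classification": {
                    "name": getattr(row, "planted_class", "")},
                "measurements": {c: getattr(row, c) for c in extra_cols
                                 if c not in ("core_id", "cell_id",
                                              "planted_class")},
                "core_id": row.core_id,
                "cell_id": int(row.cell_id),
            }
            features.append({
                "type": "Feature",
                "geometry": mapping(cell),
                "nucleusGeometry": mapping(nucleus),
                "properties": props,
            })
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_detections(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    """Read a detection table; polygons are validated per cell."""
    path = Path(path)
    if dialect == "csv":
        table = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS[:6] if c not in table.columns]
        if missing:
            raise ValueError(f"missing detection columns: {missing}")
        for row in table.itertuples(index=False):
            _check_polygon(row.nucleus_wkt, row.cell_id)
            _check_polygon(row.cell_wkt, row.cell_id)
        return table
    if dialect == "geojson":
        doc = json.loads(path.read_text())
        if doc.get("type") != "FeatureCollection":
            raise ValueError("expected a GeoJSON FeatureCollection")
        rows = []
        for feat in doc["features"]:
            props = feat.get("properties", {})
            cell = shapely_shape(feat["geometry"])
            nucleus = shapely_shape(feat["nucleusGeometry"]) \
                if "nucleusGeometry" in feat else cell
            cell_id = props.get("cell_id", len(rows))
            _check_polygon(cell.wkt, cell_id)
            c = nucleus.centroid
            row = {
                "core_id": props.get("core_id", ""),
                "cell_id": cell_id,
                "cx_um": c.x, "cy_um": c.y,
                "nucleus_wkt": nucleus.wkt,
                "cell_wkt": cell.wkt,
                "planted_class": props.get("classification", {})
                .get("name", ""),
            }
            row.update(props.get("measurements", {}))
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# MesoGram


@dataclass
class MesoGram:
    """Histogram of one core's per-cell scores on the (-1, 1) axis."""

    core_id: str
    bin_edges: np.ndarray
    counts: np.ndarray


def mesogram(scoreset: ScoreSet, n_bins: int = 40) -> MesoGram:
    """Bin the per-cell scores of one core into a MesoGram."""
    scores = scoreset.cell_score
    if scores.size == 0:
        raise ValueError("empty score set")
    counts, edges = np.histogram(scores, bins=n_bins, range=(-1.0, 1.0))
    return MesoGram(core_id=scoreset.core_id, bin_edges=edges,
                    counts=counts)


# ---------------------------------------------------------------------------
# score overlay


def score_overlay(image: np.ndarray, detections: pd.DataFrame,
                  scoreset: ScoreSet, mpp: float,
                  colormap: str = "coolwarm",
                  legend: bool = True) -> np.ndarray:
    """Fill each cell polygon with the diverging score colour.

    Blue at score -1 (epithelioid) through to red at +1 (sarcomatoid);
    a vertical colourbar legend is embedded on the right edge.
    """
    from matplotlib import colormaps
    from skimage.draw import polygon as draw_polygon

    if len(detections) != scoreset.cell_score.size:
        raise ValueError("detections and scores are different cores")
    cmap = colormaps[colormap]
    out = image.copy()
    for row, score in zip(detections.itertuples(index=False),
                          scoreset.cell_score):
        rgba = cmap((float(score) + 1.0) / 2.0)
        colour = (np.array(rgba[:3]) * 255).astype(np.uint8)
        coords = np.asarray(shapely_wkt.loads(row.cell_wkt).exterior.coords)
        rr, cc = draw_polygon(coords[:, 1] / mpp, coords[:, 0] / mpp,
                              shape=out.shape[:2])
        out[rr, cc] = colour
    if legend:
        h = out.shape[0]
        strip = cmap(np.linspace(1.0, 0.0, h))[:, :3] * 255
        bar = np.repeat(strip[:, None, :], 12, axis=1).astype(np.uint8)
        out = np.concatenate([out, bar], axis=1)
    return out


# ---------------------------------------------------------------------------
# checkpoint archive (JSON: tiny model, diffable artifact)


def _mlp_to_json(mlp: MLPParams) -> dict:
    return {k: getattr(mlp, k).data.tolist()
            for k in ("w1", "b1", "w2", "b2")}


def _mlp_from_json(d: dict) -> MLPParams:
    return MLPParams(**{k: Tensor(np.asarray(v), requires_grad=True)
                        for k, v in d.items()})


def schema_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


def save_checkpoint(path: str | Path, params: ModelParams,
                    standardizer: Standardizer | None = None) -> None:
    """Persist parameters, config, schema hash and scaling statistics."""
    doc = {
        "format": "mesograph-checkpoint-v1",
        "config": params.config.__dict__,
        "feature_names": params.feature_names,
        "schema_hash": schema_hash(params.feature_names),
        "layers": [_mlp_to_json(m) for m in params.layers],
        "branch_s": _mlp_to_json(params.branch_s),
        "branch_e": _mlp_to_json(params.branch_e),
        "alpha_s": _mlp_to_json(params.alpha_s),
        "beta_s": _mlp_to_json(params.beta_s),
        "alpha_e": _mlp_to_json(params.alpha_e),
        "beta_e": _mlp_to_json(params.beta_e),
    }
    if standardizer is not None:
        doc["standardizer"] = {
            "mean": standardizer.mean.tolist(),
            "sd": standardizer.sd.tolist(),
            "names": standardizer.names,
        }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: str | Path
                    ) -> tuple[ModelParams, Standardizer | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "mesograph-checkpoint-v1":
        raise ValueError("not a mesograph checkpoint")
    params = ModelParams(
        config=ModelConfig(**doc["config"]),
        layers=[_mlp_from_json(m) for m in doc["layers"]],
        branch_s=_mlp_from_json(doc["branch_s"]),
        branch_e=_mlp_from_json(doc["branch_e"]),
        alpha_s=_mlp_from_json(doc["alpha_s"]),
        beta_s=_mlp_from_json(doc["beta_s"]),
        alpha_e=_mlp_from_json(doc["alpha_e"]),
        beta_e=_mlp_from_json(doc["beta_e"]),
        feature_names=doc["feature_names"],
    )
    std = None
    if "standardizer" in doc:
        s = doc["standardizer"]
        std = Standardizer(mean=np.asarray(s["mean"]),
                           sd=np.asarray(s["sd"]), names=s["names"])
    return params, std


# ---------------------------------------------------------------------------
# graph bundle (edge CSV + feature table + metadata JSON)


def save_graph_bundle(directory: str | Path, graph: CoreGraph) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(graph.edges, columns=["u", "v"]).to_csv(
        directory / "edges.csv", index=False)
    table = pd.DataFrame(graph.node_features,
                         columns=graph.feature_names)
    table.insert(0, "cx_um", graph.centroids[:, 0])
    table.insert(1, "cy_um", graph.centroids[:, 1])
    table.to_csv(directory / "nodes.csv", index=False)
    meta = {
        "core_id": graph.core_id, "slide_id": graph.slide_id,
        "patient_id": graph.patient_id,
        "y_s_task": graph.y_s_task, "y_e_task": graph.y_e_task,
        "n_cells": graph.n_cells,
        "schema_hash": schema_hash(graph.feature_names),
    }
    (directory / "meta.json").write_text(json.dumps(meta))


def load_graph_bundle(directory: str | Path) -> CoreGraph:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    nodes = pd.read_csv(directory / "nodes.csv")
    edges = pd.read_csv(directory / "edges.csv").to_numpy(dtype=np.int64)
    if len(nodes) != meta["n_cells"]:
        raise ValueError("truncated graph bundle: node count mismatch")
    feature_names = [c for c in nodes.columns
                     if c not in ("cx_um", "cy_um")]
    graph = CoreGraph(
        node_features=nodes[feature_names].to_numpy(dtype=np.float64),
        feature_names=feature_names,
        edges=edges.reshape(-1, 2),
        centroids=nodes[["cx_um", "cy_um"]].to_numpy(dtype=np.float64),
        core_id=meta["core_id"], slide_id=meta["slide_id"],
        patient_id=meta["patient_id"],
        y_s_task=meta["y_s_task"], y_e_task=meta["y_e_task"],
    )
    graph.validate()
    return graph
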