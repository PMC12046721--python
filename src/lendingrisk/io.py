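"""File formats and spatial plumbing.

Tract tables travel as CSV, adjacency as a plain-text neighbor list
(``<tract_id> <k> <id_1> ... <id_k>`` per line, the classic spatial-
weights convention), polygons as GeoJSON FeatureCollections, diagnostics
and truth records as JSON. Contiguity from polygons and point-in-polygon
aggregation are built on shapely.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape
from shapely.strtree import STRtree

from .adjacency import Adjacency
from .covariates import RACE_COLUMNS

log = logging.getLogger("lendingrisk")

REQUIRED_COLUMNS = (
    "tract_id",
    "population",
    "homicide_count",
    "loans_originated",
    "loans_per_1000",
    "high_cost_fraction",
    "hrs",
    "adi",
) + RACE_COLUMNS

_NUMERIC = [c for c in REQUIRED_COLUMNS if c != "tract_id"]
_ALLOW_MISSING = {"hrs", "high_cost_fraction"}


def read_tract_table(path, schema_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a tract CSV.

    ``schema_map`` maps canonical column names to the file's column names.
    Rows with missing HRS are retained but flagged ``hrs_missing`` (they
    are excluded at classification time); a missingness report is logged.
    """
    raw = pd.read_csv(path)
    if schema_map:
        raw = raw.rename(columns={v: k for k, v in schema_map.items()})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"tract table missing required columns: {missing_cols}")
    df = raw.copy()
    df["tract_id"] = df["tract_id"].astype(str)
    if df["tract_id"].duplicated().any():
        dupes = df.loc[df["tract_id"].duplicated(), "tract_id"].tolist()
        raise ValueError(f"duplicate tract_id values: {dupes}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        if coerced.isna().any() and col not in _ALLOW_MISSING:
            row = int(coerced.isna().idxmax())
            raise ValueError(f"missing value in required column {col!r} at row {row}")
        df[col] = coerced
    if (df["homicide_count"] > df["population"]).any():
        raise ValueError("homicide_count exceeds population in at least one tract")
    race_sum = df[list(RACE_COLUMNS)].sum(axis=1)
    over = race_sum > df["population"] + 0.5
    if over.any():
        warnings.warn(
            f"{int(over.sum())} tracts have race counts exceeding population", stacklevel=2
        )
    df["hrs_missing"] = df["hrs"].isna()
    n_miss = int(df["hrs_missing"].sum())
    log.info("read %d tracts from %s (%d with missing HRS)", len(df), path, n_miss)
    return df


def write_tract_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_neighbor_list(adj: Adjacency, path, tract_ids: list[str] | None = None) -> None:
    """Plain-text neighbor list: ``<tract_id> <k> <id_1> ... <id_k>``."""
    ids = tract_ids if tract_ids is not None else [str(i) for i in range(adj.n)]
    with open(path, "w") as fh:
        for i, nbrs in enumerate(adj.neighbors):
            fh.write(" ".join([ids[i], str(len(nbrs))] + [ids[j] for j in nbrs]) + "\n")


def read_neighbor_list(path) -> tuple[Adjacency, list[str]]:
    """Inverse of :func:`write_neighbor_list`; returns adjacency + id order."""
    ids: list[str] = []
    raw_nbrs: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            tid, k, nbrs = parts[0], int(parts[1]), parts[2:]
            if len(nbrs) != k:
                raise ValueError(f"line {lineno}: declared degree {k} but {len(nbrs)} neighbors")
            ids.append(tid)
            raw_nbrs.append(nbrs)
    index = {tid: i for i, tid in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate tract ids in neighbor list")
    neighbors = tuple(tuple(sorted(index[t] for t in nbrs)) for nbrs in raw_nbrs)
    return Adjacency(neighbors), ids


def _load_polygons(geojson_path) -> tuple[list, list[str]]:
    with open(geojson_path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    geoms, ids = [], []
    for k, feat in enumerate(gj["features"]):
        tid = str(feat.get("properties", {}).get("tract_id", k))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for feature {tid!r}")
        geoms.append(geom)
        ids.append(tid)
    if len(set(ids)) != len(ids):
        raise ValueError("tract_id collision in GeoJSON features")
    return geoms, ids


def adjacency_from_polygons(geojson_path, rule: str = "queen") -> tuple[Adjacency, list[str]]:
    """Contiguity from tract polygons.

    ``queen``: any shared boundary point makes two tracts neighbors.
    ``rook``: the shared boundary must have positive length. Islands
    (tracts with no neighbors) are reported in a warning.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    geoms, ids = _load_polygons(geojson_path)
    tree = STRtree(geoms)
    n = len(geoms)
    edges = []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                edges.append((i, j))
    adj = Adjacency.from_edges(n, edges)
    isl = adj.islands()
    if isl:
        warnings.warn(f"islands (no neighbors): {[ids[i] for i in isl]}", stacklevel=2)
    return adj, ids


def assign_points_to_tracts(
    events: pd.DataFrame, geojson_path
) -> tuple[pd.Series, int]:
    """Point-in-polygon counts per tract.

    ``events`` needs ``longitude`` and ``latitude`` columns. A point on a
    shared boundary is assigned to the first containing feature in file
    order, with the boundary counted as inside. Points outside every
    polygon are excluded from the counts and returned as an unassigned
    total (mirroring exclusion of unlocated cases from a case archive).
    """
    geoms, ids = _load_polygons(geojson_path)
    if not geoms:
        raise ValueError("empty polygon set")
    lon = np.asarray(events["longitude"], dtype=float)
    lat = np.asarray(events["latitude"], dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("non-finite event coordinates")
    from shapely.geometry import Point

    tree = STRtree(geoms)
    counts = {tid: 0 for tid in ids}
    unassigned = 0
    for x, yy in zip(lon, lat):
        pt = Point(x, yy)
        hits = sorted(int(j) for j in tree.query(pt))
        placed = False
        for j in hits:
            if geoms[j].covers(pt):  # boundary counts as inside
                counts[ids[j]] += 1
                placed = True
                break
        if not placed:
            unassigned += 1
    if unassigned:
        log.info("%d events fell outside all tract polygons and were excluded", unassigned)
    return pd.Series(counts, name="homicide_count"), unassigned


def write_geojson(feature_collection: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_collection, fh)
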