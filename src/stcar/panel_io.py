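"""Reading, validating and writing areal count panels and adjacency structures.

The observational unit is an (area, year) cell of a complete N×T panel of
non-negative integer event counts with P real covariate columns.  The
spatial structure is an undirected contiguity graph over the N areas
("share a common border" -- rook-style contiguity when derived from
polygons: a shared boundary segment of positive length, never a corner
touch).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import shape

logger = logging.getLogger(__name__)


class PanelValidationError(ValueError):
    """A panel or adjacency file violates the format contract."""


class IncompletePanelError(PanelValidationError):
    """The panel is missing one or more (area, year) cells."""


@dataclass
class PanelSchema:
    """Column mapping for delimited-text panel files."""

    area_col: str = "area_id"
    year_col: str = "year"
    count_col: str = "count"
    covariate_cols: Sequence[str] | None = None  # None: every remaining column


@dataclass
class AreaPanel:
    """A complete area-by-year panel of counts and covariates.

    Attributes
    ----------
    area_ids : list of str
        Ordered unique area identifiers, length N.
    years : ndarray of int
        Consecutive years, length T.
    counts : ndarray, shape (N, T)
        Non-negative integer event counts y_it.
    covariates : ndarray, shape (N, T, P)
        Covariate values X_it; time-constant covariates are repeated
        across t.
    covariate_names : list of str
        P column labels.
    """

    area_ids: list[str]
    years: np.ndarray
    counts: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[2]

    def validate(self) -> "AreaPanel":
        if len(set(self.area_ids)) != len(self.area_ids):
            raise PanelValidationError("area_ids are not unique")
        self.years = np.asarray(self.years, dtype=int)
        if self.n_years > 1 and not np.all(np.diff(self.years) == 1):
            raise PanelValidationError(f"years are not consecutive: {self.years.tolist()}")
        counts = np.asarray(self.counts)
        if counts.shape != (self.n_areas, self.n_years):
            raise PanelValidationError(
                f"counts shape {counts.shape} != (N={self.n_areas}, T={self.n_years})"
            )
        if not np.all(np.isfinite(counts.astype(float))):
            raise PanelValidationError("counts contain non-finite values")
        if np.any(counts != np.floor(counts)) or np.any(counts < 0):
            bad = np.argwhere((counts != np.floor(counts)) | (counts < 0))[0]
            raise PanelValidationError(
                f"count at area {self.area_ids[bad[0]]}, year {self.years[bad[1]]} "
                "is negative or non-integer"
            )
        self.counts = counts.astype(np.int64)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim != 3 or cov.shape[:2] != (self.n_areas, self.n_years):
            raise PanelValidationError(
                f"covariates shape {cov.shape} != (N, T, P)"
            )
        if not np.all(np.isfinite(cov)):
            raise PanelValidationError("covariates contain non-finite values")
        self.covariates = cov
        if len(self.covariate_names) != cov.shape[2]:
            raise PanelValidationError("covariate_names length != P")
        return self

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per (area, year)."""
        n, t, p = self.covariates.shape
        rows = {
            "area_id": np.repeat(self.area_ids, t),
            "year": np.tile(self.years, n),
            "count": self.counts.reshape(-1),
        }
        for k, name in enumerate(self.covariate_names):
            rows[name] = self.covariates[:, :, k].reshape(-1)
        return pd.DataFrame(rows)


@dataclass
class AdjacencyGraph:
    """Undirected contiguity structure over the panel's areas.

    Neighbour sets are stored by area index (position in ``area_ids``);
    ``n`` holds the neighbour counts n_i and ``components`` the connected
    components (isolated areas form singleton components).
    """

    area_ids: list[str]
    neighbours: list[set[int]]
    n: np.ndarray = field(init=False)
    components: list[list[int]] = field(init=False)

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbours):
            if i in nb:
                raise PanelValidationError(f"self-loop at area {self.area_ids[i]}")
            for j in nb:
                if i not in self.neighbours[j]:
                    raise PanelValidationError(
                        f"asymmetric adjacency between {self.area_ids[i]} and {self.area_ids[j]}"
                    )
        self.n = np.array([len(nb) for nb in self.neighbours], dtype=int)
        g = self.to_networkx()
        self.components = [sorted(c) for c in nx.connected_components(g)]
        self.components.sort()
        isolated = [self.area_ids[i] for i in range(len(self.area_ids)) if self.n[i] == 0]
        if isolated:
            logger.warning("isolated areas (no neighbours): %s", isolated)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(i, j) for i, nb in enumerate(self.neighbours) for j in nb if i < j]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls, area_ids: Sequence[str], edges: Sequence[tuple[str, str]]
    ) -> "AdjacencyGraph":
        index = {a: i for i, a in enumerate(area_ids)}
        neighbours: list[set[int]] = [set() for _ in area_ids]
        seen: set[tuple[int, int]] = set()
        for a, b in edges:
            for x in (a, b):
                if x not in index:
                    raise PanelValidationError(f"adjacency pair references unknown area id {x!r}")
            i, j = index[a], index[b]
            if i == j:
                raise PanelValidationError(f"self-pair for area {a!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                logger.warning("duplicate adjacency pair (%s, %s) deduplicated", a, b)
                continue
            seen.add(key)
            neighbours[i].add(j)
            neighbours[j].add(i)
        return cls(list(area_ids), neighbours)


def read_panel(path: str | Path, schema: PanelSchema | None = None) -> AreaPanel:
    """Read a delimited-text panel (one row per (area, year)) into an AreaPanel.

    The file must contain a header naming the area, year and count columns
    of `schema`; remaining columns are taken as covariates unless the
    schema restricts them.  Rows are normalised to (area, year) order and
    the panel is validated for completeness.
    """
    schema = schema or PanelSchema()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    logger.info("read %d rows from %s", len(df), path)
    for col in (schema.area_col, schema.year_col, schema.count_col):
        if col not in df.columns:
            raise PanelValidationError(f"missing column {col!r} in {path}")
    cov_cols = list(
        schema.covariate_cols
        if schema.covariate_cols is not None
        else [c for c in df.columns if c not in (schema.area_col, schema.year_col, schema.count_col)]
    )
    df = df.sort_values([schema.area_col, schema.year_col], kind="mergesort")
    area_ids = sorted(df[schema.area_col].astype(str).unique())
    years = np.sort(df[schema.year_col].unique()).astype(int)
    dup = df.duplicated([schema.area_col, schema.year_col])
    if dup.any():
        r = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate cell for area {r[schema.area_col]!r}, year {r[schema.year_col]}"
        )
    if len(df) != len(area_ids) * len(years):
        have = set(zip(df[schema.area_col].astype(str), df[schema.year_col].astype(int)))
        for a in area_ids:
            for y in years:
                if (a, int(y)) not in have:
                    raise IncompletePanelError(f"panel is missing area {a!r}, year {y}")
    n, t = len(area_ids), len(years)
    counts = df[schema.count_col].to_numpy().reshape(n, t)
    covariates = np.empty((n, t, len(cov_cols)))
    for k, c in enumerate(cov_cols):
        covariates[:, :, k] = df[c].to_numpy(dtype=float).reshape(n, t)
    return AreaPanel(area_ids, years, counts, covariates, cov_cols).validate()


def write_panel(panel: AreaPanel, path: str | Path) -> None:
    """Write an AreaPanel to CSV (or TSV by extension), long format."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    panel.to_dataframe().to_csv(path, sep=sep, index=False)


def read_adjacency(path: str | Path, area_ids: Sequence[str]) -> AdjacencyGraph:
    """Read a two-column unordered neighbour-pair list into an AdjacencyGraph.

    Every pair must reference ids from ``area_ids``; duplicated pairs
    (including reversed duplicates) are deduplicated with a warning, and
    isolated areas are permitted but logged.
    """
    df = pd.read_csv(path, header=None, comment="#", dtype=str, skipinitialspace=True)
    if df.shape[1] < 2:
        raise PanelValidationError(f"adjacency file {path} needs two columns")
    known = set(map(str, area_ids))
    first = df.iloc[0]
    rest = df.iloc[1:]
    if (
        len(df) > 1
        and not {str(first.iloc[0]), str(first.iloc[1])} & known
        and set(rest.iloc[:, 0].astype(str)) <= known
        and set(rest.iloc[:, 1].astype(str)) <= known
    ):
        df = rest  # tolerate a header row
    edges = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    logger.info("read %d neighbour pairs from %s", len(edges), path)
    return AdjacencyGraph.from_edges(area_ids, edges)


def adjacency_from_polygons(
    path: str | Path, id_property: str = "area_id"
) -> AdjacencyGraph:
    """Derive rook-contiguity adjacency from a GeoJSON polygon file.

    Two areas are neighbours when their geometries share a boundary
    segment of positive length; polygons meeting only at a point are NOT
    neighbours.  Each GeoJSON feature must carry the area identifier in
    ``properties[id_property]`` (falling back to the feature ``id``).
    """
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features")
    if features is None:
        raise PanelValidationError(f"{path} is not a GeoJSON FeatureCollection")
    area_ids: list[str] = []
    geoms = []
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        aid = props.get(id_property, feat.get("id"))
        if aid is None:
            raise PanelValidationError(f"feature {k} has no {id_property!r} property or id")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # malformed geometry
            raise PanelValidationError(f"unreadable geometry for area {aid!r}: {exc}") from exc
        area_ids.append(str(aid))
        geoms.append(geom)
    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i].intersection(geoms[j])
            if not inter.is_empty and inter.length > 0:  # rook: shared segment, not a corner
                edges.append((area_ids[i], area_ids[j]))
    logger.info("derived %d rook-contiguity edges from %s", len(edges), path)
    return AdjacencyGraph.from_edges(area_ids, edges)


def center_covariates(panel: AreaPanel) -> tuple[AreaPanel, np.ndarray]:
    """Centre every covariate column to mean zero over all N×T cells.

    Returns the centred panel and the per-covariate offsets (grand means)
    so that a fitted intercept is interpretable at covariate means and
    original values can be restored.  Centring covariates is the standard
    conditioning step that improves MCMC mixing of the intercept.
    """
    offsets = panel.covariates.mean(axis=(0, 1))
    centred = panel.covariates - offsets[None, None, :]
    for k, name in enumerate(panel.covariate_names):
        if np.allclose(panel.covariates[:, :, k], panel.covariates[0, 0, k]):
            logger.warning("covariate %r is constant (zero variance after centring)", name)
    out = AreaPanel(
        list(panel.area_ids),
        panel.years.copy(),
        panel.counts.copy(),
        centred,
        list(panel.covariate_names),
    ).validate()
    return out, offsets


def panel_descriptives(panel: AreaPanel) -> dict:
    """Summarise per-area totals Σ_t y_it: mean, sample sd (N−1), min, max."""
    totals = panel.counts.sum(axis=1)
    sd = float(np.std(totals, ddof=1)) if len(totals) > 1 else float("nan")
    return {
        "n_areas": panel.n_areas,
        "n_years": panel.n_years,
        "total": int(totals.sum()),
        "mean": float(totals.mean()),
        "sd": sd,
        "min": int(totals.min()),
        "max": int(totals.max()),
    }
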