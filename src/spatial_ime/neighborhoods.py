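"""Cellular-neighborhood (CN) discovery and Voronoi export.

A cell's "window" is its lineage composition over itself plus its N nearest
neighbours (Euclidean, per image; row sums are therefore N + 1).  Windows
pooled across images are clustered with mini-batch k-means into K CNs; each
cell is assigned the CN of its window.  Per-image CN prevalences are
normalised so that they sum to 100% per sample.  Raw counts are clustered
rather than fractions: with N fixed the two differ by a constant factor and
yield identical k-means partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box
from sklearn.cluster import MiniBatchKMeans

from .io import LineageSet

__all__ = [
    "build_windows",
    "NeighborhoodModel",
    "fit_neighborhood_model",
    "assign_neighborhoods",
    "cn_prevalence",
    "compare_cn_abundance",
    "voronoi_export",
]


def build_windows(
    cells: pd.DataFrame,
    n_neighbors: int,
    lineages: LineageSet | None = None,
) -> pd.DataFrame:
    """Per-cell kNN composition windows (columns = lineages, rows = cells).

    Ties at the N-th neighbour distance are broken toward the lowest
    ``cell_id`` so the window is deterministic.  Images with fewer than
    N + 1 cells use all available cells and are listed in
    ``windows.attrs["degenerate_images"]``.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    lineages = lineages or LineageSet()
    lineages.validate_labels(cells["lineage"].astype(str))
    code_map = lineages.codes()
    T = len(lineages.names)

    mats, idx, degenerate = [], [], []
    for image_id, grp in cells.groupby("image_id", sort=True):
        n = len(grp)
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        codes = grp["lineage"].map(code_map).to_numpy(dtype=np.int64)
        # rank of cell_id gives the deterministic tie-break order
        id_rank = np.argsort(np.argsort(grp["cell_id"].to_numpy(), kind="stable"))
        k_eff = min(n_neighbors, n - 1)
        if k_eff < n_neighbors:
            degenerate.append(image_id)
        W = np.zeros((n, T), dtype=np.int64)
        if n == 1:
            W[0, codes[0]] = 1
        else:
            tree = cKDTree(xy)
            k_query = min(n, k_eff + 1 + 4)  # self + slack for distance ties
            dist, nbr = tree.query(xy, k=k_query)
            for c in range(n):
                cand_d, cand_i = dist[c], nbr[c]
                keep = cand_i != c
                cand_d, cand_i = cand_d[keep], cand_i[keep]
                order = np.lexsort((id_rank[cand_i], np.round(cand_d, 9)))
                chosen = cand_i[order[:k_eff]]
                W[c] = np.bincount(codes[chosen], minlength=T)
                W[c, codes[c]] += 1
        mats.append(W)
        idx.extend(zip(grp["image_id"], grp["cell_id"]))
    windows = pd.DataFrame(
        np.vstack(mats),
        columns=list(lineages.names),
        index=pd.MultiIndex.from_tuples(idx, names=["image_id", "cell_id"]),
    )
    windows.attrs["n_neighbors"] = n_neighbors
    windows.attrs["degenerate_images"] = degenerate
    return windows


@dataclass
class NeighborhoodModel:
    """Fitted CN model: K centroids over lineage-composition space."""

    kmeans: MiniBatchKMeans
    lineage_names: tuple[str, ...]
    k: int
    n_neighbors: int
    seed: int
    batch_size: int = 1024
    max_iter: int = 100

    @property
    def centroids(self) -> pd.DataFrame:
        """CN x lineage centroid matrix (mean window composition per CN)."""
        return pd.DataFrame(
            self.kmeans.cluster_centers_,
            index=[f"CN{i + 1}" for i in range(self.k)],
            columns=list(self.lineage_names),
        )


def fit_neighborhood_model(
    windows: pd.DataFrame,
    k: int,
    seed: int = 0,
    batch_size: int = 1024,
    max_iter: int = 100,
    n_init: int = 10,
) -> tuple[NeighborhoodModel, pd.DataFrame]:
    """Mini-batch k-means over window rows; returns (model, assignment).

    Assignment is a frame indexed like ``windows`` with an integer ``cn``
    column in 1..K.  k-means++ initialisation with a fixed seed makes the
    fit deterministic.  The model is typically fit on margin images and can
    project core images afterwards via :func:`assign_neighborhoods`.
    """
    W = windows.to_numpy(dtype=float)
    if k > len(W):
        raise ValueError(f"K={k} exceeds the number of window rows ({len(W)})")
    n_distinct = len(np.unique(W, axis=0))
    if k > n_distinct:
        warnings.warn(
            f"K={k} exceeds the {n_distinct} distinct window(s); "
            "consider a smaller K",
            stacklevel=2,
        )
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        max_iter=max_iter,
        n_init=n_init,
    )
    labels = km.fit_predict(W)
    model = NeighborhoodModel(
        kmeans=km,
        lineage_names=tuple(windows.columns),
        k=k,
        n_neighbors=int(windows.attrs.get("n_neighbors", -1)),
        seed=seed,
        batch_size=batch_size,
        max_iter=max_iter,
    )
    assignment = pd.DataFrame({"cn": labels + 1}, index=windows.index)
    return model, assignment


def assign_neighborhoods(model: NeighborhoodModel, windows: pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid CN labels for new windows (e.g. core images)."""
    labels = model.kmeans.predict(windows.to_numpy(dtype=float))
    return pd.DataFrame({"cn": labels + 1}, index=windows.index)


def cn_prevalence(assignment: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-image CN prevalence in percent; each row sums to exactly 100.

    Percentages are snapped to a dyadic grid (multiples of 2^-40, a
    sub-1e-12 perturbation) and the largest entry absorbs the residual;
    on that grid every float64 partial sum is exact, so the row sums equal
    100.0 under ``==`` for any summation order.
    """
    q = 2.0**40
    rows = {}
    for image_id, grp in assignment.groupby(level="image_id", sort=True):
        counts = np.bincount(grp["cn"].to_numpy() - 1, minlength=k).astype(float)
        pct = 100.0 * counts / counts.sum()
        pct = np.round(pct * q) / q
        pct[np.argmax(pct)] += 100.0 - pct.sum()
        rows[image_id] = pct
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"CN{i + 1}" for i in range(k)]
    ).rename_axis("image_id")


def compare_cn_abundance(
    prevalences: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    groups: tuple[str, str] = ("MI", "HI"),
) -> pd.DataFrame:
    """Per-CN two-tailed unpaired t-test of prevalence between the groups."""
    from scipy import stats

    pat = meta.set_index("image_id")["pattern"]
    joined = prevalences.join(pat, how="left")
    rows = []
    for cn in prevalences.columns:
        g0 = joined.loc[joined["pattern"] == groups[0], cn].to_numpy()
        g1 = joined.loc[joined["pattern"] == groups[1], cn].to_numpy()
        if len(g0) < 2 or len(g1) < 2:
            rows.append({"cn": cn, "p_value": np.nan, "favored_group": "",
                         "significant": False,
                         "skipped_reason": "group with <2 images"})
            continue
        p = float(stats.ttest_ind(g0, g1, equal_var=True).pvalue)
        m0, m1 = float(np.mean(g0)), float(np.mean(g1))
        rows.append({
            "cn": cn,
            f"mean_{groups[0]}": m0,
            f"mean_{groups[1]}": m1,
            "p_value": p,
            "favored_group": groups[0] if m0 >= m1 else groups[1],
            "significant": bool(p < alpha),
            "skipped_reason": "",
        })
    return pd.DataFrame(rows)


def voronoi_export(
    cells: pd.DataFrame,
    assignment: pd.DataFrame | None,
    bbox: tuple[float, float, float, float],
) -> list[dict]:
    """Voronoi tessellation of one image clipped to ``bbox``.

    Returns one record per cell: ``{"cell_id", "cn", "vertices", "area"}``.
    Every cell owns exactly one finite polygon and the polygons tile the
    bounding box (mirror-point construction: the point set is reflected
    across each bbox edge so that all original regions are bounded, then
    clipped).  Duplicate coordinates are jittered by 1e-9 um with a warning.
    """
    if len(cells) == 0:
        raise ValueError("voronoi_export requires at least one cell")
    xmin, ymin, xmax, ymax = bbox
    frame = box(xmin, ymin, xmax, ymax)
    xy = cells[["x", "y"]].to_numpy(dtype=float).copy()

    cn_for = None
    if assignment is not None:
        cn = assignment["cn"] if "cn" in assignment else assignment.iloc[:, 0]
        cn = cn.reset_index(level="image_id", drop=True) if isinstance(cn.index, pd.MultiIndex) else cn
        cn_for = dict(zip(cells["cell_id"], cn.reindex(cells["cell_id"]).to_numpy()))

    records = []
    if len(xy) == 1:
        poly = frame
        records.append(_voronoi_record(cells.iloc[0]["cell_id"], cn_for, poly))
        return records

    # deterministic de-duplication jitter
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    seen: dict[tuple[float, float], int] = {}
    for pos, c in enumerate(order):
        key = (xy[c, 0], xy[c, 1])
        reps = seen.get(key, 0)
        if reps:
            warnings.warn("duplicate coordinates jittered by 1e-9 um", stacklevel=2)
            xy[c, 0] += 1e-9 * reps
            xy[c, 1] += 1e-9 * reps
        seen[key] = reps + 1

    mirrors = [
        np.column_stack([2 * xmin - xy[:, 0], xy[:, 1]]),
        np.column_stack([2 * xmax - xy[:, 0], xy[:, 1]]),
        np.column_stack([xy[:, 0], 2 * ymin - xy[:, 1]]),
        np.column_stack([xy[:, 0], 2 * ymax - xy[:, 1]]),
    ]
    vor = Voronoi(np.vstack([xy, *mirrors]))
    for c in range(len(xy)):
        region = vor.regions[vor.point_region[c]]
        poly = Polygon(vor.vertices[region]).intersection(frame)
        records.append(_voronoi_record(cells.iloc[c]["cell_id"], cn_for, poly))
    return records


def _voronoi_record(cell_id, cn_for, poly) -> dict:
    if poly.geom_type != "Polygon":  # numeric slivers: keep the largest piece
        poly = max(poly.geoms, key=lambda g: g.area)
    return {
        "cell_id": cell_id,
        "cn": None if cn_for is None else cn_for.get(cell_id),
        "vertices": [(float(x), float(y)) for x, y in poly.exterior.coords],
        "area": float(poly.area),
    }
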