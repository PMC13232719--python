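"""Permutation-based pairwise cell-cell interaction / avoidance scoring.

For every image and ordered lineage pair (row -> column) the observed
statistic is the mean, over cells of the "from" type, of the number of
"to"-type cells within the interaction radius (6 um by default; the focal
cell never counts itself).  Lineage labels are then shuffled over the fixed
coordinate multiset ``n_perm`` times; the interaction score counts
permutations whose statistic falls strictly below the observed one, the
avoidance score those strictly above, and ties fill a separate bucket, so

    interaction_score + avoidance_score + tie_count == n_perm

holds for every pair.  A pair is classified as interacting (avoiding) when
its interaction (avoidance) score exceeds the score cutoff, n_perm/2 by
default.  Because the permutation preserves lineage frequencies, the
"from"-type count is constant across permutations and the strict comparisons
can be carried out on integer directed-edge counts, which makes the tie
bucket exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .io import AnalysisConfig, LineageSet, UnknownLineageError

__all__ = [
    "neighbor_stat",
    "permutation_scores",
    "compare_pair_distributions",
    "group_net_matrix",
]


def _directed_edges(xy: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return i, j


def neighbor_stat(
    cells: pd.DataFrame,
    type_from: str,
    type_to: str,
    radius_um: float,
    lineages: LineageSet | None = None,
) -> float:
    """Mean number of ``type_to`` neighbours within ``radius_um`` per
    ``type_from`` cell (self excluded).  0.0 when no ``type_from`` cell exists.

    A type label is "unknown" (an error) when it is outside the declared
    palette — or, if no palette is given, absent from the image entirely.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    known = set(lineages.names) if lineages is not None else set(cells["lineage"])
    for t in (type_from, type_to):
        if t not in known:
            raise UnknownLineageError(f"unknown type label {t!r}")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    lab = cells["lineage"].to_numpy()
    i, j = _directed_edges(xy, radius_um)
    n_from = int((lab == type_from).sum())
    if n_from == 0:
        return 0.0
    hits = int(np.sum((lab[i] == type_from) & (lab[j] == type_to)))
    return hits / n_from


def _image_scores(
    xy: np.ndarray,
    codes: np.ndarray,
    n_types: int,
    radius: float,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(observed_counts, less, greater, type_counts), each (T, T) / (T,)."""
    i, j = _directed_edges(xy, radius)
    T = n_types
    obs = np.bincount(codes[i] * T + codes[j], minlength=T * T).reshape(T, T)
    less = np.zeros((T, T), dtype=np.int64)
    greater = np.zeros((T, T), dtype=np.int64)
    if len(i):
        done = 0
        while done < n_perm:
            p = min(chunk, n_perm - done)
            labels = np.tile(codes, (p, 1))
            labels = rng.permuted(labels, axis=1)
            pair_code = labels[:, i] * T + labels[:, j]
            flat = (np.arange(p)[:, None] * (T * T) + pair_code).ravel()
            cnt = np.bincount(flat, minlength=p * T * T).reshape(p, T, T)
            less += (cnt < obs).sum(axis=0)
            greater += (cnt > obs).sum(axis=0)
            done += p
    # no edges: every permutation ties the observed zero for every pair
    type_counts = np.bincount(codes, minlength=T)
    return obs, less, greater, type_counts


def permutation_scores(
    cells: pd.DataFrame,
    lineages: LineageSet | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Interaction/avoidance scores for all ordered lineage pairs, per image.

    One permutation stream re-scores every pair of an image simultaneously
    (a single label shuffle yields all pairwise statistics).  Pairs whose
    "from" or "to" type is absent from an image are flagged
    ``present=False`` and classified ``"absent"``; group-level summaries
    must exclude them.  Deterministic given the seed.
    """
    lineages = lineages or LineageSet()
    cfg = config or AnalysisConfig()
    lineages.validate_labels(cells["lineage"].astype(str))
    code_map = lineages.codes()
    T = len(lineages.names)
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)

    out = []
    for image_id, grp in cells.groupby("image_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"image {image_id!r} has <2 cells")
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        codes = grp["lineage"].map(code_map).to_numpy(dtype=np.int64)
        obs, less, greater, n_type = _image_scores(
            xy, codes, T, cfg.radius_um, cfg.n_perm, rng
        )
        ties = cfg.n_perm - less - greater
        for a, ta in enumerate(lineages.names):
            for b, tb in enumerate(lineages.names):
                present = n_type[a] > 0 and n_type[b] > 0
                if present:
                    stat = obs[a, b] / n_type[a]
                    isc, asc, tie = int(less[a, b]), int(greater[a, b]), int(ties[a, b])
                    if isc > cfg.score_cutoff:
                        cls = "interaction"
                    elif asc > cfg.score_cutoff:
                        cls = "avoidance"
                    else:
                        cls = "none"
                else:
                    stat, isc, asc, tie, cls = np.nan, 0, 0, 0, "absent"
                out.append(
                    {
                        "image_id": image_id,
                        "type_from": ta,
                        "type_to": tb,
                        "present": present,
                        "n_from": int(n_type[a]),
                        "n_to": int(n_type[b]),
                        "observed_stat": stat,
                        "interaction_score": isc,
                        "avoidance_score": asc,
                        "tie_count": tie,
                        "classification": cls,
                    }
                )
    return pd.DataFrame(out)


def _net(results: pd.DataFrame) -> pd.Series:
    n_perm = (
        results["interaction_score"] + results["avoidance_score"] + results["tie_count"]
    )
    return (results["interaction_score"] - results["avoidance_score"]) / n_perm


def compare_pair_distributions(
    results: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    groups: tuple[str, str] = ("MI", "HI"),
    test: str = "t",
) -> pd.DataFrame:
    """Per ordered pair, compare per-image net scores between the two groups.

    The net score is (interaction - avoidance) / n_perm in [-1, 1], positive
    when interaction-favouring.  Two-tailed unpaired t-test by default;
    ``test="mannwhitney"`` switches to the rank test.  Pairs without at least
    two present images per group are excluded with a reason.
    """
    cfg = config or AnalysisConfig()
    res = results[results["present"]].copy()
    res["net"] = _net(res)
    res = res.merge(meta[["image_id", "pattern"]], on="image_id", how="left")
    rows = []
    for (ta, tb), d in res.groupby(["type_from", "type_to"], sort=True):
        g0 = d.loc[d["pattern"] == groups[0], "net"].to_numpy()
        g1 = d.loc[d["pattern"] == groups[1], "net"].to_numpy()
        row = {"type_from": ta, "type_to": tb,
               f"n_{groups[0]}": len(g0), f"n_{groups[1]}": len(g1),
               "excluded_reason": ""}
        if len(g0) < 2 or len(g1) < 2:
            row.update(p_value=np.nan, favored_group="", significant=False,
                       excluded_reason="fewer than 2 present images in a group")
        else:
            if test == "t":
                p = float(stats.ttest_ind(g0, g1, equal_var=True).pvalue)
            elif test == "mannwhitney":
                p = float(stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            m0, m1 = float(np.mean(g0)), float(np.mean(g1))
            row.update(
                p_value=p,
                favored_group=groups[0] if m0 >= m1 else groups[1],
                significant=bool(p < cfg.alpha),
                **{f"mean_net_{groups[0]}": m0, f"mean_net_{groups[1]}": m1},
            )
        rows.append(row)
    return pd.DataFrame(rows)


def group_net_matrix(
    results: pd.DataFrame, meta: pd.DataFrame, group: str,
    lineages: LineageSet | None = None,
) -> pd.DataFrame:
    """Square lineage x lineage matrix of mean net scores for one group
    (rows read row-to-column); NaN where a pair was never present.
    """
    lineages = lineages or LineageSet()
    res = results[results["present"]].copy()
    res["net"] = _net(res)
    res = res.merge(meta[["image_id", "pattern"]], on="image_id", how="left")
    res = res[res["pattern"] == group]
    mat = res.pivot_table(index="type_from", columns="type_to", values="net", aggfunc="mean")
    return mat.reindex(index=lineages.names, columns=lineages.names)
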