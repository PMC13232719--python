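"""IHC / IHF quantification: phenotype gating, H-scores, margin/core
ratios and rank correlation between per-sample marker summaries.

A gate is a conjunction of marker thresholds, e.g. the CD8+ T-cell gate
CD8+ CD4- PanCK-: a cell matches iff every required-positive marker is at
or above its threshold and every required-negative marker is below its
threshold.  Gates are evaluated independently — a cell may match several —
because marker combinations, not an exclusive partition, are what gets
reported.

The H-score of a region of interest is staining intensity (0-3) times the
percentage of positive cells (0-100), bounded by 300; the margin/core ratio
divides the mean margin H-score by the mean core H-score per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateSpec",
    "gate_phenotypes",
    "phenotype_fractions",
    "h_score",
    "h_score_table",
    "margin_core_ratio",
    "correlate_markers",
    "DEFAULT_GATES",
]


@dataclass(frozen=True)
class GateSpec:
    """One phenotype gate: required-positive and required-negative markers
    with per-marker thresholds."""

    name: str
    positive: Mapping[str, float] = field(default_factory=dict)
    negative: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"gate {self.name!r}: markers both positive and negative: {sorted(overlap)}"
            )


def default_gates(thr: float = 1.0) -> tuple[GateSpec, ...]:
    """The T-cell multiplex gates: CD8+ T (CD8+CD4-PanCK-), CD4+ T
    (CD8-CD4+PanCK-), cancer (CD8-CD4-PanCK+)."""
    return (
        GateSpec("CD8 T cell", {"CD8": thr}, {"CD4": thr, "PanCK": thr}),
        GateSpec("CD4 T cell", {"CD4": thr}, {"CD8": thr, "PanCK": thr}),
        GateSpec("Cancer cell", {"PanCK": thr}, {"CD8": thr, "CD4": thr}),
    )


DEFAULT_GATES = default_gates()


def gate_phenotypes(cells: pd.DataFrame, gates: Sequence[GateSpec]) -> pd.DataFrame:
    """Boolean cell x gate matrix; raises naming the gate and marker on a
    missing intensity column."""
    out = {}
    for gate in gates:
        mask = np.ones(len(cells), dtype=bool)
        for marker, thr in gate.positive.items():
            if marker not in cells.columns:
                raise KeyError(f"gate {gate.name!r}: marker {marker!r} missing")
            mask &= cells[marker].to_numpy(dtype=float) >= thr
        for marker, thr in gate.negative.items():
            if marker not in cells.columns:
                raise KeyError(f"gate {gate.name!r}: marker {marker!r} missing")
            mask &= cells[marker].to_numpy(dtype=float) < thr
        out[gate.name] = mask
    return pd.DataFrame(out, index=cells.index)


def phenotype_fractions(
    cells: pd.DataFrame,
    matches: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    stroma_marker: str = "PanCK",
    stroma_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-image (and region, when metadata is given) percent of stroma
    matching each gate.  Stroma = cells below the epithelial marker
    threshold (PanCK-negative)."""
    if stroma_marker not in cells.columns:
        raise KeyError(f"stroma marker {stroma_marker!r} missing")
    stroma = cells[stroma_marker].to_numpy(dtype=float) < stroma_threshold
    rows = []
    for image_id, idx in cells.groupby("image_id", sort=True).groups.items():
        loc = cells.index.get_indexer(idx)
        denom = int(stroma[loc].sum())
        for gate in matches.columns:
            hits = int((matches[gate].to_numpy()[loc] & stroma[loc]).sum())
            rows.append(
                {
                    "image_id": image_id,
                    "phenotype": gate,
                    "n_stroma": denom,
                    "percent_of_stroma": np.nan if denom == 0 else 100.0 * hits / denom,
                }
            )
    out = pd.DataFrame(rows)
    if meta is not None:
        out = out.merge(meta, on="image_id", how="left")
    return out


def h_score(intensity_score: int, percent_positive: float) -> float:
    """intensity (0-3) x percent positive (0-100); range 0-300."""
    if intensity_score not in (0, 1, 2, 3):
        raise ValueError("intensity_score must be one of 0, 1, 2, 3")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must lie in [0, 100]")
    return float(intensity_score) * float(percent_positive)


def h_score_table(rois: pd.DataFrame) -> pd.DataFrame:
    """Vectorised H-scores for a per-ROI summary table with columns
    ``sample_id, region, roi_id, intensity_score, percent_positive``."""
    out = rois.copy()
    out["h_score"] = [
        h_score(int(i), float(p))
        for i, p in zip(rois["intensity_score"], rois["percent_positive"])
    ]
    return out


def margin_core_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ratio of mean margin H-score to mean core H-score.

    ROI H-scores are averaged within each region first, then the ratio is
    formed.  Samples missing a region are skipped with a reason; a core mean
    of 0 yields an undefined (NaN, flagged) ratio, never infinity.
    """
    rows = []
    for sample_id, grp in records.groupby("sample_id", sort=True):
        regions = set(grp["region"])
        row = {"sample_id": sample_id, "flag": ""}
        if not {"core", "margin"} <= regions:
            missing = sorted({"core", "margin"} - regions)
            row.update(margin_mean=np.nan, core_mean=np.nan, ratio=np.nan,
                       flag=f"missing region(s): {','.join(missing)}")
            rows.append(row)
            continue
        m = float(grp.loc[grp["region"] == "margin", "h_score"].mean())
        c = float(grp.loc[grp["region"] == "core", "h_score"].mean())
        ratio = np.nan if c == 0 else m / c
        row.update(margin_mean=m, core_mean=c, ratio=ratio,
                   flag="core mean is 0; ratio undefined" if c == 0 else "")
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_markers(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected ranks.

    P-value by the t-approximation for n > ``exact_max_n`` and by exact
    permutation (all n! orderings, two-sided on |r_s|) for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        if abs(rs) >= 1.0:
            return rs, 0.0
        t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return rs, float(p)
    # exact permutation null over orderings of one variable (chunked so the
    # n = 10 case, 3.6M orderings, stays in bounded memory)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    obs = abs((rxc * ryc).sum() / denom)
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    for perm in permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            r = np.abs(ryc[np.asarray(chunk)] @ rxc / denom)
            count += int((r >= obs - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        r = np.abs(ryc[np.asarray(chunk)] @ rxc / denom)
        count += int((r >= obs - 1e-12).sum())
        total += len(chunk)
    return rs, count / total
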