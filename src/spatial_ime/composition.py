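"""Cell-frequency profiling as percentage of stroma and group comparison.

Stroma = all non-cancer cells (the "Undefined" bucket included by default).
Frequencies are reported per image as percent of stromal cells, so they are
invariant to the number of cancer cells in the image.  Group comparisons use
a two-tailed unpaired t-test for two groups and one-way ANOVA for more.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, LineageSet

__all__ = ["stromal_frequencies", "compare_groups"]


def stromal_frequencies(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    lineages: LineageSet | None = None,
) -> pd.DataFrame:
    """Tidy table of (image_id x stromal lineage) percent-of-stroma.

    The denominator is the number of cells whose lineage counts as stroma;
    cancer cells appear in neither numerator nor denominator.  An image with
    zero stromal cells yields missing values and a warning, never a division
    by zero.
    """
    lineages = lineages or LineageSet()
    stroma = list(lineages.stroma)
    rows = []
    for image_id, grp in cells.groupby("image_id", sort=True):
        mask = grp["lineage"].isin(stroma)
        denom = int(mask.sum())
        counts = grp.loc[mask, "lineage"].value_counts()
        if denom == 0:
            warnings.warn(
                f"image {image_id!r} has no stromal cells; frequencies undefined",
                stacklevel=2,
            )
        for lin in stroma:
            pct = np.nan if denom == 0 else 100.0 * counts.get(lin, 0) / denom
            rows.append({"image_id": image_id, "lineage": lin, "percent_of_stroma": pct})
    freqs = pd.DataFrame(rows)
    return freqs.merge(meta, on="image_id", how="left")


def _test_groups(groups: list[np.ndarray], equal_var: bool) -> tuple[float, float]:
    if len(groups) == 2:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    else:
        res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    freqs: pd.DataFrame,
    factor: str = "pattern",
    stratify_by: str | None = "region",
    config: AnalysisConfig | None = None,
    equal_var: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per (lineage x stratum) comparison of percent-of-stroma across groups.

    Two groups: two-tailed unpaired Student's t-test (``equal_var=False``
    switches to Welch).  More than two: one-way ANOVA.  Groups with fewer
    than two images are skipped with a recorded reason.  No multiple-testing
    correction by default; ``adjust=True`` adds Benjamini-Hochberg q-values.
    """
    cfg = config or AnalysisConfig()
    strata = [None] if stratify_by is None else sorted(freqs[stratify_by].dropna().unique())
    rows = []
    for stratum in strata:
        sub = freqs if stratum is None else freqs[freqs[stratify_by] == stratum]
        for lin, d in sub.groupby("lineage", sort=True):
            d = d.dropna(subset=["percent_of_stroma"])
            names = sorted(d[factor].dropna().unique())
            groups = [d.loc[d[factor] == g, "percent_of_stroma"].to_numpy() for g in names]
            row = {
                "lineage": lin,
                "region": stratum,
                "groups": "|".join(map(str, names)),
                "skipped_reason": "",
            }
            small = [str(g) for g, v in zip(names, groups) if len(v) < 2]
            if len(names) < 2 or small:
                row.update(
                    statistic=np.nan,
                    p_value=np.nan,
                    direction="",
                    significant=False,
                    skipped_reason=(
                        "fewer than 2 groups" if len(names) < 2
                        else f"group(s) with <2 images: {','.join(small)}"
                    ),
                )
            else:
                stat, p = _test_groups(groups, equal_var)
                means = {g: float(np.mean(v)) for g, v in zip(names, groups)}
                row.update(
                    statistic=stat,
                    p_value=p,
                    direction=max(means, key=means.get),
                    significant=bool(p < cfg.alpha),
                )
                for g in names:
                    row[f"mean_{g}"] = means[g]
            rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["q_value"] = q
    return out
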