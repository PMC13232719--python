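"""GeoMx digital-spatial-profiling matrix processing, differential
expression and preranked gene-set enrichment.

Pipeline order is fixed: probe collapse (geometric means per target) ->
per-ROI limit of quantification (LOQ) from the negative-control probes ->
target filtering (keep targets above LOQ in >= 1 ROI) -> ROI quality control
(drop low-total-count ROIs) -> rounding -> negative-binomial Wald
differential expression with Benjamini-Hochberg adjustment -> preranked
GSEA on the log2 fold changes.

The LOQ is "2 standard deviations above the geometric mean" of the negative
controls, read multiplicatively on the log scale (geometric SD), the
standard convention for lognormal spike-ins:

    LOQ(roi) = geomean(neg) * geoSD(neg)^2,   geoSD = exp(sd(ln neg))

An arithmetic variant is available via ``mode="arithmetic"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "TargetMatrix",
    "load_probe_matrix",
    "collapse_probes",
    "compute_loq",
    "filter_targets",
    "qc_rois",
    "size_factors",
    "de_nb_wald",
    "zscore_heatmap_matrix",
    "preranked_gsea",
]

PROBE_META_COLUMNS = ("probe_id", "target", "is_negative")


@dataclass
class TargetMatrix:
    """Targets x ROIs geometric-mean matrix plus the negative-control block."""

    values: pd.DataFrame            # targets x ROIs
    negatives: pd.DataFrame         # negative probes x ROIs (raw counts)
    loq: pd.Series | None = None    # per ROI
    excluded_targets: list = field(default_factory=list)
    excluded_rois: list = field(default_factory=list)

    @property
    def rois(self) -> list[str]:
        return list(self.values.columns)


def load_probe_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Read a probe-level count table exported as delimited text.

    Expected columns: ``probe_id, target, is_negative`` then one count
    column per ROI — the dialect written by the simulator and by common
    spreadsheet exports of DSP runs.
    """
    from pathlib import Path

    path = Path(path)
    sep = sep or ("\t" if path.suffix.lower() in {".tsv", ".txt"} else ",")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PROBE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe matrix missing column(s): {', '.join(missing)}")
    df["is_negative"] = df["is_negative"].astype(bool)
    df["target"] = df["target"].fillna("")
    return df


def _geomean_with_zero_rule(values: np.ndarray) -> float:
    """Geometric mean; a pseudocount of 0.5 is added to every value of the
    group only when the group contains a zero."""
    v = np.asarray(values, dtype=float)
    if (v == 0).any():
        v = v + 0.5
    if len(v) == 1:  # exact pass-through for single-probe targets
        return float(v[0])
    return float(np.exp(np.mean(np.log(v))))


def collapse_probes(probes: pd.DataFrame) -> TargetMatrix:
    """Collapse the probe matrix to per-target geometric means per ROI."""
    roi_cols = [c for c in probes.columns if c not in PROBE_META_COLUMNS]
    if not roi_cols:
        raise ValueError("probe matrix has no ROI columns")
    neg = probes[probes["is_negative"]]
    tgt = probes[~probes["is_negative"]]
    if (tgt["target"] == "").any():
        raise ValueError("non-control probe with empty target mapping")
    sizes = tgt.groupby("target").size()
    if len(sizes) and not sizes.between(1, 5).all():
        bad = sizes[~sizes.between(1, 5)].index.tolist()
        raise ValueError(f"target(s) with probe count outside 1-5: {bad}")
    values = tgt.groupby("target", sort=True)[roi_cols].agg(
        lambda col: _geomean_with_zero_rule(col.to_numpy())
    )
    negatives = neg.set_index("probe_id")[roi_cols].astype(float)
    return TargetMatrix(values=values, negatives=negatives)


def compute_loq(tm: TargetMatrix, mode: str = "geometric") -> pd.Series:
    """Per-ROI limit of quantification from the negative-control probes.

    ``geometric`` (default): geomean(neg) * exp(2 * sd(ln neg)) — two
    geometric SDs above the geometric mean.  ``arithmetic``: geomean + 2 *
    arithmetic SD.  ROIs whose negatives are all zero get NaN and a warning.
    """
    out = {}
    for roi in tm.negatives.columns:
        neg = tm.negatives[roi].to_numpy(dtype=float)
        if len(neg) < 2:
            raise ValueError(f"ROI {roi!r} has <2 negative-control values")
        if (neg == 0).all():
            warnings.warn(f"ROI {roi!r}: all negative controls zero; LOQ undefined",
                          stacklevel=2)
            out[roi] = np.nan
            continue
        if (neg == 0).any():
            neg = neg + 0.5
        logs = np.log(neg)
        gm = math.exp(logs.mean())
        if mode == "geometric":
            out[roi] = gm * math.exp(2.0 * logs.std(ddof=1))
        elif mode == "arithmetic":
            out[roi] = gm + 2.0 * neg.std(ddof=1)
        else:
            raise ValueError(f"unknown LOQ mode {mode!r}")
    loq = pd.Series(out, name="loq")
    tm.loq = loq
    return loq


def filter_targets(tm: TargetMatrix) -> TargetMatrix:
    """Keep targets whose value exceeds the LOQ in at least one ROI."""
    if tm.loq is None:
        compute_loq(tm)
    above = tm.values.gt(tm.loq, axis=1)
    keep = above.any(axis=1)
    excluded = tm.values.index[~keep].tolist()
    return TargetMatrix(
        values=tm.values.loc[keep],
        negatives=tm.negatives,
        loq=tm.loq,
        excluded_targets=excluded,
        excluded_rois=list(tm.excluded_rois),
    )


def qc_rois(tm: TargetMatrix, min_total_count: float = 0.0) -> TargetMatrix:
    """Drop ROIs whose total (summed target values) falls below the threshold."""
    totals = tm.values.sum(axis=0)
    keep = totals >= min_total_count
    if not keep.any():
        raise ValueError(
            f"min_total_count={min_total_count} would drop every ROI "
            f"(max total {totals.max():.1f})"
        )
    dropped = [(roi, float(totals[roi])) for roi in totals.index[~keep]]
    return TargetMatrix(
        values=tm.values.loc[:, keep],
        negatives=tm.negatives.loc[:, keep],
        loq=None if tm.loq is None else tm.loq[keep.index[keep]],
        excluded_targets=list(tm.excluded_targets),
        excluded_rois=list(tm.excluded_rois) + dropped,
    )


# ---------------------------------------------------------------------------
# differential expression: NB GLM with Wald test, DESeq-style preprocessing


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene log geomean over
    genes positive in every sample); falls back to total-count ratios when no
    gene is positive everywhere."""
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logmat = np.log(mat[allpos])
        ref = logmat.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logmat - ref, axis=0))
    else:
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, X: np.ndarray) -> float:
    """Per-gene NB dispersion by Cox-Reid adjusted profile likelihood
    (mu fixed), with a method-of-moments fallback when the optimiser
    degenerates.

    The Cox-Reid term -0.5 log det(X' W X), with W the iteratively
    reweighted least squares working weights mu/(1 + alpha mu), corrects the
    downward bias of the plain profile MLE at small sample sizes.
    """
    mu = np.maximum(mu, 1e-8)
    mom = max(float(np.mean(((y - mu) ** 2 - mu) / mu**2)), 1e-8)

    def nll(log_a: float) -> float:
        a = math.exp(log_a)
        w = mu / (1.0 + a * mu)
        _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        return -(_nb_loglik(y, mu, a) - 0.5 * logdet)

    try:
        res = optimize.minimize_scalar(
            nll, bounds=(math.log(1e-8), math.log(50.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        alpha = math.exp(res.x) if res.success else mom
    except (ValueError, FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
        alpha = mom
    return float(min(max(alpha, 1e-8), 50.0))


def _fit_gene(y: np.ndarray, group: np.ndarray, offset: np.ndarray):
    """Two-group NB GLM (log link, offset = log size factor); Wald test on
    the group coefficient.  Returns (log2fc, se_log2, p) or None on failure.

    The Wald statistic is referred to a t distribution with n - 2 degrees
    of freedom rather than the normal: with roughly a dozen regions of
    interest per contrast the plug-in dispersion makes the normal reference
    visibly anticonservative.
    """
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(offset), group.astype(float)])
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _estimate_alpha(y, pois.mu, X)
        if alpha <= 1e-7:
            res = pois
        else:
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(start_params=pois.params)
    except Exception:
        return None
    coef, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
        return None
    z = coef / se
    p = 2.0 * stats.t.sf(abs(z), df=max(len(y) - 2, 1))
    ln2 = math.log(2.0)
    return coef / ln2, se / ln2, float(p)


def de_nb_wald(
    counts: pd.DataFrame,
    condition: pd.Series,
    baseline: str = "HI",
    padj_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald differential expression.

    ``counts`` is targets x ROIs (the filtered geometric-mean matrix; values
    are rounded to integers first), ``condition`` maps ROI -> group label.
    log2FC is the non-baseline group relative to ``baseline``.  P-values are
    BH-adjusted; ``significant`` marks padj < ``padj_threshold``.  Genes with
    all-zero counts, or for which the GLM cannot be fit (e.g. one group all
    zero), are flagged and excluded from the adjustment.
    """
    condition = condition.reindex(counts.columns)
    if condition.isna().any():
        raise ValueError("condition missing for some ROI(s)")
    levels = sorted(condition.unique())
    if len(levels) != 2 or baseline not in levels:
        raise ValueError(f"need exactly 2 conditions incl. baseline {baseline!r}, got {levels}")
    test_level = next(l for l in levels if l != baseline)
    n_per = condition.value_counts()
    if (n_per < 2).any():
        raise ValueError("each condition needs >= 2 ROIs")

    mat = np.round(counts.to_numpy(dtype=float)).astype(np.int64)
    rounded = pd.DataFrame(mat, index=counts.index, columns=counts.columns)
    sf = size_factors(rounded)
    offset = np.log(sf.to_numpy())
    group = (condition == test_level).to_numpy()

    rows = []
    for gi, gene in enumerate(rounded.index):
        y = mat[gi]
        if (y == 0).all():
            rows.append({"gene": gene, "base_mean": 0.0, "log2fc": np.nan,
                         "lfc_se": np.nan, "p_value": np.nan, "flag": "all_zero"})
            continue
        fit = _fit_gene(y, group, offset)
        if fit is None:
            rows.append({"gene": gene, "base_mean": float(np.mean(y / sf.to_numpy())),
                         "log2fc": np.nan, "lfc_se": np.nan, "p_value": np.nan,
                         "flag": "fit_failed"})
            continue
        l2fc, se, p = fit
        rows.append({"gene": gene, "base_mean": float(np.mean(y / sf.to_numpy())),
                     "log2fc": l2fc, "lfc_se": se, "p_value": p, "flag": ""})
    de = pd.DataFrame(rows)

    from statsmodels.stats.multitest import multipletests

    ok = de["p_value"].notna()
    padj = np.full(len(de), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = multipletests(de.loc[ok, "p_value"], method="fdr_bh")[1]
    de["padj"] = padj
    de["significant"] = de["padj"] < padj_threshold
    de.attrs["baseline"] = baseline
    de.attrs["test_level"] = test_level
    return de


def zscore_heatmap_matrix(
    counts: pd.DataFrame,
    de: pd.DataFrame | None = None,
    padj_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes x ROIs z-score matrix of log10 library-size-normalised counts.

    Per gene: z-score across ROIs of log10(count / library_size *
    median(library_size) + pseudocount), sample SD (ddof=1); genes constant
    across ROIs map to all-zero rows.  When a DE table is given only genes
    with padj < ``padj_threshold`` are included.
    """
    sel = counts
    if de is not None:
        genes = de.loc[de["padj"] < padj_threshold, "gene"]
        sel = counts.loc[counts.index.intersection(genes)]
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    norm = sel.to_numpy(dtype=float) / lib * np.median(lib)
    x = np.log10(norm + pseudocount)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.DataFrame(z, index=sel.index, columns=sel.columns)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(metric_sorted: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Weighted Kolmogorov-Smirnov running sum over the ranked universe."""
    n = len(metric_sorted)
    nh = int(hit.sum())
    w = np.abs(metric_sorted) ** weight
    hit_total = w[hit].sum()
    inc = np.where(hit, np.divide(w, hit_total, out=np.zeros_like(w), where=hit_total > 0), 0.0)
    if n > nh:
        inc = inc - np.where(hit, 0.0, 1.0 / (n - nh))
    return np.cumsum(inc)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    # extreme deviation from zero; exact +/- magnitude ties resolve positive
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if running[imax] >= -running[imin]:
        return float(running[imax]), imax
    return float(running[imin]), imin


def preranked_gsea(
    ranks: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked GSEA on a gene -> metric series (e.g. log2 fold changes).

    The enrichment score is the extreme deviation of the weighted
    running sum (hit steps proportional to |metric|^weight, miss steps
    uniform).  The null is gene-label permutation: ``n_perm`` random
    same-size sets.  P-values and the normalised ES are sign-stratified
    (ES compared against same-sign null scores, NES = ES / mean |same-sign
    null|); BH adjustment across sets.  Sets overlapping the universe in
    fewer than ``min_size`` genes are skipped.
    """
    if len(ranks) == 0:
        raise ValueError("empty ranked universe")
    rng = np.random.default_rng(seed)
    ranks = ranks.dropna()
    order = ranks.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break: metric desc, then gene name
    order = order.iloc[np.lexsort((order.index.to_numpy(), -order.to_numpy()))]
    genes = order.index.to_numpy()
    metric = order.to_numpy(dtype=float)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for name, members in gene_sets.items():
        pos = np.asarray(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        nh = len(pos)
        if nh < min_size:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        running = _running_es(metric, hit, weight)
        es, peak = _es_from_running(running)

        # permutation null: random same-size gene sets
        keys = rng.random((n_perm, n))
        null_idx = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
        w = np.abs(metric) ** weight
        miss = 1.0 / (n - nh) if n > nh else 0.0
        inc = np.full((n_perm, n), -miss)
        rowsel = np.repeat(np.arange(n_perm), nh)
        hw = w[null_idx]
        hw_tot = hw.sum(axis=1, keepdims=True)
        hw_tot[hw_tot == 0] = 1.0
        inc[rowsel, null_idx.ravel()] = (hw / hw_tot).ravel()
        run = np.cumsum(inc, axis=1)
        mx, mn = run.max(axis=1), run.min(axis=1)
        null_es = np.where(mx >= -mn, mx, mn)

        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
            nes = es / np.mean(np.abs(same))
        if es >= 0:
            lead = [genes[i] for i in pos if i <= peak]
        else:
            lead = [genes[i] for i in pos if i >= peak]
        rows.append({"pathway": name, "es": es, "nes": float(nes), "p_value": float(p),
                     "size": nh, "leading_edge": ";".join(map(str, lead))})

    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["padj"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out
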