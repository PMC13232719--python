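"""DSP matrix processing, NB differential expression and preranked GSEA."""

import math

import numpy as np
import pandas as pd
import pytest

from spatial_ime.geomx import (
    TargetMatrix,
    collapse_probes,
    compute_loq,
    de_nb_wald,
    filter_targets,
    preranked_gsea,
    qc_rois,
    size_factors,
    zscore_heatmap_matrix,
)
from spatial_ime.scenarios import geomx_planted_config
from spatial_ime.simulate import GeoMxSimConfig, simulate_geomx


def make_probes(spec, rois=("r1",)):
    """spec: list of (target_or_None, counts_per_roi)."""
    rows = []
    for i, (target, counts) in enumerate(spec):
        rows.append(
            {"probe_id": f"p{i}", "target": target or "",
             "is_negative": target is None,
             **{roi: c for roi, c in zip(rois, np.atleast_1d(counts))}}
        )
    return pd.DataFrame(rows)


class TestCollapse:
    def test_single_probe_passes_through(self):
        tm = collapse_probes(make_probes([("T1", 7), (None, 1), (None, 2)]))
        assert tm.values.loc["T1", "r1"] == 7.0

    def test_geometric_mean_of_two_probes(self):
        tm = collapse_probes(make_probes([("T1", 4), ("T1", 9), (None, 1), (None, 2)]))
        assert tm.values.loc["T1", "r1"] == pytest.approx(6.0)

    def test_zero_count_triggers_half_pseudocount(self):
        tm = collapse_probes(make_probes([("T1", 0), ("T1", 8), (None, 1), (None, 2)]))
        assert tm.values.loc["T1", "r1"] == pytest.approx(math.sqrt(0.5 * 8.5))

    def test_unmapped_probe_rejected(self):
        bad = make_probes([("T1", 3), (None, 1)])
        bad.loc[0, "target"] = ""
        with pytest.raises(ValueError, match="empty target"):
            collapse_probes(bad)

    def test_probe_count_outside_assay_range_rejected(self):
        rows = [("T1", c) for c in range(6)] + [(None, 1)]
        with pytest.raises(ValueError, match="1-5"):
            collapse_probes(make_probes(rows))


class TestLoq:
    def _tm(self, neg_values, rois=("r1",)):
        neg = [(None, v) for v in neg_values]
        return collapse_probes(make_probes([("T1", 100)] + neg, rois))

    def test_zero_variance_limit(self):
        loq = compute_loq(self._tm([5, 5, 5]))
        assert loq["r1"] == pytest.approx(5.0)

    def test_log_space_formula(self):
        loq = compute_loq(self._tm([math.e**0, math.e**2]))
        assert loq["r1"] == pytest.approx(math.exp(1 + 2 * math.sqrt(2)))

    def test_scale_equivariance(self):
        base = compute_loq(self._tm([2.0, 8.0, 4.0]))["r1"]
        scaled = compute_loq(self._tm([20.0, 80.0, 40.0]))["r1"]
        assert scaled == pytest.approx(10.0 * base)

    def test_all_zero_negatives_flagged(self):
        with pytest.warns(UserWarning, match="LOQ undefined"):
            loq = compute_loq(self._tm([0.0, 0.0]))
        assert np.isnan(loq["r1"])

    def test_fewer_than_two_negatives_rejected(self):
        with pytest.raises(ValueError, match="<2"):
            compute_loq(self._tm([3.0]))

    def test_arithmetic_mode_differs(self):
        tm = self._tm([2.0, 8.0, 4.0])
        assert compute_loq(tm, "geometric")["r1"] != compute_loq(tm, "arithmetic")["r1"]


class TestFilterAndQc:
    def _tm(self, values, loq):
        rois = [f"r{i}" for i in range(values.shape[1])]
        vals = pd.DataFrame(values, index=[f"T{i}" for i in range(len(values))],
                            columns=rois)
        neg = pd.DataFrame(np.ones((2, len(rois))), columns=rois,
                           index=["n1", "n2"])
        return TargetMatrix(values=vals, negatives=neg,
                            loq=pd.Series(loq, index=rois))

    def test_below_loq_everywhere_excluded_single_roi_above_retained(self):
        vals = np.array([[1.0] * 20, [1.0] * 19 + [11.0]])
        tm = self._tm(vals, [10.0] * 20)
        out = filter_targets(tm)
        assert list(out.values.index) == ["T1"]
        assert out.excluded_targets == ["T0"]

    def test_survivors_match_hand_enumeration(self):
        # 5 targets x 3 ROIs, LOQ = (10, 20, 30); above-LOQ pattern by hand
        vals = np.array([
            [11, 1, 1],    # above in r0 -> keep
            [1, 19, 29],   # never above -> drop
            [10, 20, 30],  # equal is not above -> drop
            [1, 21, 1],    # above in r1 -> keep
            [1, 1, 31],    # above in r2 -> keep
        ])
        out = filter_targets(self._tm(vals, [10.0, 20.0, 30.0]))
        assert list(out.values.index) == ["T0", "T3", "T4"]
        assert out.excluded_targets == ["T1", "T2"]

    def test_qc_threshold_zero_keeps_all(self):
        tm = self._tm(np.ones((3, 4)) * 100, [1.0] * 4)
        assert qc_rois(tm, 0.0).values.shape[1] == 4

    def test_qc_drops_exactly_the_argmin_roi(self):
        vals = np.array([[100, 100, 3, 100]] * 2, dtype=float)
        tm = self._tm(vals, [1.0] * 4)
        totals = tm.values.sum(axis=0)
        out = qc_rois(tm, float(totals.min()) + 1.0)
        assert [r for r, _ in out.excluded_rois] == ["r2"]
        assert out.values.shape[1] == 3

    def test_qc_refuses_to_drop_everything(self):
        tm = self._tm(np.ones((2, 3)), [1.0] * 3)
        with pytest.raises(ValueError, match="every ROI"):
            qc_rois(tm, 1e9)


def test_size_factors_equal_depth_gives_unity():
    counts = pd.DataFrame(np.tile([[10], [20], [40]], (1, 4)),
                          index=list("abc"), columns=list("wxyz"))
    sf = size_factors(counts)
    assert np.allclose(sf, 1.0)


class TestDifferentialExpression:
    def _cond(self, n_mi, n_hi):
        rois = [f"m{i}" for i in range(n_mi)] + [f"h{i}" for i in range(n_hi)]
        return pd.Series(["MI"] * n_mi + ["HI"] * n_hi, index=rois)

    def test_constant_gene_is_null(self):
        # identical counts in every ROI (size factors exactly 1)
        cond = self._cond(3, 3)
        counts = pd.DataFrame(
            np.tile([[50], [100], [200]], (1, 6)), columns=cond.index,
            index=["g0", "g1", "g2"],
        )
        de = de_nb_wald(counts, cond).set_index("gene")
        assert de.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert de.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_all_zero_gene_flagged_and_excluded(self):
        cond = self._cond(2, 2)
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 6, 7, 8]], columns=cond.index,
                              index=["dead", "alive"])
        de = de_nb_wald(counts, cond).set_index("gene")
        assert de.loc["dead", "flag"] == "all_zero"
        assert np.isnan(de.loc["dead", "padj"])

    def test_single_replicate_recovery(self):
        cfg = geomx_planted_config(seed=21)
        probes, meta, gt = simulate_geomx(cfg)
        tm = collapse_probes(probes)
        compute_loq(tm)
        tm = filter_targets(tm)
        cond = meta.set_index("roi_id")["pattern"]
        de = de_nb_wald(tm.values, cond).set_index("gene")
        planted = [g for g in gt.true_log2fc.index
                   if gt.true_log2fc[g] != 0 and g in de.index]
        est = de.loc[planted, "log2fc"].median()
        assert 0.6 <= est <= 1.4

    def test_log2fc_matches_deseq2_reference(self):
        """Independent cross-check against the DESeq2 reimplementation on a
        small simulated matrix."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = GeoMxSimConfig(
            n_targets=60, probes_per_target=1, n_rois={"MI": 6, "HI": 6},
            baseline_mean=500.0, baseline_logsd=0.5,
            planted_log2fc={"up": 1.5, "down": -1.0}, rng_seed=2,
        )
        probes, meta, _ = simulate_geomx(cfg)
        tm = collapse_probes(probes)
        cond = meta.set_index("roi_id")["pattern"]
        de = de_nb_wald(tm.values, cond).set_index("gene")

        counts = tm.values.round().astype(int)
        dds = DeseqDataSet(
            counts=counts.T, metadata=pd.DataFrame({"condition": cond}),
            design="~condition", quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "MI", "HI"], quiet=True)
        ds.summary()
        both = de.join(ds.results_df[["log2FoldChange"]]).dropna()
        r = np.corrcoef(both["log2fc"], both["log2FoldChange"])[0, 1]
        assert r > 0.99
        assert (both["log2fc"] - both["log2FoldChange"]).abs().max() < 0.1

    def test_requires_two_rois_per_condition(self):
        cond = self._cond(1, 3)
        counts = pd.DataFrame(np.ones((2, 4)), columns=cond.index)
        with pytest.raises(ValueError, match=">= 2"):
            de_nb_wald(counts, cond)


class TestZscores:
    def test_constant_gene_maps_to_zero_row(self):
        counts = pd.DataFrame([[10, 10, 10], [1, 50, 200]], index=["c", "g"],
                              columns=list("abc"))
        # equalise library sizes so "c" stays constant after normalisation
        counts.loc["g"] = [100, 100, 100]
        z = zscore_heatmap_matrix(counts)
        assert (z.loc["c"] == 0.0).all()

    def test_sample_sd_convention(self):
        """Log-normalised values {1, 2, 3} (equal libraries, counts 9/99/999
        with a balancing gene) z-score to {-1, 0, 1}."""
        g = [9.0, 99.0, 999.0]
        balance = [1100.0 - v for v in g]
        counts = pd.DataFrame([g, balance], index=["g", "b"], columns=list("abc"))
        z = zscore_heatmap_matrix(counts, pseudocount=1.0)
        assert z.loc["g"].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_rows_standardised(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, (20, 8)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"r{i}" for i in range(8)])
        z = zscore_heatmap_matrix(counts)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        sds = z.std(axis=1, ddof=1)
        assert ((np.isclose(sds, 1.0)) | (np.isclose(sds, 0.0))).all()

    def test_de_selection_restricts_rows(self):
        counts = pd.DataFrame(np.arange(12).reshape(3, 4) + 1.0,
                              index=["a", "b", "c"], columns=list("wxyz"))
        de = pd.DataFrame({"gene": ["a", "b", "c"], "padj": [0.01, 0.5, 0.05]})
        z = zscore_heatmap_matrix(counts, de, padj_threshold=0.1)
        assert set(z.index) == {"a", "c"}


def brute_force_es(metric: pd.Series, members, weight=1.0):
    """Independent O(n^2) running-sum oracle."""
    order = metric.sort_values(ascending=False, kind="mergesort")
    order = order.iloc[np.lexsort((order.index.to_numpy(), -order.to_numpy()))]
    hits = set(members) & set(order.index)
    nh, n = len(hits), len(order)
    total = sum(abs(order[g]) ** weight for g in hits)
    running, lo, hi = 0.0, 0.0, 0.0
    for g in order.index:
        if g in hits:
            running += (abs(order[g]) ** weight) / total if total else 0.0
        elif n > nh:
            running -= 1.0 / (n - nh)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo else lo


class TestGsea:
    UNIVERSE = pd.Series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})

    def test_whole_universe_set_has_es_one(self):
        out = preranked_gsea(self.UNIVERSE, {"ALL": list(self.UNIVERSE.index)},
                             n_perm=50, seed=0)
        assert out.loc[0, "es"] == pytest.approx(1.0)

    def test_hand_running_sum(self):
        """Set {g1, g2} on metrics (5,4,3,2,1): running sum
        (5/9, 1, 2/3, 1/3, 0) peaks at 1."""
        out = preranked_gsea(self.UNIVERSE, {"S": ["g1", "g2"]}, n_perm=50, seed=0)
        assert out.loc[0, "es"] == pytest.approx(1.0)
        assert out.loc[0, "leading_edge"] == "g1;g2"

    def test_sign_antisymmetry(self):
        # sets chosen so the running-sum extreme is unique (exact +/- ties
        # resolve positive by convention and cannot be antisymmetric)
        sets = {"S1": ["g1", "g2"], "S2": ["g4", "g5"], "S3": ["g1", "g4"]}
        pos = preranked_gsea(self.UNIVERSE, sets, n_perm=100, seed=1).set_index("pathway")
        neg = preranked_gsea(-self.UNIVERSE, sets, n_perm=100, seed=1).set_index("pathway")
        for s in sets:
            assert neg.loc[s, "es"] == pytest.approx(-pos.loc[s, "es"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_es_matches_brute_force_on_random_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        metric = pd.Series(rng.normal(0, 2, n),
                           index=[f"g{i:02d}" for i in range(n)])
        sets = {
            f"S{j}": list(rng.choice(metric.index, size=int(rng.integers(2, n)),
                                     replace=False))
            for j in range(6)
        }
        out = preranked_gsea(metric, sets, n_perm=20, seed=0).set_index("pathway")
        for name, members in sets.items():
            assert out.loc[name, "es"] == pytest.approx(
                brute_force_es(metric, members), abs=1e-12
            )

    def test_nes_sign_and_determinism(self):
        sets = {"S1": ["g1", "g2"], "S2": ["g4", "g5"]}
        o1 = preranked_gsea(self.UNIVERSE, sets, n_perm=500, seed=3)
        o2 = preranked_gsea(self.UNIVERSE, sets, n_perm=500, seed=3)
        pd.testing.assert_frame_equal(o1, o2)
        assert (np.sign(o1["nes"]) == np.sign(o1["es"])).all()
        assert (o1["es"].abs() <= 1.0 + 1e-12).all()

    def test_small_sets_skipped_and_empty_universe_rejected(self):
        out = preranked_gsea(self.UNIVERSE, {"tiny": ["g1"]}, n_perm=10, seed=0)
        assert len(out) == 0
        with pytest.raises(ValueError, match="empty"):
            preranked_gsea(pd.Series(dtype=float), {"S": ["g1", "g2"]})
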