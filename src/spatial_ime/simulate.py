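"""Synthetic data with known ground truth for every downstream stage.

Three generators, all deterministic under a fixed seed:

``simulate_tissue``
    Spatial point patterns over a core / margin / brain geometry (central
    disc, annular margin band, surrounding brain parenchyma).  Lineages are
    placed as independent homogeneous Poisson processes per zone with
    configurable intensity (points per mm^2).  Pairwise attraction is added
    Neyman-Scott style (a fraction ``strength`` of type-B cells is re-seeded
    within ``kernel_radius_um`` of random type-A parents); avoidance is
    distance thinning (type-B cells within the kernel of a type-A cell are
    deleted with probability ``|strength|``).  Optional cellular-neighborhood
    domains overwrite the lineage mixture inside a sub-region, giving a
    recoverable ground-truth partition.

``simulate_geomx``
    Probe-level count matrices in the digital-spatial-profiling layout:
    1-5 probes per target, negative-binomial target counts with planted
    group log2 fold changes, lognormal spike-in negative controls.

``simulate_intensity_panel``
    Per-cell marker intensities as a two-component mixture: a bounded
    negative baseline (uniform on [0, neg_max)) and a positive component
    offset strictly above the baseline, so threshold gating has an exact
    ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .io import DEFAULT_LINEAGES

__all__ = [
    "Attraction",
    "Domain",
    "TissueSimConfig",
    "GeoMxSimConfig",
    "MarkerModel",
    "GroundTruth",
    "simulate_tissue",
    "simulate_tissue_cohort",
    "simulate_geomx",
    "simulate_intensity_panel",
]

ZONES = ("core", "margin", "brain")


@dataclass(frozen=True)
class Attraction:
    """Planted pairwise spatial structure between two lineages."""

    type_a: str
    type_b: str
    kernel_radius_um: float = 6.0
    strength: float = 0.0  # >0 attraction, <0 avoidance, in [-1, 1]

    def __post_init__(self) -> None:
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError("attraction strength must lie in [-1, 1]")
        if self.kernel_radius_um <= 0:
            raise ValueError("kernel_radius_um must be > 0")


@dataclass(frozen=True)
class Domain:
    """A spatially contiguous region whose cells are re-labelled from ``mixture``.

    ``density_factor`` thins cells inside the region first (0 empties it,
    emulating acellular/necrotic zones), then survivors are re-labelled.

    ``region`` is a small spec dict:
      {"kind": "band", "inner_um": r0, "outer_um": r1}   radial band from the
        image centre (the margin band is {"kind": "band", "inner_um": core_r,
        "outer_um": core_r + band_w});
      {"kind": "disc", "cx": x, "cy": y, "radius_um": r};
      {"kind": "rect", "xmin": ..., "ymin": ..., "xmax": ..., "ymax": ...};
      {"kind": "polygon", "coords": [(x, y), ...]}.
    """

    region: Mapping
    mixture: Mapping[str, float]
    density_factor: float = 1.0

    def __post_init__(self) -> None:
        total = float(sum(self.mixture.values()))
        if self.mixture and not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"domain mixture must sum to 1 (got {total})")
        if not 0.0 <= self.density_factor:
            raise ValueError("density_factor must be >= 0")

    def geometry(self, width: float, height: float) -> Polygon:
        spec = dict(self.region)
        kind = spec.pop("kind")
        cx, cy = width / 2.0, height / 2.0
        if kind == "band":
            outer = Point(cx, cy).buffer(spec["outer_um"], quad_segs=128)
            inner = Point(cx, cy).buffer(spec["inner_um"], quad_segs=128)
            return outer.difference(inner)
        if kind == "disc":
            return Point(spec["cx"], spec["cy"]).buffer(spec["radius_um"], quad_segs=128)
        if kind == "rect":
            return box(spec["xmin"], spec["ymin"], spec["xmax"], spec["ymax"])
        if kind == "polygon":
            return Polygon(spec["coords"])
        raise ValueError(f"unknown domain kind {kind!r}")


def default_intensities() -> dict[str, dict[str, float]]:
    """Per-lineage placement intensity (points / mm^2) per zone.

    Chosen to resemble a moderately cellular metastasis: a cancer-dominated
    core (~2,000 cells/mm^2 total), a mixed margin, and glia-rich brain.
    """
    zero = {"core": 0.0, "margin": 0.0, "brain": 0.0}
    out = {name: dict(zero) for name in DEFAULT_LINEAGES}
    out["Cancer"] = {"core": 1400.0, "margin": 700.0, "brain": 0.0}
    out["Macrophage"] = {"core": 120.0, "margin": 150.0, "brain": 20.0}
    out["Monocyte"] = {"core": 40.0, "margin": 60.0, "brain": 0.0}
    out["T helper"] = {"core": 40.0, "margin": 60.0, "brain": 5.0}
    out["T cytotoxic"] = {"core": 30.0, "margin": 50.0, "brain": 5.0}
    out["T regulatory"] = {"core": 10.0, "margin": 20.0, "brain": 0.0}
    out["Other T"] = {"core": 10.0, "margin": 15.0, "brain": 0.0}
    out["B cell"] = {"core": 10.0, "margin": 25.0, "brain": 0.0}
    out["Dendritic cell"] = {"core": 15.0, "margin": 20.0, "brain": 0.0}
    out["Neutrophil"] = {"core": 20.0, "margin": 20.0, "brain": 5.0}
    out["Endothelial"] = {"core": 80.0, "margin": 80.0, "brain": 60.0}
    out["Fibroblast"] = {"core": 40.0, "margin": 40.0, "brain": 0.0}
    out["Astrocyte"] = {"core": 5.0, "margin": 120.0, "brain": 350.0}
    out["Microglia"] = {"core": 10.0, "margin": 60.0, "brain": 180.0}
    out["Oligodendrocyte"] = {"core": 0.0, "margin": 30.0, "brain": 150.0}
    out["Neuron"] = {"core": 0.0, "margin": 20.0, "brain": 200.0}
    out["Undefined"] = {"core": 150.0, "margin": 120.0, "brain": 80.0}
    return out


@dataclass
class TissueSimConfig:
    width_um: float = 1000.0
    height_um: float = 1000.0
    core_radius_um: float = 300.0
    margin_width_um: float = 150.0
    intensities: Mapping[str, Mapping[str, float]] = field(default_factory=default_intensities)
    attraction: tuple[Attraction, ...] = ()
    cn_domains: tuple[Domain, ...] = ()
    image_id: str = "img001"
    patient_id: str = "P01"
    primary_site: str = "lung"
    region: str = "margin"
    pattern: str = "MI"
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth aligned 1:1 with the generated records."""

    cell_domain: np.ndarray | None = None  # 0 = background, i >= 1 = cn_domains[i-1]
    attractions: tuple[Attraction, ...] = ()
    true_log2fc: pd.Series | None = None
    marker_positive: pd.DataFrame | None = None


def _zone_geometries(cfg: TissueSimConfig) -> dict[str, Polygon]:
    frame = box(0.0, 0.0, cfg.width_um, cfg.height_um)
    cx, cy = cfg.width_um / 2.0, cfg.height_um / 2.0
    core_disc = Point(cx, cy).buffer(cfg.core_radius_um, quad_segs=256)
    outer_disc = Point(cx, cy).buffer(
        cfg.core_radius_um + cfg.margin_width_um, quad_segs=256
    )
    return {
        "core": core_disc.intersection(frame),
        "margin": outer_disc.difference(core_disc).intersection(frame),
        "brain": frame.difference(outer_disc),
    }


def _sample_points(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points in ``geom`` by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    out: list[np.ndarray] = []
    have = 0
    frac = max(geom.area / ((maxx - minx) * (maxy - miny) + 1e-300), 1e-3)
    while have < n:
        m = int((n - have) / frac * 1.5) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts[: n - have])
        have += len(pts[: n - have])
    return np.vstack(out)


def simulate_tissue(
    config: TissueSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one image: ``(cells, meta, ground_truth)``.

    Placement is homogeneous Poisson per (lineage, zone); attraction /
    avoidance and neighborhood domains are applied afterwards in the order
    given.  Byte-identical output under a fixed seed.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    zones = _zone_geometries(config)
    mm2 = {z: zones[z].area / 1e6 for z in ZONES}

    expected = sum(
        float(per.get(z, 0.0)) * mm2[z]
        for per in config.intensities.values()
        for z in ZONES
    )
    if expected <= 0:
        raise ValueError("degenerate config: expected cell count is 0 in every zone")

    xy_parts: list[np.ndarray] = []
    lineage_parts: list[np.ndarray] = []
    for lineage in config.intensities:
        for z in ZONES:
            lam = float(config.intensities[lineage].get(z, 0.0)) * mm2[z]
            if lam <= 0:
                continue
            n = int(rng.poisson(lam))
            pts = _sample_points(zones[z], n, rng)
            xy_parts.append(pts)
            # object dtype: fixed-width unicode would truncate later re-labels
            lineage_parts.append(np.full(n, lineage, dtype=object))
    xy = np.vstack(xy_parts) if xy_parts else np.empty((0, 2))
    lineage = (
        np.concatenate(lineage_parts) if lineage_parts else np.empty(0, dtype=object)
    )

    # planted pairwise structure
    from scipy.spatial import cKDTree

    for att in config.attraction:
        if att.strength == 0:
            continue
        a_idx = np.flatnonzero(lineage == att.type_a)
        b_idx = np.flatnonzero(lineage == att.type_b)
        if len(a_idx) == 0 or len(b_idx) == 0:
            continue
        if att.strength > 0:
            move = b_idx[rng.random(len(b_idx)) < att.strength]
            parents = xy[rng.choice(a_idx, size=len(move))]
            theta = rng.uniform(0, 2 * np.pi, len(move))
            rad = att.kernel_radius_um * np.sqrt(rng.random(len(move)))
            pos = parents + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
            pos[:, 0] = np.clip(pos[:, 0], 0.0, config.width_um)
            pos[:, 1] = np.clip(pos[:, 1], 0.0, config.height_um)
            xy[move] = pos
        else:
            tree = cKDTree(xy[a_idx])
            near = tree.query_ball_point(xy[b_idx], att.kernel_radius_um)
            exposed = b_idx[np.fromiter((len(v) > 0 for v in near), bool, len(b_idx))]
            drop = exposed[rng.random(len(exposed)) < -att.strength]
            keep = np.ones(len(xy), dtype=bool)
            keep[drop] = False
            xy, lineage = xy[keep], lineage[keep]

    # neighborhood domains: optional thinning, then overwrite the lineage
    # mixture inside their region (later domains win on overlap)
    domain_label = np.zeros(len(xy), dtype=int)
    for i, dom in enumerate(config.cn_domains, start=1):
        geom = dom.geometry(config.width_um, config.height_um)
        inside = shapely.contains_xy(geom, xy[:, 0], xy[:, 1])
        if dom.density_factor < 1.0:
            drop = inside & (rng.random(len(xy)) >= dom.density_factor)
            xy, lineage, domain_label = xy[~drop], lineage[~drop], domain_label[~drop]
            inside = inside[~drop]
        domain_label[inside] = i
        if dom.mixture and inside.any():
            names = list(dom.mixture)
            probs = np.asarray([dom.mixture[k] for k in names], dtype=float)
            probs = probs / probs.sum()
            lineage[inside] = rng.choice(
                np.asarray(names, dtype=object), size=int(inside.sum()), p=probs
            )

    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(len(xy))],
            "image_id": config.image_id,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lineage": lineage,
        }
    )
    meta = pd.DataFrame(
        [
            {
                "image_id": config.image_id,
                "patient_id": config.patient_id,
                "primary_site": config.primary_site,
                "region": config.region,
                "pattern": config.pattern,
            }
        ]
    )
    return cells, meta, GroundTruth(cell_domain=domain_label, attractions=config.attraction)


def simulate_tissue_cohort(
    base: TissueSimConfig,
    n_images: int,
    pattern: str,
    seed: int,
    patient_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GroundTruth]]:
    """A group of images sharing one configuration, one image per patient."""
    rng = np.random.default_rng(seed)
    cells_all, meta_all, truths = [], [], []
    prefix = patient_prefix or pattern
    for i in range(n_images):
        cfg = replace(
            base,
            image_id=f"{prefix}_img{i:03d}",
            patient_id=f"{prefix}_P{i:03d}",
            pattern=pattern,
            rng_seed=int(rng.integers(2**31)),
        )
        cells, meta, gt = simulate_tissue(cfg)
        cells_all.append(cells)
        meta_all.append(meta)
        truths.append(gt)
    return (
        pd.concat(cells_all, ignore_index=True),
        pd.concat(meta_all, ignore_index=True),
        truths,
    )


@dataclass
class GeoMxSimConfig:
    """Digital-spatial-profiling simulator settings.

    Defaults mirror the assay layout: 1-5 probes per target and 88 spike-in
    negative-control probes; the default target count is scaled down from the
    1,825-target panel for desk-scale runs.
    """

    n_targets: int = 500
    probes_per_target: int | str = "uniform"  # "uniform" draws 1..5 per target
    n_neg_probes: int = 88
    n_rois: Mapping[str, int] = field(default_factory=lambda: {"MI": 4, "HI": 7})
    neg_logmean: float = math.log(20.0)
    neg_logsd: float = 0.6
    baseline_mean: float = 200.0
    baseline_logsd: float = 1.0
    dispersion: float = 0.1
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)
    libsize_logsd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if isinstance(self.probes_per_target, int) and not 1 <= self.probes_per_target <= 5:
            raise ValueError("probes_per_target must be within 1-5")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 counts with Var = m + alpha m^2; Poisson limit for tiny alpha."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-7:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_geomx(
    config: GeoMxSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate ``(probe_matrix, roi_meta, ground_truth)``.

    Probe matrix columns: ``probe_id, target, is_negative`` plus one count
    column per ROI.  A target's ROI-level mean is split equally across its
    probes; planted genes' group means differ by ``2**log2fc`` (MI relative
    to the HI baseline).
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    for cond, n in config.n_rois.items():
        if n < 2:
            raise ValueError(
                f"condition {cond!r} has {n} ROI(s); >= 2 required for DE"
            )

    planted = dict(config.planted_log2fc)
    genes = list(planted)
    genes += [f"G{i:04d}" for i in range(len(genes), config.n_targets)]
    genes = genes[: config.n_targets]
    lfc = pd.Series({g: float(planted.get(g, 0.0)) for g in genes})

    rois, conds = [], []
    for cond, n in config.n_rois.items():
        for i in range(n):
            rois.append(f"{cond}_roi{i:02d}")
            conds.append(cond)
    roi_meta = pd.DataFrame(
        {
            "roi_id": rois,
            "patient_id": [f"{c}_P{i:02d}" for i, c in enumerate(conds)],
            "primary_site": "lung",
            "pattern": conds,
        }
    )
    sf = np.exp(rng.normal(0.0, config.libsize_logsd, len(rois)))

    base = np.exp(rng.normal(math.log(config.baseline_mean), config.baseline_logsd, len(genes)))
    if config.probes_per_target == "uniform":
        n_probes = rng.integers(1, 6, len(genes))
    else:
        n_probes = np.full(len(genes), int(config.probes_per_target))

    rows = []
    counts = []
    is_mi = np.asarray([c == "MI" for c in conds])
    for gi, g in enumerate(genes):
        mu_roi = base[gi] * sf * np.where(is_mi, 2.0 ** lfc[g], 1.0)
        for p in range(int(n_probes[gi])):
            rows.append((f"{g}_p{p + 1}", g, False))
            counts.append(_nb_draw(rng, mu_roi / n_probes[gi], config.dispersion))
    for p in range(config.n_neg_probes):
        rows.append((f"NEG_{p + 1:03d}", "", True))
        counts.append(
            np.round(np.exp(rng.normal(config.neg_logmean, config.neg_logsd, len(rois))))
        )

    probe_df = pd.DataFrame(rows, columns=["probe_id", "target", "is_negative"])
    probe_df = pd.concat(
        [probe_df, pd.DataFrame(np.vstack(counts), columns=rois)], axis=1
    )
    return probe_df, roi_meta, GroundTruth(true_log2fc=lfc)


@dataclass(frozen=True)
class MarkerModel:
    """Two-component intensity model for one marker.

    Negative cells draw from Uniform[0, ``neg_max``); positive cells draw
    ``neg_max + LogNormal(pos_logmean, pos_logsd)``, strictly above every
    negative value, so a threshold at ``neg_max`` separates the components
    exactly.  ``positive_fraction`` may be one number or a per-lineage map
    (lineages absent from the map get 0).
    """

    name: str
    positive_fraction: float | Mapping[str, float] = 0.3
    neg_max: float = 1.0
    pos_logmean: float = 1.0
    pos_logsd: float = 0.5

    def fraction_for(self, lineage: np.ndarray) -> np.ndarray:
        if isinstance(self.positive_fraction, Mapping):
            return np.asarray(
                [float(self.positive_fraction.get(l, 0.0)) for l in lineage]
            )
        return np.full(len(lineage), float(self.positive_fraction))


def simulate_intensity_panel(
    cells: pd.DataFrame,
    markers: Sequence[MarkerModel],
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Attach per-cell marker intensity columns; returns ``(cells, truth)``.

    The truth frame holds the Bernoulli positivity indicator per marker.
    """
    rng = np.random.default_rng(seed)
    out = cells.copy()
    lineage = cells["lineage"].to_numpy()
    truth = {}
    n = len(cells)
    for m in markers:
        pos = rng.random(n) < m.fraction_for(lineage)
        vals = rng.uniform(0.0, m.neg_max, n)
        vals[pos] = m.neg_max + np.exp(rng.normal(m.pos_logmean, m.pos_logsd, int(pos.sum())))
        out[m.name] = vals
        truth[m.name] = pos
    return out, GroundTruth(marker_positive=pd.DataFrame(truth, index=cells.index))
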