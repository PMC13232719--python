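"""Canonical synthetic study conditions.

These builders fix, in one place, the simulated "experiments" the package is
validated against: complete-spatial-randomness cohorts for calibration,
planted-attraction cohorts for power, planted neighborhood domains for CN
recovery, and planted fold changes for differential expression.  Tests and
the reproduction script both draw from here so the conditions cannot drift
apart.

Densities follow typical imaging-mass-cytometry tissue: a 1 mm^2 frame with
~500 cells for the three-type calibration cohorts, ~800 cells/mm^2 inside
the planted neighborhood domains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import LineageSet
from .simulate import (
    Attraction,
    Domain,
    GeoMxSimConfig,
    TissueSimConfig,
    simulate_tissue,
    simulate_tissue_cohort,
)

__all__ = [
    "three_type_lineages",
    "csr_config",
    "csr_images",
    "attraction_experiment",
    "two_domain_image",
    "lymphoid_band_experiment",
    "geomx_null_config",
    "geomx_planted_config",
]

#: lymphoid lineages used by the band scenario (subset of the default palette)
LYMPHOID = ("B cell", "T helper", "T cytotoxic", "T regulatory")


def three_type_lineages() -> LineageSet:
    return LineageSet(names=("A", "B", "C"), cancer="A")


def csr_config(n_cells_per_mm2: float = 500.0, seed: int = 0) -> TissueSimConfig:
    """Three exchangeable types, labels independent of position, 1 mm^2 frame."""
    per = n_cells_per_mm2 / 3.0
    return TissueSimConfig(
        width_um=1000.0,
        height_um=1000.0,
        core_radius_um=1e-6,
        margin_width_um=1e-6,
        intensities={t: {"brain": per} for t in ("A", "B", "C")},
        rng_seed=seed,
    )


def csr_images(n_images: int, seed: int, pattern: str = "MI"):
    """A cohort of CSR images: ``(cells, meta)``."""
    cells, meta, _ = simulate_tissue_cohort(csr_config(), n_images, pattern, seed)
    return cells, meta


def attraction_experiment(
    n_images_per_group: int, seed: int, strength: float = 0.8,
    kernel_radius_um: float = 6.0,
):
    """MI images carry a planted A-B attraction; HI images are CSR.

    Returns ``(cells, meta)`` for the pooled two-group cohort.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    base = csr_config()
    mi = dataclasses.replace(
        base, attraction=(Attraction("A", "B", kernel_radius_um, strength),)
    )
    c1, m1, _ = simulate_tissue_cohort(mi, n_images_per_group, "MI",
                                       int(rng.integers(2**31)))
    c2, m2, _ = simulate_tissue_cohort(base, n_images_per_group, "HI",
                                       int(rng.integers(2**31)))
    return pd.concat([c1, c2], ignore_index=True), pd.concat([m1, m2], ignore_index=True)


def two_domain_image(seed: int = 0):
    """Two spatially separated, compositionally disjoint domains.

    Pure-A and pure-B rectangles with an empty 400 um corridor between them,
    so composition windows never mix and the planted partition is exactly
    recoverable.  Returns ``(cells, meta, ground_truth)``; domain labels are
    2 (pure A) and 3 (pure B), the corridor (domain 1) is empty.
    """
    domains = (
        Domain({"kind": "rect", "xmin": 400, "ymin": 0, "xmax": 800, "ymax": 500},
               {}, density_factor=0.0),
        Domain({"kind": "rect", "xmin": 0, "ymin": 0, "xmax": 400, "ymax": 500},
               {"A": 1.0}),
        Domain({"kind": "rect", "xmin": 800, "ymin": 0, "xmax": 1200, "ymax": 500},
               {"B": 1.0}),
    )
    cfg = TissueSimConfig(
        width_um=1200.0,
        height_um=500.0,
        core_radius_um=1e-6,
        margin_width_um=1e-6,
        intensities={"A": {"brain": 800.0}},
        cn_domains=domains,
        rng_seed=seed,
    )
    return simulate_tissue(cfg)


def _band_base(lymphoid_band: bool) -> TissueSimConfig:
    intensities = {
        "Cancer": {"core": 1200.0, "margin": 500.0},
        "Astrocyte": {"margin": 150.0, "brain": 400.0},
        "Microglia": {"margin": 80.0, "brain": 200.0},
        "Macrophage": {"core": 150.0, "margin": 150.0, "brain": 20.0},
        "Undefined": {"core": 150.0, "margin": 100.0, "brain": 80.0},
    }
    domains = ()
    if lymphoid_band:
        mixture = {"B cell": 0.35, "T helper": 0.3, "T cytotoxic": 0.2,
                   "T regulatory": 0.15}
        domains = (
            Domain({"kind": "band", "inner_um": 300.0, "outer_um": 420.0}, mixture),
        )
    return TissueSimConfig(
        width_um=1000.0,
        height_um=1000.0,
        core_radius_um=300.0,
        margin_width_um=150.0,
        intensities=intensities,
        cn_domains=domains,
        region="margin",
    )


def lymphoid_band_experiment(seed: int, n_mi: int = 6, n_hi: int = 16):
    """MI margins carry a lymphoid-rich band at the tumor-brain interface;
    HI margins do not.  Group sizes default to the lung-cohort margin counts
    (6 MI, 16 HI).  Returns ``(cells, meta, mi_truths)``."""
    rng = np.random.default_rng(seed)
    c1, m1, t1 = simulate_tissue_cohort(
        _band_base(True), n_mi, "MI", int(rng.integers(2**31))
    )
    c2, m2, _ = simulate_tissue_cohort(
        _band_base(False), n_hi, "HI", int(rng.integers(2**31))
    )
    return (pd.concat([c1, c2], ignore_index=True),
            pd.concat([m1, m2], ignore_index=True), t1)


def geomx_null_config(seed: int, n_targets: int = 500,
                      n_per_group: int = 6) -> GeoMxSimConfig:
    """No planted effects: type-I error / FDR calibration conditions."""
    return GeoMxSimConfig(
        n_targets=n_targets,
        n_rois={"MI": n_per_group, "HI": n_per_group},
        baseline_mean=500.0,
        baseline_logsd=0.5,
        dispersion=0.1,
        rng_seed=seed,
    )


def geomx_planted_config(seed: int, log2fc: float = 1.0, n_planted: int = 10,
                         n_targets: int = 300, n_per_group: int = 8) -> GeoMxSimConfig:
    """Planted log2 fold changes on ``n_planted`` genes, 8 vs 8 ROIs,
    dispersion 0.1, equal size factors — the DE recovery conditions."""
    planted = {f"PLANT{i:02d}": log2fc for i in range(n_planted)}
    return GeoMxSimConfig(
        n_targets=n_targets,
        n_rois={"MI": n_per_group, "HI": n_per_group},
        baseline_mean=500.0,
        baseline_logsd=0.5,
        dispersion=0.1,
        planted_log2fc=planted,
        rng_seed=seed,
    )
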