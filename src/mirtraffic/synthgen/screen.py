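"""Synthetic ligand-uptake screens with planted effect sizes.

The per-cell model: within a well whose true median uptake is ``M``,
per-cell integrated ligand intensity is lognormal with median ``M`` and
log-scale sigma ``cell_sigma``.  Negative-control wells sit at the control
median ``M0`` plus well-to-well biological noise; a test condition with
planted effect ``e`` is shifted by ``e`` times the *total* control
well-median standard deviation (biological well noise plus the sampling
error of a finite-cell median), so that the downstream control-normalized
score recovers ``e`` directly.

Images are optional: :func:`render_well_images` paints each cell's uptake
as Gaussian puncta in an annulus around its nucleus, so the imaging
pipeline (background subtraction, segmentation, region assignment,
integration) can be validated against the same ground truth.  The
table-only path is fast enough for Monte-Carlo power studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imagequant import ImageField
from .nuclei import NucleiFieldSpec, make_nuclei_field

#: control population median uptake, arbitrary integrated-intensity units
CONTROL_MEDIAN = 1000.0
#: well-to-well biological SD of the true well median
WELL_SD = 80.0
#: lognormal sigma of per-cell uptake within a well
CELL_SIGMA = 0.5


@dataclass
class Condition:
    name: str
    role: str = "test"  # negative_control | positive_control | test
    planted_effect: float = 0.0  # in units of control well SD
    n_wells: int = 2  # wells per condition per experiment

    def __post_init__(self) -> None:
        if self.role == "negative_control" and self.planted_effect != 0:
            raise ValueError("negative controls must have planted_effect 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


@dataclass
class ScreenSpec:
    conditions: list
    cells_per_well: int = 200
    replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        nc = sum(c.n_wells for c in self.conditions if c.role == "negative_control")
        if nc < 2:
            raise ValueError("need at least 2 negative-control wells")

    @property
    def n_wells(self) -> int:
        return self.replicates * sum(c.n_wells for c in self.conditions)


def default_conditions(
    test_effects: dict | None = None,
    nc_wells: int = 8,
    positive_effect: float = -4.0,
) -> list:
    """A conventional screen layout: one negative-control condition spread
    over ``nc_wells`` wells, one positive control, and the given test
    conditions (name -> planted effect)."""
    conds = [
        Condition("neg_ctrl", "negative_control", 0.0, n_wells=nc_wells),
        Condition("pos_ctrl", "positive_control", positive_effect),
    ]
    for name, eff in (test_effects or {}).items():
        conds.append(Condition(name, "test", eff))
    return conds


def control_well_sd(spec: ScreenSpec) -> float:
    """Analytic total SD of a negative-control well's *measured* median.

    Biological well-to-well SD combined with the sampling error of the
    median of ``cells_per_well`` lognormal cells (asymptotic SE of a
    sample median: 1/(2 f(m) sqrt(n)) with f the lognormal density at the
    median m).
    """
    se_median = CONTROL_MEDIAN * CELL_SIGMA * np.sqrt(np.pi / 2) / np.sqrt(spec.cells_per_well)
    return float(np.hypot(WELL_SD, se_median))


def make_uptake_screen(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one screen: per-cell table, plate map, ground truth.

    Returns ``(cells, platemap, truth)``:

    * ``cells`` — one row per cell: well, condition, role, replicate,
      cell index, uptake;
    * ``platemap`` — well, condition, role, replicate;
    * ``truth`` — per well: the true (noise-free-measurement) median and
      the planted effect.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sigma_total = control_well_sd(spec)
    n_cells = spec.cells_per_well
    wells, conds, roles, reps, medians, effects = [], [], [], [], [], []
    well_idx = 0
    for rep in range(1, spec.replicates + 1):
        for cond in spec.conditions:
            for _ in range(cond.n_wells):
                well_idx += 1
                m_true = (
                    CONTROL_MEDIAN
                    + cond.planted_effect * sigma_total
                    + rng.normal(0.0, WELL_SD)
                )
                m_true = max(m_true, 0.05 * CONTROL_MEDIAN)
                wells.append(f"W{well_idx:04d}")
                conds.append(cond.name)
                roles.append(cond.role)
                reps.append(rep)
                medians.append(m_true)
                effects.append(cond.planted_effect)
    n_wells = len(wells)
    uptake = rng.lognormal(
        np.log(np.asarray(medians))[:, None], CELL_SIGMA, size=(n_wells, n_cells)
    )
    platemap = pd.DataFrame(
        {"well": wells, "condition": conds, "role": roles, "replicate": reps}
    )
    truth = platemap.drop(columns="role").assign(
        true_median=medians, planted_effect=effects
    )
    cells = pd.DataFrame(
        {
            "well": np.repeat(wells, n_cells),
            "condition": np.repeat(conds, n_cells),
            "role": np.repeat(roles, n_cells),
            "replicate": np.repeat(reps, n_cells),
            "cell": np.tile(np.arange(n_cells), n_wells),
            "uptake": uptake.ravel(),
        }
    )
    return cells, platemap, truth


def well_measurements(cells: pd.DataFrame):
    """Collapse a per-cell table to WellMeasurement objects (median over
    all cells of the well, pooling its images)."""
    from ..screenstats import WellMeasurement

    out = []
    for (well, cond, role, rep), grp in cells.groupby(
        ["well", "condition", "role", "replicate"], sort=True
    ):
        out.append(WellMeasurement(well, cond, role, int(rep), float(grp["uptake"].median())))
    return out


def render_well_images(
    uptakes,
    rng_seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    puncta_per_cell: int = 8,
    puncta_sigma: float = 1.5,
    annulus: tuple[float, float] = (12.0, 18.0),
) -> tuple[ImageField, "np.ndarray", list]:
    """Render one well: nuclei channel plus punctate ligand channel.

    Each cell's uptake value is split over ``puncta_per_cell`` Gaussian
    puncta placed in an annulus around its nucleus centroid; the puncta
    integrate (up to discretisation) to the cell's uptake.  Returns the
    two-channel field, the ground-truth nucleus label mask and the list of
    per-cell true uptakes in label order.
    """
    uptakes = list(uptakes)
    n = len(uptakes)
    nspec = NucleiFieldSpec(
        n_cells=n, image_shape=image_shape, class_mix=(1.0, 0, 0, 0), rng_seed=rng_seed
    )
    nuc_field, truth = make_nuclei_field(nspec)
    rng = np.random.default_rng(rng_seed + 1)
    ligand = np.zeros(image_shape, dtype=np.float64)
    rr = np.arange(image_shape[0])[:, None]
    cc = np.arange(image_shape[1])[None, :]
    two_sig2 = 2 * puncta_sigma**2
    gauss_integral = 2 * np.pi * puncta_sigma**2
    for (r0, c0), uptake in zip(truth.centers, uptakes):
        per_punctum = uptake / puncta_per_cell
        for _ in range(puncta_per_cell):
            rad = rng.uniform(*annulus)
            ang = rng.uniform(0, 2 * np.pi)
            pr = np.clip(r0 + rad * np.cos(ang), 3, image_shape[0] - 4)
            pc = np.clip(c0 + rad * np.sin(ang), 3, image_shape[1] - 4)
            amp = per_punctum / gauss_integral
            ligand += amp * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / two_sig2)
    ligand = np.clip(np.rint(ligand), 0, 65535).astype(np.uint16)
    fld = ImageField(
        {"nuclei": nuc_field.channels["nuclei"], "ligand": ligand},
        source_id=f"synthetic_well_seed{rng_seed}",
    )
    return fld, truth.label_mask, uptakes


def make_rescue_cells(
    n_rescue: int = 600,
    n_reference: int = 4000,
    inhibition: float = 0.3,
    rng_seed: int = 0,
    uptake_noise_sd: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell tables for a marker-binned rescue analysis.

    Reference cells (inert construct, no miRNA effect removed) take up
    ligand at the control level.  Rescue cells carry the inhibitory
    condition (uptake reduced by ``inhibition`` at zero marker) plus a
    rescue construct whose expression ``marker_intensity`` linearly
    restores uptake, saturating at full recovery for the brightest cells.
    """
    rng = np.random.default_rng(rng_seed)
    base = CONTROL_MEDIAN
    ref = pd.DataFrame(
        {
            "ligand_intensity": np.clip(rng.normal(base, uptake_noise_sd, n_reference), 0, None),
            "marker_intensity": rng.lognormal(4.0, 0.5, n_reference),
        }
    )
    marker = rng.lognormal(5.0, 0.9, n_rescue)
    recovery = np.clip(marker / np.quantile(marker, 0.9), 0, 1)  # linear, saturating
    mean_uptake = base * (1 - inhibition * (1 - recovery))
    res = pd.DataFrame(
        {
            "ligand_intensity": np.clip(
                rng.normal(mean_uptake, uptake_noise_sd), 0, None
            ),
            "marker_intensity": marker,
        }
    )
    return res, ref
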