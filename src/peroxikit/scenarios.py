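"""Preset simulation scenarios used to validate each analysis stage.

These fix the study conditions for the package's self-validation: parameter
recovery and test calibration for the hurdle model, detection accuracy and
density recovery for the imaging pipeline, and artifact correction and
interaction-test behavior for the plate analysis.  Each function returns a
parameter object; pass a seed (or use ``dataclasses.replace``) to draw
independent replicates.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .simulate import CountSimParams, ImageSimParams, PlateSimParams, default_plate_params

__all__ = [
    "recovery_count_params",
    "null_count_params",
    "model_selection_count_params",
    "attenuated_panel_params",
    "spot_grid_image_params",
    "snr5_image_params",
    "density_image_params",
    "null_plate_params",
    "power_plate_params",
]


def recovery_count_params(n_cells: int = 500, seed: int = 0) -> CountSimParams:
    """2 strains x 2 treatments x 2 batches with known effects in both
    hurdle components, for parameter-recovery and CI-coverage checks."""
    return CountSimParams(
        strains=("WT", "mutA"),
        treatments=("DMSO", "Tm"),
        batches=("b1", "b2"),
        gamma={
            "Intercept": 1.2,
            "strain[mutA]": -0.3,
            "treatment[Tm]": 0.5,
            "batch[b2]": 0.1,
            "strain[mutA]:treatment[Tm]": -0.4,
        },
        beta={
            "Intercept": np.log(3.0),
            "strain[mutA]": -0.2,
            "treatment[Tm]": 0.4,
            "batch[b2]": 0.05,
            "strain[mutA]:treatment[Tm]": -0.3,
        },
        theta=5.0,
        n_cells=n_cells,
        seed=seed,
    )


def null_count_params(n_cells: int = 75, seed: int = 0) -> CountSimParams:
    """Same design but with no strain:treatment interaction in the truth,
    for type-I-error calibration of the interaction LRT."""
    base = recovery_count_params(n_cells=n_cells, seed=seed)
    gamma = {k: v for k, v in base.gamma.items() if ":" not in k}
    beta = {k: v for k, v in base.beta.items() if ":" not in k}
    return replace(base, gamma=gamma, beta=beta)


def model_selection_count_params(n_cells: int = 75, seed: int = 0) -> CountSimParams:
    """Hurdle truth whose hurdle-crossing probabilities sit far from the
    NB-implied zero mass in both directions, as in the yeast data: nearly
    every live WT cell has at least one peroxisome (zero deficit relative
    to the NB for its positive counts), while a stressed mutant contributes
    heavy dead-cell zero excess.  Zero-inflated NB cannot reproduce a zero
    deficit (it would need negative inflation), so model selection by AIC
    separates the families."""
    return CountSimParams(
        strains=("WT", "mutB"),
        treatments=("DMSO", "Tm"),
        batches=("b1", "b2"),
        gamma={
            "Intercept": 3.0,
            "strain[mutB]": -3.2,
            "treatment[Tm]": 0.4,
            "strain[mutB]:treatment[Tm]": -1.0,
        },
        beta={"Intercept": np.log(3.0), "strain[mutB]": -0.2, "treatment[Tm]": 0.4},
        theta=1.5,
        n_cells=n_cells,
        seed=seed,
    )


def attenuated_panel_params(n_cells: int = 100, seed: int = 0) -> CountSimParams:
    """A strain panel (WT + three mutants) where one mutant has an
    attenuated treatment response in the positive component, as reported
    for high-PKA / chaperone-deletion strains; the others respond like WT."""
    return CountSimParams(
        strains=("WT", "mutNull1", "mutNull2", "mutDown"),
        treatments=("DMSO", "Tm"),
        batches=("b1", "b2"),
        gamma={"Intercept": 1.2, "treatment[Tm]": 0.5, "batch[b2]": 0.1},
        beta={
            "Intercept": np.log(3.0),
            "treatment[Tm]": 0.4,
            "batch[b2]": 0.05,
            "strain[mutDown]:treatment[Tm]": -0.5,
        },
        theta=5.0,
        n_cells=n_cells,
        seed=seed,
    )


def spot_grid_image_params(seed: int = 0) -> ImageSimParams:
    """30 noise-free spots (6 cells x 5 spots) separated by >= 4 sigma."""
    return ImageSimParams(
        shape=(31, 320, 320),
        voxel_size=(0.2, 0.0509, 0.0509),
        n_cells=6,
        spots_per_cell=5,
        spot_sigma=(0.25, 0.11, 0.11),
        min_spot_separation=1.0,  # 4 x the largest sigma
        poisson_noise=False,
        gaussian_noise_sd=0.0,
        seed=seed,
    )


def snr5_image_params(seed: int = 0) -> ImageSimParams:
    """Shot + read noise tuned to peak SNR ~ 5."""
    return ImageSimParams(
        n_cells=4,
        spots_per_cell=6,
        spot_amplitude=80.0,
        background=150.0,
        poisson_noise=True,
        gaussian_noise_sd=5.0,
        min_spot_separation=0.8,
        seed=seed,
    )


def density_image_params(seed: int = 0) -> ImageSimParams:
    """Fibroblast-like stack: one large flat cell, true density ~ 0.02
    spots per cubic micrometre, moderate shot + read noise."""
    return ImageSimParams(
        shape=(31, 256, 256),
        voxel_size=(0.2, 0.1, 0.1),
        n_cells=1,
        cell_geometry=(2.2, 8.0, 8.0),
        spots_per_cell=12,
        spot_sigma=(0.3, 0.15, 0.15),
        spot_amplitude=300.0,
        background=100.0,
        poisson_noise=True,
        gaussian_noise_sd=10.0,
        min_spot_separation=0.8,
        seed=seed,
    )


def null_plate_params(seed: int = 0) -> PlateSimParams:
    """Default plate response with the three-way interaction removed."""
    base = default_plate_params()
    coefs = {
        k: v
        for k, v in base.response_coefficients.items()
        if k != "genotype[pex16KO]:dose:secondary[Tm]"
    }
    return replace(base, response_coefficients=coefs, seed=seed)


def power_plate_params(seed: int = 0) -> PlateSimParams:
    """Three-way interaction sized so its effect at the top dose equals
    three times the well noise s.d."""
    base = default_plate_params()
    coefs = dict(base.response_coefficients)
    top_dose = max(base.primary_doses)
    coefs["genotype[pex16KO]:dose:secondary[Tm]"] = 3.0 * base.noise_sd / top_dose
    return replace(base, response_coefficients=coefs, seed=seed)
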