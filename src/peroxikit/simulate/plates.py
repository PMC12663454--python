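"""Synthetic 384-well viability plates.

Emulates a two-stage drug-challenge assay read out by a fluorescent
viability dye: cells carrying one of two genotypes receive a primary dose
from a 1:2 serial dilution (including dose zero), then a secondary challenge
(vehicle or drug), and each well is measured at two closely spaced
timepoints.  Well fluorescence is a linear response in genotype, dose,
secondary treatment, all their interactions (including the three-way term
that encodes genotype-dependent adaptation) plus a timepoint offset,
additive row and column artifacts, and Gaussian noise.  Conditions are
assigned to wells in a seeded randomized layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PlateConfigError(ValueError):
    pass


class PlateCapacityError(ValueError):
    """More condition x replicate combinations than wells."""


_ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: 1:2 serial dilution from 20 ug/mL down, plus dose zero (ug/mL)
SERIAL_DILUTION_DOSES = (0.0, 0.078, 0.156, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class PlateSimParams:
    genotypes: tuple[str, ...] = ("WT", "pex16KO")
    primary_doses: tuple[float, ...] = SERIAL_DILUTION_DOSES
    secondary_treatments: tuple[str, ...] = ("DMSO", "Tm")
    timepoints: tuple[str, ...] = ("12h", "12.5h")
    n_rows: int = 16
    n_cols: int = 24
    n_plates: int = 2
    row_effects: tuple[float, ...] | None = None
    col_effects: tuple[float, ...] | None = None
    response_coefficients: dict = field(default_factory=dict)
    noise_sd: float = 300.0
    replicates: int = 12
    seed: int = 0

    def __post_init__(self):
        if 0.0 not in self.primary_doses:
            raise PlateConfigError("primary_doses must include dose 0")
        if self.replicates < 1:
            raise PlateConfigError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise PlateConfigError("noise_sd must be non-negative")
        if self.row_effects is not None and len(self.row_effects) != self.n_rows:
            raise PlateConfigError("row_effects length must match plate rows")
        if self.col_effects is not None and len(self.col_effects) != self.n_cols:
            raise PlateConfigError("col_effects length must match plate columns")
        for term in self.response_coefficients:
            self._validate_term(term)

    def _validate_term(self, term: str) -> None:
        valid = {"Intercept", "dose"}
        for g in self.genotypes[1:]:
            valid |= {f"genotype[{g}]", f"genotype[{g}]:dose"}
            for s in self.secondary_treatments[1:]:
                valid |= {
                    f"genotype[{g}]:secondary[{s}]",
                    f"genotype[{g}]:dose:secondary[{s}]",
                }
        for s in self.secondary_treatments[1:]:
            valid |= {f"secondary[{s}]", f"dose:secondary[{s}]"}
        for t in self.timepoints[1:]:
            valid.add(f"timepoint[{t}]")
        if term not in valid:
            raise PlateConfigError(f"unknown response coefficient term {term!r}")


def default_plate_params() -> PlateSimParams:
    """Assay-like defaults: viability (arbitrary fluorescence units) falls
    with primary dose and secondary challenge; pretreatment protects against
    the challenge (positive dose:challenge slope) and that protection is
    diminished in the peroxisome-deficient genotype (negative three-way
    coefficient)."""
    return PlateSimParams(
        response_coefficients={
            "Intercept": 10000.0,
            "genotype[pex16KO]": -500.0,
            "dose": -150.0,
            "secondary[Tm]": -3000.0,
            "genotype[pex16KO]:dose": 60.0,
            "genotype[pex16KO]:secondary[Tm]": -400.0,
            "dose:secondary[Tm]": 120.0,
            "genotype[pex16KO]:dose:secondary[Tm]": -60.0,
            "timepoint[12.5h]": -100.0,
        },
        noise_sd=300.0,
    )


def _predictor(coefs, genotype, dose, secondary, timepoint):
    eta = coefs.get("Intercept", 0.0)
    eta += coefs.get(f"genotype[{genotype}]", 0.0)
    eta += coefs.get("dose", 0.0) * dose
    eta += coefs.get(f"secondary[{secondary}]", 0.0)
    eta += coefs.get(f"genotype[{genotype}]:dose", 0.0) * dose
    eta += coefs.get(f"genotype[{genotype}]:secondary[{secondary}]", 0.0)
    eta += coefs.get(f"dose:secondary[{secondary}]", 0.0) * dose
    eta += coefs.get(f"genotype[{genotype}]:dose:secondary[{secondary}]", 0.0) * dose
    eta += coefs.get(f"timepoint[{timepoint}]", 0.0)
    return eta


def gen_plate_table(params: PlateSimParams) -> pd.DataFrame:
    """Simulate the well-level fluorescence table.

    One row per well per timepoint, columns
    (plate_id, row, column, genotype, primary_dose, secondary_treatment,
    timepoint, fluorescence).  Conditions are scattered over wells in a
    seeded random layout; a capacity error is raised when the design does
    not fit on the available plates.
    """
    rng = np.random.default_rng(params.seed)
    conditions = [
        (g, d, s)
        for g in params.genotypes
        for d in params.primary_doses
        for s in params.secondary_treatments
    ]
    n_assign = len(conditions) * params.replicates
    wells = [
        (p + 1, r, c)
        for p in range(params.n_plates)
        for r in range(params.n_rows)
        for c in range(params.n_cols)
    ]
    if n_assign > len(wells):
        raise PlateCapacityError(
            f"{n_assign} condition x replicate wells requested but only "
            f"{len(wells)} wells available"
        )
    order = rng.permutation(len(wells))[:n_assign]
    assigned = [wells[i] for i in order]

    row_eff = np.zeros(params.n_rows) if params.row_effects is None else np.asarray(params.row_effects, float)
    col_eff = np.zeros(params.n_cols) if params.col_effects is None else np.asarray(params.col_effects, float)

    cond_per_well = [cond for cond in conditions for _ in range(params.replicates)]
    records = []
    for (plate, r, c), (g, d, s) in zip(assigned, cond_per_well):
        for t in params.timepoints:
            value = _predictor(params.response_coefficients, g, float(d), s, t)
            value += row_eff[r] + col_eff[c]
            if params.noise_sd > 0:
                value += rng.normal(0.0, params.noise_sd)
            records.append(
                (plate, _ROW_LETTERS[r], c + 1, g, float(d), s, t, float(value))
            )
    return pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "row",
            "column",
            "genotype",
            "primary_dose",
            "secondary_treatment",
            "timepoint",
            "fluorescence",
        ],
    )
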