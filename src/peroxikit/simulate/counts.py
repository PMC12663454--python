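"""Generative twin of the hurdle count model.

Simulates per-cell peroxisome counts for a strain x treatment x batch design:
each cell clears the hurdle (has any peroxisomes) with probability
``logistic(x @ gamma)``; positive counts are drawn from a zero-truncated
negative binomial with mean parameter ``exp(x @ beta)`` (mean of the
*untruncated* NB) and dispersion ``theta``.  Reference levels (first strain,
first treatment, first batch) carry implicit zero coefficients, exactly
mirroring the treatment coding used by the fitting side.

Coefficient maps are keyed by design term, e.g. ``"Intercept"``,
``"strain[ssa1d]"``, ``"treatment[Tm]"``, ``"batch[b2]"``,
``"strain[ssa1d]:treatment[Tm]"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit


class CountConfigError(ValueError):
    """A coefficient map names a term not expressible in the design."""


@dataclass(frozen=True)
class CountSimParams:
    strains: tuple[str, ...] = ("WT",)
    treatments: tuple[str, ...] = ("DMSO",)
    batches: tuple[str, ...] = ("b1",)
    gamma: dict = field(default_factory=dict)  # logit P(count > 0)
    beta: dict = field(default_factory=dict)  # log NB mean
    theta: float = 5.0
    n_cells: int = 100
    seed: int = 0
    dead_fraction: float | None = None  # optional flag column; never alters counts

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dead_fraction is not None and not 0 <= self.dead_fraction <= 1:
            raise ValueError("dead_fraction must lie in [0, 1]")
        for name, coefs in (("gamma", self.gamma), ("beta", self.beta)):
            for term in coefs:
                self._validate_term(term, name)

    def _validate_term(self, term: str, which: str) -> None:
        valid = {"Intercept"}
        for s in self.strains[1:]:
            valid.add(f"strain[{s}]")
        for t in self.treatments[1:]:
            valid.add(f"treatment[{t}]")
        for b in self.batches[1:]:
            valid.add(f"batch[{b}]")
        for s in self.strains[1:]:
            for t in self.treatments[1:]:
                valid.add(f"strain[{s}]:treatment[{t}]")
        if term not in valid:
            raise CountConfigError(
                f"{which} coefficient names unknown design term {term!r} "
                "(reference levels carry implicit zero coefficients)"
            )


def default_count_params() -> CountSimParams:
    """Study-like defaults: WT plus one mutant, DMSO vs tunicamycin, two
    batches, >=100 cells per condition per batch.

    Magnitudes are chosen to echo the yeast data: most cells have at least
    one peroxisome, a baseline mean of ~3 peroxisomes per positive cell,
    tunicamycin raising the mean by ~50% and the mutant attenuating that
    response.
    """
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
        n_cells=150,
        seed=0,
    )


def _linear_predictor(coefs: dict, strain: str, treatment: str, batch: str) -> float:
    eta = coefs.get("Intercept", 0.0)
    eta += coefs.get(f"strain[{strain}]", 0.0)
    eta += coefs.get(f"treatment[{treatment}]", 0.0)
    eta += coefs.get(f"batch[{batch}]", 0.0)
    eta += coefs.get(f"strain[{strain}]:treatment[{treatment}]", 0.0)
    return float(eta)


def _sample_trunc_nb(rng, mu, theta, size):
    """Zero-truncated NB draws by inversion: u ~ U(p0, 1), k = F^-1(u)."""
    p = theta / (theta + mu)
    p0 = np.exp(theta * np.log(p))
    u = p0 + (1.0 - p0) * rng.random(size)
    k = sps.nbinom.ppf(u, theta, p).astype(np.int64)
    return np.maximum(k, 1)


def gen_count_table(params: CountSimParams) -> pd.DataFrame:
    """Simulate a per-cell count table (cell_id, strain, treatment, batch,
    count) with ``n_cells`` cells per strain x treatment x batch condition.

    Identical params (including seed) give byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    cell_id = 0
    for strain in params.strains:
        for treatment in params.treatments:
            for batch in params.batches:
                n = params.n_cells
                pi = expit(_linear_predictor(params.gamma, strain, treatment, batch))
                mu = np.exp(_linear_predictor(params.beta, strain, treatment, batch))
                positive = rng.random(n) < pi
                counts = np.zeros(n, dtype=np.int64)
                npos = int(positive.sum())
                if npos:
                    counts[positive] = _sample_trunc_nb(rng, mu, params.theta, npos)
                for c in counts:
                    records.append((f"cell{cell_id:06d}", strain, treatment, batch, int(c)))
                    cell_id += 1
    table = pd.DataFrame(
        records, columns=["cell_id", "strain", "treatment", "batch", "count"]
    )
    if params.dead_fraction is not None:
        table["dead"] = rng.random(len(table)) < params.dead_fraction
    return table


def single_condition(mean_count: float, theta: float = 5.0, p_positive: float = 0.9,
                     n_cells: int = 100, seed: int = 0) -> CountSimParams:
    """Convenience: one-condition params for use as a spots-per-cell draw."""
    from scipy.special import logit

    return CountSimParams(
        gamma={"Intercept": float(logit(p_positive))},
        beta={"Intercept": float(np.log(mean_count))},
        theta=theta,
        n_cells=n_cells,
        seed=seed,
    )


def with_seed(params: CountSimParams, seed: int) -> CountSimParams:
    return replace(params, seed=seed)
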