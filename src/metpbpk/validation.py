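"""Prediction-performance statistics and population (VPC) simulation.

The exposure-validation fixture packaged with the model holds paired
predicted/observed Cmax and AUC values for the seven compounds; the
statistics here (fold error census, RSE, GMFE) summarize agreement between
such pairs.  The visual-predictive-check machinery simulates virtual
populations with lognormal inter-individual variability on five
transporter/transit parameters and multiplicative residual error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import (DoseRegimen, DrugProfile, GutGeometry,
                         ParameterError, PhysiologyTable)
from .simulator import SolverOptions, simulate

#: parameters carrying inter-individual variability in population simulation
RANDOM_EFFECT_PARAMETERS = ("sf_OCT3", "CLint_up_OCT1", "CLint_up_OCT2",
                            "CLint_eff_MATE", "K_t")


@dataclass(frozen=True)
class ValidationSet:
    """Paired predicted/observed exposure parameters for one metric."""

    predicted: np.ndarray
    observed: np.ndarray
    metric: str = ""

    def __post_init__(self):
        p = np.asarray(self.predicted, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "observed", o)
        if p.shape != o.shape or p.ndim != 1:
            raise ParameterError("predicted/observed must be 1-d and aligned")
        if np.any(p <= 0) or np.any(o <= 0):
            raise ParameterError("exposure parameters must be positive")

    @property
    def n(self) -> int:
        return self.predicted.size


def load_exposure_validation() -> pd.DataFrame:
    """Packaged predicted/observed exposure pairs (Cmax and AUC rows)."""
    path = resources.files("metpbpk") / "data" / "exposure_validation.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def validation_set(df: pd.DataFrame, metric: str) -> ValidationSet:
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise ParameterError(f"no rows with metric {metric!r}")
    return ValidationSet(sub["predicted"].to_numpy(),
                         sub["observed"].to_numpy(), metric)


def fold_errors(vset: ValidationSet, lower: float = 0.5,
                upper: float = 2.0) -> pd.DataFrame:
    """Per-row prediction/observation ratios with a closed-interval census.

    A ratio exactly on a boundary counts as within the acceptance band.
    The returned frame carries ``n_within`` / ``fraction_within`` attrs.
    """
    ratios = vset.predicted / vset.observed
    within = (ratios >= lower) & (ratios <= upper)
    df = pd.DataFrame({"predicted": vset.predicted, "observed": vset.observed,
                       "ratio": ratios, "within": within})
    df.attrs["n_within"] = int(within.sum())
    df.attrs["fraction_within"] = float(within.mean())
    return df


def rse(vset: ValidationSet) -> float:
    """Relative squared error, percent of observed variance.

    sum((Pre - Obs)^2) / sum((mean(Obs) - Obs)^2) * 100.
    """
    if vset.n < 2:
        raise ParameterError("RSE needs at least two pairs")
    denom = np.sum((vset.observed.mean() - vset.observed) ** 2)
    if denom == 0:
        raise ParameterError("RSE undefined: observations are all equal")
    return float(np.sum((vset.predicted - vset.observed) ** 2) / denom * 100.0)


def gmfe(vset: ValidationSet, mode: str = "signed") -> float:
    """Geometric mean fold error of predictions vs observations.

    ``abs`` applies the absolute value to each log10 ratio (the classical
    definition, always >= 1); ``signed`` omits it, yielding the geometric
    mean prediction bias, which can fall below 1 for under-prediction.
    """
    logs = np.log10(vset.predicted / vset.observed)
    if mode == "abs":
        logs = np.abs(logs)
    elif mode != "signed":
        raise ParameterError("mode must be 'abs' or 'signed'")
    return float(10 ** logs.mean())


# ---------------------------------------------------------------------------
# population simulation / visual predictive check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Lognormal inter-individual + multiplicative residual variability.

    ``cv`` maps each random-effect parameter to its coefficient of
    variation; the exponential model draws multiplier exp(eta) with
    eta ~ N(0, log(1 + CV^2)).
    """

    cv: dict = field(default_factory=lambda: {p: 0.30 for p in RANDOM_EFFECT_PARAMETERS})
    residual_cv: float = 0.20
    n_subjects: int = 12
    seed: int = 0

    def validate(self) -> "PopulationSpec":
        unknown = set(self.cv) - set(RANDOM_EFFECT_PARAMETERS)
        if unknown:
            raise ParameterError(f"unknown random-effect parameters {sorted(unknown)}")
        if any(v < 0 for v in self.cv.values()) or self.residual_cv < 0:
            raise ParameterError("variability must be >= 0")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        return self

    def omega(self, name: str) -> float:
        """Standard deviation of the log-scale random effect."""
        cv = self.cv.get(name, 0.0)
        return float(np.sqrt(np.log1p(cv ** 2)))


@dataclass
class VPCBands:
    """Percentile bands (across subjects) with replicate confidence bands."""

    t_min: np.ndarray
    percentiles: dict            # 5/50/95 -> median across replicates
    ci_low: dict                 # 5/50/95 -> lower 90% CI across replicates
    ci_high: dict
    n_replicates: int
    n_subjects: int
    seed: int


def vpc_simulate(profile: DrugProfile, regimen: DoseRegimen,
                 pop_spec: PopulationSpec,
                 phys: Optional[PhysiologyTable] = None,
                 geom: Optional[GutGeometry] = None, *,
                 n_replicates: int = 200, t_end_min: float = 1440.0,
                 options: SolverOptions = SolverOptions(rtol=1e-6, atol=1e-8),
                 quantiles: Sequence[float] = (5.0, 50.0, 95.0)) -> VPCBands:
    """Replicate population simulations and their percentile bands.

    Each replicate simulates ``n_subjects`` virtual subjects (lognormal
    parameter perturbations plus multiplicative residual error on the
    plasma profile), takes the requested percentiles across subjects per
    time point, and the band reported is the median of each percentile
    across replicates with a 90% confidence band.
    """
    from .synthetic import generate_population

    pop_spec.validate()
    rng = np.random.default_rng(pop_spec.seed)
    t_ref = None
    per_rep = {q: [] for q in quantiles}
    for _ in range(n_replicates):
        subjects = generate_population(pop_spec, profile, geom,
                                       rng=rng)
        profiles = []
        for subj_profile, subj_geom in subjects:
            res = simulate(subj_profile, regimen, phys, subj_geom,
                           t_end_min=t_end_min, options=options)
            conc = res.plasma_conc()
            if pop_spec.residual_cv > 0:
                sigma = np.sqrt(np.log1p(pop_spec.residual_cv ** 2))
                conc = conc * np.exp(rng.normal(0.0, sigma, size=conc.shape))
            profiles.append(conc)
            t_ref = res.t_min
        arr = np.vstack(profiles)
        for q in quantiles:
            per_rep[q].append(np.percentile(arr, q, axis=0))
    percentiles, lo, hi = {}, {}, {}
    for q in quantiles:
        stack = np.vstack(per_rep[q])
        percentiles[q] = np.median(stack, axis=0)
        lo[q] = np.percentile(stack, 5.0, axis=0)
        hi[q] = np.percentile(stack, 95.0, axis=0)
    return VPCBands(t_min=t_ref, percentiles=percentiles, ci_low=lo,
                    ci_high=hi, n_replicates=n_replicates,
                    n_subjects=pop_spec.n_subjects, seed=pop_spec.seed)


def vpc_coverage(observations: pd.DataFrame, bands: VPCBands,
                 lo_q: float = 5.0, hi_q: float = 95.0) -> float:
    """Fraction of observed points inside the [lo_q, hi_q] percentile band.

    ``observations`` needs ``time_h`` and ``conc_ug_per_ml`` columns; band
    values are interpolated to the observation times.
    """
    if observations.empty:
        raise ParameterError("no observations supplied")
    t_obs = observations["time_h"].to_numpy() * 60.0
    c_obs = observations["conc_ug_per_ml"].to_numpy()
    lo = np.interp(t_obs, bands.t_min, bands.percentiles[lo_q])
    hi = np.interp(t_obs, bands.t_min, bands.percentiles[hi_q])
    return float(np.mean((c_obs >= lo) & (c_obs <= hi)))
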