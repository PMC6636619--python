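"""Forecasting phenophase timing from a fitted pheno-climatic model.

A model that includes the phenological index as a main effect can be
inverted into a forecast: pick the PI that identifies a phenophase of
interest (2.5 is a conventional stand-in for peak flowering in the 1–4
scheme), supply climate covariates, and evaluate the linear predictor to
obtain the expected collection day of year of plants at that stage.  The
PI coefficient itself is the mean number of days per unit PI — the pace of
phenological progression — so (k - 1) times it estimates the total
duration of the reproductive phase of a k-stage scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import ClimateCovariates
from .core import DEFAULT_SCHEME, PhenoclimError, StageScheme
from .pcm import PCMFit

#: Conventional PI identifying peak flowering under the default 1-4 scheme.
PEAK_FLOWERING_PI = 2.5


class ForecastError(PhenoclimError):
    """Raised when a fit cannot support the requested forecast."""


@dataclass(frozen=True)
class PhenophaseTarget:
    """A phenophase identified by a PI value (onset, peak, termination...)."""

    label: str
    pi_value: float

    def validate(self, scheme: StageScheme) -> None:
        if not (scheme.min_weight <= self.pi_value <= scheme.max_weight):
            raise ForecastError(
                f"target {self.label!r}: PI {self.pi_value} outside scheme bounds "
                f"[{scheme.min_weight}, {scheme.max_weight}]"
            )


def peak_flowering(pi_value: float = PEAK_FLOWERING_PI) -> PhenophaseTarget:
    return PhenophaseTarget(label="peak", pi_value=pi_value)


@dataclass(frozen=True)
class DOYPrediction:
    doy: float
    se: float
    extrapolated: bool


@dataclass(frozen=True)
class DurationEstimate:
    """Days per stage transition and the implied total reproductive duration."""

    per_stage_days: float
    per_stage_se: float
    n_transitions: int

    @property
    def total_days(self) -> float:
        return self.per_stage_days * self.n_transitions

    @property
    def total_se(self) -> float:
        return self.per_stage_se * self.n_transitions


def _covariate_value(covariates, term: str) -> float:
    if isinstance(covariates, ClimateCovariates):
        mapping = {"winter_ppt_mm": covariates.winter_ppt, "spring_tmax_c": covariates.spring_tmax}
    else:
        mapping = dict(covariates)
    if term not in mapping:
        raise ForecastError(f"covariates do not supply model term {term!r}")
    return float(mapping[term])


def predict_doy(
    fit: PCMFit,
    target: PhenophaseTarget,
    covariates: ClimateCovariates | Mapping[str, float],
    scheme: StageScheme = DEFAULT_SCHEME,
    pi_term: str = "pi",
    prediction_interval: bool = False,
) -> DOYPrediction:
    """Expected DOY at which plants reach ``target.pi_value`` under ``covariates``.

    The standard error is that of the mean prediction (x'Σx)^½; with
    ``prediction_interval=True`` the residual variance is added, giving the
    spread of a single new specimen rather than of the mean.  Covariates
    outside the fitted data's min–max range set the ``extrapolated`` flag
    (the prediction is still returned).  Predictions are not wrapped at
    year boundaries; values outside 1..366 signal extrapolated phenology.
    """
    if pi_term not in fit.spec.terms:
        raise ForecastError(
            f"fit has no {pi_term!r} term; a stage-aware model is required to forecast "
            "phenophase timing"
        )
    target.validate(scheme)

    x = []
    extrapolated = False
    if fit.spec.include_intercept:
        x.append(1.0)
    for term in fit.spec.terms:
        value = target.pi_value if term == pi_term else _covariate_value(covariates, term)
        lo, hi = fit.term_ranges.get(term, (-math.inf, math.inf))
        if not (lo <= value <= hi):
            extrapolated = True
        x.append(value)
    xv = np.asarray(x)
    doy = float(xv @ fit.params_vector())
    var = float(xv @ fit.cov_params @ xv)
    if prediction_interval:
        var += fit.mse
    return DOYPrediction(doy=doy, se=math.sqrt(max(var, 0.0)), extrapolated=extrapolated)


def stage_duration(
    fit: PCMFit, scheme: StageScheme = DEFAULT_SCHEME, pi_term: str = "pi"
) -> DurationEstimate:
    """Days per stage transition (the PI coefficient) and total duration.

    With the default four-class scheme there are three transitions, so the
    total is three times the per-stage coefficient.
    """
    if pi_term not in fit.coefficients:
        raise ForecastError(f"fit has no {pi_term!r} term; cannot estimate stage duration")
    est, se = fit.coefficients[pi_term]
    return DurationEstimate(per_stage_days=est, per_stage_se=se, n_transitions=scheme.n_transitions)


def scenario_table(
    fit: PCMFit,
    targets: Sequence[PhenophaseTarget],
    scenarios: Sequence[ClimateCovariates | Mapping[str, float]],
    scheme: StageScheme = DEFAULT_SCHEME,
    pi_term: str = "pi",
    scenario_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Predicted DOY for every target × scenario combination.

    Columns: ``scenario_id, target_label, pi_value, predicted_doy, se,
    extrapolated``.
    """
    if scenario_ids is None:
        scenario_ids = [
            s.sheet_id if isinstance(s, ClimateCovariates) else f"S{i}"
            for i, s in enumerate(scenarios)
        ]
    rows = []
    for sid, scen in zip(scenario_ids, scenarios):
        for target in targets:
            pred = predict_doy(fit, target, scen, scheme=scheme, pi_term=pi_term)
            rows.append(
                {
                    "scenario_id": sid,
                    "target_label": target.label,
                    "pi_value": target.pi_value,
                    "predicted_doy": pred.doy,
                    "se": pred.se,
                    "extrapolated": pred.extrapolated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["scenario_id", "target_label", "pi_value", "predicted_doy", "se", "extrapolated"],
    )
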