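"""Synthetic herbarium datasets with known pheno-climatic structure.

The generator draws, for each synthetic specimen, a site's winter
precipitation and spring maximum temperature, a reproductive *onset* day
of year that responds linearly to that climate, and a collection offset
``u`` within the reproductive window.  The latent phenological index at
collection is ``PI = w_min + u/d`` (``d`` = days per unit PI), so the
collection day obeys

    DOY = intercept + d·PI + b_ppt·winterPPT + b_tmax·springTmax + ε

with ε Gaussian.  Per-plant stage counts are then drawn so that their
weighted mean scatters around the latent PI, and monthly climate rows are
emitted whose seasonal windows reproduce the drawn covariates.  The full
CSV contracts of the scoring, metadata and climate tables are produced,
plus a truth record for parameter-recovery tests.

Collection bias modes mimic how collectors sample the reproductive
window: ``uniform`` (no preference), ``pre_peak`` (early stages
over-collected) and ``post_peak`` (late stages over-collected), as linear
tilts of the collection-offset density with a strength in [0, 1].

The stage-count mixture (a beta-binomial split between the two classes
bracketing the latent PI) is a tractable stand-in: any count distribution
with the right weighted mean satisfies the PI model, and no canonical
choice exists.  ``count_dispersion`` is the beta concentration; at
``inf`` the split is deterministic rounding and the collection day is
re-coupled to the achieved sheet PI, making coefficients exactly
identifiable from noiseless data.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pcm
from .cellcounter import counts_to_frame
from .climate import build_analysis_table
from .core import DEFAULT_SCHEME, PhenoclimError, PlantCounts, StageScheme

BIAS_MODES = ("uniform", "pre_peak", "post_peak")


class ConfigError(PhenoclimError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class Coefficients:
    """True linear-model coefficients used to generate collection days."""

    intercept: float = 179.2      # days
    per_stage_days: float = 17.08  # days per unit PI
    ppt_slope: float = 0.02        # days per mm winter precipitation
    tmax_slope: float = -4.14      # days per °C spring maximum temperature


@dataclass(frozen=True)
class GeneratorConfig:
    n_specimens: int = 119
    seed: int = 0
    coefficients: Coefficients = field(default_factory=Coefficients)
    winter_ppt_mean: float = 400.0   # mm; Mediterranean-winter rainfall scale
    winter_ppt_sd: float = 200.0
    spring_tmax_mean: float = 17.0   # °C
    spring_tmax_sd: float = 4.0
    residual_sd: float = 25.0        # days
    units_per_plant: float = 40.0    # mean reproductive units per plant
    plants_per_sheet: float = 2.67   # mean plants per sheet
    collection_bias: str = "uniform"
    bias_strength: float = 0.8
    count_dispersion: float = 200.0  # beta concentration; math.inf = deterministic
    year_range: tuple[int, int] = (1950, 1999)

    def validate(self) -> None:
        if self.n_specimens <= 0:
            raise ConfigError(f"n_specimens must be positive, got {self.n_specimens}")
        if self.residual_sd < 0:
            raise ConfigError(f"residual_sd must be >= 0, got {self.residual_sd}")
        if self.coefficients.per_stage_days <= 0:
            raise ConfigError("per_stage_days must be positive")
        if self.collection_bias not in BIAS_MODES:
            raise ConfigError(
                f"collection_bias must be one of {BIAS_MODES}, got {self.collection_bias!r}"
            )
        if not (0.0 <= self.bias_strength <= 1.0):
            raise ConfigError(f"bias_strength must lie in [0, 1], got {self.bias_strength}")
        if self.units_per_plant < 1 or self.plants_per_sheet < 1:
            raise ConfigError("units_per_plant and plants_per_sheet must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    coefficients: Coefficients
    seed: int
    per_specimen: pd.DataFrame  # sheet_id, year, winter_ppt, spring_tmax,
    #                             onset_doy, u, latent_pi, sheet_pi, doy_exact, doy

    def to_dict(self) -> dict:
        return {
            "coefficients": dataclasses.asdict(self.coefficients),
            "seed": self.seed,
            "per_specimen": self.per_specimen.to_dict(orient="records"),
        }


@dataclass
class SyntheticDataset:
    counts: list[PlantCounts]
    metadata: pd.DataFrame
    climate: pd.DataFrame
    truth: SyntheticTruth
    scheme: StageScheme = DEFAULT_SCHEME

    def analysis_table(self, exact: bool = False) -> pd.DataFrame:
        """Model-ready table.

        ``exact=False`` runs the real pipeline (counts -> sheet PI, metadata
        date -> integer DOY, climate windows); ``exact=True`` uses the truth
        record's float DOY and achieved sheet PI — the table on which the
        generating coefficients are exactly identifiable when noise is off,
        since calendar dates quantise DOY to whole days.
        """
        if exact:
            t = self.truth.per_specimen
            return pd.DataFrame(
                {
                    "sheet_id": t["sheet_id"],
                    "doy": t["doy_exact"],
                    "pi": t["sheet_pi"],
                    "winter_ppt_mm": t["winter_ppt"],
                    "spring_tmax_c": t["spring_tmax"],
                }
            )
        table, rejects = build_analysis_table(self.counts, self.metadata, self.climate, self.scheme)
        assert not rejects, f"synthetic dataset should be complete, got rejects {rejects}"
        return table

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write the CSV/JSON bundle; returns the paths written."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "counts": os.path.join(outdir, "counts.csv"),
            "metadata": os.path.join(outdir, "metadata.csv"),
            "climate": os.path.join(outdir, "climate.csv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        counts_to_frame(self.counts, self.scheme).to_csv(paths["counts"], index=False)
        self.metadata.to_csv(paths["metadata"], index=False)
        self.climate.to_csv(paths["climate"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)
        return paths


# ---------------------------------------------------------------------------
# Sampling pieces


def _sample_offset_fraction(rng: np.random.Generator, mode: str, strength: float) -> float:
    """Collection position t in [0, 1] within the reproductive window.

    Densities are linear tilts: f(t) ∝ 1 + s(1-2t) for pre_peak (early
    over-sampled), 1 + s(2t-1) for post_peak, flat for uniform; inverse-CDF
    sampling keeps everything on one random stream.
    """
    q = rng.random()
    s = strength
    if mode == "uniform" or s == 0.0:
        return q
    if mode == "pre_peak":
        # F(t) = (1+s)t - s t^2
        return ((1 + s) - math.sqrt((1 + s) ** 2 - 4 * s * q)) / (2 * s)
    # post_peak: F(t) = (1-s)t + s t^2
    return (-(1 - s) + math.sqrt((1 - s) ** 2 + 4 * s * q)) / (2 * s)


def _split_counts(
    rng: np.random.Generator,
    latent_pi: float,
    n_units: int,
    scheme: StageScheme,
    dispersion: float,
) -> dict[str, int]:
    """Counts over the two classes bracketing the latent PI.

    The expected weighted mean equals the latent PI; finite dispersion adds
    beta-binomial scatter around it.
    """
    ws = scheme.weights
    j = max(i for i in range(len(ws)) if ws[i] <= latent_pi or i == 0)
    j = min(j, len(ws) - 2)
    frac = (latent_pi - ws[j]) / (ws[j + 1] - ws[j])
    frac = min(max(frac, 0.0), 1.0)
    if math.isinf(dispersion) or frac in (0.0, 1.0):
        p_hi = frac
        n_hi = int(round(n_units * p_hi)) if math.isinf(dispersion) else None
        if n_hi is None:
            n_hi = int(rng.binomial(n_units, p_hi))
    else:
        p_hi = rng.beta(dispersion * frac, dispersion * (1.0 - frac))
        n_hi = int(rng.binomial(n_units, p_hi))
    counts = {name: 0 for name in scheme.names}
    counts[scheme.names[j]] = n_units - n_hi
    counts[scheme.names[j + 1]] = n_hi
    return counts


def _plant_pi(counts: dict[str, int], scheme: StageScheme) -> float:
    total = sum(counts.values())
    return sum(counts[n] * w for n, w in scheme.classes) / total


# winter precipitation split across Dec/Jan/Feb; spring tmax offsets around the mean
_WINTER_FRACTIONS = (0.40, 0.35)  # Dec, Jan; Feb takes the remainder exactly
_SPRING_OFFSETS = (-2.0, 2.0)     # Mar, May; Apr balances the mean exactly
_FILL_SPRING_PPT = 20.0           # mm, unused by the covariate windows
_FILL_WINTER_TMAX = 8.0           # °C, unused by the covariate windows


def generate(config: GeneratorConfig, scheme: StageScheme = DEFAULT_SCHEME) -> SyntheticDataset:
    """Generate a complete synthetic dataset (counts, metadata, climate, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    co = config.coefficients
    wmin, wmax = scheme.min_weight, scheme.max_weight
    span_days = (wmax - wmin) * co.per_stage_days

    # gamma parameterised by mean/sd keeps precipitation positive and skewed
    g_shape = (config.winter_ppt_mean / config.winter_ppt_sd) ** 2
    g_scale = config.winter_ppt_sd**2 / config.winter_ppt_mean

    counts: list[PlantCounts] = []
    meta_rows, clim_rows, truth_rows = [], [], []
    for i in range(config.n_specimens):
        sid = f"SYN{i:04d}"
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        ppt = float(rng.gamma(g_shape, g_scale))
        tmax = float(rng.normal(config.spring_tmax_mean, config.spring_tmax_sd))
        eps = float(rng.normal(0.0, config.residual_sd)) if config.residual_sd > 0 else 0.0
        onset = co.intercept + co.per_stage_days * wmin + co.ppt_slope * ppt + co.tmax_slope * tmax + eps
        t = _sample_offset_fraction(rng, config.collection_bias, config.bias_strength)
        u = t * span_days
        latent_pi = wmin + u / co.per_stage_days

        n_plants = 1 + int(rng.poisson(config.plants_per_sheet - 1.0))
        plant_pis = []
        for p in range(n_plants):
            n_units = 1 + int(rng.poisson(config.units_per_plant - 1.0))
            c = _split_counts(rng, latent_pi, n_units, scheme, config.count_dispersion)
            counts.append(PlantCounts(sheet_id=sid, plant_id=f"P{p + 1}", counts=c))
            plant_pis.append(_plant_pi(c, scheme))
        sheet_pi_achieved = float(np.mean(plant_pis))

        if math.isinf(config.count_dispersion):
            # deterministic counting: collection day tracks the achieved stage
            u = (sheet_pi_achieved - wmin) * co.per_stage_days
        doy_exact = onset + u
        days_in_year = 366 if _dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
        doy_int = int(min(max(round(doy_exact), 1), days_in_year))
        date = _dt.date(year, 1, 1) + _dt.timedelta(days=doy_int - 1)

        meta_rows.append(
            {
                "sheet_id": sid,
                "collection_date": date.isoformat(),
                "latitude": 36.0 + (i % 40) * 0.05,
                "longitude": -120.0 + (i // 40) * 0.05,
            }
        )
        dec, jan = (f * ppt for f in _WINTER_FRACTIONS)
        feb = ppt - dec - jan
        mar, may = (tmax + o for o in _SPRING_OFFSETS)
        apr = 3.0 * tmax - mar - may
        clim_rows += [
            {"id": sid, "year": year - 1, "month": 12, "ppt_mm": dec, "tmax_c": _FILL_WINTER_TMAX},
            {"id": sid, "year": year, "month": 1, "ppt_mm": jan, "tmax_c": _FILL_WINTER_TMAX},
            {"id": sid, "year": year, "month": 2, "ppt_mm": feb, "tmax_c": _FILL_WINTER_TMAX},
            {"id": sid, "year": year, "month": 3, "ppt_mm": _FILL_SPRING_PPT, "tmax_c": mar},
            {"id": sid, "year": year, "month": 4, "ppt_mm": _FILL_SPRING_PPT, "tmax_c": apr},
            {"id": sid, "year": year, "month": 5, "ppt_mm": _FILL_SPRING_PPT, "tmax_c": may},
        ]
        truth_rows.append(
            {
                "sheet_id": sid,
                "year": year,
                "winter_ppt": ppt,
                "spring_tmax": tmax,
                "onset_doy": onset,
                "u": u,
                "latent_pi": latent_pi,
                "sheet_pi": sheet_pi_achieved,
                "doy_exact": doy_exact,
                "doy": doy_int,
            }
        )

    return SyntheticDataset(
        counts=counts,
        metadata=pd.DataFrame(meta_rows),
        climate=pd.DataFrame(clim_rows),
        truth=SyntheticTruth(
            coefficients=co, seed=config.seed, per_specimen=pd.DataFrame(truth_rows)
        ),
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Collector-bias experiment


def bias_experiment(
    config: GeneratorConfig,
    modes: tuple[str, ...] = BIAS_MODES,
    scheme: StageScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Fit the climate-only and stage-aware models under each collection bias.

    For each mode the dataset is regenerated (same seed and conditions,
    only the bias mode changes), both models are fitted to the pipeline
    analysis table, and the gaps between fitted and true climate slopes are
    reported together with both training R² values.
    """
    co = config.coefficients
    rows = []
    for mode in modes:
        cfg = dataclasses.replace(config, collection_bias=mode)
        ds = generate(cfg, scheme)
        table = ds.analysis_table()
        f1 = pcm.fit(pcm.MODEL1, table)
        f2 = pcm.fit(pcm.MODEL2, table)
        rows.append(
            {
                "mode": mode,
                "mean_latent_pi": float(ds.truth.per_specimen["latent_pi"].mean()),
                "m1_ppt_gap": f1.coefficients["winter_ppt_mm"][0] - co.ppt_slope,
                "m1_tmax_gap": f1.coefficients["spring_tmax_c"][0] - co.tmax_slope,
                "m2_ppt_gap": f2.coefficients["winter_ppt_mm"][0] - co.ppt_slope,
                "m2_tmax_gap": f2.coefficients["spring_tmax_c"][0] - co.tmax_slope,
                "m2_ppt_se": f2.coefficients["winter_ppt_mm"][1],
                "m2_tmax_se": f2.coefficients["spring_tmax_c"][1],
                "r2_model1": f1.r2,
                "r2_model2": f2.r2,
                "delta_r2": f2.r2 - f1.r2,
            }
        )
    return pd.DataFrame(rows)
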