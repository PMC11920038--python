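"""Seeded synthetic station profiles and titration curves.

The generator emulates the statistical structure the analysis chain
assumes so every stage is testable without field data:

* eHS is lognormal around a depth-dependent mean that relaxes from the
  surface value (75.7 µg/L) to the deep value (39.9 µg/L) with a 100 m
  e-folding scale;
* the ligand pool tracks the humic signal linearly,
  Fe-L = 1.3 + 0.045 × eHS (+ Gaussian noise), the observed circumpolar
  regression;
* DFe is a Beta-distributed fraction of Fe-L (mean ≈ 0.3), so ligands are
  in excess in most samples;
* log K_Fe'L ~ Normal(11.28, 0.46);
* carbohydrates and bacterial abundance attenuate with depth.

Negative draws are resampled rather than clipped, so no probability mass
piles up at zero.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from . import speciation

__all__ = [
    "StationGeneratorConfig",
    "generate_station_dataset",
    "draw_titration_truth",
    "generate_titration_dataset",
]

#: e-folding depth (m) of the surface-to-deep transition in mean profiles.
DEPTH_SCALE_M = 100.0


@dataclass(frozen=True)
class StationGeneratorConfig:
    """Study conditions for the synthetic circumpolar survey.

    Scale defaults are anchored to the printed summary statistics of the
    observed dataset: surface/deep eHS means, the Fe-L ~ eHS regression
    intercept and slope, and the log K distribution.  The DFe fraction and
    depth-decay rates are package conventions (see docs/methods.md).
    """

    n_stations: int = 10
    depths: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    ehs_surface_mean: float = 75.7      # µg/L
    ehs_deep_mean: float = 39.9         # µg/L
    ehs_lognorm_cv: float = 0.8
    fel_intercept: float = 1.3          # nmol/L
    fel_slope: float = 0.045            # nmol/L per µg/L eHS
    fel_noise_sd: float = 0.5           # nmol/L
    logK_mean: float = 11.28
    logK_sd: float = 0.46
    dfe_frac_alpha: float = 1.5         # Beta(α, β): DFe as fraction of Fe-L
    dfe_frac_beta: float = 3.5          # mean α/(α+β) = 0.3
    carb_surface_mean: float = 200.0    # µg/L glucose equivalent
    carb_deep_mean: float = 50.0        # µg/L
    carb_lognorm_cv: float = 0.4
    bacteria_surface_mean: float = 5e5  # cells/mL
    bacteria_deep_mean: float = 4e4     # cells/mL
    bacteria_lognorm_cv: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        bad = []
        positive = [f.name for f in fields(self)
                    if f.name not in ("seed", "depths", "n_stations")]
        for name in positive:
            if not (getattr(self, name) > 0):
                bad.append(name)
        if self.n_stations < 1:
            bad.append("n_stations")
        if len(self.depths) < 1 or any(d < 0 for d in self.depths):
            bad.append("depths")
        if bad:
            raise DomainError(f"invalid generator config fields: {', '.join(bad)}")


def _depth_mean(depth: np.ndarray, surface: float, deep: float) -> np.ndarray:
    return deep + (surface - deep) * np.exp(-depth / DEPTH_SCALE_M)


def _lognormal_mean_cv(rng: np.random.Generator, mean, cv: float) -> np.ndarray:
    """Lognormal draws parameterised by arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2))


def generate_station_dataset(
    config: StationGeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a synthetic station table (one row per station × depth).

    Columns follow the station-file convention (units in names):
    station, latitude, longitude, depth_m, dfe_nM, fel_nM, logK, ehs_ugL,
    carb_ugL, bacteria_per_mL, fvfm, chla_ugL.  ``seed`` overrides
    ``config.seed``; one of the two is required.
    """
    config = config or StationGeneratorConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise DomainError("a seed is required (config.seed or seed argument)")
    rng = np.random.default_rng(seed)

    depths = np.asarray(config.depths, dtype=float)
    n_rows = config.n_stations * depths.size
    depth_col = np.tile(depths, config.n_stations)
    station_col = np.repeat(
        [f"ST{i + 1:02d}" for i in range(config.n_stations)], depths.size)
    lat = np.repeat(rng.uniform(-70.0, -45.0, config.n_stations), depths.size)
    lon = np.repeat(rng.uniform(-180.0, 180.0, config.n_stations), depths.size)

    # lognormal draws are positive by construction; no resampling needed here
    ehs_mean = _depth_mean(depth_col, config.ehs_surface_mean, config.ehs_deep_mean)
    ehs = _lognormal_mean_cv(rng, ehs_mean, config.ehs_lognorm_cv)

    # Fe-L tracks eHS linearly; Gaussian noise, negatives resampled.
    fel = config.fel_intercept + config.fel_slope * ehs
    if config.fel_noise_sd > 0:
        noise = rng.normal(0.0, config.fel_noise_sd, n_rows)
        fel_noisy = fel + noise
        for _ in range(100):
            bad = fel_noisy <= 0
            if not bad.any():
                break
            fel_noisy[bad] = fel[bad] + rng.normal(
                0.0, config.fel_noise_sd, int(bad.sum()))
        else:
            raise DomainError("fel_noise_sd too large relative to Fe-L scale")
        fel = fel_noisy

    # DFe as a Beta fraction of Fe-L keeps ligands in excess in most rows.
    dfe = fel * rng.beta(config.dfe_frac_alpha, config.dfe_frac_beta, n_rows)
    logk = rng.normal(config.logK_mean, config.logK_sd, n_rows)

    carb_mean = _depth_mean(depth_col, config.carb_surface_mean, config.carb_deep_mean)
    carb = _lognormal_mean_cv(rng, carb_mean, config.carb_lognorm_cv)
    bact_mean = _depth_mean(
        depth_col, config.bacteria_surface_mean, config.bacteria_deep_mean)
    bacteria = _lognormal_mean_cv(rng, bact_mean, config.bacteria_lognorm_cv)

    # Photophysiology and chlorophyll only in the upper 100 m.
    fvfm = np.where(depth_col <= 100.0,
                    rng.uniform(0.2, 0.65, n_rows), np.nan)
    chla = np.where(depth_col <= 100.0,
                    _lognormal_mean_cv(
                        rng, _depth_mean(depth_col, 0.7, 0.05), 0.5),
                    np.nan)

    return pd.DataFrame({
        "station": station_col,
        "latitude": np.round(lat, 4),
        "longitude": np.round(lon, 4),
        "depth_m": depth_col,
        "dfe_nM": dfe,
        "fel_nM": fel,
        "logK": logk,
        "ehs_ugL": ehs,
        "carb_ugL": carb,
        "bacteria_per_mL": bacteria,
        "fvfm": fvfm,
        "chla_ugL": chla,
    })


def draw_titration_truth(
    n: int,
    seed: int,
    lt_range: tuple[float, float] = (0.5, 5.0),
    logK_mean: float = 11.28,
    logK_sd: float = 0.46,
    dfe_frac_mean: float = 0.3,
) -> pd.DataFrame:
    """Draw a truth table of (L_T, logK, dfe0) for titration simulations."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lt = rng.uniform(*lt_range, n)
    logk = rng.normal(logK_mean, logK_sd, n)
    dfe0 = lt * rng.beta(1.5, 1.5 * (1 - dfe_frac_mean) / dfe_frac_mean, n)
    return pd.DataFrame({
        "sample": [f"S{i + 1:03d}" for i in range(n)],
        "L_T_nM": lt, "logK": logk, "dfe0_nM": dfe0,
    })


def generate_titration_dataset(
    truth: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int | None = None,
    additions: Sequence[float] | None = None,
    alpha_sa: float | None = None,
    sensitivity: float = 1e9,
) -> list[speciation.TitrationCurve]:
    """One simulated titration per truth row (columns L_T_nM, logK, dfe0_nM).

    Per-curve noise seeds are spawned deterministically from ``seed``; the
    truth table rides along in each curve's ``meta`` for recovery scoring.
    """
    if noise_sd > 0 and seed is None:
        raise DomainError("a seed is required when noise_sd > 0")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(len(truth))]
    curves = []
    for (idx, row), sub_seed in zip(truth.iterrows(), child_seeds):
        curve = speciation.simulate_titration(
            dfe0=float(row["dfe0_nM"]),
            L_T=float(row["L_T_nM"]),
            logK=float(row["logK"]),
            additions=additions,
            alpha_sa=alpha_sa,
            sensitivity=sensitivity,
            noise_sd=noise_sd,
            seed=sub_seed if noise_sd > 0 else None,
            meta={"sample": row.get("sample", str(idx)),
                  "true_L_T_nM": float(row["L_T_nM"]),
                  "true_logK": float(row["logK"])},
        )
        curves.append(curve)
    return curves
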