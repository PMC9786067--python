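"""Synthetic data generation for end-to-end pipeline testing.

The generator emulates the three layers of the study's data:

1. **Retention series** — for each compound, Foley-linear 1/k values over
   the four working SDS concentrations (0.10, 0.105, 0.11, 0.12 mol/L)
   with additive Gaussian noise on the 1/k scale (the scale on which the
   straight line is fitted, so OLS recovery is exactly unbiased).
2. **Descriptor table** — draws from a multivariate normal whose
   correlation matrix reproduces the three-group structure of the study
   descriptors: a polar pair (TPSA, HBA) correlated at ~0.99, a size trio
   (MW, alpha, parachor) at ~0.93, weak polar-size coupling, and NRB
   independent.  Count descriptors (HBA, NRB) are rounded to integers and
   clipped to the observed ranges, so target correlations hold exactly on
   the latent (pre-rounding) scale only.
3. **Response** — a known linear model in the predictors plus Gaussian
   noise, defaulting to the coefficients of the study's shortlisted
   log BB model.

Everything is driven by one :class:`GeneratorConfig` and a seed;
generation is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .foley import RetentionSeries

__all__ = [
    "GeneratorConfig",
    "generate_descriptor_table",
    "generate_retention_series",
    "generate_response",
    "simulate_study",
]

#: Descriptor means and standard deviations of the study table (frozen
#: summary statistics of the 65-compound descriptor matrix).
_DESCRIPTOR_MOMENTS: dict[str, tuple[float, float]] = {
    "tpsa": (56.8, 11.1),
    "hba": (5.7, 0.9),
    "mw": (326.6, 31.3),
    "alpha": (35.7, 3.6),
    "parachor_P": (645.3, 63.5),
    "nrb": (3.2, 1.2),
}

_POLAR = ("tpsa", "hba")
_SIZE = ("mw", "alpha", "parachor_P")
_FLEX = ("nrb",)
_COLUMNS = _POLAR + _SIZE + _FLEX

#: Observed integer ranges used to clip the rounded count descriptors.
_CLIP = {"hba": (5, 8), "nrb": (2, 6)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic study generator.

    Defaults restate the study's conditions: 65 compounds, the four SDS
    working concentrations, Foley parameters spanning the observed ranges
    (slope 1.55-13.8 L/mol with intercept/slope ratio ~0.075-0.089, i.e.
    small negative intercepts), the observed descriptor moments and group
    correlations, the shortlisted log BB model's coefficients as truth,
    and moderate noise (sigma_y = 0.08 response units, sigma_k = 0.01 on
    the 1/k scale).
    """

    n_compounds: int = 65
    concentrations: tuple[float, ...] = (0.10, 0.105, 0.11, 0.12)
    slope_range: tuple[float, float] = (1.55, 13.8)
    intercept_ratio_range: tuple[float, float] = (0.075, 0.089)
    rho_polar: float = 0.99
    rho_size: float = 0.93
    rho_cross: float = 0.2
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "const": 0.253,
            "log_km_over_kam": 0.198,
            "hba": -0.160,
            "nrb": -0.019,
            "parachor_P": 0.002,
        }
    )
    sigma_y: float = 0.08
    sigma_k: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, rho in (("rho_polar", self.rho_polar), ("rho_size", self.rho_size), ("rho_cross", self.rho_cross)):
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"{name} must lie in (-1, 1), got {rho}")
        if self.sigma_y < 0 or self.sigma_k < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be positive")
        if len(self.concentrations) < 2:
            raise ConfigError("need at least two surfactant concentrations")

    def correlation_matrix(self) -> np.ndarray:
        """Target correlation matrix over (tpsa, hba, mw, alpha, parachor, nrb)."""
        k = len(_COLUMNS)
        R = np.full((k, k), 0.0)
        idx = {c: i for i, c in enumerate(_COLUMNS)}
        for a in _COLUMNS:
            for b in _COLUMNS:
                i, j = idx[a], idx[b]
                if i == j:
                    R[i, j] = 1.0
                elif a in _POLAR and b in _POLAR:
                    R[i, j] = self.rho_polar
                elif a in _SIZE and b in _SIZE:
                    R[i, j] = self.rho_size
                elif a in _FLEX or b in _FLEX:
                    R[i, j] = 0.0
                else:
                    R[i, j] = self.rho_cross
        eigvals = np.linalg.eigvalsh(R)
        if eigvals.min() <= 1e-10:
            raise ConfigError(
                f"target correlation matrix is not positive definite (min eigenvalue {eigvals.min():.3g})"
            )
        return R


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), stream))


def generate_descriptor_table(
    config: GeneratorConfig,
    return_latent: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic descriptor table with the study's group structure.

    Returns a frame with ``compound_id`` plus the six descriptor columns;
    HBD is identically zero as in the study compounds.  With
    ``return_latent=True`` the pre-rounding Gaussian draws are returned as
    a second frame (the scale on which correlation targets are exact).
    """
    config.validate()
    R = config.correlation_matrix()
    rng = _rng(config, 1)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((config.n_compounds, len(_COLUMNS))) @ L.T
    latent = pd.DataFrame(Z, columns=list(_COLUMNS))
    table = {"compound_id": np.arange(1, config.n_compounds + 1)}
    for col in _COLUMNS:
        mean, sd = _DESCRIPTOR_MOMENTS[col]
        vals = mean + sd * latent[col].to_numpy()
        if col in _CLIP:
            lo, hi = _CLIP[col]
            vals = np.clip(np.round(vals), lo, hi).astype(int)
        table[col] = vals
    frame = pd.DataFrame(table)
    frame.insert(1, "hbd", 0)
    if return_latent:
        return frame, latent
    return frame


def generate_retention_series(
    config: GeneratorConfig,
    truth: Sequence[tuple[float, float]] | None = None,
) -> tuple[list[RetentionSeries], pd.DataFrame]:
    """Generate Foley-linear retention series for each compound.

    Parameters
    ----------
    config : GeneratorConfig
    truth : sequence of (intercept, slope), optional
        Per-compound Foley parameters.  When omitted, slopes are drawn
        uniformly from ``config.slope_range`` and intercepts as
        ``-ratio*slope`` with the ratio uniform in
        ``config.intercept_ratio_range`` (mimicking the small negative
        intercepts of strongly retained solutes while guaranteeing
        1/k > 0 at every working concentration).

    Returns
    -------
    (series, truth_frame)
        The noisy series and a frame with the true per-compound
        parameters.  Noise is additive Gaussian on the 1/k scale
        (homoscedastic within a compound, so the straight-line OLS noise
        model is exact) with standard deviation ``sigma_k`` *relative* to
        the compound's mean 1/k level — matching the observed pattern
        that weakly retained solutes show proportionally smaller absolute
        scatter, and keeping 1/k safely positive.
    """
    config.validate()
    rng = _rng(config, 2)
    conc = np.asarray(config.concentrations, dtype=float)
    n = config.n_compounds
    if truth is None:
        slopes = rng.uniform(*config.slope_range, size=n)
        ratios = rng.uniform(*config.intercept_ratio_range, size=n)
        intercepts = -ratios * slopes
        truth = list(zip(intercepts, slopes))
    series: list[RetentionSeries] = []
    rows = []
    for i, (b0, b1) in enumerate(truth, start=1):
        inv_k = b0 + b1 * conc
        if (inv_k <= 0).any():
            raise ConfigError(
                f"compound {i}: 1/k = {b0:.3g} + {b1:.3g}*[M] is non-positive at a "
                "configured concentration"
            )
        sd = config.sigma_k * float(inv_k.mean())
        noisy = inv_k + rng.normal(0.0, sd, size=conc.size)
        if (noisy <= 0).any():
            raise ConfigError(f"compound {i}: noise drove 1/k non-positive; lower sigma_k")
        series.append(RetentionSeries(compound_id=str(i), total_conc=conc, k=1.0 / noisy))
        rows.append({"compound_id": i, "intercept": b0, "slope": b1})
    return series, pd.DataFrame(rows)


def generate_response(
    config: GeneratorConfig,
    table: pd.DataFrame,
    name: str = "log_bb",
) -> pd.Series:
    """Generate y = a0 + sum_j a_j x_j + Normal(0, sigma_y^2) noise."""
    config.validate()
    coeffs = dict(config.true_coefficients)
    a0 = coeffs.pop("const", 0.0)
    missing = [c for c in coeffs if c not in table.columns]
    if missing:
        raise ConfigError(f"table lacks predictor column(s) {', '.join(missing)}")
    rng = _rng(config, 3)
    y = np.full(len(table), a0, dtype=float)
    for col, a in coeffs.items():
        y += a * table[col].to_numpy(dtype=float)
    y += rng.normal(0.0, config.sigma_y, size=len(table))
    return pd.Series(y, name=name)


def simulate_study(config: GeneratorConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the generator end to end: descriptors, retention, response.

    Fits the Foley model to each synthetic retention series to obtain the
    micellar lipophilicity column, then generates the response from the
    configured true coefficients.

    Returns
    -------
    (table, foley_truth)
        ``table`` is a complete descriptor/response frame ready for
        :class:`~mlcqsar.qsar.QSARModel`; ``foley_truth`` records the true
        per-compound Foley parameters.
    """
    from .foley import NegativeInterceptWarning, fit_foley

    config = config or GeneratorConfig()
    table = generate_descriptor_table(config)
    series, truth = generate_retention_series(config)
    with warnings.catch_warnings():
        # the generator deliberately produces negative intercepts, as the
        # strongly retained study compounds do
        warnings.simplefilter("ignore", NegativeInterceptWarning)
        descr = [fit_foley(s).log_km_over_kam for s in series]
    table.insert(1, "log_km_over_kam", descr)
    table[config_response_name(config)] = generate_response(config, table).to_numpy()
    return table, truth


def config_response_name(config: GeneratorConfig) -> str:
    """Name of the generated response column (fixed to log_bb)."""
    return "log_bb"
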