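"""Micellar liquid chromatography retention and the Foley model.

In micellar liquid chromatography (MLC) the retention factor ``k`` of a
solute decreases as the concentration of micellised surfactant ``[M]`` in
the mobile phase increases.  The Foley model describes this as a straight
line in reciprocal space::

    1/k = 1/k_m + (K_AM / k_m) * [M]

where ``k_m`` is the retention factor extrapolated to zero micelle
concentration and ``K_AM`` the solute-micelle binding constant.  Both
parameters reflect solute lipophilicity, so the slope-derived quantity

    log(k_m / K_AM) = -log10(slope)

serves as a chromatographic (micellar) lipophilicity descriptor.  The
slope is used rather than the intercept because strongly retained solutes
commonly yield small negative fitted intercepts, which have no physical
interpretation as 1/k_m; the slope-based descriptor is unaffected by this
and is likewise invariant to the assumed critical micellisation
concentration (shifting ``[M]`` by a constant cannot change an OLS slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .errors import DescriptorUndefinedError, SingularFitError, ValidationError

__all__ = [
    "retention_factor",
    "micelle_concentration",
    "micellar_lipophilicity",
    "RetentionSeries",
    "FoleyFit",
    "FoleyModel",
    "fit_foley",
    "NegativeInterceptWarning",
]


class NegativeInterceptWarning(UserWarning):
    """Fitted Foley intercept is negative (1/k_m has no physical meaning)."""


def retention_factor(t_r: float, t_m: float) -> float:
    """Chromatographic retention factor k = (t_R - t_M) / t_M.

    ``t_R`` is the solute retention time, ``t_M`` the dead (hold-up) time
    of an unretained marker.  ``t_R < t_M`` is permitted and yields a
    negative k, which downstream fitting flags and excludes.
    """
    if not (np.isfinite(t_r) and np.isfinite(t_m)):
        raise ValidationError("retention times must be finite")
    if t_m <= 0:
        raise ValidationError(f"dead time t_M must be positive, got {t_m}")
    return (t_r - t_m) / t_m


def micelle_concentration(total_conc: float, cmc: float = 0.0) -> float:
    """Micellised surfactant concentration [M] = total - cmc (mol/L)."""
    if cmc < 0:
        raise ValidationError(f"cmc must be non-negative, got {cmc}")
    if total_conc <= cmc:
        raise ValidationError(
            f"total surfactant {total_conc} mol/L does not exceed the cmc {cmc} mol/L: "
            "no micellar pseudophase"
        )
    return total_conc - cmc


@dataclass
class RetentionSeries:
    """One compound's retention factors across surfactant concentrations.

    Attributes
    ----------
    compound_id : str
        Compound label.
    total_conc : array of float
        Total surfactant concentrations, mol/L.  Must all exceed ``cmc``.
    k : array of float
        Retention factors at the matching concentrations.
    cmc : float
        Critical micellisation concentration, mol/L.  Defaults to 0, i.e.
        [M] is taken as the total surfactant concentration; the Foley
        slope (and the descriptor derived from it) is invariant to this
        choice.
    """

    compound_id: str
    total_conc: np.ndarray
    k: np.ndarray
    cmc: float = 0.0

    def __post_init__(self) -> None:
        self.total_conc = np.asarray(self.total_conc, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.total_conc.shape != self.k.shape:
            raise ValidationError("total_conc and k must have equal length")
        if self.total_conc.size < 2:
            raise ValidationError("a retention series needs at least 2 points")
        if self.cmc < 0:
            raise ValidationError("cmc must be non-negative")
        if (self.total_conc <= self.cmc).any():
            raise ValidationError("all total concentrations must exceed the cmc")

    @classmethod
    def from_times(
        cls,
        compound_id: str,
        total_conc: Sequence[float],
        t_r: Sequence[float],
        t_m: float | Sequence[float],
        cmc: float = 0.0,
    ) -> "RetentionSeries":
        """Build a series from retention times and the dead time."""
        t_r = np.asarray(t_r, dtype=float)
        t_m_arr = np.broadcast_to(np.asarray(t_m, dtype=float), t_r.shape)
        k = np.array([retention_factor(r, m) for r, m in zip(t_r, t_m_arr)])
        return cls(compound_id=compound_id, total_conc=np.asarray(total_conc, float), k=k, cmc=cmc)

    @property
    def micelle_conc(self) -> np.ndarray:
        """[M] values, mol/L."""
        return self.total_conc - self.cmc


@dataclass(frozen=True)
class FoleyFit:
    """Results of the straight-line fit 1/k = intercept + slope*[M].

    ``log_km_over_kam`` is the micellar lipophilicity descriptor
    -log10(slope); it is defined from the slope alone.
    """

    compound_id: str
    intercept: float
    slope: float
    r2: float
    n_points: int
    log_km_over_kam: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_km_over_kam", -np.log10(self.slope))

    def summary(self) -> str:
        return (
            f"Foley fit [{self.compound_id}]  1/k = {self.intercept:.3f} + "
            f"{self.slope:.3f}*[M]   R2 = {self.r2:.4f}  (n = {self.n_points})\n"
            f"log(k_m/K_AM) = {self.log_km_over_kam:.3f}"
        )


class FoleyModel:
    """Foley retention model for one compound's series.

    Ordinary least squares of y = 1/k on x = [M].  Rows with k <= 0
    (solute eluting at or before the dead time) are excluded with a
    warning, since 1/k is then meaningless.
    """

    def __init__(self, series: RetentionSeries):
        self.series = series

    def fit(self) -> FoleyFit:
        """Fit the model and return a :class:`FoleyFit`.

        Raises
        ------
        SingularFitError
            Fewer than two usable points or zero variance in [M].
        DescriptorUndefinedError
            Non-positive fitted slope (log descriptor undefined).
        """
        s = self.series
        usable = s.k > 0
        if not usable.all():
            warnings.warn(
                f"compound {s.compound_id}: excluding {int((~usable).sum())} "
                "non-positive retention factor(s) from the Foley fit",
                UserWarning,
                stacklevel=2,
            )
        x = s.micelle_conc[usable]
        y = 1.0 / s.k[usable]
        if x.size < 2:
            raise SingularFitError(
                f"compound {s.compound_id}: fewer than 2 usable points for the Foley fit"
            )
        if np.ptp(x) == 0:
            raise SingularFitError(
                f"compound {s.compound_id}: zero variance in micelle concentration"
            )
        if x.size == 2:
            # exact interpolating line; linregress r is undefined only for
            # zero y-variance, so compute directly
            slope = (y[1] - y[0]) / (x[1] - x[0])
            intercept = y[0] - slope * x[0]
            r2 = 1.0
        else:
            res = _stats.linregress(x, y)
            slope, intercept = res.slope, res.intercept
            r2 = res.rvalue**2
        if slope <= 0:
            raise DescriptorUndefinedError(
                f"compound {s.compound_id}: non-positive Foley slope {slope:.4g}; "
                "log(k_m/K_AM) undefined"
            )
        if intercept < 0:
            warnings.warn(
                f"compound {s.compound_id}: negative Foley intercept {intercept:.4g} "
                "(1/k_m not physically interpretable; slope-derived descriptor unaffected)",
                NegativeInterceptWarning,
                stacklevel=2,
            )
        return FoleyFit(
            compound_id=s.compound_id,
            intercept=float(intercept),
            slope=float(slope),
            r2=float(r2),
            n_points=int(x.size),
        )


def fit_foley(series: RetentionSeries) -> FoleyFit:
    """Convenience wrapper: ``FoleyModel(series).fit()``."""
    return FoleyModel(series).fit()


def micellar_lipophilicity(fit_or_slope: FoleyFit | float) -> float:
    """Micellar lipophilicity descriptor log(k_m/K_AM) = -log10(slope)."""
    slope = fit_or_slope.slope if isinstance(fit_or_slope, FoleyFit) else float(fit_or_slope)
    if slope <= 0:
        raise DescriptorUndefinedError(f"slope must be positive, got {slope}")
    return -float(np.log10(slope))
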