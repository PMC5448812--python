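"""Gel-band quantification and cooperative-binding / enzyme-kinetics fits.

EMSA titrations are fitted with the Hill equation for the bound fraction,

    f(L) = L^n / (K^n + L^n),

parameterised by the half-saturation constant K (so K carries concentration
units) and the Hill slope n; n > 1 indicates cooperative binding. The data
are typically recorded as the unbound fraction 1 - f(L), which is what gel
quantification of the free-substrate band yields directly.

ATPase titrations are fitted with the Michaelis-Menten law

    v(S) = V_max S / (K_m + S),

with k_cat = V_max when rates are already per enzyme, else V_max divided by
the enzyme concentration. Parameter standard errors come from the local
curvature (covariance) of the least-squares objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "TitrationSeries",
    "HillFit",
    "MMFit",
    "gel_fraction",
    "hill_bound",
    "michaelis_menten",
    "fit_hill",
    "fit_michaelis_menten",
    "competition_normalize",
]


@dataclass
class TitrationSeries:
    """Concentration-response data for one substrate or condition.

    ``kind`` declares what y is: ``"unbound_fraction"`` (free-band EMSA
    quantification, the default), ``"bound_fraction"``, or ``"rate"`` (for
    kinetics, in min^-1).
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "unbound_fraction"
    label: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matching 1-D arrays")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if self.kind.endswith("_fraction") and (
            np.any(self.y < 0) or np.any(self.y > 1)
        ):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, kind: str = "unbound_fraction", label: str = "") -> "TitrationSeries":
        """Read (x, y[, replicate]) CSV; replicates are averaged per x."""
        df = pd.read_csv(path)
        grouped = df.groupby(df.columns[0])[df.columns[1]].mean()
        return cls(grouped.index.to_numpy(), grouped.to_numpy(), kind=kind, label=label)

    def bound_fraction(self) -> np.ndarray:
        if self.kind == "bound_fraction":
            return self.y
        if self.kind == "unbound_fraction":
            return 1.0 - self.y
        raise ValueError(f"series of kind {self.kind!r} is not a binding fraction")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: half-saturation K_D and slope n_H."""

    kd: float
    n_h: float
    kd_se: float
    n_h_se: float
    rss: float
    n_points: int

    def __post_init__(self):
        if self.kd <= 0 or self.n_h <= 0:
            raise ValueError("K_D and n_H must be positive")

    def bound(self, concentration):
        return hill_bound(np.asarray(concentration, dtype=float), self.kd, self.n_h)


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    kcat: float
    rss: float
    n_points: int

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("V_max and K_m must be positive")

    def rate(self, substrate):
        return michaelis_menten(np.asarray(substrate, dtype=float), self.vmax, self.km)


def gel_fraction(band_intensities) -> dict[str, float]:
    """Per-band fraction of total lane intensity.

    ``band_intensities`` maps band labels to non-negative intensities (a
    plain sequence is labelled band_1, band_2, ...). For a two-band EMSA lane
    the bound fraction is simply 1 - free fraction.
    """
    if not isinstance(band_intensities, dict):
        band_intensities = {
            f"band_{i + 1}": v for i, v in enumerate(band_intensities)
        }
    values = np.array(list(band_intensities.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("band intensities must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero lane: total intensity must be positive")
    return {k: float(v / total) for k, v in band_intensities.items()}


def hill_bound(concentration, kd, n):
    """Hill bound fraction L^n / (K^n + L^n), saturating at 1."""
    conc = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / kd) ** n, 0.0)
    return ratio / (1.0 + ratio)


def michaelis_menten(substrate, vmax, km):
    return vmax * np.asarray(substrate, dtype=float) / (km + substrate)


def _hill_init(x, bound):
    """Initial (K, n) from the half-max crossing and the local log-log slope."""
    order = np.argsort(x)
    xs, bs = x[order], bound[order]
    crossing = np.nonzero(np.diff(np.sign(bs - 0.5)))[0]
    if len(crossing):
        i = crossing[0]
        x0, x1, b0, b1 = xs[i], xs[i + 1], bs[i], bs[i + 1]
        k0 = x0 + (0.5 - b0) * (x1 - x0) / (b1 - b0) if b1 != b0 else x0
    else:
        k0 = float(np.median(xs[xs > 0])) if np.any(xs > 0) else 1.0
    # log-log slope of the odds f/(1-f) near half-max gives the Hill slope
    mid = (bs > 0.1) & (bs < 0.9) & (xs > 0)
    if mid.sum() >= 2:
        odds = bs[mid] / (1.0 - bs[mid])
        slope = np.polyfit(np.log(xs[mid]), np.log(odds), 1)[0]
        n0 = float(np.clip(slope, 0.2, 6.0))
    else:
        n0 = 1.0
    return max(float(k0), np.finfo(float).tiny), n0


def fit_hill(series: TitrationSeries, free_amplitude: bool = False) -> HillFit:
    """Least-squares Hill fit of a binding titration.

    The fit targets the series on its native scale (the unbound fraction for
    EMSA free-band quantification), with the saturating bound fraction fixed
    at 1; ``free_amplitude=True`` frees the saturation amplitude for
    titrations that plateau below complete binding. Requires at least 4
    points with observations on both sides of half-maximal binding, otherwise
    K_D is not identifiable.
    """
    if len(series.x) < 4:
        raise ValueError("need at least 4 titration points")
    bound = series.bound_fraction()
    if bound.max() < 0.5 or bound.min() > 0.5:
        raise ValueError(
            "titration does not bracket half-maximal binding; K_D not identifiable"
        )
    sign = -1.0 if series.kind == "unbound_fraction" else 1.0
    y = series.y

    if free_amplitude:
        def model(L, kd, n, amp):
            f = amp * hill_bound(L, kd, n)
            return 1.0 - f if sign < 0 else f

        p0 = (*_hill_init(series.x, bound), 1.0)
        bounds = ([np.finfo(float).tiny, 1e-3, 0.1], [np.inf, 6.0, 1.2])
    else:
        def model(L, kd, n):
            f = hill_bound(L, kd, n)
            return 1.0 - f if sign < 0 else f

        p0 = _hill_init(series.x, bound)
        bounds = ([np.finfo(float).tiny, 1e-3], [np.inf, 6.0])

    popt, pcov = scipy.optimize.curve_fit(
        model, series.x, y, p0=p0, bounds=bounds, maxfev=20000
    )
    se = np.sqrt(np.diag(pcov))
    resid = y - model(series.x, *popt)
    return HillFit(
        kd=float(popt[0]),
        n_h=float(popt[1]),
        kd_se=float(se[0]),
        n_h_se=float(se[1]),
        rss=float(np.sum(resid**2)),
        n_points=len(series.x),
    )


def fit_michaelis_menten(series: TitrationSeries, enzyme_conc: float | None = None) -> MMFit:
    """Least-squares Michaelis-Menten fit of rate vs substrate concentration.

    ``enzyme_conc`` (same units as needed to make V_max per-enzyme) converts
    V_max to k_cat; if omitted the rates are taken as already per-enzyme and
    k_cat = V_max. If no point reaches half-saturation coverage the fit is
    returned with a warning — its SEs will be wide.
    """
    if len(series.x) < 4:
        raise ValueError("need at least 4 substrate concentrations")
    y = series.y
    vmax0 = float(y.max()) or 1.0
    km0 = float(np.median(series.x[series.x > 0])) if np.any(series.x > 0) else 1.0
    popt, pcov = scipy.optimize.curve_fit(
        michaelis_menten, series.x, y, p0=(vmax0, km0),
        bounds=([np.finfo(float).tiny] * 2, [np.inf] * 2), maxfev=20000,
    )
    vmax, km = map(float, popt)
    se = np.sqrt(np.diag(pcov))
    if series.x.max() < 2.0 * km:
        warnings.warn(
            "substrate range does not saturate the enzyme (max S < 2 K_m); "
            "parameter standard errors will be wide",
            stacklevel=2,
        )
    kcat = vmax if enzyme_conc is None else vmax / enzyme_conc
    resid = y - michaelis_menten(series.x, vmax, km)
    return MMFit(
        vmax=vmax, km=km, vmax_se=float(se[0]), km_se=float(se[1]),
        kcat=kcat, rss=float(np.sum(resid**2)), n_points=len(series.x),
    )


@dataclass(frozen=True)
class CompetitionPoint:
    competitor: float
    percent_competition: float
    clipped: bool


def competition_normalize(series: TitrationSeries, reference_bound: float) -> list[CompetitionPoint]:
    """Percent competition relative to a no-competitor reference.

    percent = 100 (1 - bound / bound_reference), clipped to [0, 100]; points
    where noise pushes binding above the reference clip to 0% and are
    flagged.
    """
    if reference_bound <= 0:
        raise ValueError("reference binding must be positive")
    bound = series.bound_fraction()
    out = []
    for x, b in zip(series.x, bound):
        raw = 100.0 * (1.0 - b / reference_bound)
        clipped = not (0.0 <= raw <= 100.0)
        out.append(
            CompetitionPoint(
                competitor=float(x),
                percent_competition=float(np.clip(raw, 0.0, 100.0)),
                clipped=clipped,
            )
        )
    return out
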