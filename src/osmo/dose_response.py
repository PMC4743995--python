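"""Growth-rate estimation and sigmoidal salt dose-response fitting.

Maximum exponential growth rates are read off growth curves by sliding a
log-linear regression window; rates normalised to the unstressed control
are then fitted with a three-parameter Hill inhibition curve

    r(c) = top / (1 + (c / k)**h)

from which the concentrations inhibiting growth by 10, 25 and 50 percent
(IC10/IC25/IC50) follow in closed form. ``top`` absorbs normalisation
error and is bounded to [0.8, 1.2]; the bottom asymptote is fixed at 0
because rates are expressed relative to the unstressed control.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GrowthCurve",
    "max_growth_rate",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
    "inhibitory_concentration",
    "fit_linear_calibration",
]


@dataclass
class GrowthCurve:
    """One growth curve: optical density (or cell count) against time."""

    times: np.ndarray  # h
    values: np.ndarray  # OD600 or derived cell count, arbitrary units
    salt_conc: float = 0.0  # mM NaCl

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")


def max_growth_rate(
    curve: GrowthCurve, window: int = 8, detection_floor: float = 0.0
) -> float:
    """Maximum exponential growth rate (per h) from a growth curve.

    Fits a least-squares line to ln(value) against time in every run of
    ``window`` consecutive points above ``detection_floor`` and returns
    the largest slope. Negative maxima are clipped at 0 (no growth).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    mask = curve.values > detection_floor
    t, v = curve.times[mask], curve.values[mask]
    if len(t) < window:
        raise ValueError(
            f"need at least {window} points above the detection floor, got {len(t)}"
        )
    logv = np.log(v)
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(logv, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = np.einsum("ij,ij->i", tc, yc) / np.einsum("ij,ij->i", tc, tc)
    return float(max(slopes.max(), 0.0))


def _hill(c: np.ndarray, top: float, k: float, h: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, top, dtype=float)
    pos = c > 0
    out[pos] = top / (1.0 + (c[pos] / k) ** h)
    return out


def _hill_jac(c: np.ndarray, top: float, k: float, h: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    jac = np.zeros((len(c), 3))
    pos = c > 0
    u = (c[pos] / k) ** h
    denom = (1.0 + u) ** 2
    jac[:, 0] = 1.0
    jac[pos, 0] = 1.0 / (1.0 + u)
    jac[pos, 1] = top * u * h / (k * denom)
    jac[pos, 2] = -top * u * np.log(c[pos] / k) / denom
    return jac


@dataclass
class DoseResponseResults:
    """Fitted Hill inhibition curve with derived inhibitory concentrations."""

    top: float
    k: float  # concentration of half-maximal inhibition, mM
    hill_slope: float
    rss: float
    n_obs: int
    concentrations: np.ndarray
    relative_rates: np.ndarray
    determined: bool  # False when no inhibition is reached inside the tested range
    ic10: float = field(init=False)
    ic25: float = field(init=False)
    ic50: float = field(init=False)

    def __post_init__(self) -> None:
        self.ic10 = self.inhibitory_concentration(0.10)
        self.ic25 = self.inhibitory_concentration(0.25)
        self.ic50 = self.inhibitory_concentration(0.50)

    @property
    def params(self) -> dict[str, float]:
        return {"top": self.top, "ic50_param": self.k, "hill_slope": self.hill_slope}

    def predict(self, conc) -> np.ndarray:
        return _hill(np.asarray(conc, dtype=float), self.top, self.k, self.hill_slope)

    def inhibitory_concentration(self, fraction: float) -> float:
        return inhibitory_concentration(self, fraction)

    def summary(self) -> str:
        lines = [
            "Sigmoidal (Hill) growth-inhibition fit",
            "=" * 42,
            f"{'observations':<24}{self.n_obs:>18}",
            f"{'top (rel. rate)':<24}{self.top:>18.4f}",
            f"{'k = IC50 (mM)':<24}{self.k:>18.2f}",
            f"{'Hill slope':<24}{self.hill_slope:>18.3f}",
            f"{'residual SS':<24}{self.rss:>18.4g}",
            f"{'IC10 (mM)':<24}{self.ic10:>18.2f}",
            f"{'IC25 (mM)':<24}{self.ic25:>18.2f}",
            f"{'IC50 (mM)':<24}{self.ic50:>18.2f}",
            f"{'IC50 determined':<24}{str(self.determined):>18}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observed relative rates and the fitted inhibition curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, float(np.max(self.concentrations)) * 1.05, 200)
        ax.plot(self.concentrations, self.relative_rates, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="Hill fit")
        ax.axvline(self.ic50, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("NaCl (mM)")
        ax.set_ylabel("relative growth rate")
        ax.legend()
        return ax


class DoseResponseModel:
    """Hill inhibition model for growth rates against salt concentration.

    Parameters
    ----------
    concentrations : array of mM NaCl; must include an unstressed point
        (the minimum concentration) and >= 4 distinct values.
    relative_rates : rates normalised to the unstressed control, in [0, ~1.2].
    """

    N_STARTS_H = (0.8, 2.0, 4.0)

    def __init__(self, concentrations, relative_rates):
        conc = np.asarray(concentrations, dtype=float)
        rates = np.asarray(relative_rates, dtype=float)
        if conc.shape != rates.shape or conc.ndim != 1:
            raise ValueError("concentrations and rates must be 1-D and equal length")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(rates < 0) or np.any(rates > 1.5):
            raise ValueError("relative rates must lie in [0, ~1.2]")
        self.conc = conc
        self.rates = rates

    def _k_guess(self) -> float:
        """Concentration where the rate first falls through half-maximum."""
        order = np.argsort(self.conc)
        c, r = self.conc[order], self.rates[order]
        half = 0.5 * r[c == c.min()].mean()
        below = np.nonzero(r < half)[0]
        if len(below) == 0 or below[0] == 0:
            return float(np.sqrt(c[c > 0].min() * c.max()))
        i = below[0]
        c0, c1, r0, r1 = c[i - 1], c[i], r[i - 1], r[i]
        if r0 == r1 or c0 <= 0:
            return float(c1)
        return float(c0 + (r0 - half) / (r0 - r1) * (c1 - c0))

    def fit(self) -> DoseResponseResults:
        pos = self.conc[self.conc > 0]
        k_starts = np.unique([self._k_guess(), pos.min(), pos.max() * 2])
        bounds = ([0.8, 1e-9, 1e-3], [1.2, np.inf, np.inf])
        best = None
        for k0 in k_starts:
            for h0 in self.N_STARTS_H:
                try:
                    popt, _ = optimize.curve_fit(
                        _hill,
                        self.conc,
                        self.rates,
                        p0=[1.0, k0, h0],
                        bounds=bounds,
                        jac=_hill_jac,
                        maxfev=20000,
                    )
                except RuntimeError:
                    continue
                rss = float(np.sum((self.rates - _hill(self.conc, *popt)) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss)
            if best is not None and best[1] < 1e-9:
                break  # exact-model data: no further starts needed
        if best is None:
            raise RuntimeError(
                "dose-response fit failed to converge from any start "
                f"(n={len(self.conc)}, rate range "
                f"[{self.rates.min():.3g}, {self.rates.max():.3g}])"
            )
        (top, k, h), rss = best
        determined = bool(k <= self.conc.max())
        return DoseResponseResults(
            top=float(top),
            k=float(k),
            hill_slope=float(h),
            rss=rss,
            n_obs=len(self.conc),
            concentrations=self.conc,
            relative_rates=self.rates,
            determined=determined,
        )


def fit_dose_response(concentrations, relative_rates) -> DoseResponseResults:
    """Fit the Hill inhibition curve; functional wrapper around the model."""
    return DoseResponseModel(concentrations, relative_rates).fit()


def inhibitory_concentration(fit: DoseResponseResults, fraction: float) -> float:
    """Concentration at which the fitted rate drops by ``fraction`` of top.

    Solves r(c) = (1 - fraction) * top, giving
    c = k * (fraction / (1 - fraction)) ** (1 / h).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return float(fit.k * (fraction / (1.0 - fraction)) ** (1.0 / fit.hill_slope))


@dataclass
class OrganismICEstimate:
    """Per-replicate IC fits for one organism, summarised as mean +- SD."""

    ic10: float
    ic25: float
    ic50: float
    ic10_sd: float
    ic25_sd: float
    ic50_sd: float
    n_replicates: int
    fits: list[DoseResponseResults]


def estimate_ic_from_curves(
    curves: "list[GrowthCurve]",
    window: int | None = None,
    window_hours: float = 4.0,
) -> OrganismICEstimate:
    """IC10/IC25/IC50 for one organism from replicated growth curves.

    Curves sharing a salt concentration are treated as replicates in
    order of appearance. Each replicate series is fitted separately
    (rates normalised to its own unstressed curve) and the IC values are
    averaged across replicate fits, matching a mean +- SD report.

    When ``window`` is None the rate-regression window is sized to span
    ``window_hours`` of the exponential phase regardless of the sampling
    interval (never fewer than 8 points): short windows make the maximum
    over sliding windows noticeably upward-biased under multiplicative
    observation noise.
    """
    by_conc: dict[float, list[GrowthCurve]] = {}
    for c in curves:
        by_conc.setdefault(float(c.salt_conc), []).append(c)
    if window is None:
        dts = np.concatenate([np.diff(c.times) for c in curves[:1]])
        dt = float(np.median(dts)) if len(dts) else 1.0
        window = max(8, int(round(window_hours / dt)) + 1)
    concs = sorted(by_conc)
    if 0.0 not in by_conc:
        raise ValueError("an unstressed (0 mM) curve is required")
    n_rep = min(len(v) for v in by_conc.values())
    fits = []
    for r in range(n_rep):
        rates = np.array(
            [max_growth_rate(by_conc[c][r], window=window) for c in concs]
        )
        r0 = rates[concs.index(0.0)]
        if r0 <= 0:
            raise ValueError("unstressed growth rate is zero")
        rel = np.clip(rates / r0, 0.0, 1.2)
        fits.append(fit_dose_response(np.array(concs), rel))
    ics = np.array([[f.ic10, f.ic25, f.ic50] for f in fits])
    mean = ics.mean(axis=0)
    sd = ics.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(3)
    return OrganismICEstimate(
        ic10=float(mean[0]),
        ic25=float(mean[1]),
        ic50=float(mean[2]),
        ic10_sd=float(sd[0]),
        ic25_sd=float(sd[1]),
        ic50_sd=float(sd[2]),
        n_replicates=n_rep,
        fits=fits,
    )


def fit_linear_calibration(
    cell_numbers, signal, min_points: int = 3, r2_threshold: float = 0.999
):
    """Linear signal-to-cell-count calibration fitted in the unsaturated range.

    Fluorescence readouts saturate at high cell numbers; the calibration
    line is fitted to the longest low-count prefix (sorted by cell number)
    whose linear fit reaches ``r2_threshold``, and must have positive slope.
    Returns (slope, intercept, n_used).
    """
    x = np.asarray(cell_numbers, dtype=float)
    y = np.asarray(signal, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < min_points:
        raise ValueError("need at least min_points calibration points")
    best = None
    for n in range(len(x), min_points - 1, -1):
        xs, ys = x[:n], y[:n]
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * xs + intercept
        ss_res = np.sum((ys - pred) ** 2)
        ss_tot = np.sum((ys - ys.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if slope > 0 and r2 >= r2_threshold:
            best = (float(slope), float(intercept), n)
            break
    if best is None:
        raise ValueError("no unsaturated linear range with positive slope found")
    return best
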