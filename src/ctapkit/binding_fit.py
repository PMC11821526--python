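"""Fluorescence-polarization titration processing and one-site binding fits.

After baseline subtraction, each amide/acid peptide pair is normalized to
the maximum polarization signal across the pair (×100), so the stronger
binder saturates at 100%.  Binding curves are then fitted by least squares
over K_D alone, with maximal binding fixed at 100% and no nonspecific term:

    hyperbolic:  F(L) = 100 · L / (K_D + L)
    depletion:   F(L) = 100 · θ,   P·θ² − (K_D + L + P)·θ + L = 0

where L is total titrated-protein concentration and P the labeled-probe
concentration.  The depletion (tight-binding) quadratic is required when
K_D approaches P; fits returning K_D below 5×P carry an "approximate"
warning rather than being censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

MODELS = ("hyperbolic", "depletion")


@dataclass
class TitrationSeries:
    """One titration: ligand (titrated protein) concentrations in nM versus
    polarization signal, with probe concentration and baseline."""

    ligand_conc: np.ndarray
    signal: np.ndarray
    probe_conc: float = 5.0
    baseline: float = 0.0

    def __post_init__(self):
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_conc.shape != self.signal.shape:
            raise ValueError("ligand_conc and signal must have equal length")
        if np.any(self.ligand_conc < 0):
            raise ValueError("concentrations must be >= 0")
        order = np.argsort(self.ligand_conc)
        self.ligand_conc = self.ligand_conc[order]
        self.signal = self.signal[order]
        if np.any(np.diff(self.ligand_conc) == 0):
            raise ValueError("duplicate ligand concentrations")

    def baseline_subtracted(self) -> np.ndarray:
        return self.signal - self.baseline


@dataclass
class BindingFitResult:
    model: str
    kd: float
    rss: float
    converged: bool
    tight_binding_warning: bool = False
    name: str = ""

    def __post_init__(self):
        if self.converged and self.kd <= 0:
            raise ValueError("converged fit must have kd > 0")


def predict_curve(
    kd: float,
    model: str = "hyperbolic",
    probe_conc: float = 0.0,
    concentrations: Union[Sequence[float], np.ndarray] = (),
) -> np.ndarray:
    """Forward model on the percent scale (F_max = 100).

    The depletion quadratic is evaluated in the numerically stable form
    θ = 2L / (K_D + L + P + sqrt((K_D + L + P)² − 4·L·P)), which reduces to
    the hyperbola as P → 0.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    L = np.asarray(concentrations, dtype=float)
    if model == "hyperbolic" or probe_conc == 0.0:
        return 100.0 * L / (kd + L)
    P = float(probe_conc)
    s = kd + L + P
    disc = np.sqrt(np.maximum(s * s - 4.0 * L * P, 0.0))
    return 100.0 * 2.0 * L / (s + disc)


def normalize_pair(series_amide: TitrationSeries, series_acid: TitrationSeries):
    """Divide both baseline-subtracted series by the maximum signal across
    the pair and scale to percent; the pair maximum maps to exactly 100."""
    a = series_amide.baseline_subtracted()
    b = series_acid.baseline_subtracted()
    pair_max = max(a.max(), b.max())
    if pair_max <= 0:
        raise ValueError("non-positive pair maximum; check baselines")

    def scaled(series: TitrationSeries, values: np.ndarray) -> TitrationSeries:
        return TitrationSeries(
            ligand_conc=series.ligand_conc.copy(),
            signal=100.0 * values / pair_max,
            probe_conc=series.probe_conc,
            baseline=0.0,
        )

    return scaled(series_amide, a), scaled(series_acid, b)


def fit_binding(
    series: TitrationSeries,
    model: str = "hyperbolic",
    name: str = "",
) -> BindingFitResult:
    """Least-squares fit of K_D on pair-normalized percent-scale data.

    Multistart: the RSS is evaluated on a log-spaced K_D grid spanning
    [min positive conc / 100, max conc × 100], then refined around the best
    grid point with bounded scalar minimization.  Non-convergence is flagged
    on the result, not raised.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    L = series.ligand_conc
    y = series.baseline_subtracted()
    positive = L[L > 0]
    if positive.size == 0:
        raise ValueError("no positive ligand concentrations")
    if L.size < 4:
        raise ValueError("need at least 4 concentration points")

    probe = series.probe_conc if model == "depletion" else 0.0

    def rss(kd: float) -> float:
        resid = y - predict_curve(kd, model, probe, L)
        return float(resid @ resid)

    lo, hi = positive.min() / 100.0, L.max() * 100.0
    grid = np.geomspace(lo, hi, 80)
    values = [rss(k) for k in grid]
    i = int(np.argmin(values))
    lb = grid[max(i - 1, 0)]
    ub = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(rss, bounds=(lb, ub), method="bounded", options={"xatol": 1e-12})
    converged = bool(res.success)
    kd = float(res.x) if converged else float(grid[i])
    return BindingFitResult(
        model=model,
        kd=kd,
        rss=float(rss(kd)),
        converged=converged,
        tight_binding_warning=kd < 5.0 * series.probe_conc,
        name=name,
    )
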