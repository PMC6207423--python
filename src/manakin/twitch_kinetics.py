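"""Muscle twitch-kinetics analysis of stimulation-train recordings.

The wing muscle driving the roll-snap (the scapulohumeralis caudalis) is
stimulated with trains of 10 pulses at a fixed frequency; each inter-pulse
interval yields a *percent relaxation* — the measured force decay as a
percentage of the decay needed to return to the unstimulated baseline.
Analyses use the first eight pulses of a train:

* mean percent relaxation per frequency, fit with a four-parameter
  logistic (4PL) whose inflection is the half-relaxation frequency f50,
  an index of twitch speed;
* within-train "rapid fatigue" slopes (percent relaxation regressed on
  pulse number) per stimulation frequency;
* the slope-vs-frequency regression whose upper 95% confidence band
  crosses zero at f* — the fastest sustainable contraction rate;
* contraction/relaxation phase-duration trend tests, and a paired
  stability check on the repeated control-frequency train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import brentq, curve_fit

from .io_formats import DataTable, ValidationError

__all__ = [
    "StimulationTrain",
    "trains_from_table",
    "phase_table",
    "ForceTrace",
    "percent_relaxation_from_trace",
    "FitError",
    "FrequencyResponse",
    "four_pl",
    "frequency_response_4pl",
    "compare_frequency_response",
    "compare_half_relaxation",
    "FatigueSlope",
    "fatigue_slope",
    "compare_fatigue_slopes",
    "fatigue_comparison_table",
    "FatigueTrend",
    "fatigue_vs_frequency",
    "phase_duration_test",
    "stability_check",
    "N_ANALYSIS_PULSES",
    "FUSED_THRESHOLD",
]

#: pulses entering every analysis (first eight of the 10-pulse train)
N_ANALYSIS_PULSES = 8

#: mean percent relaxation below which a train is flagged as fused
FUSED_THRESHOLD = 10.0


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class StimulationTrain:
    """Per-pulse percent relaxation for one train (pulse index 1-based)."""

    species: str
    individual: str
    frequency_hz: float
    replicate: int
    percent_relaxation: np.ndarray
    shortening_ms: np.ndarray | None = None
    lengthening_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.percent_relaxation, dtype=float)
        if r.size < N_ANALYSIS_PULSES:
            raise ValidationError(
                f"train {self.species}/{self.individual} @ {self.frequency_hz} Hz: "
                f"needs >= {N_ANALYSIS_PULSES} pulses, got {r.size}"
            )
        if np.any(r < 0):
            raise ValidationError("percent relaxation must be non-negative")
        if self.frequency_hz <= 0:
            raise ValidationError("stimulation frequency must be positive")
        self.percent_relaxation = r

    @property
    def analysis_pulses(self) -> np.ndarray:
        return self.percent_relaxation[:N_ANALYSIS_PULSES]

    @property
    def mean_relaxation(self) -> float:
        return float(self.analysis_pulses.mean())


def trains_from_table(table: DataTable) -> list[StimulationTrain]:
    """Build trains from a per-pulse fatigue table (one row per pulse)."""
    out = []
    df = table.df.sort_values(["species", "individual", "frequency_hz",
                               "replicate", "pulse"])
    for (sp, ind, f, rep), g in df.groupby(
        ["species", "individual", "frequency_hz", "replicate"], sort=True
    ):
        kwargs = {}
        for col, name in (("shortening_ms", "shortening_ms"),
                          ("lengthening_ms", "lengthening_ms")):
            if col in g.columns:
                kwargs[name] = g[col].to_numpy(dtype=float)
        out.append(StimulationTrain(
            species=str(sp), individual=str(ind), frequency_hz=float(f),
            replicate=int(rep),
            percent_relaxation=g["percent_relaxation"].to_numpy(dtype=float),
            **kwargs,
        ))
    return out


def phase_table(table: DataTable) -> pd.DataFrame:
    """Long-form phase durations (one row per pulse) from a twitch table."""
    return table.df.copy()


@dataclass
class ForceTrace:
    """Uniformly sampled force trace with stimulus onsets (optional input)."""

    time_s: np.ndarray
    force: np.ndarray
    stim_times_s: np.ndarray
    species: str = ""
    individual: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("trace must be uniformly sampled in time")
        s = np.asarray(self.stim_times_s, dtype=float)
        if s.size < 2:
            raise ValidationError("need at least 2 stimulus onsets")
        if np.any(np.diff(s) <= 0):
            raise ValidationError("stimulus onsets must be strictly increasing")
        self.time_s, self.force, self.stim_times_s = t, np.asarray(self.force, float), s


def percent_relaxation_from_trace(trace: ForceTrace) -> StimulationTrain:
    """Per-pulse percent relaxation from a raw force trace.

    The baseline is the mean force before the first stimulus.  For pulse k
    the window runs from its onset to the next onset (the last pulse gets
    one inter-pulse period); within the window,
    R_k = 100 * (peak - trough) / (peak - baseline), with the trough taken
    after the peak.
    """
    t, f, onsets = trace.time_s, trace.force, trace.stim_times_s
    pre = f[t < onsets[0]]
    if pre.size == 0:
        raise ValidationError("no pre-train samples to estimate the baseline")
    baseline = float(pre.mean())
    period = float(np.median(np.diff(onsets)))
    edges = np.append(onsets, onsets[-1] + period)
    rel = []
    for k in range(len(onsets)):
        win = (t >= edges[k]) & (t < edges[k + 1])
        if win.sum() < 3:
            raise ValidationError(f"pulse {k + 1}: too few samples in window")
        seg = f[win]
        ipk = int(np.argmax(seg))
        peak = float(seg[ipk])
        if peak <= baseline:
            raise ValidationError(f"pulse {k + 1}: no contraction above baseline")
        trough = float(seg[ipk:].min())
        rel.append(100.0 * (peak - trough) / (peak - baseline))
    freq = 1.0 / period
    return StimulationTrain(
        species=trace.species, individual=trace.individual,
        frequency_hz=freq, replicate=trace.replicate,
        percent_relaxation=np.asarray(rel),
    )


# ---------------------------------------------------------------------------
# Frequency response (4PL)
# ---------------------------------------------------------------------------


def four_pl(f, a, d, b, c):
    """Reverse-sigmoid logistic: R(f) = d + (a - d) / (1 + exp(b (f - c)))."""
    return d + (a - d) / (1.0 + np.exp(np.clip(b * (f - c), -500, 500)))


@dataclass
class FrequencyResponse:
    """Species-level 4PL fit of mean percent relaxation vs frequency."""

    species: str
    individual_means: pd.DataFrame       # individual, frequency_hz, mean_relaxation
    params: np.ndarray                   # (a, d, b, c)
    cov: np.ndarray
    sse: float
    n: int
    monotone: bool
    f50_extrapolated: bool
    axis: str = "linear"

    @property
    def f50(self) -> float:
        """Half-relaxation frequency (the inflection parameter c)."""
        return float(self.params[3])

    @property
    def f50_se(self) -> float:
        return float(np.sqrt(self.cov[3, 3]))

    @property
    def df_resid(self) -> int:
        return self.n - 4

    def predict(self, f: np.ndarray) -> np.ndarray:
        x = np.log(f) if self.axis == "log" else np.asarray(f, float)
        return four_pl(x, *self.params)


def _individual_means(trains: Sequence[StimulationTrain]) -> pd.DataFrame:
    rows = [
        dict(species=tr.species, individual=tr.individual,
             frequency_hz=tr.frequency_hz, mean_relaxation=tr.mean_relaxation)
        for tr in trains
    ]
    df = pd.DataFrame(rows)
    # technical replicates averaged first
    return (
        df.groupby(["species", "individual", "frequency_hz"], sort=True)
        ["mean_relaxation"].mean().reset_index()
    )


def _fit_4pl(x: np.ndarray, y: np.ndarray):
    """Multi-start 4PL least squares; returns (params, cov, sse)."""
    a0, d0 = float(y.max()), float(y.min())
    span = max(a0 - d0, 1e-6)
    best = None
    cs = np.quantile(x, [0.25, 0.5, 0.75])
    for b0 in (0.05, 0.1, 0.3, 1.0):
        for c0 in cs:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        four_pl, x, y, p0=[a0, d0, b0, c0], maxfev=20000,
                    )
                sse = float(np.sum((y - four_pl(x, *popt)) ** 2))
                if np.any(~np.isfinite(popt)):
                    continue
                if best is None or sse < best[2] - 1e-12:
                    best = (popt, pcov, sse)
            except (RuntimeError, ValueError):
                continue
    if best is None:
        raise FitError(
            "4PL fit did not converge from any start "
            f"(n={len(y)}, y-range {y.min():.3g}-{y.max():.3g})"
        )
    return best


def frequency_response_4pl(
    trains: Sequence[StimulationTrain], axis: str = "linear"
) -> FrequencyResponse:
    """Fit the species 4PL frequency response.

    Technical replicates are averaged per individual and frequency before
    fitting.  ``axis="log"`` fits on log frequency instead of linear.
    Fitted-curve monotonicity over the data range and whether f50 falls
    inside it are checked and flagged, not enforced.
    """
    if axis not in ("linear", "log"):
        raise ValidationError("axis must be 'linear' or 'log'")
    means = _individual_means(trains)
    species = means["species"].unique()
    if len(species) != 1:
        raise ValidationError("frequency_response_4pl expects a single species")
    freqs = means["frequency_hz"].to_numpy(dtype=float)
    if len(np.unique(freqs)) < 4:
        raise ValidationError("need >= 4 distinct stimulation frequencies")
    x = np.log(freqs) if axis == "log" else freqs
    y = means["mean_relaxation"].to_numpy(dtype=float)
    popt, pcov, sse = _fit_4pl(x, y)
    grid = np.linspace(x.min(), x.max(), 200)
    pred = four_pl(grid, *popt)
    monotone = bool(np.all(np.diff(pred) <= 1e-9))
    c = popt[3]
    extrapolated = not (x.min() <= c <= x.max())
    if extrapolated:
        warnings.warn(
            f"{species[0]}: half-relaxation frequency {c:.1f} lies outside the "
            "measured frequency range (extrapolated)", stacklevel=2,
        )
    f50_val = float(np.exp(c)) if axis == "log" else float(c)
    fr = FrequencyResponse(
        species=str(species[0]), individual_means=means,
        params=popt, cov=pcov, sse=sse, n=len(y),
        monotone=monotone, f50_extrapolated=extrapolated, axis=axis,
    )
    return fr


def compare_frequency_response(
    trains_a: Sequence[StimulationTrain],
    trains_b: Sequence[StimulationTrain],
    axis: str = "linear",
) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F test: one shared 4PL vs per-species 4PLs.

    Pooled and separate fits share the residual df of the separate model:
    F = ((SSE_pooled - SSE_separate)/q) / (SSE_separate/df2), q = 4,
    df2 = n_total - 8.
    """
    fa = frequency_response_4pl(trains_a, axis=axis)
    fb = frequency_response_4pl(trains_b, axis=axis)
    pooled_means = pd.concat([fa.individual_means, fb.individual_means])
    x = pooled_means["frequency_hz"].to_numpy(dtype=float)
    if axis == "log":
        x = np.log(x)
    y = pooled_means["mean_relaxation"].to_numpy(dtype=float)
    _, _, sse_pooled = _fit_4pl(x, y)
    sse_sep = fa.sse + fb.sse
    q = 4
    df2 = len(y) - 8
    if df2 < 1:
        raise ValidationError("too few observations for the model comparison")
    F = ((sse_pooled - sse_sep) / q) / (sse_sep / df2)
    return float(max(F, 0.0)), (q, df2), float(st.f.sf(max(F, 0.0), q, df2))


def compare_half_relaxation(
    fit_a: FrequencyResponse, fit_b: FrequencyResponse
) -> tuple[float, tuple[int, int], float]:
    """Wald F comparing the two half-relaxation frequencies.

    Uses the delta-method SEs of the inflection parameters with pooled
    residual df from the two fits.
    """
    var = fit_a.cov[3, 3] + fit_b.cov[3, 3]
    if not np.isfinite(var) or var <= 0:
        raise ValidationError("singular covariance for the inflection parameters")
    df2 = fit_a.df_resid + fit_b.df_resid
    F = float((fit_a.params[3] - fit_b.params[3]) ** 2 / var)
    return F, (1, df2), float(st.f.sf(F, 1, df2))


# ---------------------------------------------------------------------------
# Rapid-fatigue slopes
# ---------------------------------------------------------------------------


@dataclass
class FatigueSlope:
    """Within-train slope of percent relaxation on pulse number (1-8)."""

    species: str
    frequency_hz: float
    slope: float
    se: float
    F: float
    dfs: tuple[int, int]
    p: float
    pulse_means: np.ndarray
    mean_relaxation: float
    fused: bool
    n_trains: int


def _pulse_means(trains: Sequence[StimulationTrain]) -> np.ndarray:
    """Replicate means per pulse, then the mean across individuals."""
    by_ind: dict[str, list[np.ndarray]] = {}
    for tr in trains:
        by_ind.setdefault(tr.individual, []).append(tr.analysis_pulses)
    per_ind = np.stack([np.mean(np.stack(v), axis=0) for v in by_ind.values()])
    return per_ind.mean(axis=0)


def fatigue_slope(trains: Sequence[StimulationTrain]) -> FatigueSlope:
    """OLS slope of percent relaxation vs pulse number for one frequency.

    Technical replicates are averaged per pulse (within individual), then
    pulses are averaged across individuals, and the 8 pulse means are
    regressed on pulse index 1..8.  Trains whose overall mean relaxation
    is below 10% are flagged as fused (the muscle never unfuses, so a flat
    slope there is not evidence of endurance).
    """
    if not trains:
        raise ValidationError("no trains supplied")
    freqs = {tr.frequency_hz for tr in trains}
    species = {tr.species for tr in trains}
    if len(freqs) != 1 or len(species) != 1:
        raise ValidationError("fatigue_slope expects one species at one frequency")
    means = _pulse_means(trains)
    k = np.arange(1, N_ANALYSIS_PULSES + 1, dtype=float)
    res = st.linregress(k, means)
    dfs = (1, N_ANALYSIS_PULSES - 2)
    F = float(res.slope ** 2 / res.stderr ** 2) if res.stderr > 0 else 0.0
    p = float(st.f.sf(F, *dfs)) if res.stderr > 0 else 1.0
    overall = float(means.mean())
    return FatigueSlope(
        species=species.pop(), frequency_hz=freqs.pop(),
        slope=float(res.slope), se=float(res.stderr), F=F, dfs=dfs, p=p,
        pulse_means=means, mean_relaxation=overall,
        fused=overall < FUSED_THRESHOLD, n_trains=len(trains),
    )


def compare_fatigue_slopes(
    slopes_a: FatigueSlope, slopes_b: FatigueSlope
) -> tuple[float, tuple[int, int], float]:
    """F-test of slope equality between species at a shared frequency.

    Pooled pulse-level regression with a species-by-pulse interaction on
    the 2 x 8 pulse means: df = (1, 12).
    """
    if slopes_a.frequency_hz != slopes_b.frequency_hz:
        raise ValidationError("fatigue slopes measured at different frequencies")
    k = np.arange(1, N_ANALYSIS_PULSES + 1, dtype=float)
    y = np.concatenate([slopes_a.pulse_means, slopes_b.pulse_means])
    kk = np.concatenate([k, k])
    s = np.repeat([0.0, 1.0], N_ANALYSIS_PULSES)
    X = np.column_stack([np.ones_like(kk), kk, s, kk * s])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = len(y) - X.shape[1]
    mse = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(X.T @ X)
    var_int = mse * xtx_inv[3, 3]
    F = float(beta[3] ** 2 / var_int)
    return F, (1, df2), float(st.f.sf(F, 1, df2))


def fatigue_comparison_table(
    trains_a: Sequence[StimulationTrain],
    trains_b: Sequence[StimulationTrain],
) -> pd.DataFrame:
    """Per-frequency slope table for two species with BH-adjusted p.

    Slopes are reported for every frequency measured in each species; the
    species comparison is computed only at shared frequencies, and both
    the within-species and comparison p-values are FDR-adjusted across
    frequencies (within their own families).
    """
    from .display_divergence import benjamini_hochberg

    def by_freq(trains):
        d: dict[float, list[StimulationTrain]] = {}
        for tr in trains:
            d.setdefault(tr.frequency_hz, []).append(tr)
        return {f: fatigue_slope(v) for f, v in sorted(d.items())}

    sa, sb = by_freq(trains_a), by_freq(trains_b)
    freqs = sorted(set(sa) | set(sb))
    rows = []
    for f in freqs:
        row: dict = dict(frequency_hz=f)
        for tag, s in (("a", sa.get(f)), ("b", sb.get(f))):
            if s is not None:
                row.update({f"slope_{tag}": s.slope, f"se_{tag}": s.se,
                            f"F_{tag}": s.F, f"p_{tag}": s.p,
                            f"fused_{tag}": s.fused})
        if f in sa and f in sb:
            F, dfs, p = compare_fatigue_slopes(sa[f], sb[f])
            row.update(F_comparison=F, p_comparison=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ("p_a", "p_b", "p_comparison"):
        if col in out:
            mask = out[col].notna()
            adj = benjamini_hochberg(out.loc[mask, col])
            out.loc[mask, col + "_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# Rapid fatigue vs stimulation frequency
# ---------------------------------------------------------------------------


@dataclass
class FatigueTrend:
    """Regression of within-train slopes on stimulation frequency."""

    species: str
    frequencies: np.ndarray
    slopes: np.ndarray
    intercept: float
    gamma: float                 # change in fatigue slope per Hz
    se: float
    F: float
    dfs: tuple[int, int]
    p: float
    r2: float
    resid_sd: float
    fstar: float | None          # upper-95% band zero crossing (Hz)

    def band(self, f: np.ndarray, level: float = 0.95):
        """(lower, mean, upper) pointwise confidence band of the mean line."""
        f = np.asarray(f, dtype=float)
        n = len(self.frequencies)
        fbar = self.frequencies.mean()
        sxx = float(np.sum((self.frequencies - fbar) ** 2))
        pred = self.intercept + self.gamma * f
        tcrit = st.t.ppf(0.5 + level / 2, n - 2)
        half = tcrit * self.resid_sd * np.sqrt(1.0 / n + (f - fbar) ** 2 / sxx)
        return pred - half, pred, pred + half


def fatigue_vs_frequency(
    slopes: Mapping[float, float] | pd.DataFrame,
    species: str = "",
) -> FatigueTrend:
    """Fit rapid-fatigue slope as a function of stimulation frequency.

    OLS of the per-frequency within-train slopes on frequency; the band
    is the pointwise 95% CI of the regression line (not a prediction
    band).  f* is the smallest frequency at which the upper band reaches
    zero — the fastest contraction rate sustainable without an endurance
    cost — and is None when the band never crosses below zero.
    """
    if isinstance(slopes, pd.DataFrame):
        f = slopes["frequency_hz"].to_numpy(dtype=float)
        s = slopes["slope"].to_numpy(dtype=float)
    else:
        items = sorted(slopes.items())
        f = np.array([k for k, _ in items], dtype=float)
        s = np.array([v for _, v in items], dtype=float)
    if len(f) < 4:
        raise ValidationError("need slopes at >= 4 frequencies")
    res = st.linregress(f, s)
    n = len(f)
    resid = s - (res.intercept + res.slope * f)
    resid_sd = float(np.sqrt(resid @ resid / (n - 2)))
    F = float(res.slope ** 2 / res.stderr ** 2) if res.stderr > 0 else 0.0
    trend = FatigueTrend(
        species=species, frequencies=f, slopes=s,
        intercept=float(res.intercept), gamma=float(res.slope),
        se=float(res.stderr), F=F, dfs=(1, n - 2),
        p=float(st.f.sf(F, 1, n - 2)) if res.stderr > 0 else 1.0,
        r2=float(res.rvalue ** 2), resid_sd=resid_sd, fstar=None,
    )
    if resid_sd == 0 and res.slope == 0:
        return trend  # perfectly flat: no crossing
    grid = np.linspace(0.0, float(f.max()), 2000)
    upper = trend.band(grid)[2]
    sign = np.sign(upper)
    crossings = np.flatnonzero(np.diff(sign) < 0)
    if crossings.size:
        i = crossings[0]
        trend.fstar = float(
            brentq(lambda z: trend.band(np.array([z]))[2][0],
                   grid[i], grid[i + 1])
        )
    return trend


# ---------------------------------------------------------------------------
# Phase durations and stability
# ---------------------------------------------------------------------------


def phase_duration_test(
    phases: pd.DataFrame, frequency_hz: float | None = None
) -> pd.DataFrame:
    """Trend of contraction/relaxation phase durations over the train.

    For each species (and frequency, if several are present) and each
    phase (shortening/lengthening), replicate durations are averaged per
    pulse and the pulse means regressed on pulse number; returns slope,
    se, t and p per combination.  A flat result means contractile timing
    is stable even while percent relaxation declines.
    """
    needed = {"species", "pulse", "shortening_ms", "lengthening_ms"}
    missing = needed - set(phases.columns)
    if missing:
        raise ValidationError(f"phase table missing columns {sorted(missing)}")
    df = phases.copy()
    if frequency_hz is not None:
        df = df[np.isclose(df["frequency_hz"].astype(float), frequency_hz)]
        if df.empty:
            raise ValidationError(f"no phase data at {frequency_hz} Hz")
    rows = []
    group_cols = ["species"]
    if "frequency_hz" in df.columns:
        group_cols.append("frequency_hz")
    for key, g in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for phase in ("shortening_ms", "lengthening_ms"):
            means = g.groupby("pulse")[phase].mean()
            pulses = means.index.to_numpy(dtype=float)[:N_ANALYSIS_PULSES]
            vals = means.to_numpy(dtype=float)[:N_ANALYSIS_PULSES]
            if len(pulses) < 3:
                raise ValidationError("need >= 3 pulses for a phase trend")
            res = st.linregress(pulses, vals)
            if res.stderr > 0:
                t = res.slope / res.stderr
                p = 2 * st.t.sf(abs(t), len(pulses) - 2)
            else:
                t, p = 0.0, 1.0
            row = dict(zip(group_cols, key))
            row.update(phase=phase.replace("_ms", ""), slope=float(res.slope),
                       se=float(res.stderr), t=float(t), p=float(p))
            rows.append(row)
    return pd.DataFrame(rows)


def stability_check(
    first: Sequence[StimulationTrain], repeat: Sequence[StimulationTrain]
) -> tuple[float, float, int]:
    """Paired t-test of per-individual mean relaxation, first vs repeat.

    Guards against overall preparation run-down during a recording
    session (the control-frequency train is delivered twice).  Unpaired
    individuals are dropped with a warning.  Returns (t, p, n_pairs).
    """

    def per_ind(trains):
        d: dict[str, list[float]] = {}
        for tr in trains:
            d.setdefault(tr.individual, []).append(tr.mean_relaxation)
        return {k: float(np.mean(v)) for k, v in d.items()}

    a, b = per_ind(first), per_ind(repeat)
    shared = sorted(set(a) & set(b))
    dropped = (set(a) | set(b)) - set(shared)
    if dropped:
        warnings.warn(f"dropping unpaired individuals {sorted(dropped)}", stacklevel=2)
    if len(shared) < 2:
        raise ValidationError("need >= 2 paired individuals")
    xa = np.array([a[k] for k in shared])
    xb = np.array([b[k] for k in shared])
    if np.allclose(xa, xb):
        return 0.0, 1.0, len(shared)
    t, p = st.ttest_rel(xa, xb)
    return float(t), float(p), len(shared)
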