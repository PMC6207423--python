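"""Divergence and speed-endurance trade-offs in roll-snap displays.

The roll-snap is characterised by speed (snaps per second) and length
(total snaps).  This module (i) computes those metrics per display,
(ii) tests species divergence with linear mixed models (individual as a
random intercept) and FDR-corrected pairwise post-hocs, and (iii) scans
the individual-level speed-length distribution with weighted quantile
regression across tau = 0.1..0.9 to detect a negative upper bound — the
signature of a performance constraint — including an F-test for slope
equivalence between species at the top quantile.

Quantile fits minimise the weighted check loss
``sum_i w_i rho_tau(y_i - x_i'b)`` exactly via linear programming;
standard errors come from a seeded weighted pair bootstrap over
individuals (a fast iid-sparsity approximation is available for large
simulation studies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import linprog
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .io_formats import DataTable, ValidationError

__all__ = [
    "compute_display_metrics",
    "individual_summaries",
    "LMMResult",
    "lmm_species_test",
    "posthoc_fdr",
    "QuantileFit",
    "quantile_fit",
    "QuantileScanResult",
    "quantile_scan",
    "slope_equivalence_test",
    "threshold_contrast",
    "check_loss",
]


# ---------------------------------------------------------------------------
# Display metrics
# ---------------------------------------------------------------------------


def compute_display_metrics(
    raw: DataTable | pd.DataFrame | Mapping[tuple, Sequence[float]],
    speed_convention: str = "n",
) -> pd.DataFrame:
    """Per-display speed and length.

    ``raw`` is either an acoustics table with ``snaps`` and ``duration_s``
    columns (duration = time from first to last snap) or a mapping
    ``(species, individual, display) -> ordered snap times`` from which
    both are derived.  Speed is ``n / duration`` by convention; the
    fencepost alternative ``(n - 1) / duration`` is available via
    ``speed_convention="n_minus_1"``.
    """
    if speed_convention not in ("n", "n_minus_1"):
        raise ValidationError("speed_convention must be 'n' or 'n_minus_1'")
    if isinstance(raw, DataTable):
        df = raw.df.copy()
    elif isinstance(raw, pd.DataFrame):
        df = raw.copy()
    else:
        rows = []
        for key, times in raw.items():
            t = np.asarray(times, dtype=float)
            if t.size < 2:
                raise ValidationError(f"display {key}: needs >= 2 snap times")
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"display {key}: snap times not increasing")
            sp, ind, disp = key
            rows.append(
                dict(species=sp, individual=ind, display=disp,
                     snaps=t.size, duration_s=float(t[-1] - t[0]))
            )
        df = pd.DataFrame(rows)
    if "display" not in df.columns:
        df["display"] = df.groupby(["species", "individual"]).cumcount() + 1
    n = df["snaps"].to_numpy(dtype=float)
    dur = df["duration_s"].to_numpy(dtype=float)
    if np.any(n < 2):
        raise ValidationError("every display needs at least 2 snaps")
    if np.any(dur <= 0):
        raise ValidationError("display durations must be positive")
    numer = n if speed_convention == "n" else n - 1
    df["speed"] = numer / dur
    df["length"] = n
    return df


def individual_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean speed/length with the display count as weight."""
    g = records.groupby(["species", "individual"], sort=True)
    out = g.agg(
        mean_speed=("speed", "mean"),
        mean_length=("length", "mean"),
        w=("speed", "size"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """Wald F test from a random-intercept mixed model."""

    response: str
    term: str
    F: float
    df1: int
    df2: int
    p: float
    emmeans: pd.DataFrame          # species-level marginal means +/- SEM
    params: pd.Series
    cov: pd.DataFrame
    species: list[str]
    n_obs: int
    n_groups: int
    singular: bool
    fit: object = field(repr=False, default=None)


def _containment_df(n_obs: int, n_groups: int, k_between: int, k_within: int,
                    within: bool) -> int:
    """nlme-style containment denominator df.

    Terms constant within grouping units are tested against the number of
    units; terms varying within units against the residual level.
    """
    if within:
        return max(n_obs - n_groups - k_within, 1)
    return max(n_groups - k_between, 1)


def _wald_F(L: np.ndarray, beta: np.ndarray, cov: np.ndarray, df2: int):
    q = L.shape[0]
    Lb = L @ beta
    M = L @ cov @ L.T
    stat = float(Lb @ np.linalg.solve(M, Lb)) / q
    p = float(st.f.sf(stat, q, df2))
    return stat, q, p


def lmm_species_test(records: pd.DataFrame, response: str = "speed") -> LMMResult:
    """Species effect on a display metric, individual as random intercept.

    REML fit; the species term is tested with a Wald F whose denominator
    df follow the containment rule (species varies between individuals, so
    df2 = n_individuals - n_fixed_effects).  Estimated marginal means +/-
    SEM per species are returned for plotting.
    """
    if response not in records.columns:
        raise ValidationError(f"no column {response!r} in records")
    df = records.copy()
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValidationError("need at least 2 species")
    df["_grp"] = df["species"].astype(str) + "/" + df["individual"].astype(str)
    X = pd.get_dummies(df["species"], dtype=float).reindex(columns=species)
    X = X.drop(columns=species[0])
    X.insert(0, "Intercept", 1.0)
    y = df[response].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(), groups=df["_grp"].to_numpy())
        fit = model.fit(reml=True)
    k_fe = X.shape[1]
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    singular = bool(float(np.asarray(fit.cov_re)[0, 0]) < 1e-8 * max(np.var(y), 1e-12))
    if singular:
        warnings.warn("singular fit: random-intercept variance is ~0", stacklevel=2)
    n_groups = df["_grp"].nunique()
    df2 = _containment_df(len(df), n_groups, k_between=k_fe, k_within=0, within=False)
    L = np.zeros((len(species) - 1, k_fe))
    L[:, 1:] = np.eye(len(species) - 1)
    F, df1, p = _wald_F(L, beta, cov, df2)
    # marginal means: intercept + species offset
    rows = []
    for i, sp in enumerate(species):
        l = np.zeros(k_fe)
        l[0] = 1.0
        if i > 0:
            l[i] = 1.0
        rows.append(dict(species=sp, emmean=float(l @ beta),
                         sem=float(np.sqrt(l @ cov @ l))))
    return LMMResult(
        response=response, term="species", F=F, df1=df1, df2=df2, p=p,
        emmeans=pd.DataFrame(rows),
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        species=species, n_obs=len(df), n_groups=n_groups,
        singular=singular, fit=fit,
    )


def _letter_display(order: list[str], distinct: set[frozenset]) -> dict[str, str]:
    """Compact letter display: species sharing a letter do not differ."""
    groups: list[set[str]] = []
    for sp in order:
        placed = False
        for g in groups:
            if all(frozenset((sp, other)) not in distinct for other in g):
                g.add(sp)
                placed = True
        if not placed:
            groups.append({sp})
    # drop groups fully contained in another
    groups = [g for g in groups
              if not any(g < h for h in groups)]
    letters = {sp: "" for sp in order}
    for i, g in enumerate(groups):
        for sp in order:
            if sp in g:
                letters[sp] += chr(ord("a") + i)
    return letters


def posthoc_fdr(result: LMMResult, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise species contrasts with Benjamini-Hochberg adjusted p.

    z statistics use the fixed-effect covariance of the mixed model.  A
    letters column gives the usual compact grouping (species sharing a
    letter are not significantly different after FDR control).
    """
    species = result.species
    k = len(result.params)
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            l = np.zeros(k)
            if i > 0:
                l[i] = 1.0
            if j > 0:
                l[j] -= 1.0
            est = float(l @ result.params.to_numpy())
            se = float(np.sqrt(l @ result.cov.to_numpy() @ l))
            z = est / se
            rows.append(dict(a=species[i], b=species[j], estimate=est,
                             se=se, z=z, p=2 * st.norm.sf(abs(z))))
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) > 1 \
        else out["p"]
    distinct = {
        frozenset((r.a, r.b)) for r in out.itertuples() if r.p_adj < alpha
    }
    order = list(result.emmeans.sort_values("emmean", ascending=False)["species"])
    letters = _letter_display(order, distinct)
    out["letters"] = [f"{letters[r.a]}|{letters[r.b]}" for r in out.itertuples()]
    out.attrs["letters"] = letters
    return out


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below the raw p)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Weighted quantile regression
# ---------------------------------------------------------------------------


def check_loss(u: np.ndarray, tau: float, w: np.ndarray | None = None) -> float:
    """Weighted check (pinball) loss: sum_i w_i u_i (tau - 1{u_i < 0})."""
    u = np.asarray(u, dtype=float)
    w = np.ones_like(u) if w is None else np.asarray(w, dtype=float)
    return float(np.sum(w * u * (tau - (u < 0))))


def _qr_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float) -> np.ndarray:
    """Exact weighted quantile regression by LP (HiGHS).

    Decision variables: beta+ , beta- (p each), u+, u- (n each);
    minimise sum w (tau u+ + (1-tau) u-) s.t. X(beta+ - beta-) + u+ - u- = y.
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(2 * p), tau * w, (1 - tau) * w])
    A = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise ValidationError(f"quantile LP failed: {res.message}")
    z = res.x
    return z[:p] - z[p:2 * p]


@dataclass
class QuantileFit:
    """One weighted quantile-regression fit (speed on length)."""

    tau: float
    intercept: float
    slope: float
    se: float
    t: float
    p: float
    n: int
    loss: float
    coef: np.ndarray = field(repr=False, default=None)
    se_method: str = "bootstrap"


def _hall_sheather_h(tau: float, n: int) -> float:
    z = st.norm.ppf(tau)
    za = st.norm.ppf(0.975)
    h = n ** (-1 / 3) * za ** (2 / 3) * (
        1.5 * st.norm.pdf(z) ** 2 / (2 * z ** 2 + 1)
    ) ** (1 / 3)
    return min(max(h, 1e-3), min(tau, 1 - tau) * 0.9 + 1e-9)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def _qr_cov_iid(X, y, w, tau, beta) -> np.ndarray:
    """Fast asymptotic covariance under iid errors (sparsity by
    Hall-Sheather difference quotient on the weighted residual quantiles)."""
    n = len(y)
    r = y - X @ beta
    h = _hall_sheather_h(tau, n)
    s = (_weighted_quantile(r, w, min(tau + h, 1.0))
         - _weighted_quantile(r, w, max(tau - h, 0.0))) / (2 * h)
    s = max(s, 1e-8)
    XtWX = X.T @ (w[:, None] * X)
    return tau * (1 - tau) * s ** 2 * np.linalg.inv(XtWX) * np.sum(w) / n


def _qr_cov_bootstrap(X, y, w, tau, n_boot, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = len(y)
    betas = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            betas[b] = _qr_solve(X[idx], y[idx], w[idx], tau)
        except ValidationError:
            betas[b] = np.nan
    betas = betas[~np.isnan(betas).any(axis=1)]
    if len(betas) < 10:
        raise ValidationError("bootstrap produced too few valid refits")
    return np.cov(betas, rowvar=False)


def quantile_fit(
    summaries: pd.DataFrame,
    tau: float,
    n_boot: int = 2000,
    seed: int = 0,
    se_method: str = "bootstrap",
    x: str = "mean_length",
    y: str = "mean_speed",
    weight: str = "w",
) -> QuantileFit:
    """Weighted quantile regression of individual mean speed on mean length.

    Individuals are weighted by the number of displays measured.  The point
    estimate minimises the weighted check loss exactly (LP); SE/t/p come
    from a seeded weighted pair bootstrap over individuals (default
    B=2000), or from an iid-sparsity approximation (``se_method="iid"``).
    """
    if not 0 < tau < 1:
        raise ValidationError("tau must be inside (0, 1)")
    xs = summaries[x].to_numpy(dtype=float)
    ys = summaries[y].to_numpy(dtype=float)
    ws = summaries[weight].to_numpy(dtype=float) if weight in summaries \
        else np.ones_like(ys)
    if np.ptp(xs) == 0:
        raise ValidationError("predictor is constant: slope undefined")
    X = np.column_stack([np.ones_like(xs), xs])
    beta = _qr_solve(X, ys, ws, tau)
    if se_method == "bootstrap":
        cov = _qr_cov_bootstrap(X, ys, ws, tau, n_boot, seed)
    elif se_method == "iid":
        cov = _qr_cov_iid(X, ys, ws, tau, beta)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")
    se = float(np.sqrt(cov[1, 1]))
    tval = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    dof = max(len(ys) - 2, 1)
    return QuantileFit(
        tau=tau, intercept=float(beta[0]), slope=float(beta[1]),
        se=se, t=float(tval), p=float(2 * st.t.sf(abs(tval), dof)),
        n=len(ys), loss=check_loss(ys - X @ beta, tau, ws),
        coef=beta, se_method=se_method,
    )


@dataclass
class QuantileScanResult:
    """Per-tau constraint scan for one species."""

    species: str
    taus: np.ndarray
    table: pd.DataFrame          # tau, slope, se, t, p, p_adj, significant
    extent: float | None         # lowest tau of the contiguous run ending at max tau
    alpha: float
    fdr: bool


def quantile_scan(
    summaries: pd.DataFrame,
    taus: Sequence[float] | None = None,
    fdr: bool = True,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    se_method: str = "bootstrap",
    species: str | None = None,
) -> QuantileScanResult:
    """Scan quantiles for a negative speed-length upper bound.

    Default grid is tau = 0.1 .. 0.9 in steps of 0.1 (use step 0.01 for
    the fine scan).  p-values are BH-adjusted across the grid within the
    species.  The constraint extent is the smallest tau of the maximal
    contiguous run of significantly negative slopes that ends at the top
    of the grid; a single non-significant tau breaks the run.
    """
    taus = np.round(np.asarray(
        taus if taus is not None else np.arange(0.1, 0.91, 0.1)
    , dtype=float), 10)
    if taus.min() < 0.1 - 1e-9 or taus.max() > 0.9 + 1e-9:
        raise ValidationError("tau grid must stay within [0.1, 0.9]")
    if species is None:
        uniq = summaries["species"].unique() if "species" in summaries else ["?"]
        species = uniq[0] if len(uniq) == 1 else "pooled"
    fits = [
        quantile_fit(summaries, t, n_boot=n_boot, seed=seed + i,
                     se_method=se_method)
        for i, t in enumerate(taus)
    ]
    tab = pd.DataFrame(
        dict(tau=taus,
             slope=[f.slope for f in fits],
             se=[f.se for f in fits],
             t=[f.t for f in fits],
             p=[f.p for f in fits])
    )
    tab["p_adj"] = benjamini_hochberg(tab["p"]) if fdr else tab["p"]
    tab["significant"] = (tab["p_adj"] < alpha) & (tab["slope"] < 0)
    extent: float | None = None
    for row in tab.iloc[::-1].itertuples():
        if row.significant:
            extent = float(row.tau)
        else:
            break
    return QuantileScanResult(
        species=str(species), taus=taus, table=tab, extent=extent,
        alpha=alpha, fdr=fdr,
    )


def slope_equivalence_test(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    tau: float = 0.9,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[int, int], float]:
    """F-test for equality of the speed-length slopes of two species at tau.

    Fits the pooled quantile model with a species-by-length interaction and
    tests the interaction coefficient with a Wald F using the seeded
    bootstrap covariance (resampling individuals within species);
    df = (1, n_a + n_b - 4).
    """
    xa = summaries_a["mean_length"].to_numpy(dtype=float)
    xb = summaries_b["mean_length"].to_numpy(dtype=float)
    ya = summaries_a["mean_speed"].to_numpy(dtype=float)
    yb = summaries_b["mean_speed"].to_numpy(dtype=float)
    wa = summaries_a["w"].to_numpy(dtype=float)
    wb = summaries_b["w"].to_numpy(dtype=float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValidationError("degenerate fit: constant predictor in a species")
    na, nb = len(ya), len(yb)

    def design(xa_, xb_):
        x = np.concatenate([xa_, xb_])
        s = np.concatenate([np.zeros(len(xa_)), np.ones(len(xb_))])
        return np.column_stack([np.ones_like(x), x, s, x * s])

    X = design(xa, xb)
    y = np.concatenate([ya, yb])
    w = np.concatenate([wa, wb])
    beta = _qr_solve(X, y, w, tau)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 4))
    for b in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        Xb = design(xa[ia], xb[ib])
        yb_ = np.concatenate([ya[ia], yb[ib]])
        wb_ = np.concatenate([wa[ia], wb[ib]])
        try:
            draws[b] = _qr_solve(Xb, yb_, wb_, tau)
        except ValidationError:
            draws[b] = np.nan
    draws = draws[~np.isnan(draws).any(axis=1)]
    var_int = float(np.var(draws[:, 3], ddof=1))
    if var_int <= 0:
        raise ValidationError("degenerate bootstrap covariance")
    F = float(beta[3] ** 2 / var_int)
    dfs = (1, max(na + nb - 4, 1))
    p = float(st.f.sf(F, *dfs))
    return F, dfs, p


# ---------------------------------------------------------------------------
# Threshold contrast
# ---------------------------------------------------------------------------


def threshold_contrast(
    records: pd.DataFrame, cutoff: float = 60.0
) -> tuple[float, float, tuple[int, int], float]:
    """Effect of displaying at/above a speed cutoff on roll-snap length.

    Mixed model of length on the indicator 1{speed >= cutoff} with
    individual as random intercept; returns (beta, F, (df1, df2), p).
    """
    df = records.copy()
    ind = (df["speed"] >= cutoff).astype(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ValidationError(
            f"empty stratum: no displays {'at/above' if ind.sum() == 0 else 'below'} "
            f"{cutoff} snaps/s"
        )
    df["_grp"] = df["species"].astype(str) + "/" + df["individual"].astype(str)
    X = np.column_stack([np.ones(len(df)), ind.to_numpy()])
    y = df["length"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(y, X, groups=df["_grp"].to_numpy()).fit(reml=True)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:2, :2]
    n_groups = df["_grp"].nunique()
    df2 = _containment_df(len(df), n_groups, k_between=1, k_within=1, within=True)
    L = np.array([[0.0, 1.0]])
    F, df1, p = _wald_F(L, beta, cov, df2)
    return float(beta[1]), F, (df1, df2), p
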