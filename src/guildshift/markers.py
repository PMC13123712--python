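"""Microbe-immune association testing with two cross-validating arms.

Arm one regresses each genus's CLR abundance on an immune-cell density
with a small penalized spline (basis dimension 3: linear + curvature
term) whose smoothing parameter is chosen by restricted maximum
likelihood. A shrinkage penalty on the (otherwise unpenalized) linear
component lets the whole smooth be selected out of the model, so the
effective degrees of freedom run from ~0 (no relationship) through ~1
(linear) to at most 2 (curved). Arm two is the Monte-Carlo CLR Spearman
correlation (see :mod:`guildshift.diffabund`). Only associations
significant in both arms after FDR adjustment — and, by default, with
agreeing direction — are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import GuildshiftError
from .tables import CompositionTable

@dataclass
class SplineFit:
    """One penalized-spline regression of CLR abundance on a marker."""

    taxon: str
    marker: str
    edf: float
    adj_r2: float
    p: float
    trend_sign: int  # sign of fitted(end) - fitted(start); 0 when flat
    lam: tuple[float, float]  # REML smoothing parameters (curvature, null space)


def _design(x: np.ndarray) -> np.ndarray:
    """Two-column smooth basis: standardized x and orthogonal curvature."""
    xs = (x - x.mean()) / x.std()
    q = xs**2
    q -= q.mean()
    q -= (q @ xs) / (xs @ xs) * xs  # orthogonalize against the linear term
    nrm = np.linalg.norm(q)
    if nrm > 1e-10 * np.linalg.norm(xs):
        q = q / nrm * np.linalg.norm(xs)
    else:
        q = np.zeros_like(q)
    return np.column_stack([xs, q])


def spline_assoc(
    clr_values: pd.Series | np.ndarray,
    marker: pd.Series | np.ndarray,
    taxon: str = "",
    marker_name: str = "",
) -> SplineFit:
    """Penalized-spline regression of one taxon's CLR on one marker.

    Uses the double-penalty construction behind automatic smooth-term
    selection: the curvature direction and the smooth's null space (the
    linear direction) carry separate shrinkage penalties whose two
    smoothing parameters jointly minimize the restricted likelihood, so
    the whole smooth can be selected out of the model. edf is the trace
    of the smoother matrix. Significance is assessed by the exact F-test
    of the (unpenalized) 2-df smooth basis against the intercept-only
    model, which is exactly calibrated under Gaussian noise;
    penalization informs edf and adjusted R^2, not the test.
    """
    y = np.asarray(pd.Series(clr_values), dtype=float)
    x = np.asarray(pd.Series(marker), dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 10:
        raise GuildshiftError(f"need >= 10 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise GuildshiftError("marker is constant; fit undefined")
    yc = y - y.mean()
    b = _design(x)
    live = np.linalg.norm(b, axis=0) > 1e-10  # curvature column can degenerate
    b = b[:, live]
    g = np.einsum("ij,ij->j", b, b)  # columns are orthogonal by construction
    bt_y = b.T @ yc
    tss = float(yc @ yc)

    def fit(lam: np.ndarray):
        beta = bt_y / (g + lam)
        rss = tss - 2.0 * bt_y @ beta + (g * beta) @ beta
        edf = float(np.sum(g / (g + lam)))
        return beta, float(rss), edf

    def reml(log_lam: np.ndarray) -> float:
        lam = np.exp(np.clip(log_lam, -15.0, 25.0))
        beta, rss, _ = fit(lam)
        pen = float((lam * beta) @ beta)
        sigma2 = (rss + pen) / n
        return n * np.log(sigma2) + float(
            np.sum(np.log(g + lam)) - np.sum(np.log(lam))
        )

    res = optimize.minimize(
        reml, np.zeros(b.shape[1]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8},
    )
    lam = np.exp(np.clip(res.x, -15.0, 25.0))
    beta, rss, edf = fit(lam)
    adj_r2 = 1.0 - (rss / max(n - 1.0 - edf, 1e-8)) / (tss / (n - 1.0))
    # exact F-test on the unpenalized basis
    beta_un = bt_y / g
    rss_un = tss - float(bt_y @ beta_un)
    df_model = b.shape[1]
    f_stat = ((tss - rss_un) / df_model) / (rss_un / (n - 1 - df_model))
    p = float(stats.f.sf(f_stat, df_model, n - 1 - df_model))
    fitted_ends = _design_eval(b, x, beta)
    trend = fitted_ends[1] - fitted_ends[0]
    trend_sign = int(np.sign(trend)) if abs(trend) > 1e-10 else 0
    lam_full = [float("inf")] * 2
    for k, j in enumerate(np.flatnonzero(live)):
        lam_full[j] = float(lam[k])
    return SplineFit(
        taxon=taxon,
        marker=marker_name,
        edf=edf,
        adj_r2=float(adj_r2),
        p=p,
        trend_sign=trend_sign,
        lam=(lam_full[1], lam_full[0]),
    )


def _design_eval(b: np.ndarray, x: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    """Fitted smooth values at the smallest and largest marker value."""
    i0, i1 = int(np.argmin(x)), int(np.argmax(x))
    f = b @ beta
    return float(f[i0]), float(f[i1])


def prevalent_taxa(rel: CompositionTable, min_prevalence: float = 0.3) -> list[str]:
    """Taxa detected (proportion > 0) in at least ``min_prevalence`` of samples."""
    frac = (rel.data.to_numpy(dtype=float) > 0).mean(axis=0)
    return [t for t, f in zip(rel.data.columns, frac) if f >= min_prevalence]


def spline_arm(
    clr: pd.DataFrame, densities: pd.DataFrame
) -> pd.DataFrame:
    """Fit every (taxon, marker) spline on the shared samples.

    ``clr`` is samples x taxa (e.g. the mean over MC instances);
    ``densities`` is samples x markers. Returns one row per pair.
    """
    rows = []
    for marker in densities.columns:
        y = densities[marker]
        for taxon in clr.columns:
            f = spline_assoc(clr[taxon], y, taxon=taxon, marker_name=marker)
            rows.append(
                {
                    "taxon": taxon,
                    "marker": marker,
                    "edf": f.edf,
                    "adj_r2": f.adj_r2,
                    "p": f.p,
                    "trend_sign": f.trend_sign,
                }
            )
    return pd.DataFrame(rows)


def concordance(
    spline_fits: pd.DataFrame,
    corr_results: pd.DataFrame,
    q_threshold: float = 0.05,
    require_sign_agreement: bool = True,
) -> pd.DataFrame:
    """Associations significant in both arms (FDR-adjusted P <= threshold).

    The spline arm's raw p-values are BH-adjusted across the full
    taxon x marker grid; the correlation arm contributes its expected
    adjusted p (``q_expected``). A pair is reported iff both adjusted
    values pass and (by default) the fitted trend sign matches the sign
    of the expected correlation.
    """
    cols_s = {"taxon", "marker", "p", "trend_sign"}
    cols_c = {"taxon", "marker", "rho_expected", "q_expected"}
    if spline_fits.empty and corr_results.empty:
        return pd.DataFrame(
            columns=["taxon", "marker", "p_adj_spline", "q_corr", "rho_expected", "direction"]
        )
    if not cols_s.issubset(spline_fits.columns):
        raise GuildshiftError(f"spline arm missing columns {cols_s - set(spline_fits.columns)}")
    if not cols_c.issubset(corr_results.columns):
        raise GuildshiftError(f"correlation arm missing columns {cols_c - set(corr_results.columns)}")
    key = ["taxon", "marker"]
    s_keys = set(map(tuple, spline_fits[key].to_numpy()))
    c_keys = set(map(tuple, corr_results[key].to_numpy()))
    if s_keys != c_keys:
        raise GuildshiftError(
            f"arms computed on different grids; spline-only: "
            f"{sorted(s_keys - c_keys)}, corr-only: {sorted(c_keys - s_keys)}"
        )
    sf = spline_fits.copy()
    sf["p_adj_spline"] = multipletests(sf["p"].to_numpy(), method="fdr_bh")[1]
    merged = sf.merge(corr_results, on=key, validate="one_to_one")
    hit = (merged["p_adj_spline"] <= q_threshold) & (
        merged["q_expected"] <= q_threshold
    )
    if require_sign_agreement:
        hit &= merged["trend_sign"] * np.sign(merged["rho_expected"]) > 0
    out = merged[hit].copy()
    out["direction"] = np.sign(out["rho_expected"]).astype(int)
    out = out.rename(columns={"q_expected": "q_corr"})
    return out[
        ["taxon", "marker", "edf", "adj_r2", "p_adj_spline", "rho_expected", "q_corr", "direction"]
    ].reset_index(drop=True)
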