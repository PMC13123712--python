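"""Dirichlet Monte-Carlo CLR differential abundance and marker correlation.

Sampling error in compositional counts is propagated by drawing, for
every sample, many plausible proportion vectors from a Dirichlet
posterior (counts + a half-count prior), CLR-transforming each draw, and
carrying the whole collection of Monte-Carlo instances through the
tests. Per instance, a rank test is run per taxon and BH-adjusted across
taxa; the expected adjusted p is the mean over instances. The effect
size is the median, over pooled random pairings, of the between-group
CLR difference scaled by the larger within-group dispersion. A taxon is
called differentially abundant when |effect| > 0.5 and the expected
BH-adjusted p <= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GuildshiftError
from .tables import CountTable


@dataclass
class McClrInstances:
    """n_mc CLR matrices (samples x taxa) drawn from per-sample Dirichlets."""

    values: np.ndarray  # (n_mc, n_samples, n_taxa)
    sample_ids: list[str]
    taxon_ids: list[str]
    prior: float
    seed: int

    @property
    def n_mc(self) -> int:
        return self.values.shape[0]

    def mean_clr(self) -> pd.DataFrame:
        """Per-sample CLR averaged over instances (the plotted values)."""
        return pd.DataFrame(
            self.values.mean(axis=0), index=self.sample_ids, columns=self.taxon_ids
        )


def mc_clr_instances(
    counts: CountTable, n_mc: int = 128, prior: float = 0.5, seed: int = 0
) -> McClrInstances:
    """Draw Monte-Carlo Dirichlet CLR instances from a count table."""
    if n_mc < 16:
        raise GuildshiftError("n_mc < 16 gives unusably noisy expected p-values")
    mat = counts.data.to_numpy(dtype=float)
    if mat.size and (mat.sum(axis=1) <= 0).any():
        raise GuildshiftError("every sample needs a positive total count")
    rng = np.random.default_rng(seed)
    alpha = mat + prior
    # Dirichlet via normalized gammas, vectorized over instances and samples
    g = rng.standard_gamma(alpha[None, :, :], size=(n_mc, *alpha.shape))
    props = g / g.sum(axis=2, keepdims=True)
    logp = np.log(props)
    clr = logp - logp.mean(axis=2, keepdims=True)
    return McClrInstances(
        values=clr,
        sample_ids=list(counts.data.index),
        taxon_ids=list(counts.data.columns),
        prior=prior,
        seed=seed,
    )


def _rank_test_p(a: np.ndarray, b: np.ndarray, paired: bool) -> np.ndarray:
    """Two-sided rank-test p per taxon (columns)."""
    if paired:
        d = b - a
        # signed-rank is undefined for all-zero difference columns
        p = np.ones(d.shape[1])
        nz = np.ptp(d, axis=0) > 0
        if nz.any():
            res = stats.wilcoxon(d[:, nz], axis=0)
            p[nz] = np.atleast_1d(res.pvalue)
        return p
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    return np.atleast_1d(res.pvalue)


def aldex_da(
    instances: McClrInstances,
    groups: pd.Series,
    paired: bool = False,
    counts: CountTable | None = None,
    prevalence_detection: float = 0.01,
) -> pd.DataFrame:
    """Monte-Carlo CLR differential abundance between two groups.

    Positive effect = higher in the second group level (sorted label
    order unless the labels are a pandas Categorical). When ``counts``
    is supplied, per-group prevalence (> 1% proportion) and median
    proportions are reported alongside.
    """
    groups = pd.Series(groups).reindex(instances.sample_ids)
    if groups.isna().any():
        raise GuildshiftError("group labels missing for some samples")
    levels = (
        list(groups.cat.categories)
        if isinstance(groups.dtype, pd.CategoricalDtype)
        else sorted(pd.unique(groups))
    )
    if len(levels) != 2:
        raise GuildshiftError(f"need exactly two group levels, got {levels}")
    ia = np.flatnonzero((groups == levels[0]).to_numpy())
    ib = np.flatnonzero((groups == levels[1]).to_numpy())
    if min(len(ia), len(ib)) < 2:
        raise GuildshiftError("each group needs at least 2 samples")
    if paired and len(ia) != len(ib):
        raise GuildshiftError("paired analysis needs equal group sizes")
    vals = instances.values
    n_mc, _, n_taxa = vals.shape

    q_sum = np.zeros(n_taxa)
    for m in range(n_mc):
        p = _rank_test_p(vals[m][ia], vals[m][ib], paired)
        q_sum += multipletests(p, method="fdr_bh")[1]
    q_expected = q_sum / n_mc

    # effect size: random pairings per instance, pooled median of
    # between-group difference over the larger within-group dispersion
    rng = np.random.default_rng(instances.seed + 1)
    npair = min(len(ia), len(ib))
    btw, denom = [], []
    for m in range(n_mc):
        xa, xb = vals[m][ia], vals[m][ib]
        pa = rng.permutation(len(ia))[:npair]
        pb = rng.permutation(len(ib))[:npair]
        btw.append(xb[pb] - xa[pa])
        wa = xa[rng.permutation(len(ia))[:npair]] - xa[rng.permutation(len(ia))[:npair]]
        wb = xb[rng.permutation(len(ib))[:npair]] - xb[rng.permutation(len(ib))[:npair]]
        denom.append(np.maximum(np.abs(wa), np.abs(wb)))
    btw = np.concatenate(btw, axis=0)
    denom = np.concatenate(denom, axis=0)
    denom = np.where(denom == 0, np.nan, denom)
    with np.errstate(invalid="ignore"):
        effect = np.nanmedian(btw / denom, axis=0)
    effect = np.where(np.isnan(effect), 0.0, effect)
    # median of the same pooled between-group differences, unscaled:
    # shares the effect's sign since the dispersion denominator is > 0
    median_clr_diff = np.median(btw, axis=0)
    out = pd.DataFrame(
        {
            "effect": effect,
            "q_expected": q_expected,
            "median_clr_diff": median_clr_diff,
        },
        index=pd.Index(instances.taxon_ids, name="taxon"),
    )
    if counts is not None:
        rel = counts.data.div(counts.data.sum(axis=1), axis=0)
        rel_a = rel.iloc[ia]
        rel_b = rel.iloc[ib]
        out["prevalence_a"] = (rel_a > prevalence_detection).mean(axis=0)
        out["prevalence_b"] = (rel_b > prevalence_detection).mean(axis=0)
        out["median_prop_a"] = rel_a.median(axis=0)
        out["median_prop_b"] = rel_b.median(axis=0)
    out.attrs["levels"] = levels
    return out


def classify_da(
    results: pd.DataFrame, effect_min: float = 0.5, q_max: float = 0.001
) -> pd.DataFrame:
    """Label taxa increased/decreased/unchanged under the strict rule
    |effect| > effect_min AND q_expected <= q_max; sorted by effect."""
    out = results.copy()
    sig = (out["effect"].abs() > effect_min) & (out["q_expected"] <= q_max)
    out["classification"] = "unchanged"
    out.loc[sig & (out["effect"] > 0), "classification"] = "increased"
    out.loc[sig & (out["effect"] < 0), "classification"] = "decreased"
    return out.sort_values("effect", ascending=False, kind="stable")


def aldex_corr(instances: McClrInstances, marker: pd.Series) -> pd.DataFrame:
    """Expected Spearman correlation of each taxon's CLR with a marker.

    Per instance: Spearman rho and two-sided p (t approximation) per
    taxon against the marker, BH across taxa; means over instances are
    reported as (rho_expected, q_expected).
    """
    marker = pd.Series(marker).reindex(instances.sample_ids)
    if marker.isna().any():
        raise GuildshiftError("marker value missing for some samples")
    y = marker.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise GuildshiftError("marker is constant; correlation undefined")
    n = len(y)
    ry = stats.rankdata(y)
    ry = (ry - ry.mean()) / ry.std()
    vals = instances.values
    rho_sum = np.zeros(vals.shape[2])
    q_sum = np.zeros(vals.shape[2])
    for m in range(vals.shape[0]):
        rx = stats.rankdata(vals[m], axis=0)
        rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
        rho = rx.T @ ry / n
        rho = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.isnan(p), 0.0, p)  # |rho| == 1
        rho_sum += rho
        q_sum += multipletests(p, method="fdr_bh")[1]
    n_mc = vals.shape[0]
    return pd.DataFrame(
        {"rho_expected": rho_sum / n_mc, "q_expected": q_sum / n_mc},
        index=pd.Index(instances.taxon_ids, name="taxon"),
    )
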