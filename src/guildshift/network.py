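"""Co-occurrence networks, cross-cohort correlation shifts, and cohesion.

The community-structure contrast between cohorts is built from Spearman
correlation matrices of the most abundant genera: pairwise rho with BH
adjustment over the matrix's upper triangle, hierarchical clustering for
display order, the per-pair shift delta_rho = rho_A - rho_B between two
cohorts, and the cohesion/connectedness summaries. Connectedness of a
genus is the mean of its positive (resp. negative) correlations with
the other network genera; cohesion of a sample is the abundance-weighted
sum of those connectedness values — no null-model correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import GuildshiftError
from .tables import CompositionTable


@dataclass
class CorrelationNetwork:
    """Symmetric Spearman matrix with BH q-values over a fixed taxon set."""

    taxa: list[str]
    rho: pd.DataFrame
    q: pd.DataFrame
    cluster_order: list[str]
    n_excluded_pairs: int = 0  # zero-variance pairs left out of the BH family


@dataclass
class NetworkComparison:
    shared_taxa: list[str]
    delta_rho: pd.DataFrame
    median_abs_rho: dict
    wilcoxon_abs_rho: tuple[float, float]
    wilcoxon_delta: tuple[float, float]
    top_shifts: pd.DataFrame


@dataclass
class CohesionResult:
    connectedness_pos: pd.Series
    connectedness_neg: pd.Series
    cohesion_pos: pd.Series
    cohesion_neg: pd.Series


def top_taxa(rel: CompositionTable, n: int = 30) -> list[str]:
    """The n taxa with greatest mean relative abundance (ties: by name)."""
    if n > rel.data.shape[1]:
        raise GuildshiftError(
            f"requested top {n} taxa but table has only {rel.data.shape[1]}"
        )
    means = rel.data.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:n]


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def correlation_network(
    rel: CompositionTable | pd.DataFrame, taxa: list[str] | None = None
) -> CorrelationNetwork:
    """Pairwise Spearman network over the given taxa.

    Average ranks for ties; two-sided p per pair; BH adjustment over the
    upper triangle only. Pairs involving a zero-variance taxon get
    rho = NA and are excluded from the BH family (their count is
    reported). Display order comes from average-linkage clustering on
    1 - rho. Accepts a closed composition or, being rank-based, any
    samples x taxa abundance frame.
    """
    data = rel.data if isinstance(rel, CompositionTable) else rel
    if data.shape[0] < 4:
        raise GuildshiftError("correlation network needs at least 4 samples")
    if taxa is None:
        taxa = list(data.columns)
    x = data[list(taxa)].to_numpy(dtype=float)
    n = len(taxa)
    constant = x.std(axis=0) == 0
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    good = np.flatnonzero(~constant)
    if len(good) >= 2:
        res = stats.spearmanr(x[:, good])
        if len(good) == 2:  # spearmanr collapses 2-column input to a scalar
            r = float(np.asarray(res.statistic).reshape(-1)[0])
            p = float(np.asarray(res.pvalue).reshape(-1)[0])
            sub_r = np.array([[1.0, r], [r, 1.0]])
            sub_p = np.array([[0.0, p], [p, 0.0]])
        else:
            sub_r = np.asarray(res.statistic, dtype=float)
            sub_p = np.asarray(res.pvalue, dtype=float)
        rho[np.ix_(good, good)] = sub_r
        pval[np.ix_(good, good)] = sub_p
    np.fill_diagonal(rho, 1.0)
    iu = np.triu_indices(n, k=1)
    pvec = pval[iu]
    valid = ~np.isnan(rho[iu])
    qvec = np.full_like(pvec, np.nan)
    if valid.any():
        qvec[valid] = multipletests(pvec[valid], method="fdr_bh")[1]
    q = np.full((n, n), np.nan)
    q[iu] = qvec
    q.T[iu] = qvec
    np.fill_diagonal(q, 0.0)
    # display order: average linkage on 1 - rho (NA pairs treated as distance 1)
    d = 1.0 - np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if n > 2:
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        leaf_order = hierarchy.leaves_list(link)
    else:
        leaf_order = np.arange(n)
    taxa = list(taxa)
    return CorrelationNetwork(
        taxa=taxa,
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        q=pd.DataFrame(q, index=taxa, columns=taxa),
        cluster_order=[taxa[i] for i in leaf_order],
        n_excluded_pairs=int((~valid).sum()),
    )


def delta_rho(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> NetworkComparison:
    """Per-pair correlation shift delta_rho = rho_a - rho_b on shared taxa.

    |rho| distributions (upper triangles) are compared with a two-sided
    Wilcoxon rank-sum test; the delta_rho distribution is tested against
    zero with a signed-rank test. top_shifts ranks pairs by |delta_rho|.
    """
    shared = [t for t in net_a.taxa if t in set(net_b.taxa)]
    if len(shared) < 3:
        raise GuildshiftError(f"only {len(shared)} shared taxa; need at least 3")
    ra = net_a.rho.loc[shared, shared].to_numpy()
    rb = net_b.rho.loc[shared, shared].to_numpy()
    delta = ra - rb
    abs_a, abs_b = np.abs(_upper(ra)), np.abs(_upper(rb))
    abs_a, abs_b = abs_a[~np.isnan(abs_a)], abs_b[~np.isnan(abs_b)]
    w_abs = stats.mannwhitneyu(abs_a, abs_b, alternative="two-sided")
    dvec = _upper(delta)
    dvec_valid = dvec[~np.isnan(dvec)]
    if np.all(dvec_valid == 0):
        w_delta = (0.0, 1.0)
    else:
        res = stats.wilcoxon(dvec_valid)
        w_delta = (float(res.statistic), float(res.pvalue))
    iu = np.triu_indices(len(shared), k=1)
    pairs = pd.DataFrame(
        {
            "taxon_a": [shared[i] for i in iu[0]],
            "taxon_b": [shared[j] for j in iu[1]],
            "delta_rho": dvec,
        }
    ).sort_values("delta_rho", key=lambda s: -s.abs(), kind="stable")
    return NetworkComparison(
        shared_taxa=shared,
        delta_rho=pd.DataFrame(delta, index=shared, columns=shared),
        median_abs_rho={
            "a": float(np.median(abs_a)),
            "b": float(np.median(abs_b)),
        },
        wilcoxon_abs_rho=(float(w_abs.statistic), float(w_abs.pvalue)),
        wilcoxon_delta=w_delta,
        top_shifts=pairs.reset_index(drop=True),
    )


def connectedness(net: CorrelationNetwork) -> pd.DataFrame:
    """Per-taxon mean positive and mean negative off-diagonal correlation."""
    if len(net.taxa) < 2:
        raise GuildshiftError("connectedness needs at least 2 taxa")
    rho = net.rho.to_numpy().copy()
    np.fill_diagonal(rho, np.nan)
    pos = np.where(rho > 0, rho, np.nan)
    neg = np.where(rho < 0, rho, np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN rows (no positive/negative partners) fall back to 0 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        kpos = np.nanmean(pos, axis=1)
        kneg = np.nanmean(neg, axis=1)
    kpos = np.where(np.isnan(kpos), 0.0, kpos)
    kneg = np.where(np.isnan(kneg), 0.0, kneg)
    return pd.DataFrame(
        {"connectedness_pos": kpos, "connectedness_neg": kneg}, index=net.taxa
    )


def cohesion(rel: CompositionTable, kappa: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted cohesion per sample over the network's taxa.

    C_pos(i) = sum_j x_ij * kappa_pos(j) with x re-closed over the
    network taxa; samples with zero total abundance on those taxa get NA.
    """
    taxa = [t for t in kappa.index if t in rel.data.columns]
    x = rel.data[taxa].to_numpy(dtype=float)
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = x / totals[:, None]
    cpos = xc @ kappa.loc[taxa, "connectedness_pos"].to_numpy()
    cneg = xc @ kappa.loc[taxa, "connectedness_neg"].to_numpy()
    out = pd.DataFrame(
        {"cohesion_pos": cpos, "cohesion_neg": cneg}, index=rel.data.index
    )
    if (totals == 0).any():
        import warnings

        warnings.warn(
            f"{int((totals == 0).sum())} sample(s) have no abundance on the "
            "network taxa; cohesion reported as NA",
            stacklevel=2,
        )
    return out


def cohesion_result(rel: CompositionTable, net: CorrelationNetwork) -> CohesionResult:
    """Convenience: connectedness then cohesion for one cohort."""
    kappa = connectedness(net)
    coh = cohesion(rel, kappa)
    return CohesionResult(
        connectedness_pos=kappa["connectedness_pos"],
        connectedness_neg=kappa["connectedness_neg"],
        cohesion_pos=coh["cohesion_pos"],
        cohesion_neg=coh["cohesion_neg"],
    )


def compare_cohesion(res_a: CohesionResult, res_b: CohesionResult) -> pd.DataFrame:
    """Rank-sum comparison of the four cohesion/connectedness quantities."""
    rows = []
    for name in ("cohesion_pos", "cohesion_neg", "connectedness_pos", "connectedness_neg"):
        a = getattr(res_a, name).dropna().to_numpy(dtype=float)
        b = getattr(res_b, name).dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise GuildshiftError(f"empty group for {name}")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "quantity": name,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
            }
        )
    return pd.DataFrame(rows).set_index("quantity")
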