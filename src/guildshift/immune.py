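"""Immune-cell density comparisons and cohort demographic tests.

Densities (cells/mm^2) are compared between epidermis and dermis with
paired signed-rank tests and between elective and pathological-phimosis
groups with unpaired rank-sum tests; BH adjustment spans all markers and
compartments within one comparison family. Demographics use
Kruskal-Wallis for age and an r x c Fisher's exact test for ethnicity
(exact enumeration when the table is small; seeded Monte-Carlo over
fixed-margin tables, with a reported standard error, otherwise).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import GuildshiftError
from .tables import CellDensityTable

log = logging.getLogger(__name__)


def cell_density(count: int, area_mm2: float) -> float:
    """Cells per mm^2 of tissue."""
    if area_mm2 <= 0:
        raise GuildshiftError("tissue area must be positive")
    if count < 0:
        raise GuildshiftError("cell count must be nonnegative")
    return count / area_mm2


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_densities(
    table: CellDensityTable, metadata: pd.DataFrame, comparison: str
) -> pd.DataFrame:
    """Density comparisons per (marker, aspect[, layer]) with BH adjustment.

    comparison='epidermis_vs_dermis': paired signed-rank per (marker,
    aspect) over participants with both layers; participants missing a
    layer are excluded and logged. comparison='elective_vs_phimosis':
    unpaired rank-sum per (marker, aspect, layer) between indication
    groups, looked up per participant from the metadata's subject_id.
    """
    df = table.data
    rows = []
    if comparison == "epidermis_vs_dermis":
        wide = df.pivot_table(
            index=["participant_id", "aspect", "marker"],
            columns="layer",
            values="density",
        ).reset_index()
        if "epidermis" not in wide or "dermis" not in wide:
            raise GuildshiftError("both layers are required for the paired comparison")
        any_pairs = False
        for (aspect, marker), grp in wide.groupby(["aspect", "marker"]):
            complete = grp.dropna(subset=["epidermis", "dermis"])
            n_excl = len(grp) - len(complete)
            if n_excl:
                log.info(
                    "%d participant(s) missing a layer for %s/%s; excluded from "
                    "the paired test",
                    n_excl,
                    aspect,
                    marker,
                )
            if len(complete) < 2:
                continue
            any_pairs = True
            stat, p = _paired_wilcoxon(
                complete["epidermis"].to_numpy(), complete["dermis"].to_numpy()
            )
            rows.append(
                {
                    "marker": marker,
                    "aspect": aspect,
                    "layer": "epidermis_vs_dermis",
                    "statistic": stat,
                    "p": p,
                    "median_epidermis": float(complete["epidermis"].median()),
                    "median_dermis": float(complete["dermis"].median()),
                    "n": len(complete),
                }
            )
        if not any_pairs:
            raise GuildshiftError("no complete epidermis/dermis pairs")
    elif comparison == "elective_vs_phimosis":
        ind = (
            metadata.drop_duplicates("subject_id")
            .set_index("subject_id")["indication"]
        )
        df = df.assign(indication=df["participant_id"].map(ind))
        df = df[df["indication"].isin(["elective", "pathological_phimosis"])]
        for (aspect, layer, marker), grp in df.groupby(["aspect", "layer", "marker"]):
            a = grp.loc[grp["indication"] == "elective", "density"].to_numpy()
            b = grp.loc[
                grp["indication"] == "pathological_phimosis", "density"
            ].to_numpy()
            if min(len(a), len(b)) < 2:
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "marker": marker,
                    "aspect": aspect,
                    "layer": layer,
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "median_elective": float(np.median(a)),
                    "median_phimosis": float(np.median(b)),
                    "n": len(a) + len(b),
                }
            )
        if not rows:
            raise GuildshiftError("no testable marker/compartment groups")
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# --- r x c Fisher's exact test ------------------------------------------------

#: Above this bound on the number of candidate tables, fall back to
#: Monte-Carlo sampling of fixed-margin tables.
_ENUM_LIMIT = 5_000_000


def _table_bound(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    bound = 1.0
    for _ in rows[:-1]:
        for c in cols[:-1]:
            bound *= c + 1
    return bound


def _log_p_table(table: np.ndarray) -> float:
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_enum(table: np.ndarray) -> float:
    """Exact two-sided Fisher p by enumeration over fixed-margin tables.

    Depth-first fill of the (r-1) x (c-1) free cells with pruning on the
    remaining margins; sums the probabilities of all tables no more
    likely than the observed one (with a small tolerance on ties).
    """
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    r, c = len(rows), len(cols)
    n = table.sum()
    const = float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    log_obs = _log_p_table(table) + 1e-7  # tie tolerance at printed precision
    lf = gammaln(np.arange(n + 1) + 1.0)  # log factorial lookup
    total = 0.0

    def fill_row(i: int, j: int, colrem: np.ndarray, rowrem: int, acc: float):
        nonlocal total
        if i == r - 1:
            # last row is forced by the remaining column margins
            lp = const - acc - float(lf[colrem].sum())
            if lp <= log_obs:
                total += float(np.exp(lp))
            return
        if j == c - 1:
            # last cell of the row is forced by the row margin
            if rowrem > colrem[j]:
                return
            nxt = colrem.copy()
            nxt[j] -= rowrem
            fill_row(i + 1, 0, nxt, int(rows[i + 1]), acc + float(lf[rowrem]))
            return
        hi = min(rowrem, int(colrem[j]))
        lo = max(0, rowrem - int(colrem[j + 1 :].sum()))
        for v in range(lo, hi + 1):
            nxt = colrem.copy()
            nxt[j] -= v
            fill_row(i, j + 1, nxt, rowrem - v, acc + float(lf[v]))

    fill_row(0, 0, cols.copy(), int(rows[0]), 0.0)
    return min(total, 1.0)


def _fisher_mc(
    table: np.ndarray, n_draws: int, seed: int
) -> tuple[float, float]:
    """Seeded Monte-Carlo Fisher p over fixed-margin tables, with its SE."""
    rng = np.random.default_rng(seed)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    r, c = len(rows), len(cols)
    row_labels = np.repeat(np.arange(r), rows)
    col_labels = np.repeat(np.arange(c), cols)
    log_obs = _log_p_table(table) + 1e-7  # printed-precision tolerance
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(col_labels)
        t = np.zeros((r, c), dtype=np.int64)
        np.add.at(t, (row_labels, perm), 1)
        if _log_p_table(t) <= log_obs:
            hits += 1
    p = (hits + 1) / (n_draws + 1)
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return float(p), se


def fisher_exact_rxc(
    table, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float | None]:
    """Two-sided Fisher's exact test for an r x c contingency table.

    Uses exact enumeration over tables with fixed margins (summing the
    probabilities of tables no more likely than the observed one) when
    the candidate space is small, else seeded Monte-Carlo with at least
    ``n_mc`` sampled tables. Returns (p, mc_standard_error); the SE is
    None for the exact path.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.min() < 0:
        raise GuildshiftError("contingency table must be a nonnegative 2-D array")
    if _table_bound(t) <= _ENUM_LIMIT:
        return _fisher_enum(t), None
    if n_mc < 100_000:
        n_mc = 100_000
    return _fisher_mc(t, n_mc, seed)


def demographic_tests(
    metadata: pd.DataFrame,
    groups: pd.Series | str = "indication",
    seed: int = 0,
) -> dict:
    """Kruskal-Wallis on age and Fisher's exact on group x ethnicity.

    ``groups`` may name a metadata column or be an aligned label series.
    """
    meta = metadata.drop_duplicates("subject_id")
    labels = meta[groups] if isinstance(groups, str) else pd.Series(groups)
    levels = [g for g in pd.unique(labels) if pd.notna(g)]
    if len(levels) < 2:
        raise GuildshiftError("demographic tests need at least two groups")
    ages = [meta.loc[labels == g, "age_years"].dropna().to_numpy() for g in levels]
    kw = stats.kruskal(*ages)
    contingency = pd.crosstab(labels, meta["ethnicity"])
    p, se = fisher_exact_rxc(contingency.to_numpy(), seed=seed)
    return {
        "kw_age": (float(kw.statistic), float(kw.pvalue)),
        "fisher_ethnicity": (p, contingency),
        "fisher_mc_se": se,
    }
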