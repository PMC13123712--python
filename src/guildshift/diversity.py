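"""Alpha diversity, core-taxa determination, and gated group comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GuildshiftError
from .tables import CompositionTable, CountTable


def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Shannon diversity (nats), Pielou evenness, and richness per sample.

    H = -sum p ln p over observed taxa; J = H / ln(S). J is NA when only
    one taxon is observed.
    """
    depths = counts.data.sum(axis=1)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0][0]
        raise GuildshiftError(f"sample {bad!r} has zero total reads")
    rel = counts.data.div(depths, axis=0).to_numpy(dtype=float)
    out = []
    for i, sid in enumerate(counts.data.index):
        p = rel[i][rel[i] > 0]
        h = float(-(p * np.log(p)).sum())
        s = int(p.size)
        j = h / np.log(s) if s > 1 else np.nan
        out.append({"sample_id": sid, "shannon": h, "pielou": j, "richness": s})
    return pd.DataFrame(out).set_index("sample_id")


def core_taxa(
    rel: CompositionTable,
    detection: float = 0.01,
    prevalence: float = 0.5,
    detection_grid: list[float] | None = None,
) -> tuple[list[str], pd.DataFrame | None]:
    """Core members: proportion strictly above ``detection`` in at least
    a ``prevalence`` fraction of samples.

    Returns the core taxon list (ranked by prevalence at the detection
    threshold, then name) and, if a grid of detection thresholds is
    given, a taxa x thresholds frame of prevalence fractions.
    """
    if not (0 < detection < 1):
        raise GuildshiftError("detection must lie in (0, 1)")
    x = rel.data.to_numpy(dtype=float)
    frac = (x > detection).mean(axis=0)
    core = pd.Series(frac, index=rel.data.columns)
    members = core[core >= prevalence]
    ranked = members.sort_values(ascending=False, kind="stable")
    order = sorted(ranked.index, key=lambda t: (-ranked[t], t))
    grid = None
    if detection_grid is not None:
        grid = pd.DataFrame(
            {d: (x > d).mean(axis=0) for d in detection_grid},
            index=rel.data.columns,
        )
    return order, grid


@dataclass
class GroupComparison:
    """Result of a two-group location comparison."""

    test: str  # the test actually run after any normality gate
    statistic: float
    p: float
    medians: dict

    def __iter__(self):  # (statistic, p) unpacking convenience
        return iter((self.statistic, self.p))


def compare_alpha(
    values: pd.Series,
    groups: pd.Series,
    paired: bool = False,
    gate: str = "shapiro_then_t",
) -> GroupComparison:
    """Two-group comparison with an optional Shapiro-Wilk normality gate.

    gate='shapiro_then_t' runs Shapiro-Wilk per group (on differences
    when paired) at alpha = 0.05 and falls back to the rank test on
    rejection; 'wilcoxon' and 't' force one family. For paired data the
    group labels must split complete pairs aligned by index.
    """
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) != 2:
        raise GuildshiftError(f"need exactly two groups, got {levels}")
    a = values[groups == levels[0]].to_numpy(dtype=float)
    b = values[groups == levels[1]].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise GuildshiftError("each group needs at least two observations")
    medians = {levels[0]: float(np.median(a)), levels[1]: float(np.median(b))}
    if paired:
        if len(a) != len(b):
            raise GuildshiftError(
                f"paired comparison with unequal group sizes "
                f"({len(a)} vs {len(b)}); pairs are incomplete"
            )
        diffs = a - b
        normal = len(diffs) >= 3 and stats.shapiro(diffs).pvalue >= 0.05
        use_t = gate == "t" or (gate == "shapiro_then_t" and normal)
        if use_t:
            res = stats.ttest_rel(a, b)
            name = "paired t"
        elif np.all(diffs == 0):
            return GroupComparison("wilcoxon signed-rank", 0.0, 1.0, medians)
        else:
            res = stats.wilcoxon(a, b)
            name = "wilcoxon signed-rank"
    else:
        normal = (
            min(len(a), len(b)) >= 3
            and stats.shapiro(a).pvalue >= 0.05
            and stats.shapiro(b).pvalue >= 0.05
        )
        use_t = gate == "t" or (gate == "shapiro_then_t" and normal)
        if use_t:
            res = stats.ttest_ind(a, b)
            name = "t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "wilcoxon rank-sum"
    return GroupComparison(name, float(res.statistic), float(res.pvalue), medians)
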