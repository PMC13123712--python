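"""From raw feature table to analyzable genus tables.

Contaminant removal follows the two-evidence rule used for low-biomass
amplicon data: a frequency score (abundance inversely tracking sample
DNA concentration) and a prevalence score (enrichment in negative
controls). Only taxa flagged by *both* modes are removed, together with
off-target lineages (Eukaryota / Chloroplast / Mitochondria). Samples
below a read-depth floor are dropped before rare taxa are pruned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GuildshiftError, ValidationError
from .tables import RANKS, CompositionTable, CountTable

_EXCLUDED_LINEAGES = (
    ("kingdom", ("eukaryota",)),
    ("order", ("chloroplast", "chloroplasts")),
    ("family", ("mitochondria",)),
)


def _frequency_p(counts: CountTable, metadata: pd.DataFrame) -> pd.Series:
    """One-sided p favoring the contaminant model per taxon.

    For samples where the taxon is present, compares residual sums of
    squares of log(relative abundance) ~ log(1/dna_conc) with unit slope
    (contaminant) against an intercept-only fit (genuine taxon), scored
    on an F(n-1, n-1) scale. Small p = abundance tracks 1/concentration.
    """
    meta = metadata.set_index("sample_id")
    keep = meta.index[(~meta["is_negative_control"]) & meta["dna_conc"].notna()]
    keep = keep.intersection(counts.data.index)
    if len(keep) == 0:
        raise GuildshiftError(
            "frequency mode requires dna_conc on at least one true sample"
        )
    sub = counts.data.loc[keep]
    depths = sub.sum(axis=1)
    rel = sub.div(depths.replace(0, np.nan), axis=0)
    x_all = np.log(1.0 / meta.loc[keep, "dna_conc"].to_numpy(dtype=float))
    out = {}
    for taxon in sub.columns:
        mask = rel[taxon].to_numpy() > 0
        n = int(mask.sum())
        if n < 3:
            out[taxon] = np.nan
            continue
        y = np.log(rel[taxon].to_numpy()[mask])
        x = x_all[mask]
        rss_cont = np.sum((y - x - np.mean(y - x)) ** 2)
        rss_null = np.sum((y - y.mean()) ** 2)
        if rss_null <= 0:
            out[taxon] = 1.0 if rss_cont > 0 else np.nan
        else:
            out[taxon] = float(stats.f.cdf(rss_cont / rss_null, n - 1, n - 1))
    return pd.Series(out, name="freq_p")


def _prevalence_p(counts: CountTable, metadata: pd.DataFrame) -> pd.Series:
    """One-sided chi-squared p for higher presence in negative controls."""
    meta = metadata.set_index("sample_id")
    is_neg = meta.reindex(counts.data.index)["is_negative_control"].fillna(False)
    if not is_neg.any():
        raise GuildshiftError("prevalence mode requires at least one negative control")
    present = counts.data > 0
    neg, true = present[is_neg.to_numpy()], present[~is_neg.to_numpy()]
    n_neg, n_true = len(neg), len(true)
    out = {}
    for taxon in counts.data.columns:
        a, c = int(neg[taxon].sum()), int(true[taxon].sum())
        table = np.array([[a, n_neg - a], [c, n_true - c]], dtype=float)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            out[taxon] = 1.0
            continue
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        tail = stats.chi2.sf(chi2, 1) / 2.0
        prev_neg, prev_true = a / n_neg, c / n_true
        out[taxon] = float(tail if prev_neg > prev_true else 1.0 - tail)
    return pd.Series(out, name="prev_p")


def flag_contaminants(
    counts: CountTable,
    metadata: pd.DataFrame,
    mode: str,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Score every taxon under one contaminant-detection mode.

    Returns a frame indexed by taxon with columns ``p`` and ``flagged``
    (p < threshold; NaN scores are never flagged).
    """
    if mode == "frequency":
        p = _frequency_p(counts, metadata)
    elif mode == "prevalence":
        p = _prevalence_p(counts, metadata)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"p": p, "flagged": p < threshold})


def contaminant_flags(
    counts: CountTable, metadata: pd.DataFrame, threshold: float = 0.1
) -> pd.DataFrame:
    """Run both modes and combine into the both-modes removal flags."""
    freq = flag_contaminants(counts, metadata, "frequency", threshold)
    prev = flag_contaminants(counts, metadata, "prevalence", threshold)
    out = pd.DataFrame(
        {
            "freq_p": freq["p"],
            "prev_p": prev["p"],
            "flagged_freq": freq["flagged"],
            "flagged_prev": prev["flagged"],
        }
    )
    out["flagged_both"] = out["flagged_freq"] & out["flagged_prev"]
    return out


def remove_contaminants(counts: CountTable, flags: pd.DataFrame) -> CountTable:
    """Drop taxa flagged by both modes, plus off-target lineages.

    Eukaryota (kingdom), Chloroplast(s) (order), and Mitochondria
    (family) are removed whenever taxonomy is available, regardless of
    the statistical flags.
    """
    missing = counts.data.columns.difference(flags.index)
    if len(missing):
        raise ValidationError(f"flags missing for taxa: {missing.tolist()}")
    drop = set(flags.index[flags["flagged_both"].fillna(False)])
    if counts.taxonomy is not None:
        tax = counts.taxonomy
        for rank, names in _EXCLUDED_LINEAGES:
            vals = tax[rank].astype(str).str.lower()
            drop |= set(tax.index[vals.isin(names)])
    keep = [t for t in counts.data.columns if t not in drop]
    taxonomy = (
        counts.taxonomy.loc[keep] if counts.taxonomy is not None else None
    )
    return CountTable(counts.data[keep].copy(), taxonomy=taxonomy)


def prune(
    counts: CountTable, min_reads: int = 1000, min_max_prop: float = 0.01
) -> CountTable:
    """Drop shallow samples, then taxa that never reach a proportion floor.

    Samples with fewer than ``min_reads`` total reads are removed first;
    a taxon is retained only if its proportional abundance reaches
    ``min_max_prop`` in at least one retained sample.
    """
    depths = counts.data.sum(axis=1)
    kept = counts.data[depths >= min_reads]
    if kept.empty:
        raise GuildshiftError(
            f"all samples have fewer than {min_reads} reads; nothing to analyze"
        )
    rel = kept.div(kept.sum(axis=1), axis=0)
    keep_taxa = rel.columns[rel.max(axis=0) >= min_max_prop]
    taxonomy = (
        counts.taxonomy.loc[keep_taxa] if counts.taxonomy is not None else None
    )
    return CountTable(kept[list(keep_taxa)].copy(), taxonomy=taxonomy)


def agglomerate(counts: CountTable, rank: str = "genus") -> CountTable:
    """Sum counts over taxa sharing the lineage prefix down to ``rank``.

    Taxa unassigned at ``rank`` are pooled per nearest assigned parent
    as ``unclassified_<parent>``. Idempotent at a fixed rank.
    """
    if counts.taxonomy is None:
        raise GuildshiftError("agglomerate requires a taxonomy table")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    upto = RANKS[: RANKS.index(rank) + 1]
    tax = counts.taxonomy

    def label(taxon: str) -> tuple:
        lineage = [tax.loc[taxon, r] for r in upto]
        lineage = [None if (pd.isna(v) or v == "") else str(v) for v in lineage]
        if lineage[-1] is None:
            parents = [v for v in lineage[:-1] if v is not None]
            parent = parents[-1] if parents else "unknown"
            name = f"unclassified_{parent}"
            if name.startswith("unclassified_unclassified_"):
                name = name[len("unclassified_") :]
            lineage[-1] = name
        return tuple(lineage)

    lineages = {t: label(t) for t in counts.data.columns}
    groups: dict[tuple, list[str]] = {}
    for t, lin in lineages.items():
        groups.setdefault(lin, []).append(t)
    names, seen = {}, {}
    for lin in groups:
        base = lin[-1]
        if base in seen:  # same rank name under different parents
            parent = next((v for v in reversed(lin[:-1]) if v), "unknown")
            names[lin] = f"{base}_{parent}"
        else:
            names[lin] = base
            seen[base] = lin
    data = pd.DataFrame(index=counts.data.index)
    taxrows = {}
    for lin, members in groups.items():
        name = names[lin]
        data[name] = counts.data[members].sum(axis=1)
        row = dict.fromkeys(RANKS)
        row.update(dict(zip(upto, lin)))
        row[rank] = name
        taxrows[name] = row
    taxonomy = pd.DataFrame.from_dict(taxrows, orient="index").reindex(
        columns=list(RANKS)
    )
    return CountTable(data, taxonomy=taxonomy)


def relative_abundance(counts: CountTable) -> CompositionTable:
    """Close each sample's counts to proportions (rows sum to 1)."""
    depths = counts.data.sum(axis=1)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0][0]
        raise GuildshiftError(
            f"sample {bad!r} has zero total reads; prune before closing"
        )
    rel = counts.data.div(depths, axis=0)
    return CompositionTable(rel, totals=depths)
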