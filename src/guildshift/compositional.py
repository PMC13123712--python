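"""Compositional geometry: zero replacement, CLR, Aitchison ordination.

Count compositions live on the simplex, where ordinary Euclidean
statistics are invalid. Zeros are first replaced by a small fraction of
each sample's detection limit (count-zero multiplicative replacement),
compositions are mapped to unconstrained coordinates with the centered
log-ratio (CLR) transform, and ordination is a PCA of the centered CLR
matrix — equivalent to principal coordinates on Aitchison distances,
but with taxon loadings. Group separation in the plotted plane is
tested by permutation (factor fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GuildshiftError
from .tables import ClrTable, CompositionTable


@dataclass
class Ordination:
    """PCA scores/loadings of a CLR matrix plus optional group centroids."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # per-component fraction, nonincreasing
    loadings: pd.DataFrame  # taxa x components
    centroids: pd.DataFrame | None = None  # group -> (PC1, PC2)


def czm_replace(
    composition: CompositionTable, fraction: float = 0.65
) -> CompositionTable:
    """Multiplicative count-zero replacement.

    Each zero in sample i becomes delta_i = fraction / (N_i + 1), where
    N_i is the sample's total read count; nonzero parts are rescaled
    multiplicatively so the row still closes to 1.
    """
    if composition.totals is None:
        raise GuildshiftError(
            "czm_replace needs per-sample totals; build the composition "
            "with relative_abundance()"
        )
    x = composition.data.to_numpy(dtype=float).copy()
    totals = composition.totals.to_numpy(dtype=float)
    for i in range(x.shape[0]):
        row = x[i]
        zeros = row == 0
        if not zeros.any():
            continue
        if zeros.all():
            raise GuildshiftError(
                f"sample {composition.data.index[i]!r} is entirely zero"
            )
        delta = fraction / (totals[i] + 1.0)
        if delta >= row[~zeros].min():
            warnings.warn(
                f"replacement delta {delta:.3g} is not below the smallest "
                f"nonzero proportion in sample {composition.data.index[i]!r}",
                stacklevel=2,
            )
        replaced = delta * zeros.sum()
        row[~zeros] *= (1.0 - replaced) / row[~zeros].sum()
        row[zeros] = delta
    out = pd.DataFrame(
        x, index=composition.data.index, columns=composition.data.columns
    )
    return CompositionTable(out, totals=composition.totals)


def clr_transform(composition: CompositionTable) -> ClrTable:
    """Centered log-ratio: log part over the sample's geometric mean."""
    x = composition.data.to_numpy(dtype=float)
    if x.size and x.min() <= 0:
        raise GuildshiftError(
            "composition contains zeros; apply czm_replace before the CLR"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrTable(
        pd.DataFrame(clr, index=composition.data.index, columns=composition.data.columns)
    )


def aitchison_pca(clr: ClrTable, groups: pd.Series | None = None) -> Ordination:
    """PCA of the column-centered CLR matrix via singular values.

    Euclidean distances between full score rows equal the Aitchison
    distances between the samples. Centroids (PC1/PC2 means) are
    reported per group when labels are given.
    """
    if clr.data.shape[0] < 3:
        raise GuildshiftError("ordination needs at least 3 samples")
    x = clr.data.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    ncomp = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    scores = u * s
    var = s**2 / np.sum(s**2)
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    scores_df = pd.DataFrame(scores, index=clr.data.index, columns=comp_names)
    loadings_df = pd.DataFrame(vt.T, index=clr.data.columns, columns=comp_names)
    centroids = None
    if groups is not None:
        groups = pd.Series(groups).reindex(clr.data.index)
        centroids = scores_df.iloc[:, :2].groupby(groups).mean()
    return Ordination(scores_df, var, loadings_df, centroids)


def envfit_factor(
    ordination: Ordination,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation factor fit of group labels onto the first two components.

    r2 = 1 - SS_within / SS_total over the 2-D scores; the p-value is the
    seeded permutation tail (1 + #{perm r2 >= observed}) / (n_perm + 1).
    """
    scores = ordination.scores.iloc[:, :2].to_numpy(dtype=float)
    labels = pd.Series(labels).reindex(ordination.scores.index)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise GuildshiftError("factor fitting needs at least two groups")
    if np.bincount(codes).min() < 2:
        raise GuildshiftError("every group needs at least two members")

    def r2_of(code_vec: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(len(uniques)):
            pts = scores[code_vec == g]
            ss_within += np.sum((pts - pts.mean(axis=0)) ** 2)
        ss_total = np.sum((scores - scores.mean(axis=0)) ** 2)
        return 1.0 - ss_within / ss_total

    observed = r2_of(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r2_of(rng.permutation(codes)) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(observed), float(p)
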