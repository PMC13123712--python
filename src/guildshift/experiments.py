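"""Planted-structure recovery and null-calibration experiments.

Because the pipeline's headline numbers depend on cohort data, its
correctness is established on synthetic cohorts where the truth is
known: the generator plants guild structure, differential taxa,
microbe-marker links, and contaminants, and these experiments measure
how reliably each analysis stage recovers them, plus the null rejection
rates of every test family. Both the test suite and the acceptance
script run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compositional, diffabund, diversity, markers, network, preprocess, simulate
from .tables import ClrTable


def _timepoint_labels(counts, meta) -> pd.Series:
    tp = meta.set_index("sample_id")["timepoint"].reindex(counts.data.index)
    return pd.Series(
        pd.Categorical(tp, categories=["pre", "post"], ordered=True),
        index=counts.data.index,
    )


def _child_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    """n decorrelated 31-bit seeds for one experiment stream."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag]))
    return rng.integers(0, 2**31 - 1, size=n)


def guild_recovery(
    n_seeds: int = 10, n_samples: int = 60, top_n: int = 30, seed: int = 0
) -> dict:
    """Adult-like vs pediatric-like presets: network contrast per seed.

    Measures, per seed, the median |rho| of each cohort's top-N Spearman
    network and the rank-sum comparison of negative cohesion; counts
    seeds where the adult-like cohort has strictly higher median |rho|
    and significantly more negative cohesion.
    """
    rho_wins = coh_wins = 0
    med_adult, med_ped = [], []
    seeds_a = _child_seeds(seed, 1, n_seeds)
    seeds_p = _child_seeds(seed, 2, n_seeds)
    for k in range(n_seeds):
        cfg_a = simulate.preset("adult-like", n_samples=n_samples, seed=int(seeds_a[k]))
        cfg_p = simulate.preset(
            "pediatric-like", n_samples=n_samples, seed=int(seeds_p[k])
        )
        rels, nets, cohs = [], [], []
        for cfg in (cfg_a, cfg_p):
            counts, _, _ = simulate.simulate_cohort(cfg)
            rel = preprocess.relative_abundance(counts)
            net = network.correlation_network(rel, network.top_taxa(rel, n=top_n))
            rels.append(rel)
            nets.append(net)
            cohs.append(network.cohesion_result(rel, net))
        cmp_ = network.delta_rho(nets[0], nets[1])
        med_adult.append(cmp_.median_abs_rho["a"])
        med_ped.append(cmp_.median_abs_rho["b"])
        rho_wins += cmp_.median_abs_rho["a"] > cmp_.median_abs_rho["b"]
        tests = network.compare_cohesion(cohs[0], cohs[1])
        neg = tests.loc["cohesion_neg"]
        coh_wins += (neg["median_a"] < neg["median_b"]) and (neg["p"] < 0.05)
    return {
        "n_seeds": n_seeds,
        "rho_wins": int(rho_wins),
        "cohesion_wins": int(coh_wins),
        "median_abs_rho_adult": float(np.median(med_adult)),
        "median_abs_rho_pediatric": float(np.median(med_ped)),
    }


def da_recovery(
    n_seeds: int = 10,
    n_pairs: int = 40,
    n_mc: int = 128,
    shift: float = 2.0,
    taxon: str = "Ezakiella",
    seed: int = 0,
) -> dict:
    """Paired-shift recovery and null specificity of the MC-CLR test.

    Plants a +/-``shift`` latent log-abundance change on one taxon
    (sign alternating across seeds) in paired pre/post cohorts; counts
    seeds where that taxon is classified with the correct sign. Null
    seeds (no shift) count as clean when nothing is classified.
    """
    correct = null_clean = 0
    seeds_s = _child_seeds(seed, 3, n_seeds)
    seeds_0 = _child_seeds(seed, 4, n_seeds)
    for k in range(n_seeds):
        sgn = 1.0 if k % 2 == 0 else -1.0
        cfg = simulate.preset("pediatric-like", n_samples=n_pairs, seed=int(seeds_s[k]))
        cfg.post_shift = {taxon: sgn * shift}
        counts, meta, _ = simulate.simulate_circumcision_pair(cfg)
        inst = diffabund.mc_clr_instances(counts, n_mc=n_mc, seed=int(seeds_s[k]))
        res = diffabund.aldex_da(inst, _timepoint_labels(counts, meta))
        cls = diffabund.classify_da(res)
        want = "increased" if sgn > 0 else "decreased"
        correct += cls.loc[taxon, "classification"] == want
        cfg0 = simulate.preset(
            "pediatric-like", n_samples=n_pairs, seed=int(seeds_0[k])
        )
        counts0, meta0, _ = simulate.simulate_circumcision_pair(cfg0)
        inst0 = diffabund.mc_clr_instances(counts0, n_mc=n_mc, seed=int(seeds_0[k]))
        cls0 = diffabund.classify_da(
            diffabund.aldex_da(inst0, _timepoint_labels(counts0, meta0))
        )
        null_clean += (cls0["classification"] == "unchanged").all()
    return {
        "n_seeds": n_seeds,
        "correct_sign": int(correct),
        "null_clean": int(null_clean),
    }


def _density_grid(counts, meta, dens, aspect="inner", layer="dermis"):
    sub = dens.data[(dens.data["aspect"] == aspect) & (dens.data["layer"] == layer)]
    wide = sub.pivot(index="participant_id", columns="marker", values="density")
    subj = meta.set_index("sample_id")["subject_id"]
    wide = wide.loc[[subj[s] for s in counts.data.index]]
    return wide.set_axis(counts.data.index)


def _concordance_hits(counts, meta, dens, n_mc, seed):
    wide = _density_grid(counts, meta, dens)
    inst = diffabund.mc_clr_instances(counts, n_mc=n_mc, seed=seed)
    fits = markers.spline_arm(inst.mean_clr(), wide)
    corr = pd.concat(
        [
            diffabund.aldex_corr(inst, wide[m]).reset_index().assign(marker=m)
            for m in wide.columns
        ],
        ignore_index=True,
    )
    return markers.concordance(fits, corr)


def concordance_recovery(
    n_seeds: int = 10,
    n_samples: int = 50,
    strength: float = 0.8,
    n_mc: int = 128,
    taxon: str = "Mobiluncus",
    marker: str = "CD11c",
    seed: int = 0,
) -> dict:
    """Dual-arm association recovery: one planted negative link vs all-null.

    Counts seeds where the planted (taxon, marker) pair is the *sole*
    reported association, and null seeds where nothing is reported.
    """
    sole = null_clean = 0
    seeds_s = _child_seeds(seed, 5, n_seeds)
    seeds_0 = _child_seeds(seed, 6, n_seeds)
    for k in range(n_seeds):
        cfg = simulate.preset(
            "pediatric-like", n_samples=n_samples, seed=int(seeds_s[k])
        )
        cfg.marker_links = [(taxon, marker, strength, -1)]
        counts, meta, truth = simulate.simulate_cohort(cfg)
        dens = simulate.simulate_markers(counts, truth, cfg, metadata=meta)
        hits = _concordance_hits(counts, meta, dens, n_mc, int(seeds_s[k]))
        sole += (
            len(hits) == 1
            and hits.iloc[0]["taxon"] == taxon
            and hits.iloc[0]["marker"] == marker
            and hits.iloc[0]["direction"] == -1
        )
        cfg0 = simulate.preset(
            "pediatric-like", n_samples=n_samples, seed=int(seeds_0[k])
        )
        counts0, meta0, truth0 = simulate.simulate_cohort(cfg0)
        dens0 = simulate.simulate_markers(counts0, truth0, cfg0, metadata=meta0)
        null_clean += (
            len(_concordance_hits(counts0, meta0, dens0, n_mc, int(seeds_0[k]))) == 0
        )
    return {"n_seeds": n_seeds, "sole_hit": int(sole), "null_clean": int(null_clean)}


def null_calibration(n_reps: int = 200, seed: int = 0) -> dict:
    """Null rejection rates at alpha = 0.05 for every test family.

    envfit: random labels on a structureless cloud (n = 40, 199
    permutations). spline: pure-noise response (n = 50). rank test:
    Shapiro-gated two-group comparison of one normal sample (n = 15/15).
    FDR: fraction of replicates with any BH discovery among 45 Spearman
    pairs of independent normals (n = 30), plus the pooled q < 0.05
    fraction; this family runs at 2 x n_reps because the any-discovery
    indicator is a single Bernoulli per replicate and needs the extra
    replicates for a stable rate.
    """
    env_rej = spl_rej = rank_rej = fdr_any = 0
    fdr_pooled = []
    fdr_seeds = _child_seeds(seed, 7, 2 * n_reps)
    rep_seeds = _child_seeds(seed, 8, n_reps)
    for rep in range(2 * n_reps):
        rng = np.random.default_rng(int(fdr_seeds[rep]))
        frame = pd.DataFrame(rng.normal(size=(30, 10)))
        q = network.correlation_network(frame).q.to_numpy()[np.triu_indices(10, 1)]
        fdr_any += bool((q < 0.05).any())
        fdr_pooled.append(float((q < 0.05).mean()))
    for rep in range(n_reps):
        rng = np.random.default_rng(int(rep_seeds[rep]))
        # envfit
        x = rng.normal(size=(40, 6))
        x -= x.mean(axis=1, keepdims=True)
        clr = ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(40)]))
        ordn = compositional.aitchison_pca(clr)
        labels = pd.Series(
            rng.permutation(["a"] * 20 + ["b"] * 20), index=clr.data.index
        )
        _, p = compositional.envfit_factor(
            ordn, labels, n_perm=199, seed=int(rep_seeds[rep])
        )
        env_rej += p < 0.05
        # spline arm
        spl_rej += (
            markers.spline_assoc(rng.normal(size=50), rng.uniform(0, 1, 50)).p < 0.05
        )
        # gated two-group test
        res = diversity.compare_alpha(
            pd.Series(rng.normal(size=30)), pd.Series(["a"] * 15 + ["b"] * 15)
        )
        rank_rej += res.p < 0.05
    return {
        "n_reps": n_reps,
        "envfit": env_rej / n_reps,
        "spline": spl_rej / n_reps,
        "rank_test": rank_rej / n_reps,
        "fdr_any_discovery": fdr_any / (2 * n_reps),
        "fdr_pooled_fraction": float(np.mean(fdr_pooled)),
    }
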