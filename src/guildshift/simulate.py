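"""Synthetic cohorts with the statistical structure the analysis assumes.

The generative model is logistic-normal-multinomial: per sample a latent
log-abundance vector z ~ MVN(mu, Sigma), proportions = softmax(z), and
counts ~ Multinomial(depth, proportions) with a lognormal sequencing
depth. Sigma is assembled from "guild" blocks — positive covariance
within a block, negative covariance between blocks — which plants the
anti-correlated community structure seen in adult penile microbiota,
while a block-free Sigma yields the diffuse, weakly-correlated structure
typical of pediatric communities. The same machinery plants paired
pre/post-circumcision abundance shifts, monotone microbe -> immune-cell
density links on the CLR scale, an indication-group effect on chosen
markers, and contaminant spike-ins tied to per-sample DNA concentration,
each recorded in a ground-truth object for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compositional, preprocess
from .errors import GuildshiftError
from .tables import MARKERS, CellDensityTable, CountTable, validate_metadata

#: Genera common in penile microbiota, roughly by typical abundance.
DEFAULT_GENERA = (
    "Peptoniphilus", "Hoylesella", "Varibaculum", "Ezakiella",
    "Porphyromonas", "Finegoldia", "Corynebacterium", "Anaerococcus",
    "Prevotella", "Campylobacter", "Staphylococcus", "Mobiluncus",
    "Propionimicrobium", "Dialister", "Negativicoccus", "Fastidiosipila",
    "Arcanobacterium", "Actinotignum", "Lactobacillus", "Streptococcus",
    "Actinomyces", "Murdochiella", "Peptostreptococcus", "Fusobacterium",
    "Veillonella", "Gardnerella", "Fenollaria", "Micrococcus",
    "Cutibacterium", "Escherichia",
)

#: Baseline log-density (cells/mm^2) per layer and marker, at the scale
#: observed in foreskin tissue (macrophages dominate the dermis,
#: Langerhans cells the epidermis).
_BASE_DENSITY = {
    "dermis": {
        "CD68": 2700.0, "CD11c": 860.0, "CD3": 470.0, "CD4": 450.0,
        "CD56": 130.0, "CD207": 97.0, "CD117": 110.0, "tryptase": 100.0,
    },
    "epidermis": {
        "CD68": 150.0, "CD11c": 120.0, "CD3": 100.0, "CD4": 80.0,
        "CD56": 60.0, "CD207": 550.0, "CD117": 30.0, "tryptase": 30.0,
    },
}

_ETHNICITIES = ("caucasian", "middle_eastern", "asian", "african_american", "other")
_ETHNICITY_P = (0.75, 0.11, 0.09, 0.03, 0.02)
_INDICATIONS = ("elective", "non_elective", "pathological_phimosis")
_INDICATION_P = (0.31, 0.27, 0.42)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults emulate a pediatric-like cohort."""

    n_taxa: int = 30
    taxon_names: list[str] | None = None
    guild_blocks: list[list[str]] = field(default_factory=list)
    within_block_cov: float = 0.0
    between_block_cov: float = 0.0
    baseline_logmean: np.ndarray | None = None
    n_samples: int = 60
    depth_logmean: float = float(np.log(47_743))
    depth_logsd: float = 0.4
    post_shift: np.ndarray | dict | None = None
    marker_links: list[tuple] = field(default_factory=list)  # (taxon, marker, strength, sign)
    group_effect: dict = field(default_factory=dict)  # marker -> factor (phimosis)
    contaminant_taxa: list[str] = field(default_factory=list)
    seed: int = 0
    cohort: str = "pediatric"
    marker_noise_sd: float = 0.3
    link_compartment: tuple[str, str] = ("inner", "dermis")
    group_effect_layer: str = "dermis"
    n_negatives: int = 5
    contaminant_freq_coupled: bool = True

    def names(self) -> list[str]:
        if self.taxon_names is not None:
            if len(self.taxon_names) != self.n_taxa:
                raise GuildshiftError("taxon_names length must equal n_taxa")
            return list(self.taxon_names)
        if self.n_taxa <= len(DEFAULT_GENERA):
            return list(DEFAULT_GENERA[: self.n_taxa])
        extra = [f"Genus{i:03d}" for i in range(self.n_taxa - len(DEFAULT_GENERA))]
        return list(DEFAULT_GENERA) + extra

    def mean_vector(self) -> np.ndarray:
        if self.baseline_logmean is not None:
            mu = np.asarray(self.baseline_logmean, dtype=float)
            if mu.shape != (self.n_taxa,):
                raise GuildshiftError("baseline_logmean length must equal n_taxa")
            return mu
        # gently decaying abundance profile
        return np.linspace(1.5, -1.5, self.n_taxa)

    def shift_vector(self) -> np.ndarray:
        if self.post_shift is None:
            return np.zeros(self.n_taxa)
        if isinstance(self.post_shift, dict):
            names = self.names()
            vec = np.zeros(self.n_taxa)
            for taxon, val in self.post_shift.items():
                if taxon not in names:
                    raise GuildshiftError(f"post_shift names unknown taxon {taxon!r}")
                vec[names.index(taxon)] = val
            return vec
        vec = np.asarray(self.post_shift, dtype=float)
        if vec.shape != (self.n_taxa,):
            raise GuildshiftError("post_shift length must equal n_taxa")
        return vec


@dataclass
class GroundTruth:
    sigma: np.ndarray
    post_shift: np.ndarray
    marker_links: list[tuple]
    contaminant_taxa: list[str]
    group_effect: dict


def build_covariance(config: SimConfig) -> np.ndarray:
    """Assemble the block latent covariance and project to nearest PSD.

    Unit variances; ``within_block_cov`` inside a block,
    ``between_block_cov`` across distinct blocks, 0 elsewhere. Negative
    eigenvalues are clipped at 1e-10 (nearest-PSD projection).
    """
    names = config.names()
    idx = {t: i for i, t in enumerate(names)}
    block_of = np.full(config.n_taxa, -1)
    for b, members in enumerate(config.guild_blocks):
        for t in members:
            if t not in idx:
                raise GuildshiftError(f"guild block names unknown taxon {t!r}")
            block_of[idx[t]] = b
    sigma = np.eye(config.n_taxa)
    for i in range(config.n_taxa):
        for j in range(i + 1, config.n_taxa):
            if block_of[i] < 0 or block_of[j] < 0:
                continue
            cov = (
                config.within_block_cov
                if block_of[i] == block_of[j]
                else config.between_block_cov
            )
            sigma[i, j] = sigma[j, i] = cov
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < 1e-10:
        vals = np.clip(vals, 1e-10, None)
        sigma = vecs @ np.diag(vals) @ vecs.T
        sigma = (sigma + sigma.T) / 2
    vals = np.linalg.eigvalsh(sigma)
    if vals.min() < 0:
        raise GuildshiftError("covariance not PSD even after projection")
    return sigma


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _draw_depths(rng, n: int, config: SimConfig) -> np.ndarray:
    d = np.round(rng.lognormal(config.depth_logmean, config.depth_logsd, size=n))
    return np.maximum(d, 1).astype(np.int64)


def _metadata_frame(rng, sample_ids, subject_ids, timepoints, config) -> pd.DataFrame:
    n = len(sample_ids)
    uniq = list(dict.fromkeys(subject_ids))
    if config.cohort == "pediatric":
        ind = dict(zip(uniq, rng.choice(_INDICATIONS, size=len(uniq), p=_INDICATION_P)))
        age = dict(zip(uniq, np.round(rng.uniform(0.5, 17.5, size=len(uniq)), 1)))
    else:
        ind = dict.fromkeys(uniq, "none")
        age = dict(zip(uniq, np.round(rng.uniform(18.0, 60.0, size=len(uniq)), 1)))
    eth = dict(zip(uniq, rng.choice(_ETHNICITIES, size=len(uniq), p=_ETHNICITY_P)))
    dna = dict(zip(uniq, np.round(rng.lognormal(0.0, 0.7, size=len(uniq)), 4)))
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": config.cohort,
            "subject_id": subject_ids,
            "timepoint": timepoints,
            "indication": [ind[s] for s in subject_ids],
            "age_years": [age[s] for s in subject_ids],
            "ethnicity": [eth[s] for s in subject_ids],
            "dna_conc": [dna[s] for s in subject_ids],
            "is_negative_control": [False] * n,
        }
    )
    return validate_metadata(df)


def _taxonomy(names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": np.nan,
            "class": np.nan,
            "order": np.nan,
            "family": np.nan,
            "genus": names,
        },
        index=pd.Index(names, name="taxon_id"),
    )


def simulate_cohort(
    config: SimConfig,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """One cross-sectional cohort under the logistic-normal-multinomial model."""
    names = config.names()
    sigma = build_covariance(config)
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(
        sigma=sigma,
        post_shift=config.shift_vector(),
        marker_links=list(config.marker_links),
        contaminant_taxa=list(config.contaminant_taxa),
        group_effect=dict(config.group_effect),
    )
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    subject_ids = [f"P{i + 1:03d}" for i in range(n)]
    if n == 0:
        counts = CountTable(
            pd.DataFrame(np.zeros((0, config.n_taxa), dtype=np.int64), columns=names),
            taxonomy=_taxonomy(names),
        )
        meta = _metadata_frame(rng, [], [], [], config)
        return counts, meta, truth
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.n_taxa))
    z = config.mean_vector() + rng.standard_normal((n, config.n_taxa)) @ chol.T
    props = _softmax(z)
    depths = _draw_depths(rng, n, config)
    counts = np.vstack([rng.multinomial(depths[i], props[i]) for i in range(n)])
    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=names),
        taxonomy=_taxonomy(names),
    )
    meta = _metadata_frame(rng, sample_ids, subject_ids, ["none"] * n, config)
    return table, meta, truth


def simulate_circumcision_pair(
    config: SimConfig,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Paired pre/post samples: shared subject latent z, post gets z + shift.

    ``config.n_samples`` is the number of subjects (pairs).
    """
    names = config.names()
    sigma = build_covariance(config)
    shift = config.shift_vector()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(
        sigma=sigma,
        post_shift=shift,
        marker_links=list(config.marker_links),
        contaminant_taxa=list(config.contaminant_taxa),
        group_effect=dict(config.group_effect),
    )
    n = config.n_samples
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.n_taxa))
    z = config.mean_vector() + rng.standard_normal((n, config.n_taxa)) @ chol.T
    rows, sample_ids, subject_ids, timepoints = [], [], [], []
    for i in range(n):
        subj = f"P{i + 1:03d}"
        for tp, latent in (("pre", z[i]), ("post", z[i] + shift)):
            depth = _draw_depths(rng, 1, config)[0]
            rows.append(rng.multinomial(depth, _softmax(latent)))
            sample_ids.append(f"{subj}_{tp}")
            subject_ids.append(subj)
            timepoints.append(tp)
    table = CountTable(
        pd.DataFrame(np.vstack(rows) if rows else np.zeros((0, config.n_taxa), int),
                     index=sample_ids, columns=names),
        taxonomy=_taxonomy(names),
    )
    meta = _metadata_frame(rng, sample_ids, subject_ids, timepoints, config)
    return table, meta, truth


def simulate_markers(
    counts: CountTable,
    truth: GroundTruth,
    config: SimConfig,
    metadata: pd.DataFrame | None = None,
) -> CellDensityTable:
    """Immune-cell densities with planted log-linear links to CLR abundances.

    density = exp(log base + sum_links sign*strength*CLR(taxon) + noise)
    in the link compartment; the phimosis group effect multiplies the
    configured markers in the dermis when metadata with indications is
    given. One participant per sample row.
    """
    names = list(counts.data.columns)
    for taxon, marker, _, _ in truth.marker_links:
        if taxon not in names:
            raise GuildshiftError(f"marker link references unknown taxon {taxon!r}")
        if marker not in MARKERS:
            raise GuildshiftError(f"marker link references unknown marker {marker!r}")
    rel = preprocess.relative_abundance(counts)
    clr = compositional.clr_transform(compositional.czm_replace(rel)).data
    rng = np.random.default_rng(config.seed + 101)
    indication = {}
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        indication = meta["indication"].to_dict()
        subject = meta["subject_id"].to_dict()
    else:
        subject = {s: s for s in counts.data.index}
    link_aspect, link_layer = config.link_compartment
    records = []
    for sid in counts.data.index:
        pid = subject.get(sid, sid)
        phimosis = indication.get(sid) == "pathological_phimosis"
        for aspect in ("inner", "outer"):
            for layer in ("epidermis", "dermis"):
                for marker in MARKERS:
                    mu = np.log(_BASE_DENSITY[layer][marker])
                    if aspect == link_aspect and layer == link_layer:
                        for taxon, m, strength, sign in truth.marker_links:
                            if m == marker:
                                mu += sign * strength * clr.loc[sid, taxon]
                    noise = rng.normal(0.0, config.marker_noise_sd)
                    dens = float(np.exp(mu + noise))
                    if (
                        phimosis
                        and layer == config.group_effect_layer
                        and marker in truth.group_effect
                    ):
                        dens *= truth.group_effect[marker]
                    records.append(
                        {
                            "participant_id": pid,
                            "aspect": aspect,
                            "layer": layer,
                            "marker": marker,
                            "density": dens,
                        }
                    )
    return CellDensityTable(pd.DataFrame(records))


def spike_negatives(
    counts: CountTable,
    config: SimConfig,
    metadata: pd.DataFrame | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Append negative controls and tie contaminant reads to DNA concentration.

    Contaminant taxa (reagent organisms; appended as new columns when
    not already present) dominate the negative controls. Each true
    sample is contaminated with probability ~1/2 — so contaminants are
    *sporadic* in true samples but ubiquitous in negatives, the signal
    the prevalence mode keys on — and, when contaminated, receives a
    contaminant proportion proportional to 1/dna_conc (the frequency-
    mode signal; a constant proportion when ``contaminant_freq_coupled``
    is off). Returns the augmented table and metadata.
    """
    if config.n_negatives == 0:
        if metadata is None:
            raise GuildshiftError("metadata required when not generating it")
        return counts, metadata
    if not config.contaminant_taxa:
        raise GuildshiftError("contaminant_taxa must be nonempty")
    rng = np.random.default_rng(config.seed + 202)
    n = counts.data.shape[0]
    if metadata is None:
        meta = _metadata_frame(
            rng, list(counts.data.index), list(counts.data.index), ["none"] * n, config
        )
    else:
        meta = metadata.copy()
    data = counts.data.copy()
    taxonomy = counts.taxonomy
    new = [t for t in config.contaminant_taxa if t not in data.columns]
    for t in new:
        data[t] = 0
    if taxonomy is not None and new:
        taxonomy = pd.concat([taxonomy, _taxonomy(new)])
    names = list(data.columns)
    dna = rng.lognormal(0.0, 0.7, size=n)
    meta = meta.set_index("sample_id")
    meta.loc[counts.data.index, "dna_conc"] = np.round(dna, 4)
    # contaminant profile over the contaminant taxa
    k = len(config.contaminant_taxa)
    profile = rng.dirichlet(np.full(k, 5.0))
    depths = data.sum(axis=1).to_numpy()
    c0 = 0.02
    contaminated = rng.random(n) < 0.5
    for i, sid in enumerate(data.index):
        if not contaminated[i]:
            continue
        prop = c0 / dna[i] if config.contaminant_freq_coupled else c0
        prop = min(prop, 0.3)
        extra = int(round(depths[i] * prop / (1.0 - prop)))
        if extra > 0:
            add = rng.multinomial(extra, profile)
            data.loc[sid, config.contaminant_taxa] += add
    neg_rows, neg_ids = [], []
    background = np.full(len(names), 1.0 / len(names))
    for j in range(config.n_negatives):
        depth = max(1, int(round(rng.lognormal(np.log(2000.0), 0.4))))
        # negatives: nearly all reads on contaminants, a whiff of carry-over
        n_cont = rng.binomial(depth, 0.995)
        row = np.zeros(len(names), dtype=np.int64)
        cont_counts = rng.multinomial(n_cont, profile)
        for t, c in zip(config.contaminant_taxa, cont_counts):
            row[names.index(t)] += c
        if depth - n_cont > 0:
            row += rng.multinomial(depth - n_cont, background)
        neg_rows.append(row)
        neg_ids.append(f"NEG{j + 1:02d}")
    neg_df = pd.DataFrame(neg_rows, index=neg_ids, columns=names)
    out = CountTable(pd.concat([data, neg_df]), taxonomy=taxonomy)
    neg_meta = pd.DataFrame(
        {
            "sample_id": neg_ids,
            "cohort": config.cohort,
            "subject_id": neg_ids,
            "timepoint": "none",
            "indication": "none",
            "age_years": 0.0,
            "ethnicity": "other",
            "dna_conc": np.round(rng.lognormal(np.log(0.05), 0.3, config.n_negatives), 4),
            "is_negative_control": True,
        }
    )
    meta = pd.concat([meta.reset_index(), neg_meta], ignore_index=True)
    return out, validate_metadata(meta)


def preset(name: str, n_samples: int = 60, seed: int = 0, **overrides) -> SimConfig:
    """Named study-condition presets.

    'pediatric-like': no guild blocks (diffuse correlation structure),
    depth scale ~48k reads. 'adult-like': two anti-correlated guilds
    (within-block covariance 0.6, between -0.4) — a gram-positive skin
    guild and an anaerobe guild — at depth scale ~190k reads.
    """
    if name == "pediatric-like":
        cfg = SimConfig(n_samples=n_samples, seed=seed, cohort="pediatric")
    elif name == "adult-like":
        skin = [
            "Finegoldia", "Corynebacterium", "Anaerococcus", "Staphylococcus",
            "Cutibacterium", "Micrococcus", "Streptococcus", "Lactobacillus",
            "Actinomyces", "Propionimicrobium", "Mobiluncus", "Actinotignum",
        ]
        anaerobe = [
            "Prevotella", "Hoylesella", "Peptoniphilus", "Porphyromonas",
            "Campylobacter", "Dialister", "Ezakiella", "Varibaculum",
            "Negativicoccus", "Fastidiosipila", "Murdochiella", "Fusobacterium",
        ]
        cfg = SimConfig(
            n_samples=n_samples,
            seed=seed,
            cohort="adult",
            guild_blocks=[skin, anaerobe],
            within_block_cov=0.6,
            between_block_cov=-0.4,
            depth_logmean=float(np.log(190_591)),
        )
    else:
        raise GuildshiftError(f"unknown preset {name!r}")
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise GuildshiftError(f"unknown SimConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg
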