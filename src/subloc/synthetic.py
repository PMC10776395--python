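"""Synthetic density-gradient fractionation experiments with known ground truth.

Emulates the measurement process of gradient LoRNA/dLOPIT-style experiments:

* Every localization has a unimodal "archetype" profile over the gradient
  fractions (where RNA/protein of that compartment sediments).
* Each transcript distributes its copies across localizations according to a
  ground-truth proportion vector drawn per biotype; its absolute amount in a
  fraction is abundance x sum_l p_l * archetype_lf.
* Per-fraction RNA content differences are produced by an unprofiled
  background RNA mass (rRNA-like carrier) whose distribution over fractions is
  the config's content vector; content is therefore a real property of the
  gradient, recoverable from spike-ins, rather than an exogenous multiplier on
  the profiled transcripts.
* Spike-ins enter every fraction at the same absolute amount; each fraction
  library is then sequenced to a fixed depth, with negative-binomial counting
  noise, so raw quantifications are relative within a library.
* Under UPR, mRNAs shift part of their mass to the granule compartment with a
  logistic gain in length, AU content and prior membrane localization; lncRNAs
  do not relocalize.
* PSM tables mimic a TMT reporter-ion export: several PSMs per protein around
  its localization archetype, planted contaminants sharing peptides with
  flagged cRAP entries, planted displaced-profile outlier PSMs, and intensity-
  dependent missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rna import ProfileTable, SpikeInSet

DEFAULT_LOCALIZATIONS = (
    "nucleus",
    "nucleolus",
    "cytosol",
    "cytosol_light",
    "membrane",
    "er",
)

DEFAULT_PROTEIN_LOCALIZATIONS = (
    "nucleus",
    "nucleolus",
    "cytosol",
    "er",
    "golgi",
    "lysosome",
    "mitochondria",
    "pm",
)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ArchetypeSet:
    """Row-normalized localization x fraction profile matrix."""

    localizations: list[str]
    profiles: np.ndarray
    fraction_count: int

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.localizations), self.fraction_count):
            raise ValueError("profile matrix shape does not match metadata")
        if np.any(self.profiles < 0):
            raise ValueError("archetype profiles must be non-negative")
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("archetype rows must sum to 1")
        for i in range(len(self.localizations)):
            for j in range(i + 1, len(self.localizations)):
                if np.array_equal(self.profiles[i], self.profiles[j]):
                    raise ValueError("two archetype rows are identical")

    def row(self, localization: str) -> np.ndarray:
        return self.profiles[self.localizations.index(localization)]


def generate_archetypes(
    localizations: list[str] | tuple[str, ...],
    fraction_count: int,
    seed: int,
    width_range: tuple[float, float] = (0.35, 1.0),
    min_flat_residual: float = 0.2,
) -> ArchetypeSet:
    """Unimodal triangular bump profiles with distinct, evenly spaced peaks.

    Peaks are placed at ``linspace(0, F-1, L)``; each bump's half-width is a
    seeded draw from ``width_range`` times the peak spacing. Heterogeneous
    widths emulate how compartments spread differently along a real gradient
    and keep pairwise cosine similarity well below 0.95.

    The draw is additionally required to leave the flat (all-ones) profile
    direction outside the row span (relative least-squares residual of the
    ones vector >= ``min_flat_residual``): the downstream deconvolution fits
    a free intercept, and when a basis can nearly synthesize a flat profile
    the intercept estimate becomes noise and its QC filter loses meaning.
    Draws are rejection-sampled (seeded, deterministic); if the geometry
    cannot satisfy the bound (e.g. as many localizations as fractions), the
    best of the attempted draws is kept.
    """
    localizations = list(localizations)
    n_loc = len(localizations)
    if n_loc < 2:
        raise ValueError("need at least 2 localizations")
    if fraction_count < 2:
        raise ValueError("invalid config: fraction_count must be >= 2")
    if fraction_count < n_loc:
        raise ValueError("fraction_count must be >= number of localizations")
    rng = np.random.default_rng(seed)
    peaks = np.linspace(0, fraction_count - 1, n_loc)
    spacing = peaks[1] - peaks[0]
    frac_idx = np.arange(fraction_count, dtype=float)
    lo, hi = width_range
    if not 0 < lo <= hi <= 1.0:
        raise ValueError("width_range must satisfy 0 < lo <= hi <= 1")
    ones = np.ones(fraction_count)
    best = None
    for _ in range(100):
        profiles = np.empty((n_loc, fraction_count))
        for i, peak in enumerate(peaks):
            half_width = spacing * rng.uniform(lo, hi)
            bump = np.maximum(0.0, 1.0 - np.abs(frac_idx - peak) / half_width)
            profiles[i] = bump / bump.sum()
        coef, *_ = np.linalg.lstsq(profiles.T, ones, rcond=None)
        flat_resid = (np.linalg.norm(ones - profiles.T @ coef)
                      / np.linalg.norm(ones))
        if best is None or flat_resid > best[0]:
            best = (flat_resid, profiles)
        if flat_resid >= min_flat_residual:
            break
    return ArchetypeSet(localizations, best[1], fraction_count)


@dataclass
class SimulationConfig:
    """Study conditions for the simulated fractionation experiment.

    Defaults describe a desk-scale version of an 8-fraction density gradient:
    3 replicates x 2 conditions, negative-binomial counting noise at low
    dispersion (within-gradient noise is largely technical), sparse Dirichlet
    truth so most transcripts concentrate in one or two compartments, ~5% of
    each library from spike-ins, and a cytosol-heavy background RNA content
    profile.
    """

    n_transcripts: int = 3000
    n_proteins: int = 600
    fraction_count: int = 8
    replicates: int = 3
    conditions: tuple[str, str] = ("control", "upr")
    localizations: tuple[str, ...] = DEFAULT_LOCALIZATIONS
    protein_localizations: tuple[str, ...] = DEFAULT_PROTEIN_LOCALIZATIONS
    granule_localization: str = "cytosol_light"
    membrane_localization: str = "membrane"
    lncrna_share: float = 0.2
    dirichlet_concentrations: dict | None = None
    markers_per_class: int = 20
    nb_dispersion: float = 0.01
    library_depth: float = 5.0e6
    abundance_log_mean: float = float(np.log(30.0))
    abundance_log_sd: float = 1.0
    n_spikeins: int = 40
    spikein_fraction_of_library: float = 0.05
    content: tuple[float, ...] = (0.05, 0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.10)
    background_share: float = 0.3
    n_background: int = 30
    proportion_used: tuple[float, ...] | None = None
    relocalization_coefficients: tuple[float, float, float, float] = (
        -8.0,
        1.5,
        3.0,
        -2.0,
    )
    n_rbps: int = 20
    # PSM simulation
    n_channels: int = 8
    psms_per_protein_mean: float = 3.0
    psm_noise_sd: float = 0.1
    missing_rate: float = 0.05
    outlier_rate: float = 0.02
    contaminant_rate: float = 0.02
    nonunique_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "outlier_rate", "contaminant_rate",
                     "nonunique_rate", "lncrna_share",
                     "spikein_fraction_of_library"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        content = np.asarray(self.content, dtype=float)
        if content.size != self.fraction_count:
            raise ValueError("content vector length must equal fraction_count")
        if np.any(content <= 0):
            raise ValueError("content vector must be strictly positive")
        if self.proportion_used is not None:
            p = np.asarray(self.proportion_used, dtype=float)
            if p.size != self.fraction_count or np.any((p <= 0) | (p > 1)):
                raise ValueError("proportion_used entries must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("conditions", "localizations", "protein_localizations",
                    "content", "proportion_used", "relocalization_coefficients"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticDataset:
    """Simulated experiment plus every ground-truth quantity needed to score it."""

    rna_profiles: ProfileTable
    true_proportions: pd.DataFrame  # feature_id, condition, one column per localization
    feature_table: pd.DataFrame
    sequences: dict[str, str]
    spikeins: SpikeInSet
    marker_sets: dict[str, list[str]]
    rbp_binding: pd.DataFrame
    psm_table: pd.DataFrame | None = None
    protein_truth: pd.DataFrame | None = None
    psm_truth: dict | None = None
    archetypes: ArchetypeSet | None = None

    def __post_init__(self) -> None:
        loc_cols = [c for c in self.true_proportions.columns
                    if c not in ("feature_id", "condition")]
        sums = self.true_proportions[loc_cols].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("true proportion rows must sum to 1")


def _random_sequences(
    rng: np.random.Generator,
    lengths: np.ndarray,
    au: np.ndarray,
    is_mrna: np.ndarray,
) -> tuple[dict[str, str], np.ndarray, np.ndarray]:
    """Random DNA sequences at the requested AU(=AT) content.

    mRNAs carry an embedded CDS (ATG ... stop) framing a 5'UTR of ~10% and a
    3'UTR of ~30% of the transcript. Returns sequences keyed t_<i> plus
    cds_start / cds_end arrays (-1 where non-coding).
    """
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    cds_start = np.full(lengths.size, -1)
    cds_end = np.full(lengths.size, -1)
    for i, (length, au_i) in enumerate(zip(lengths, au)):
        p = np.array([au_i / 2, (1 - au_i) / 2, (1 - au_i) / 2, au_i / 2])
        seq = rng.choice(bases, size=int(length), p=p)
        if is_mrna[i] and length >= 120:
            start = int(round(0.1 * length))
            n_codons = max(10, int(0.6 * length) // 3)
            end = min(start + 3 * n_codons, int(length) - 3)
            end -= (end - start) % 3
            seq[start:start + 3] = list("ATG")
            seq[end:end + 3] = list("TAA")
            cds_start[i] = start
            cds_end[i] = end + 3
        seqs[f"t_{i}"] = "".join(seq)
    return seqs, cds_start, cds_end


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson counts with var = mu + dispersion * mu^2; exact mean at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    lam = rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam).astype(float)


def granule_gain(
    lengths: np.ndarray,
    au: np.ndarray,
    membrane_prior: np.ndarray,
    coefficients: tuple[float, float, float, float],
) -> np.ndarray:
    """Logistic probability-like gain of granule mass under UPR for mRNAs."""
    b0, b1, b2, b3 = coefficients
    return _expit(b0 + b1 * np.log10(lengths) + b2 * au + b3 * membrane_prior)


def simulate_rna_experiment(
    config: SimulationConfig,
    archetypes: ArchetypeSet | None = None,
) -> SyntheticDataset:
    """Simulate the RNA arm of the experiment under ``config``.

    Counts for transcript t in fraction f of a library have expected value
    depth x (abundance_t x sum_l p_tl archetype_lf x used_f) / library total,
    with spike-ins added at a fixed absolute amount per fraction before the
    depth scaling. Ground truth proportions are stored per condition; mRNAs
    relocalize toward the granule class under UPR with the configured logistic
    gain, lncRNAs do not.
    """
    if archetypes is None:
        archetypes = generate_archetypes(
            list(config.localizations), config.fraction_count, seed=config.seed
        )
    if archetypes.fraction_count != config.fraction_count:
        raise ValueError("archetype fraction count does not match config")
    if list(archetypes.localizations) != list(config.localizations):
        raise ValueError("archetype localizations do not match config")

    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    locs = list(config.localizations)
    n_loc = len(locs)
    frac_cols = [f"fraction_{i + 1}" for i in range(config.fraction_count)]

    n_lnc = int(round(config.lncrna_share * n))
    biotype = np.array(["protein_coding"] * n)
    lnc_idx = rng.choice(n, size=n_lnc, replace=False)
    biotype[lnc_idx] = "lncRNA"
    is_mrna = biotype == "protein_coding"

    conc = config.dirichlet_concentrations or {
        "protein_coding": np.full(n_loc, 1.0),
        "lncRNA": _lncrna_concentrations(locs),
    }
    # support-sparse truth: each transcript occupies 1-3 compartments (the
    # rest exactly zero), with compartment weights per biotype; proportions
    # within the support are Dirichlet
    truth = np.zeros((n, n_loc))
    for bt in ("protein_coding", "lncRNA"):
        weights = np.asarray(conc[bt], dtype=float)
        weights = weights / weights.sum()
        for i in np.flatnonzero(biotype == bt):
            size = 1 + rng.binomial(2, 0.6)
            support = rng.choice(n_loc, size=size, replace=False, p=weights)
            truth[i, support] = rng.dirichlet(np.full(size, 0.8))

    # marker transcripts: one-hot truth, mRNA biotype, anchored per class
    marker_sets: dict[str, list[str]] = {}
    cursor = 0
    mrna_order = np.flatnonzero(is_mrna)
    for li, loc in enumerate(locs):
        idx = mrna_order[cursor:cursor + config.markers_per_class]
        cursor += config.markers_per_class
        truth[idx] = 0.0
        truth[idx, li] = 1.0
        marker_sets[loc] = [f"t_{i}" for i in idx]

    lengths = np.round(10 ** rng.normal(3.1, 0.35, size=n)).astype(int)
    lengths = np.clip(lengths, 200, 20000)
    au = rng.beta(5, 5, size=n)
    abundance = np.exp(rng.normal(config.abundance_log_mean,
                                  config.abundance_log_sd, size=n))

    mem_idx = locs.index(config.membrane_localization)
    gran_idx = locs.index(config.granule_localization)
    gain = granule_gain(lengths, au, truth[:, mem_idx],
                        config.relocalization_coefficients)
    gain = np.where(is_mrna, gain, 0.0)

    truth_by_cond = {config.conditions[0]: truth}
    upr = truth * (1.0 - gain[:, None])
    upr[:, gran_idx] += gain * truth.sum(axis=1)
    truth_by_cond[config.conditions[1]] = upr / upr.sum(axis=1, keepdims=True)

    content = np.asarray(config.content, dtype=float)
    content = content / content.sum()
    used = (np.asarray(config.proportion_used, dtype=float)
            if config.proportion_used is not None
            else np.full(config.fraction_count, 0.5))

    spike_amount_each = None
    spike_ids = [f"SIRV_{i}" for i in range(config.n_spikeins)]
    bg_ids = [f"bg_{i}" for i in range(config.n_background)]
    bg_split = rng.dirichlet(np.full(config.n_background, 5.0))

    rows = []
    truth_rows = []
    for cond in config.conditions:
        p_cond = truth_by_cond[cond]
        absolute = (abundance[:, None] * (p_cond @ archetypes.profiles))
        endo_total_f = absolute.sum(axis=0)
        bg_total = config.background_share * endo_total_f.sum()
        bg_f = bg_total * content  # background distributed per content vector
        if spike_amount_each is None:
            # same absolute spike pool for both conditions, sized to the
            # requested mean library share in the control condition
            target = config.spikein_fraction_of_library
            mean_endo = ((endo_total_f + bg_f) * used).mean()
            spike_total = target / (1 - target) * mean_endo
            spike_per = rng.dirichlet(np.full(config.n_spikeins, 5.0)) * spike_total
        for rep in range(1, config.replicates + 1):
            for f in range(config.fraction_count):
                amounts = np.concatenate([
                    absolute[:, f] * used[f],
                    bg_split * bg_f[f] * used[f],
                    spike_per,
                ])
                mu = config.library_depth * amounts / amounts.sum()
                counts = _nb_counts(rng, mu, config.nb_dispersion)
                tpm = counts / max(counts.sum(), 1e-12) * 1e6
                rows.append((cond, rep, f, tpm))
        for i in range(n):
            truth_rows.append({"feature_id": f"t_{i}", "condition": cond,
                               **dict(zip(locs, p_cond[i]))})

    feature_ids = [f"t_{i}" for i in range(n)] + bg_ids + spike_ids
    feature_biotype = (list(biotype) + ["background"] * config.n_background
                       + ["spikein"] * config.n_spikeins)
    # pivot per (condition, replicate): one row per feature with fraction columns
    records = []
    by_sample: dict[tuple[str, int], np.ndarray] = {}
    for cond, rep, f, tpm in rows:
        by_sample.setdefault((cond, rep), np.zeros((len(feature_ids),
                                                    config.fraction_count)))
        by_sample[(cond, rep)][:, f] = tpm
    for (cond, rep), mat in by_sample.items():
        df = pd.DataFrame(mat, columns=frac_cols)
        df.insert(0, "replicate", rep)
        df.insert(0, "condition", cond)
        df.insert(0, "biotype", feature_biotype)
        df.insert(0, "feature_id", feature_ids)
        records.append(df)
    profile_df = pd.concat(records, ignore_index=True)

    seqs, cds_start, cds_end = _random_sequences(rng, lengths, au, is_mrna)
    feature_table = pd.DataFrame({
        "feature_id": [f"t_{i}" for i in range(n)],
        "gene_id": [f"g_{i}" for i in range(n)],
        "biotype": biotype,
        "length": lengths,
        "au_content": au,
        "abundance": abundance,
        "cds_start": cds_start,
        "cds_end": cds_end,
        "granule_gain_truth": gain,
    })

    rbp_rows = []
    for r in range(config.n_rbps):
        p_bind = rng.uniform(0.05, 0.3)
        bound = np.flatnonzero(rng.random(n) < p_bind)
        for i in bound:
            rbp_rows.append({"rbp": f"RBP_{r}", "feature_id": f"t_{i}"})
    rbp_binding = pd.DataFrame(rbp_rows)

    return SyntheticDataset(
        rna_profiles=ProfileTable(profile_df, level="transcript", state="raw"),
        true_proportions=pd.DataFrame(truth_rows),
        feature_table=feature_table,
        sequences=seqs,
        spikeins=SpikeInSet(ids=spike_ids, proportion_used=used),
        marker_sets=marker_sets,
        rbp_binding=rbp_binding,
        archetypes=archetypes,
    )


def _lncrna_concentrations(locs: list[str]) -> np.ndarray:
    """Nucleus/cytosol-weighted Dirichlet concentrations for lncRNAs."""
    weights = {"nucleus": 1.2, "nucleolus": 0.2, "cytosol": 0.8,
               "cytosol_light": 0.2}
    return np.array([weights.get(l, 0.05) for l in locs])


def simulate_psm_table(
    config: SimulationConfig,
    protein_archetypes: ArchetypeSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a TMT PSM-level reporter-intensity table with planted defects.

    Returns (psm_table, protein_truth, psm_truth). Planted defects:

    * contaminants: ``CRAP_*`` proteins (listed in ``psm_truth['contaminant_ids']``)
      plus "shadow" proteins that share one observed peptide with a CRAP entry;
    * outlier PSMs displaced onto a distant localization archetype, planted only
      in proteins keeping >= 4 PSMs after the missing-value filter so the
      median-distance rule can in principle recover every plant;
    * missing values injected with probability decreasing in intensity rank
      (mean equal to ``missing_rate``); PSMs pushed over the 20% missing rule
      are recorded in ``psm_truth['heavy_missing_psms']``.
    """
    if config.outlier_rate >= 0.5:
        raise ValueError("invalid config: outlier_rate must be < 0.5")
    if protein_archetypes is None:
        protein_archetypes = generate_archetypes(
            list(config.protein_localizations),
            config.n_channels,
            seed=config.seed + 1,
        )
    rng = np.random.default_rng(config.seed + 2)
    locs = list(protein_archetypes.localizations)
    n_prot = config.n_proteins
    channels = [f"channel_{i + 1}" for i in range(config.n_channels)]
    # reporter channels carry a noise floor: no channel is ever exactly zero
    floor = 0.02
    prof = protein_archetypes.profiles + floor
    prof = prof / prof.sum(axis=1, keepdims=True)

    prot_loc = rng.integers(0, len(locs), size=n_prot)
    protein_ids = [f"p_{i}" for i in range(n_prot)]

    n_crap = max(1, int(round(config.contaminant_rate * n_prot)))
    crap_ids = [f"CRAP_{i}" for i in range(n_crap)]
    shadow_idx = rng.choice(n_prot, size=n_crap, replace=False)
    shadow_ids = {protein_ids[i] for i in shadow_idx}

    records = []
    pep_counter = 0
    shared_peptides = {cid: f"PEP_shared_{j}" for j, cid in enumerate(crap_ids)}
    all_proteins = protein_ids + crap_ids
    all_locs = list(prot_loc) + list(rng.integers(0, len(locs), size=n_crap))
    for pi, (prot, li) in enumerate(zip(all_proteins, all_locs)):
        n_psm = 1 + rng.poisson(config.psms_per_protein_mean)
        base = prof[li]
        for j in range(n_psm):
            total = np.exp(rng.normal(np.log(1e5), 1.0))
            noise = (np.exp(rng.normal(0.0, config.psm_noise_sd,
                                       size=config.n_channels))
                     if config.psm_noise_sd > 0 else 1.0)
            intensities = total * base * noise
            peptide = f"PEP_{pep_counter}"
            pep_counter += 1
            records.append({
                "psm_id": f"psm_{pi}_{j}",
                "master_protein": prot,
                "peptide_seq": peptide,
                "unique_flag": bool(rng.random() >= config.nonunique_rate),
                "localization_index": li,
                **dict(zip(channels, intensities)),
            })
    # shadow proteins re-use one peptide observed on a CRAP protein
    for cid, sid in zip(crap_ids, sorted(shadow_ids)):
        for rec in records:
            if rec["master_protein"] == cid:
                rec["peptide_seq"] = shared_peptides[cid]
                break
        for rec in records:
            if rec["master_protein"] == sid:
                rec["peptide_seq"] = shared_peptides[cid]
                break

    psm = pd.DataFrame.from_records(records)

    # intensity-rank missingness: p = 2 * rate * (1 - rank quantile)
    mat = psm[channels].to_numpy()
    flat = mat.ravel()
    order = flat.argsort().argsort()  # ranks
    q = (order + 0.5) / flat.size
    p_miss = 2.0 * config.missing_rate * (1.0 - q)
    miss_mask = (rng.random(flat.size) < p_miss).reshape(mat.shape)
    mat[miss_mask] = np.nan
    psm[channels] = mat

    missing_share = psm[channels].isna().mean(axis=1)
    heavy_missing = set(psm.loc[missing_share > 0.2, "psm_id"])

    # plant outliers among clean proteins with >=4 PSMs surviving both the
    # missing-share and unique-master filters, so the median-distance rule
    # always has >=3 concordant siblings
    surviving = psm[~psm["psm_id"].isin(heavy_missing)
                    & psm["unique_flag"].astype(bool)]
    eligible = (
        surviving[surviving["master_protein"].isin(protein_ids)]
        .groupby("master_protein")["psm_id"].count()
    )
    eligible_prots = [p for p in eligible.index[eligible >= 4]
                      if p not in shadow_ids]
    n_outliers = int(round(config.outlier_rate * len(psm)))
    n_outliers = min(n_outliers, len(eligible_prots))
    outlier_psms: set[str] = set()
    chosen = rng.choice(len(eligible_prots), size=n_outliers, replace=False)
    dist = np.linalg.norm(prof[:, None, :] - prof[None, :, :], axis=2)
    for ci in chosen:
        prot = eligible_prots[ci]
        sub = surviving[surviving["master_protein"] == prot]
        row = sub.sample(n=1, random_state=int(rng.integers(2**31)))
        li = int(row["localization_index"].iloc[0])
        target = int(np.argmax(dist[li]))
        idx = row.index[0]
        vals = psm.loc[idx, channels].to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        total = np.nansum(vals)
        displaced = total * prof[target] / prof[target][observed].sum()
        displaced[~observed] = np.nan
        psm.loc[idx, channels] = displaced
        outlier_psms.add(psm.loc[idx, "psm_id"])

    protein_truth = pd.DataFrame({
        "protein_id": all_proteins,
        "localization": [locs[i] for i in all_locs],
        "is_marker": [i < n_prot and i % 3 == 0 for i in range(len(all_proteins))],
        "is_contaminant": [p in shadow_ids or p in crap_ids for p in all_proteins],
    })
    psm_truth = {
        "contaminant_ids": set(crap_ids),
        "contaminant_proteins": set(crap_ids) | shadow_ids,
        "outlier_psms": outlier_psms,
        "heavy_missing_psms": heavy_missing,
    }
    psm = psm.drop(columns=["localization_index"])
    return psm, protein_truth, psm_truth


def simulate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset: RNA profiles plus the PSM-level protein arm."""
    dataset = simulate_rna_experiment(config)
    psm, protein_truth, psm_truth = simulate_psm_table(config)
    dataset.psm_table = psm
    dataset.protein_truth = protein_truth
    dataset.psm_truth = psm_truth
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as plain-text TSV/FASTA under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.rna_profiles.data.to_csv(outdir / "rna_profiles.tsv", sep="\t",
                                     index=False)
    dataset.true_proportions.to_csv(outdir / "true_proportions.tsv", sep="\t",
                                    index=False)
    dataset.feature_table.to_csv(outdir / "feature_table.tsv", sep="\t",
                                 index=False)
    dataset.rbp_binding.to_csv(outdir / "rbp_binding.tsv", sep="\t", index=False)
    if dataset.psm_table is not None:
        dataset.psm_table.to_csv(outdir / "psm_table.tsv", sep="\t", index=False)
        dataset.protein_truth.to_csv(outdir / "protein_truth.tsv", sep="\t",
                                     index=False)
    with open(outdir / "transcripts.fasta", "w") as fh:
        for name, seq in dataset.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
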