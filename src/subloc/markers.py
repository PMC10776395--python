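"""Localization marker discovery: a priori rules + semi-supervised NNMF.

Gene-level markers come from orthogonal evidence (nuclear/cytoplasm
fractionation ratios, APEX proximity labeling, ER ribosome profiling,
signal-peptide/TM annotation, the mitochondrially encoded mRNAs, curated
lncRNA lists). Non-negative matrix factorization of the normalized profiles,
with the rank chosen by held-out-entry imputation error, then expands each
a priori set to the full membership of its best-overlap cluster — and exposes
clusters claimed by no a priori set as novel profiles (the route by which the
cytosol-light / granule class is discovered).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 13 mitochondrially encoded, mitochondrially translated human mRNAs.
#: Their transcripts never leave the mitochondrion, anchoring 100% membrane
#: localization in the deconvolution basis.
MITOCHONDRIAL_MRNAS = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8",
)

NUCLEAR_LNCRNAS = ("XIST", "MALAT1", "MEG3", "DLX6-AS1", "PINCR",
                   "UCHL1-AS1", "NEAT1")
CYTOSOLIC_LNCRNAS = ("LINCMD1", "NORAD", "H19", "NKILA", "SNHG5", "DANCR",
                     "OIP5-AS1", "SNHG1")


@dataclass
class MarkerSet:
    """localization -> member ids, with per-member provenance and a blacklist."""

    level: str  # "gene" | "transcript"
    members: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for loc, ids in self.members.items():
            for m in ids:
                if m in seen and seen[m] != loc:
                    raise ValueError(
                        f"marker {m!r} assigned to both {seen[m]!r} and {loc!r}"
                    )
                seen[m] = loc

    def localization_of(self, member: str) -> str | None:
        for loc, ids in self.members.items():
            if member in ids:
                return loc
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"member_id": m, "localization": loc,
             "provenance": self.provenance.get(m, "apriori")}
            for loc, ids in self.members.items()
            for m in ids
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: str = "gene",
                   blacklist: frozenset[str] = frozenset()) -> "MarkerSet":
        """Rebuild from a (member_id, localization[, provenance]) table."""
        members = {
            loc: sorted(sub["member_id"])
            for loc, sub in frame.groupby("localization")
        }
        provenance = (
            dict(zip(frame["member_id"], frame["provenance"]))
            if "provenance" in frame.columns else {}
        )
        return cls(level=level, members=members, provenance=provenance,
                   blacklist=blacklist)


@dataclass
class AprioriRuleInputs:
    """Evidence tables for the a priori marker rules (gene-level ids).

    nuclear_cytoplasm: gene_id, log2_ratio (nucleus over cytoplasm)
    nes_apex: gene_id, significant (bool), log2_enrichment
    kdel_apex: gene_id, significant (bool), log2_enrichment
    er_riboseq: gene_id, enrichment (linear scale)
    signal_peptide: gene ids with a predicted signal peptide or TM domain
    mitochondrial_genes: mitochondrially encoded mRNA ids
    """

    nuclear_cytoplasm: pd.DataFrame | None = None
    nes_apex: pd.DataFrame | None = None
    kdel_apex: pd.DataFrame | None = None
    er_riboseq: pd.DataFrame | None = None
    signal_peptide: frozenset[str] = frozenset()
    mitochondrial_genes: tuple[str, ...] = MITOCHONDRIAL_MRNAS
    nuclear_lncrnas: tuple[str, ...] = NUCLEAR_LNCRNAS
    cytosolic_lncrnas: tuple[str, ...] = CYTOSOLIC_LNCRNAS


def define_apriori_markers(
    inputs: AprioriRuleInputs,
    universe: set[str] | None = None,
) -> MarkerSet:
    """Gene-level marker sets from the a priori evidence rules.

    * nucleus: >16-fold nuclear enrichment in nuclear/cytoplasm RNA-seq, or a
      curated nuclear lncRNA;
    * cytosol: significant NES APEX enrichment, or a curated cytosolic lncRNA;
    * er: ER-Ribo-seq enrichment > 2^0.5 AND significant >8-fold KDEL APEX
      enrichment AND a predicted signal peptide or TM domain;
    * mitochondria: the mitochondrially encoded mRNAs.

    ``universe`` restricts members to quantified ids (dropped with a log).
    """
    sets: dict[str, set[str]] = {"nucleus": set(), "cytosol": set(),
                                 "er": set(), "mitochondria": set()}
    if inputs.nuclear_cytoplasm is not None:
        t = inputs.nuclear_cytoplasm
        sets["nucleus"] |= set(t.loc[t["log2_ratio"] > np.log2(16), "gene_id"])
    sets["nucleus"] |= set(inputs.nuclear_lncrnas)
    if inputs.nes_apex is not None:
        t = inputs.nes_apex
        sets["cytosol"] |= set(t.loc[t["significant"], "gene_id"])
    sets["cytosol"] |= set(inputs.cytosolic_lncrnas)
    if inputs.er_riboseq is not None and inputs.kdel_apex is not None:
        ribo = set(
            inputs.er_riboseq.loc[
                inputs.er_riboseq["enrichment"] > 2 ** 0.5, "gene_id"
            ]
        )
        kdel_t = inputs.kdel_apex
        kdel = set(
            kdel_t.loc[
                kdel_t["significant"] & (kdel_t["log2_enrichment"] > np.log2(8)),
                "gene_id",
            ]
        )
        sets["er"] |= ribo & kdel & set(inputs.signal_peptide)
    sets["mitochondria"] |= set(inputs.mitochondrial_genes)

    members: dict[str, list[str]] = {}
    for loc, ids in sets.items():
        if universe is not None:
            dropped = ids - universe
            if dropped:
                logger.info("define_apriori_markers: %d %s markers not in the "
                            "quantified universe", len(dropped), loc)
            ids = ids & universe
        if not ids:
            raise ValueError(f"a priori rule produced no markers for {loc!r}")
        members[loc] = sorted(ids)
    provenance = {m: "apriori" for ids in members.values() for m in ids}
    return MarkerSet(level="gene", members=members, provenance=provenance)


# --------------------------------------------------------------------------
# Masked non-negative matrix factorization


def _masked_nmf(
    X: np.ndarray,
    mask: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-6,
    l2: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing ||mask * (X - WH)||_F^2.

    Observed entries have mask 1; held-out/missing entries 0. Seeded uniform
    initialization, relative-change stopping rule. A small ridge term keeps
    factor directions that touch only masked entries from diverging (they are
    otherwise unconstrained and multiplicative updates can blow up there).
    """
    n, m = X.shape
    scale = np.sqrt(X[mask > 0].mean() / k) if mask.any() else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    MX = mask * X
    reg = l2 * (X[mask > 0].mean() if mask.any() else 1.0)
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H
        W *= (MX @ H.T) / np.maximum((mask * WH) @ H.T + reg * W, 1e-12)
        WH = W @ H
        H *= (W.T @ MX) / np.maximum(W.T @ (mask * WH) + reg * H, 1e-12)
        if it % 10 == 0:
            err = float(np.sum((mask * (X - W @ H)) ** 2))
            if np.isfinite(prev) and prev - err <= tol * max(prev, 1e-12):
                break
            prev = err
    return W, H


@dataclass
class NNMFModel:
    """Fitted NNMF at the imputation-selected rank."""

    rank: int
    basis: np.ndarray        # k x fractions (H)
    coefficients: np.ndarray  # features x k (W)
    assignments: pd.Series    # feature_id -> cluster index (argmax rule)
    imputation_mse: dict[int, float]
    seed: int


def select_k_by_imputation(
    profiles: pd.DataFrame,
    k_candidates: list[int],
    holdout_share: float = 0.05,
    seed: int = 0,
    n_repeats: int = 5,
    feature_ids: list[str] | None = None,
) -> NNMFModel:
    """Choose the NNMF rank minimizing held-out-entry imputation error.

    For each candidate k, ``holdout_share`` of the entries are masked at
    random, the masked matrix is factorized, and the mean squared
    reconstruction error on the held-out entries recorded; the error is
    averaged over ``n_repeats`` independent masks (shared across candidates)
    to stabilize the curve. The model refit on the full matrix at the
    arg-min k is returned together with the whole MSE curve.
    """
    if isinstance(profiles, pd.DataFrame):
        num = profiles.select_dtypes("number")
        X = num.to_numpy(dtype=float)
        ids = feature_ids or list(profiles.index.astype(str))
    else:
        X = np.asarray(profiles, dtype=float)
        ids = feature_ids or [str(i) for i in range(X.shape[0])]
    if np.any(X < 0):
        raise ValueError("profiles must be non-negative")
    if not k_candidates:
        raise ValueError("k_candidates is empty")
    rng = np.random.default_rng(seed)
    n_holdout = max(1, int(round(holdout_share * X.size)))
    masks = []
    for _ in range(n_repeats):
        mask = np.ones_like(X)
        flat = rng.choice(X.size, size=n_holdout, replace=False)
        mask.ravel()[flat] = 0.0
        masks.append((mask, flat))

    mse: dict[int, float] = {}
    for k in k_candidates:
        errs = []
        for r, (mask, flat) in enumerate(masks):
            k_rng = np.random.default_rng(seed + 1000 * (r + 1) + k)
            W, H = _masked_nmf(X, mask, k, k_rng)
            recon = W @ H
            errs.append(np.mean((X.ravel()[flat] - recon.ravel()[flat]) ** 2))
        mse[k] = float(np.mean(errs))
    best_k = min(mse, key=lambda k: (mse[k], k))
    full_rng = np.random.default_rng(seed + 1000 + best_k)
    W, H = _masked_nmf(X, np.ones_like(X), best_k, full_rng)
    assignments = pd.Series(np.argmax(W, axis=1), index=ids, name="cluster")
    return NNMFModel(rank=best_k, basis=H, coefficients=W,
                     assignments=assignments, imputation_mse=mse, seed=seed)


def map_clusters_to_apriori(
    model: NNMFModel, apriori: MarkerSet
) -> tuple[MarkerSet, dict[int, list[str]]]:
    """Expand each a priori set to its maximal-overlap NNMF cluster.

    Every a priori localization is matched to the cluster sharing the most
    members with it; the expanded marker set is the cluster's entire
    membership. Clusters claimed by no localization are returned as novel
    profiles. Conflicts (two localizations on one cluster) and overlap ties
    raise, since they require curation.
    """
    cluster_members: dict[int, list[str]] = {
        int(c): list(idx) for c, idx in
        model.assignments.groupby(model.assignments).groups.items()
    }
    claims: dict[int, str] = {}
    for loc, ids in apriori.members.items():
        overlaps = {
            c: len(set(ids) & set(members))
            for c, members in cluster_members.items()
        }
        best = max(overlaps.values())
        winners = [c for c, v in overlaps.items() if v == best]
        if len(winners) > 1:
            raise ValueError(
                f"overlap tie for {loc!r} between clusters {winners}; "
                "manual curation required"
            )
        c = winners[0]
        if c in claims:
            raise ValueError(
                f"cluster {c} claimed by both {claims[c]!r} and {loc!r}"
            )
        claims[c] = loc
    members = {loc: sorted(cluster_members[c]) for c, loc in claims.items()}
    provenance = {m: "nnmf" for ids in members.values() for m in ids}
    for loc, ids in apriori.members.items():
        for m in ids:
            if m in provenance:
                provenance[m] = "apriori"
    novel = {c: sorted(ids) for c, ids in cluster_members.items()
             if c not in claims}
    if novel:
        logger.info("map_clusters_to_apriori: %d novel cluster(s): %s",
                    len(novel), sorted(novel))
    expanded = MarkerSet(level=apriori.level, members=members,
                         provenance=provenance, blacklist=apriori.blacklist)
    return expanded, novel


def define_cytosol_light(novel_basal: set[str], novel_upr: set[str]) -> set[str]:
    """Genes in the novel cluster under both conditions define cytosol-light."""
    out = set(novel_basal) & set(novel_upr)
    if not out:
        warnings.warn("cytosol-light intersection is empty", stacklevel=2)
    return out


def define_nucleolus_markers(
    nuclear_cluster_genes: set[str],
    snorna_ranking: list[str],
    top_n: int = 30,
) -> set[str]:
    """Nucleolus = nuclear-associated cluster ∩ top-n most abundant snoRNAs."""
    if top_n > 0 and len(snorna_ranking) < top_n:
        raise ValueError("snoRNA ranking shorter than top_n")
    return set(nuclear_cluster_genes) & set(snorna_ranking[:top_n])


def extend_to_transcripts(
    gene_markers: MarkerSet,
    annotation: pd.DataFrame,
    blacklist: frozenset[str] = frozenset(),
) -> MarkerSet:
    """Transcript-level markers: all isoforms whose biotype matches the gene's.

    ``annotation`` needs columns transcript_id, gene_id, transcript_biotype,
    gene_biotype. Genes absent from the annotation are skipped with a log;
    blacklisted transcripts are removed.
    """
    ann = annotation.set_index("transcript_id") \
        if "transcript_id" in annotation.columns else annotation
    by_gene = ann.groupby("gene_id")
    members: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    n_removed = 0
    for loc, genes in gene_markers.members.items():
        out: list[str] = []
        for g in genes:
            if g not in by_gene.groups:
                logger.info("extend_to_transcripts: gene %s absent from "
                            "annotation; skipped", g)
                continue
            iso = by_gene.get_group(g)
            match = iso[iso["transcript_biotype"] == iso["gene_biotype"]]
            for t in match.index:
                if t in blacklist:
                    n_removed += 1
                    continue
                out.append(t)
                provenance[t] = gene_markers.provenance.get(g, "apriori")
        members[loc] = sorted(out)
    if n_removed:
        logger.info("extend_to_transcripts: removed %d blacklisted "
                    "transcripts", n_removed)
    return MarkerSet(level="transcript", members=members,
                     provenance=provenance, blacklist=blacklist)


def fold_checksum(assignments: np.ndarray) -> str:
    """Stable checksum of an integer assignment vector (clusters or CV folds)."""
    return hashlib.sha256(np.asarray(assignments, dtype=np.int64).tobytes()) \
        .hexdigest()
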