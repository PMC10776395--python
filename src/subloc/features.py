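"""Transcript feature construction and localization/relocalization models.

Builds the predictor matrices behind three models: (i) a binary elastic-net
model of lncRNA cytosolic localization, (ii) an elastic-net model of granule
relocalization (UPR granule proportion minus control), and (iii) a lasso on
RBP binding of the GAM residuals measuring UPR-resistant membrane retention.
Sequence-derived predictors cover k-mer frequencies, AU content, upstream AUG
counts split by reading frame, codon / dinucleotide / wobble-base frequencies
and a pluggable codon-optimality score.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from .glmnet import PenalizedModelFit, fit_penalized_model

RNA_BASES = "ACGU"

STOP_CODONS = {"UAA", "UAG", "UGA"}

#: standard genetic code grouped by amino acid (U alphabet), stops excluded
GENETIC_CODE = {
    "F": ["UUU", "UUC"], "L": ["UUA", "UUG", "CUU", "CUC", "CUA", "CUG"],
    "I": ["AUU", "AUC", "AUA"], "M": ["AUG"],
    "V": ["GUU", "GUC", "GUA", "GUG"],
    "S": ["UCU", "UCC", "UCA", "UCG", "AGU", "AGC"],
    "P": ["CCU", "CCC", "CCA", "CCG"], "T": ["ACU", "ACC", "ACA", "ACG"],
    "A": ["GCU", "GCC", "GCA", "GCG"], "Y": ["UAU", "UAC"],
    "H": ["CAU", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAU", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAU", "GAC"], "E": ["GAA", "GAG"],
    "C": ["UGU", "UGC"], "W": ["UGG"], "R": ["CGU", "CGC", "CGA", "CGG",
                                             "AGA", "AGG"],
    "G": ["GGU", "GGC", "GGA", "GGG"],
}


def _canonical(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def kmer_frequencies(sequence: str, k: int) -> dict[str, float]:
    """Overlapping k-mer counts divided by the window count (len - k + 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = _canonical(sequence)
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        warnings.warn(f"sequence shorter than k={k}; all-zero frequencies",
                      stacklevel=2)
        return {}
    counts = Counter(seq[i:i + k] for i in range(n_windows))
    return {kmer: c / n_windows for kmer, c in counts.items()}


def au_content(sequence: str) -> float:
    seq = _canonical(sequence)
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("U")) / len(seq)


def count_upstream_augs(sequence: str, cds_start: int) -> tuple[int, int]:
    """(in_frame, out_of_frame) AUG counts in the 5'UTR.

    Frame is measured from the annotated CDS start: an upstream AUG at
    position i is in frame when (cds_start - i) is divisible by 3.
    """
    seq = _canonical(sequence)
    in_frame = out_frame = 0
    for i in range(max(cds_start - 2, 0)):
        if seq[i:i + 3] == "AUG" and i + 3 <= cds_start + 2:
            if i >= cds_start:
                break
            if (cds_start - i) % 3 == 0:
                in_frame += 1
            else:
                out_frame += 1
    return in_frame, out_frame


def codon_frequencies(cds: str) -> dict[str, float]:
    """Frequencies over the in-frame codons of a CDS (stops included)."""
    seq = _canonical(cds)
    codons = [seq[i:i + 3] for i in range(0, len(seq) - 2, 3)]
    if not codons:
        return {}
    counts = Counter(codons)
    return {c: n / len(codons) for c, n in counts.items()}


def wobble_frequencies(cds: str) -> dict[str, float]:
    """Third-position (wobble) base frequencies over in-frame codons."""
    seq = _canonical(cds)
    wobbles = [seq[i + 2] for i in range(0, len(seq) - 2, 3)]
    if not wobbles:
        return {}
    counts = Counter(wobbles)
    return {f"wobble_{b}": n / len(wobbles) for b, n in counts.items()}


def milc(cds: str, reference_codon_freqs: dict[str, float]) -> float:
    """MILC codon-usage distance of one CDS from reference codon frequencies.

    MILC = (sum_a M_a) / L - C with M_a = 2 sum_{c in a} o_c ln(f_c / g_c),
    where o_c are observed codon counts, f_c within-amino-acid frequencies of
    the gene, g_c those of the reference, L the gene's codon count and the
    correction C = (sum_a (r_a - 1)) / L - 0.5 over amino acids present
    (r_a = number of synonymous codons of a). Serves as the default
    codon-optimality hook; any per-transcript scalar can replace it.
    """
    seq = _canonical(cds)
    codons = Counter(
        seq[i:i + 3] for i in range(0, len(seq) - 2, 3)
        if seq[i:i + 3] not in STOP_CODONS
    )
    L = sum(codons.values())
    if L == 0:
        return np.nan
    total_m = 0.0
    correction_terms = 0.0
    for aa, syn in GENETIC_CODE.items():
        obs = {c: codons.get(c, 0) for c in syn}
        n_aa = sum(obs.values())
        if n_aa == 0:
            continue
        g_tot = sum(reference_codon_freqs.get(c, 0.0) for c in syn)
        if g_tot == 0:
            continue
        for c, o in obs.items():
            if o == 0:
                continue
            f_c = o / n_aa
            g_c = reference_codon_freqs.get(c, 0.0) / g_tot
            if g_c <= 0:
                g_c = 1e-9
            total_m += 2.0 * o * np.log(f_c / g_c)
        correction_terms += len(syn) - 1
    C = correction_terms / L - 0.5
    return total_m / L - C


def ribosome_density(cds_counts: float, cds_length: float) -> float:
    """Ribosome-protected read counts over the CDS divided by its length."""
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if cds_counts < 0:
        raise ValueError("cds_counts must be non-negative")
    return cds_counts / cds_length


def binarize_cytosol(proportions: pd.Series | np.ndarray) -> pd.Series:
    """Binary cytosolic labels: >= 2/3 -> 1, < 1/3 -> 0, in between excluded."""
    p = pd.Series(np.asarray(proportions, dtype=float),
                  index=getattr(proportions, "index", None))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    labels = pd.Series(np.nan, index=p.index)
    labels[p >= 2 / 3] = 1.0
    labels[p < 1 / 3] = 0.0
    return labels.dropna().astype(int)


def select_rbp_columns(
    binding_table: pd.DataFrame,
    min_targets: int,
    universe: set[str],
) -> pd.DataFrame:
    """0/1 binding columns for RBPs with strictly more targets than the cutoff.

    ``binding_table`` is long form (rbp, feature_id); target counts are taken
    within ``universe``, and the returned frame is indexed by the universe.
    """
    universe = sorted(universe)
    if binding_table.empty:
        warnings.warn("empty binding table; no RBP columns", stacklevel=2)
        return pd.DataFrame(index=pd.Index(universe, name="feature_id"))
    in_universe = binding_table[binding_table["feature_id"].isin(universe)]
    counts = in_universe.groupby("rbp")["feature_id"].nunique()
    kept = counts.index[counts > min_targets]
    out = pd.DataFrame(0, index=pd.Index(universe, name="feature_id"),
                       columns=[f"rbp_{r}" for r in kept], dtype=float)
    for rbp in kept:
        bound = in_universe.loc[in_universe["rbp"] == rbp, "feature_id"]
        out.loc[out.index.isin(bound), f"rbp_{rbp}"] = 1.0
    return out


def _kmer_matrix(sequences: dict[str, str], ids: list[str],
                 k_values: tuple[int, ...]) -> pd.DataFrame:
    cols: dict[str, dict[str, float]] = {}
    for fid in ids:
        seq = sequences.get(fid, "")
        feats: dict[str, float] = {}
        for k in k_values:
            if len(seq) >= k:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for kmer, freq in kmer_frequencies(seq, k).items():
                        feats[f"kmer_{kmer}"] = freq
        cols[fid] = feats
    return pd.DataFrame.from_dict(cols, orient="index").fillna(0.0)


def build_granule_features(
    feature_table: pd.DataFrame,
    sequences: dict[str, str],
    control_proportions: pd.DataFrame,
    localizations: list[str],
    rbp_binding: pd.DataFrame | None = None,
    min_rbp_targets: int = 100,
    k_values: tuple[int, ...] = (1, 2, 3),
    codon_optimality: pd.Series | None = None,
) -> pd.DataFrame:
    """Predictor matrix for the granule-relocalization model (mRNAs).

    Covers: transcript/5'UTR/CDS/3'UTR lengths (log10), AU content, k-mer
    frequencies, in/out-of-frame upstream AUG counts, codon, dinucleotide and
    wobble-base frequencies, a codon-optimality column (the MILC hook unless
    supplied), binary RBP binding, one-hot basal localization (argmax of the
    control proportions) and basal-localization x length / x RBP interaction
    columns. Transcripts lacking a CDS annotation get zero codon features and
    a ``no_cds`` flag.
    """
    ft = feature_table.set_index("feature_id")
    ids = [i for i in ft.index if i in set(control_proportions["feature_id"])]
    props = control_proportions.set_index("feature_id").loc[ids]

    out = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    out["log10_length"] = np.log10(ft.loc[ids, "length"].astype(float))
    cds_start = ft.loc[ids, "cds_start"].astype(int)
    cds_end = ft.loc[ids, "cds_end"].astype(int)
    has_cds = (cds_start >= 0) & (cds_end > cds_start)
    out["no_cds"] = (~has_cds).astype(float)
    length = ft.loc[ids, "length"].astype(float)
    utr5 = np.where(has_cds, cds_start, 0).astype(float)
    cds_len = np.where(has_cds, cds_end - cds_start, 0).astype(float)
    utr3 = np.where(has_cds, length - cds_end, 0).astype(float)
    out["log10_utr5"] = np.log10(utr5 + 1)
    out["log10_cds"] = np.log10(cds_len + 1)
    out["log10_utr3"] = np.log10(utr3 + 1)
    out["au_content"] = ft.loc[ids, "au_content"].astype(float)

    out = out.join(_kmer_matrix(sequences, ids, k_values))

    aug_in = np.zeros(len(ids))
    aug_out = np.zeros(len(ids))
    codon_cols: dict[str, dict[str, float]] = {}
    ref_freqs = _reference_codon_frequencies(sequences, ids, cds_start,
                                             cds_end, has_cds)
    milc_scores = np.zeros(len(ids))
    for j, fid in enumerate(ids):
        seq = sequences.get(fid, "")
        if not seq or not has_cds.loc[fid]:
            codon_cols[fid] = {}
            continue
        start, end = int(cds_start.loc[fid]), int(cds_end.loc[fid])
        aug_in[j], aug_out[j] = count_upstream_augs(seq, start)
        cds = seq[start:end]
        feats = {f"codon_{c}": v for c, v in codon_frequencies(cds).items()}
        feats.update({f"dinuc_{d}": v
                      for d, v in kmer_frequencies(cds, 2).items()})
        feats.update(wobble_frequencies(cds))
        codon_cols[fid] = feats
        milc_scores[j] = milc(cds, ref_freqs)
    out["aug_in_frame"] = aug_in
    out["aug_out_of_frame"] = aug_out
    out = out.join(pd.DataFrame.from_dict(codon_cols, orient="index")
                   .fillna(0.0))
    out["codon_optimality"] = (
        codon_optimality.reindex(ids).fillna(0.0).to_numpy()
        if codon_optimality is not None else np.nan_to_num(milc_scores)
    )

    if rbp_binding is not None and not rbp_binding.empty:
        rbp = select_rbp_columns(rbp_binding, min_rbp_targets, set(ids))
        out = out.join(rbp)
    rbp_cols = [c for c in out.columns if c.startswith("rbp_")]

    basal = props[localizations].to_numpy()
    argmax = np.array(localizations)[np.argmax(basal, axis=1)]
    length_cols = ["log10_length", "log10_utr5", "log10_cds", "log10_utr3"]
    extra: dict[str, np.ndarray] = {}
    for loc in localizations:
        onehot = (argmax == loc).astype(float)
        extra[f"basal_{loc}"] = onehot
        for col in length_cols + rbp_cols:
            extra[f"basal_{loc}_x_{col}"] = onehot * out[col].to_numpy()
    out = pd.concat([out, pd.DataFrame(extra, index=out.index)], axis=1)
    return out.fillna(0.0)


def _reference_codon_frequencies(sequences, ids, cds_start, cds_end, has_cds
                                 ) -> dict[str, float]:
    counts: Counter = Counter()
    for fid in ids:
        if not has_cds.loc[fid]:
            continue
        seq = _canonical(sequences.get(fid, ""))
        cds = seq[int(cds_start.loc[fid]):int(cds_end.loc[fid])]
        counts.update(
            cds[i:i + 3] for i in range(0, len(cds) - 2, 3)
            if cds[i:i + 3] not in STOP_CODONS
        )
    total = sum(counts.values()) or 1
    return {c: n / total for c, n in counts.items()}


def model_residuals_by_rbp(
    residuals: pd.Series,
    rbp_columns: pd.DataFrame,
    signal_peptide: pd.Series | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, PenalizedModelFit]:
    """Lasso of the GAM residuals on binary RBP binding columns.

    When a signal-peptide/TM indicator is supplied, transcripts with and
    without it are modeled separately; groups with fewer than 10 members are
    skipped with a warning. Returns one fit per group keyed
    ``with_sp`` / ``without_sp`` (or ``all``).
    """
    common = residuals.index.intersection(rbp_columns.index)
    res = residuals.loc[common]
    X = rbp_columns.loc[common]
    if signal_peptide is None:
        groups = {"all": np.ones(len(common), dtype=bool)}
    else:
        sp = signal_peptide.reindex(common).fillna(False).astype(bool)
        groups = {"with_sp": sp.to_numpy(), "without_sp": (~sp).to_numpy()}
    fits: dict[str, PenalizedModelFit] = {}
    for name, mask in groups.items():
        if mask.sum() < 10:
            warnings.warn(f"group {name!r} has <10 members; skipped",
                          stacklevel=2)
            continue
        fits[name] = fit_penalized_model(
            X.loc[mask], res.loc[mask], family="gaussian",
            alpha_grid=(1.0,), seed=seed, **fit_kwargs,
        )
    return fits
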