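"""PSM-level TMT processing, marker classification and differential calls.

Processing order mirrors a conservative reporter-ion workflow: contaminant
removal (cRAP ids plus any master protein sharing an observed peptide with
one), PSM filters (unique master, <=20% missing), knn imputation in
sum-normalized space, removal of outlier PSMs disagreeing with their protein
siblings, median-center normalization, aggregation to proteins with >=2 PSMs
and row-sum normalization. Downstream, marker-based SVM classification and
tiered differential-localization calls from supplied per-replicate posterior
probability tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

ASSIGNMENT_THRESHOLD = 0.95
TIER_THRESHOLDS = (("highly_confident", 0.99), ("confident", 0.95),
                   ("candidate", 0.85))


def channel_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("channel_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def remove_contaminants(
    psms: pd.DataFrame, contaminant_ids: set[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop PSMs of contaminant proteins and of peptide-sharing shadows.

    A master protein is flagged when it is on the contaminant list, or when
    any of its observed peptide sequences is also observed on a listed
    contaminant. Returns the cleaned table and a per-reason removal report.
    """
    contaminant_ids = set(contaminant_ids)
    listed = psms["master_protein"].isin(contaminant_ids)
    crap_peptides = set(psms.loc[listed, "peptide_seq"])
    shares = psms["peptide_seq"].isin(crap_peptides) & ~listed
    shadow_proteins = set(psms.loc[shares, "master_protein"])
    flagged = listed | psms["master_protein"].isin(shadow_proteins)
    report = pd.DataFrame({
        "reason": ["listed_contaminant", "shared_peptide"],
        "n_psms_removed": [
            int(listed.sum()),
            int((flagged & ~listed).sum()),
        ],
        "n_proteins": [len(contaminant_ids & set(psms["master_protein"])),
                       len(shadow_proteins)],
    })
    return psms[~flagged].reset_index(drop=True), report


def filter_psms(
    psms: pd.DataFrame, max_missing_share: float = 0.2
) -> pd.DataFrame:
    """Keep PSMs with a unique master protein and <= 20% missing channels."""
    cols = channel_columns(psms)
    missing_share = psms[cols].isna().mean(axis=1)
    keep = psms["unique_flag"].astype(bool) & (missing_share <= max_missing_share)
    return psms[keep].reset_index(drop=True)


def impute_knn(psms: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """knn-impute missing reporter intensities in sum-normalized space.

    Rows are compared in sum-normalized space so neighbors share similar
    fraction profiles rather than similar average abundance. For each row
    with missing values, candidate neighbors (observed wherever the target is
    missing) are ranked by Euclidean distance over the shared observed
    support, both rows renormalized over that support and the distance
    rescaled by the shared channel count. Each missing entry becomes the mean
    over the k nearest neighbors of the neighbor's value renormalized to the
    target row's observed channel set; rows are then rescaled back so
    observed entries are restored exactly.
    """
    out = psms.reset_index(drop=True).copy()
    cols = channel_columns(out)
    mat = out[cols].to_numpy(dtype=float)
    n_ch = mat.shape[1]
    observed = ~np.isnan(mat)
    totals = np.nansum(mat, axis=1)
    norm = mat / totals[:, None]
    rows_missing = np.flatnonzero(~observed.all(axis=1))
    filled = np.zeros_like(mat)
    filled[observed] = mat[observed]
    for i in rows_missing:
        obs_i = observed[i]
        miss_ch = np.flatnonzero(~obs_i)
        # usable neighbors: observed at every channel the target misses,
        # with some shared observed signal to normalize against
        shared_mask = observed & obs_i  # per-row shared support with target
        usable = observed[:, miss_ch].all(axis=1)
        usable[i] = False
        shared_tot = (filled * shared_mask).sum(axis=1)
        usable &= shared_tot > 0
        cand = np.flatnonzero(usable)
        if cand.size < k:
            warnings.warn(
                f"impute_knn: only {cand.size} usable neighbors for row {i}",
                stacklevel=2,
            )
        if cand.size == 0:
            continue
        # distance on the shared observed support, with both rows
        # renormalized over that support: sum normalization is only
        # comparable on a common support, otherwise rows overlapping the
        # target only on uninformative channels score distance zero
        sm = shared_mask[cand]
        nbr = (filled[cand] * sm) / shared_tot[cand, None]
        tgt_tot = (filled[i] * sm).sum(axis=1)
        tgt = (filled[i] * sm) / tgt_tot[:, None]
        n_shared = sm.sum(axis=1)
        d = np.sqrt(((nbr - tgt) ** 2).sum(axis=1) * n_ch / n_shared)
        # quantize so float dust cannot outrank the shared-support tie-break
        order = np.lexsort((-n_shared, np.round(d, 9)))
        nearest = cand[order[:k]]
        # neighbor values renormalized to the target's observed channels
        nbr_obs_tot = (filled[nearest] * obs_i).sum(axis=1)
        vals = filled[nearest][:, miss_ch] / nbr_obs_tot[:, None]
        norm[i, miss_ch] = vals.mean(axis=0)
    mat = norm * totals[:, None]
    mat[observed] = out[cols].to_numpy(dtype=float)[observed]
    out[cols] = mat
    return out


def remove_outlier_psms(
    psms: pd.DataFrame, distance_threshold: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove PSMs far from their protein siblings in profile space.

    Profiles are row-sum normalized; a PSM is removed when its median
    Euclidean distance to all other PSMs of the same master protein exceeds
    the threshold. Applied literally even for 2-PSM proteins (both removed;
    the protein then fails the >=2-PSM aggregation rule).
    """
    cols = channel_columns(psms)
    mat = psms[cols].to_numpy(dtype=float)
    norm = mat / mat.sum(axis=1, keepdims=True)
    drop = np.zeros(len(psms), dtype=bool)
    for prot, idx in psms.groupby("master_protein").groups.items():
        pos = psms.index.get_indexer(idx)
        if pos.size < 2:
            continue
        sub = norm[pos]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        med = np.array([
            np.median(np.delete(d[i], i)) for i in range(pos.size)
        ])
        drop[pos[med > distance_threshold]] = True
    removed = psms.loc[drop, ["psm_id", "master_protein"]].copy()
    return psms[~drop].reset_index(drop=True), removed


def median_center(psms: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-channel medians (divisive centering).

    Each channel is divided by its median over PSMs and multiplied by the
    grand median (median of the channel medians), so all channel medians are
    equal afterwards.
    """
    out = psms.copy()
    cols = channel_columns(out)
    medians = out[cols].median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise ValueError(f"zero or negative channel median in {bad}")
    grand = float(np.median(medians))
    out[cols] = out[cols] / medians * grand
    return out


def aggregate_proteins(
    psms: pd.DataFrame, min_psms: int = 2
) -> pd.DataFrame:
    """Sum PSMs to protein profiles (>=2 PSMs), row-sum normalized.

    A ``replicate`` column, if present, partitions the aggregation; otherwise
    the table is treated as one replicate.
    """
    cols = channel_columns(psms)
    keys = ["master_protein"] + (["replicate"] if "replicate" in psms else [])
    grouped = psms.groupby(keys)
    agg = grouped[cols].sum()
    counts = grouped["psm_id"].count().rename("psm_count")
    out = agg.join(counts).reset_index()
    out = out[out["psm_count"] >= min_psms].reset_index(drop=True)
    if out.empty:
        warnings.warn("aggregate_proteins produced an empty table", stacklevel=2)
        return out.rename(columns={"master_protein": "protein_id"})
    out[cols] = out[cols].div(out[cols].sum(axis=1), axis=0)
    if "replicate" not in out:
        out["replicate"] = 1
    return out.rename(columns={"master_protein": "protein_id"})


def process_psm_pipeline(
    psms: pd.DataFrame,
    contaminant_ids: set[str],
    k: int = 10,
    distance_threshold: float = 0.2,
) -> dict:
    """Full PSM -> protein-profile pipeline; returns every intermediate."""
    cleaned, contaminant_report = remove_contaminants(psms, contaminant_ids)
    filtered = filter_psms(cleaned)
    imputed = impute_knn(filtered, k=k)
    inliers, outlier_report = remove_outlier_psms(imputed, distance_threshold)
    centered = median_center(inliers)
    proteins = aggregate_proteins(centered)
    return {
        "contaminant_report": contaminant_report,
        "filtered": filtered,
        "imputed": imputed,
        "outliers_removed": outlier_report,
        "centered": centered,
        "proteins": proteins,
    }


@dataclass
class ClassificationResult:
    f1_scores: pd.DataFrame        # iteration x class F1
    best_params: dict
    predictions: pd.DataFrame      # protein_id, predicted, score


def classify_markers_svm(
    profiles: pd.DataFrame,
    protein_markers: dict[str, list[str]],
    iterations: int = 50,
    seed: int = 0,
    test_share: float = 0.2,
    param_grid: dict | None = None,
) -> ClassificationResult:
    """Marker-trained RBF-SVM localization classification.

    Per iteration: stratified train/test split of the markers, grid-searched
    hyperparameters on the training markers, per-class F1 on the test
    markers. The final model is refit on all markers with grid-searched
    hyperparameters and predicts a localization (with the one-vs-one decision
    margin as score) for every unlabeled protein.
    """
    cols = channel_columns(profiles)
    prof = profiles.set_index("protein_id")
    labels = {}
    for loc, ids in protein_markers.items():
        present = [i for i in ids if i in prof.index]
        if len(present) < 6:
            raise ValueError(
                f"marker class {loc!r} has only {len(present)} profiled members"
            )
        for i in present:
            labels[i] = loc
    marker_ids = list(labels)
    X = prof.loc[marker_ids, cols].to_numpy()
    y = np.array([labels[i] for i in marker_ids])
    grid = param_grid or {"C": [0.1, 1, 10, 100],
                          "gamma": ["scale", 0.1, 1, 10]}
    classes = sorted(set(y))

    splitter = StratifiedShuffleSplit(n_splits=iterations,
                                      test_size=test_share,
                                      random_state=seed)
    rows = []
    for it, (tr, te) in enumerate(splitter.split(X, y)):
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=3, n_jobs=1)
        search.fit(X[tr], y[tr])
        pred = search.best_estimator_.predict(X[te])
        scores = f1_score(y[te], pred, labels=classes, average=None,
                          zero_division=0)
        rows.append({"iteration": it, **dict(zip(classes, scores))})
    f1 = pd.DataFrame(rows)

    final = GridSearchCV(SVC(kernel="rbf", random_state=seed), grid, cv=3,
                         n_jobs=1)
    final.fit(X, y)
    unlabeled = prof.index.difference(marker_ids)
    if len(unlabeled):
        Xu = prof.loc[unlabeled, cols].to_numpy()
        pred = final.best_estimator_.predict(Xu)
        margin = final.best_estimator_.decision_function(Xu)
        score = margin.max(axis=1) if margin.ndim > 1 else np.abs(margin)
        predictions = pd.DataFrame({
            "protein_id": unlabeled,
            "predicted": pred,
            "score": score,
        })
    else:
        predictions = pd.DataFrame(columns=["protein_id", "predicted", "score"])
    return ClassificationResult(f1_scores=f1, best_params=final.best_params_,
                                predictions=predictions)


def select_exclusive_nuclear(score_table: pd.DataFrame) -> list[str]:
    """Protein ids with Nucleus score 5 and no other localization above 2.

    ``score_table``: protein_id column plus one integer 0-5 column per
    localization (COMPARTMENTS-style confidence scores).
    """
    t = score_table.set_index("protein_id")
    other = t.drop(columns=["Nucleus"])
    keep = (t["Nucleus"] == 5) & (other.max(axis=1) <= 2)
    return sorted(t.index[keep])


def split_nuclear_groups(
    profiles: pd.DataFrame, candidates: list[str]
) -> dict[str, list[str]]:
    """Split exclusively nuclear profiles into three threshold-defined groups.

    Rules on row-sum-normalized shares, applied in order with first match
    winning: group 1 > 0.3 in fraction 4; group 2 > 0.2 in fraction 5;
    group 3 > 0.4 in fraction 8. Unmatched candidates land in 'unassigned'.
    """
    prof = profiles.set_index("protein_id")
    groups: dict[str, list[str]] = {"group_1": [], "group_2": [],
                                    "group_3": [], "unassigned": []}
    for pid in candidates:
        row = prof.loc[pid]
        if row["channel_4"] > 0.3:
            groups["group_1"].append(pid)
        elif row["channel_5"] > 0.2:
            groups["group_2"].append(pid)
        elif row["channel_8"] > 0.4:
            groups["group_3"].append(pid)
        else:
            groups["unassigned"].append(pid)
    return groups


def assign_localization(
    p_localization: float,
    p_outlier: float,
    localization: str,
    threshold: float = ASSIGNMENT_THRESHOLD,
) -> str:
    """Assign iff localization probability x (1 - outlier probability) > 0.95."""
    for name, p in (("p_localization", p_localization),
                    ("p_outlier", p_outlier)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return localization if p_localization * (1 - p_outlier) > threshold \
        else "undefined"


@dataclass
class DifferentialLocalizationCall:
    protein_id: str
    tier: str  # highly_confident | confident | candidate | none
    assignments: dict[str, set[str]]  # condition -> assigned localizations
    dl_probabilities: list[float]


def call_differential_localization(
    calls: pd.DataFrame,
    replicates: int = 3,
) -> pd.DataFrame:
    """Tier differential-localization calls from per-replicate probabilities.

    ``calls``: protein, replicate, condition, localization, p_loc, p_out,
    p_dl. A protein reaches a tier when at least 2/3 of replicates have a
    differential-localization probability over that tier's threshold
    (0.99 / 0.95 / 0.85) AND it is never assigned to the same localization in
    the two conditions (assignment per replicate via the 0.95 product rule).
    """
    needed = int(np.ceil(2 * replicates / 3))
    rows = []
    for prot, sub in calls.groupby("protein"):
        assigned: dict[str, set[str]] = {}
        for _, r in sub.iterrows():
            loc = assign_localization(r["p_loc"], r["p_out"], r["localization"])
            if loc != "undefined":
                assigned.setdefault(r["condition"], set()).add(loc)
        conditions = list(sub["condition"].unique())
        never_same = True
        if len(conditions) == 2:
            a = assigned.get(conditions[0], set())
            b = assigned.get(conditions[1], set())
            never_same = len(a & b) == 0
        p_dl = sub.groupby("replicate")["p_dl"].max()
        tier = "none"
        if never_same:
            for name, thr in TIER_THRESHOLDS:
                if int((p_dl >= thr).sum()) >= needed:
                    tier = name
                    break
        rows.append({"protein": prot, "tier": tier,
                     "never_same_localization": never_same,
                     "n_replicates_over_0.85": int((p_dl >= 0.85).sum())})
    return pd.DataFrame(rows)
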