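"""NNLS deconvolution of fraction profiles into localization proportions.

Each feature's row-normalized gradient profile x (length F) is modeled as a
non-negative linear combination of the mean marker profile of every
localization plus a sign-free intercept:

    x  ~=  sum_l  p_l * b_l  +  c * 1,      p_l >= 0

solved by non-negative least squares with the intercept represented as a
(+1, -1) column pair. Fits are kept when the model explains >= 90% of the
profile variance and |c| <= 0.05. Mitochondrially encoded mRNAs cannot leave
the mitochondrion, so their marker mean anchors 100% membrane localization in
the density design; in the sedimentation design mitochondria and ER are
fitted separately and summed into a membrane proportion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .rna import ProfileTable, fraction_columns

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.90
INTERCEPT_THRESHOLD = 0.05


@dataclass
class MarkerBasis:
    """Localization x fraction basis of mean marker profiles (rows sum to 1)."""

    localizations: list[str]
    matrix: np.ndarray
    mode: str = "density"
    membrane_reference: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.localizations):
            raise ValueError("basis shape does not match localization names")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("basis rows must sum to 1")
        self.condition_number = float(np.linalg.cond(self.matrix))
        if self.condition_number > 1e6:
            warnings.warn(
                f"marker basis is ill-conditioned (cond={self.condition_number:.3g})",
                stacklevel=2,
            )

    @property
    def fraction_count(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ProportionEstimate:
    """One NNLS fit: proportions, intercept, fit quality and QC verdict."""

    feature_id: str
    proportions: dict[str, float]
    intercept: float
    r_squared: float
    qc_pass: bool
    qc_reason: str = ""
    replicate: int | None = None
    condition: str | None = None
    bootstrap: pd.DataFrame | None = None


def _mean_marker_profile(
    profiles: pd.DataFrame, members: list[str], frac_cols: list[str]
) -> np.ndarray:
    sub = profiles[profiles["feature_id"].isin(members)]
    if sub.empty:
        raise ValueError("no profiles found for marker class members")
    mat = sub[frac_cols].to_numpy(dtype=float)
    sums = mat.sum(axis=1, keepdims=True)
    mat = mat[sums[:, 0] > 0] / sums[sums[:, 0] > 0]
    return mat.mean(axis=0)


def build_marker_basis(
    profiles: ProfileTable | pd.DataFrame,
    markers: dict[str, list[str]],
    mode: str = "density",
    er_class: str = "er",
    mitochondria_class: str = "mitochondria",
    membrane_label: str = "membrane",
) -> MarkerBasis:
    """Mean row-normalized marker profile per localization.

    In ``density`` mode the ER class is dropped from the basis (its markers
    relocalize under UPR) and the mitochondrial class is relabeled
    ``membrane``: the 13 mitochondrially encoded mRNAs anchor 100% membrane
    localization. In ``sedimentation`` mode mitochondria and ER stay separate
    basis rows, to be summed downstream into a membrane proportion.
    """
    if mode not in ("density", "sedimentation"):
        raise ValueError(f"unknown mode {mode!r}")
    df = profiles.data if isinstance(profiles, ProfileTable) else profiles
    frac_cols = fraction_columns(df)
    classes = dict(markers)
    membrane_reference = None
    if mode == "density":
        if er_class in classes:
            classes.pop(er_class)
        if mitochondria_class in classes:
            classes[membrane_label] = classes.pop(mitochondria_class)
        if membrane_label in classes:
            membrane_reference = membrane_label
    rows = []
    names = []
    for loc, members in classes.items():
        if not members:
            raise ValueError(f"marker class {loc!r} is empty")
        prof = _mean_marker_profile(df, members, frac_cols)
        rows.append(prof / prof.sum())
        names.append(loc)
    return MarkerBasis(names, np.vstack(rows), mode=mode,
                       membrane_reference=membrane_reference)


def _nnls_fit(x: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Solve min ||x - (B^T p + c 1)||^2, p >= 0, c free. Returns (p, c, R^2)."""
    n_frac = x.size
    ones = np.ones((n_frac, 1))
    design = np.hstack([basis.T, ones, -ones])
    coef, _ = nnls(design, x)
    p = coef[:-2]
    c = coef[-2] - coef[-1]
    fitted = design @ coef
    ss_res = float(np.sum((x - fitted) ** 2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return p, c, r2


def estimate_proportions(
    profile_row: np.ndarray,
    basis: MarkerBasis,
    feature_id: str = "",
    replicate: int | None = None,
    condition: str | None = None,
) -> ProportionEstimate:
    """NNLS fit of one row-normalized profile against the marker basis."""
    x = np.asarray(profile_row, dtype=float)
    if x.size != basis.fraction_count:
        raise ValueError("profile length does not match basis fraction count")
    if np.all(x == 0):
        raise ValueError("cannot deconvolve an all-zero profile")
    p, c, r2 = _nnls_fit(x, basis.matrix)
    reasons = []
    if r2 < R2_THRESHOLD:
        reasons.append(f"r_squared {r2:.3f} < {R2_THRESHOLD}")
    if abs(c) > INTERCEPT_THRESHOLD:
        reasons.append(f"|intercept| {abs(c):.3f} > {INTERCEPT_THRESHOLD}")
    return ProportionEstimate(
        feature_id=feature_id,
        proportions=dict(zip(basis.localizations, p)),
        intercept=c,
        r_squared=r2,
        qc_pass=not reasons,
        qc_reason="; ".join(reasons),
        replicate=replicate,
        condition=condition,
    )


def bootstrap_proportions(
    profile_row: np.ndarray,
    profiles: ProfileTable | pd.DataFrame,
    markers: dict[str, list[str]],
    B: int = 100,
    seed: int = 0,
    mode: str = "density",
    **basis_kwargs,
) -> pd.DataFrame:
    """Bootstrap the fit by resampling each marker class with replacement.

    Each of the B resamples redraws every class's members (same size, with
    replacement), rebuilds the mean-profile basis, and re-estimates the
    proportions. Returns per-localization mean and 2.5/97.5 percentile bounds.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    df = profiles.data if isinstance(profiles, ProfileTable) else profiles
    samples = []
    for _ in range(B):
        resampled = {
            loc: list(rng.choice(members, size=len(members), replace=True))
            for loc, members in markers.items()
        }
        basis = build_marker_basis(df, resampled, mode=mode, **basis_kwargs)
        est = estimate_proportions(profile_row, basis)
        samples.append([est.proportions[l] for l in basis.localizations])
        localizations = basis.localizations
    arr = np.asarray(samples)
    return pd.DataFrame({
        "localization": localizations,
        "boot_mean": arr.mean(axis=0),
        "boot_lower": np.percentile(arr, 2.5, axis=0),
        "boot_upper": np.percentile(arr, 97.5, axis=0),
    })


def deconvolve_table(
    table: ProfileTable,
    basis: MarkerBasis,
    feature_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-row NNLS fits for every feature x condition x replicate profile."""
    if table.state != "row_normalized":
        raise ValueError("deconvolve_table expects a row_normalized table")
    df = table.data
    if feature_subset is not None:
        df = df[df["feature_id"].isin(feature_subset)]
    frac_cols = fraction_columns(df)
    mat = df[frac_cols].to_numpy(dtype=float)
    out = []
    for i, (_, meta) in enumerate(df[["feature_id", "condition",
                                      "replicate"]].iterrows()):
        est = estimate_proportions(mat[i], basis, feature_id=meta["feature_id"],
                                   replicate=meta["replicate"],
                                   condition=meta["condition"])
        out.append({
            "feature_id": est.feature_id,
            "condition": est.condition,
            "replicate": est.replicate,
            "intercept": est.intercept,
            "r_squared": est.r_squared,
            "qc_pass": est.qc_pass,
            **est.proportions,
        })
    return pd.DataFrame(out)


def average_replicates(
    estimates: pd.DataFrame,
    localizations: list[str],
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Mean proportions across QC-passing replicates per feature x condition.

    Features with fewer than ``min_replicates`` passing replicates in a
    condition are dropped (the 2-of-3 rule by default).
    """
    passing = estimates[estimates["qc_pass"]]
    grouped = passing.groupby(["feature_id", "condition"])
    rows = []
    n_dropped = 0
    for (fid, cond), sub in grouped:
        if len(sub) < min_replicates:
            n_dropped += 1
            continue
        rows.append({
            "feature_id": fid,
            "condition": cond,
            "replicates_used": len(sub),
            **{l: sub[l].mean() for l in localizations},
        })
    if n_dropped:
        logger.info("average_replicates: dropped %d feature/conditions below "
                    "the %d-replicate minimum", n_dropped, min_replicates)
    return pd.DataFrame(rows)


def normalize_proportions(
    table: pd.DataFrame, localizations: list[str]
) -> pd.DataFrame:
    """Sum-to-one view of the proportions (for ternary-style displays)."""
    out = table.copy()
    total = out[localizations].sum(axis=1)
    out[localizations] = out[localizations].div(total, axis=0)
    return out


def relocalization_delta(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    localization: str,
) -> pd.Series:
    """Per-feature proportion change (condition b minus condition a)."""
    a = table_a.set_index("feature_id")[localization]
    b = table_b.set_index("feature_id")[localization]
    common = a.index.intersection(b.index)
    n_missing = len(a.index.union(b.index)) - len(common)
    if n_missing:
        logger.info("relocalization_delta: %d features absent from one "
                    "condition were excluded", n_missing)
    return (b.loc[common] - a.loc[common]).rename(f"delta_{localization}")


def proportion_to_enrichment(p: float | np.ndarray) -> float | np.ndarray:
    """log2 odds of a proportion: log2(p / (1 - p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("proportions must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        out = np.log2(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
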