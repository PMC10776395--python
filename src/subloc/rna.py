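"""Fraction-profile normalization for gradient RNA-seq.

The quantitative object throughout the package is the :class:`ProfileTable`:
per-feature abundances across the gradient fractions of one experiment, with
replicate and condition metadata. Raw per-fraction libraries are sequenced to
arbitrary depth, so relative quantifications (TPM/CPM) say nothing about how
much RNA each fraction actually held. Spike-ins added at a fixed absolute
amount per fraction recover the per-fraction RNA content, which is used to
re-weight the relative quantifications before row-sum normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("feature_id", "biotype", "condition", "replicate")


def fraction_columns(df: pd.DataFrame) -> list[str]:
    """Names of the ``fraction_*`` columns, in gradient order."""
    cols = [c for c in df.columns if c.startswith("fraction_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


@dataclass
class ProfileTable:
    """Feature x fraction abundance table with replicate/condition metadata.

    ``state`` tracks normalization: ``raw`` (TPM/CPM scale),
    ``content_adjusted`` (re-weighted by per-fraction RNA content) or
    ``row_normalized`` (each feature x replicate row sums to 1).
    """

    data: pd.DataFrame
    level: str = "transcript"
    state: str = "raw"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ProfileTable missing metadata columns: {missing}")
        if not self.fraction_cols:
            raise ValueError("ProfileTable has no fraction_* columns")
        mat = self.data[self.fraction_cols].to_numpy()
        if np.any(mat < -1e-12):
            raise ValueError("abundances must be non-negative")

    @property
    def fraction_cols(self) -> list[str]:
        return fraction_columns(self.data)

    @property
    def fraction_count(self) -> int:
        return len(self.fraction_cols)

    def matrix(self) -> np.ndarray:
        return self.data[self.fraction_cols].to_numpy(dtype=float)

    def copy(self) -> "ProfileTable":
        return ProfileTable(self.data.copy(), level=self.level, state=self.state)


@dataclass
class SpikeInSet:
    """Spike-in feature ids plus the share of each fraction used for library prep."""

    ids: frozenset[str]
    proportion_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)
        if self.proportion_used is not None:
            p = np.asarray(self.proportion_used, dtype=float)
            if np.any((p <= 0) | (p > 1)):
                raise ValueError("proportion_used must lie in (0, 1]")
            self.proportion_used = p


@dataclass
class GradientFraction:
    """One gradient fraction: refractometer reading, iodixanol %, density."""

    index: int
    refractive_index: float | None = None
    iodixanol_percent: float | None = field(default=None)
    density: float | None = None

    def __post_init__(self) -> None:
        if self.refractive_index is not None and self.iodixanol_percent is None:
            self.iodixanol_percent = iodixanol_from_refractive_index(
                self.refractive_index
            )
        if self.density is not None and self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class FilterConfig:
    """Expression and annotation filter thresholds.

    Defaults follow the density-gradient design: mean TPM < 0.5 or zero TPM in
    at least two thirds of a condition's samples discards a feature. The
    sedimentation design uses CPM < 1 and a 20% zero share. lncRNAs with a
    protein-coding neighbor within 15 kb downstream or 30 kb upstream are
    excluded because read bridging corrupts their profiles.
    """

    min_mean_abundance: float = 0.5
    max_zero_share: float = 2.0 / 3.0
    downstream_window: int = 15_000
    upstream_window: int = 30_000

    def __post_init__(self) -> None:
        if self.min_mean_abundance <= 0:
            raise ValueError("min_mean_abundance must be positive")
        if not 0 < self.max_zero_share <= 1:
            raise ValueError("max_zero_share must be in (0, 1]")


SEDIMENTATION_FILTERS = FilterConfig(min_mean_abundance=1.0, max_zero_share=0.2)


def read_gene_annotation(path: str) -> pd.DataFrame:
    """Load a GFF3 into the gene table used for neighbor exclusion.

    Returns one row per gene: gene_id, chromosome, strand, start, end,
    biotype (from the ``gene_biotype``/``biotype`` attribute). Start/end are
    converted to 0-based half-open coordinates.
    """
    import pyranges as pr

    gr = pr.read_gff3(path).df
    genes = gr[gr["Feature"] == "gene"]
    biotype_col = next(
        (c for c in ("gene_biotype", "biotype", "gene_type")
         if c in genes.columns),
        None,
    )
    if biotype_col is None:
        raise ValueError("GFF3 lacks a gene biotype attribute")
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "chromosome": genes["Chromosome"].astype(str).to_numpy(),
        "strand": genes["Strand"].astype(str).to_numpy(),
        "start": genes["Start"].to_numpy(),
        "end": genes["End"].to_numpy(),
        "biotype": genes[biotype_col].to_numpy(),
    })


def iodixanol_from_refractive_index(ri: float) -> float:
    """Convert a refractometer scale reading to iodixanol % (w/v).

    Uses the affine calibration iodixanol% = RI/0.83 - 10.111. Note the
    formula zeroes near a scale reading of 8.39, not near the physical
    refractive index of water (~1.334): the reading is an instrument scale
    value, and the formula is applied exactly as calibrated.
    """
    ri = float(ri)
    if not np.isfinite(ri) or ri <= 0:
        raise ValueError(f"refractive index must be finite and positive, got {ri}")
    return ri / 0.83 - 10.111


def estimate_fraction_content(
    table: pd.DataFrame | ProfileTable,
    spikeins: SpikeInSet,
) -> np.ndarray:
    """Per-fraction RNA content from spike-in ratios, normalized to sum 1.

    content_f is proportional to (endogenous_total_f / spikein_total_f)
    divided by the proportion of fraction f used for library preparation:
    spike-ins enter each fraction at the same absolute amount, so the
    endogenous:spike-in ratio measures how much RNA the fraction held.
    The ratio is invariant to the sequencing depth of each fraction library.
    """
    df = table.data if isinstance(table, ProfileTable) else table
    cols = fraction_columns(df)
    is_spike = df["feature_id"].isin(spikeins.ids).to_numpy()
    if not is_spike.any():
        raise ValueError("no spike-in features found in table")
    mat = df[cols].to_numpy(dtype=float)
    spike_tot = mat[is_spike].sum(axis=0)
    endo_tot = mat[~is_spike].sum(axis=0)
    zero = np.flatnonzero(spike_tot <= 0)
    if zero.size:
        raise ValueError(
            f"zero spike-in signal in fraction(s): {[cols[i] for i in zero]}"
        )
    content = endo_tot / spike_tot
    if spikeins.proportion_used is not None:
        if len(spikeins.proportion_used) != len(cols):
            raise ValueError("proportion_used length does not match fraction count")
        content = content / spikeins.proportion_used
    return content / content.sum()


def estimate_content_by_sample(
    table: ProfileTable, spikeins: SpikeInSet
) -> pd.DataFrame:
    """Content vectors estimated separately for every condition x replicate."""
    rows = []
    cols = table.fraction_cols
    for (cond, rep), sub in table.data.groupby(["condition", "replicate"]):
        content = estimate_fraction_content(sub, spikeins)
        rows.append({"condition": cond, "replicate": rep,
                     **dict(zip(cols, content))})
    return pd.DataFrame(rows)


def rescale_to_endogenous(table: ProfileTable, spikeins: SpikeInSet) -> ProfileTable:
    """Drop spike-in rows and re-express each library on endogenous features.

    TPM denominators include the spike-ins; once the content vector has been
    estimated from them, quantifications are re-scaled so each fraction
    library's endogenous total is 1e6. Content adjustment then recovers
    absolute per-fraction abundances exactly rather than up to the per-library
    spike-in share.
    """
    df = table.data[~table.data["feature_id"].isin(spikeins.ids)].copy()
    cols = fraction_columns(df)
    for _, idx in df.groupby(["condition", "replicate"]).groups.items():
        sub = df.loc[idx, cols].to_numpy(dtype=float)
        totals = sub.sum(axis=0)
        totals[totals == 0] = 1.0
        df.loc[idx, cols] = sub / totals * 1e6
    return ProfileTable(df.reset_index(drop=True), level=table.level,
                        state=table.state)


def normalize_profiles(
    table: ProfileTable,
    content: np.ndarray | pd.DataFrame,
    drop_spikeins: Iterable[str] = (),
) -> ProfileTable:
    """Content-adjust then row-sum normalize each feature x replicate profile.

    Each abundance is multiplied by its fraction's RNA content (a single
    vector, or a per-sample frame from :func:`estimate_content_by_sample`),
    then every row is divided by its sum so the profile reads as the share of
    the feature's molecules in each fraction. All-zero rows are dropped.
    """
    if table.state != "raw":
        raise ValueError(f"expected a raw-state table, got state={table.state!r}")
    df = table.data.copy()
    spike_ids = frozenset(drop_spikeins)
    if spike_ids:
        df = df[~df["feature_id"].isin(spike_ids)].reset_index(drop=True)
    cols = fraction_columns(df)
    mat = df[cols].to_numpy(dtype=float)

    if isinstance(content, pd.DataFrame):
        for (cond, rep), idx in df.groupby(["condition", "replicate"]).groups.items():
            sel = (content["condition"] == cond) & (content["replicate"] == rep)
            if not sel.any():
                raise ValueError(f"no content vector for sample ({cond}, {rep})")
            vec = content.loc[sel, cols].to_numpy(dtype=float)[0]
            if np.any(vec < 0):
                raise ValueError("content must be non-negative")
            mat[df.index.get_indexer(idx)] *= vec
    else:
        vec = np.asarray(content, dtype=float)
        if np.any(vec < 0):
            raise ValueError("content must be non-negative")
        if vec.size != len(cols):
            raise ValueError("content length does not match fraction count")
        mat = mat * vec

    sums = mat.sum(axis=1)
    keep = sums > 0
    if (~keep).any():
        logger.info("normalize_profiles: dropped %d all-zero rows", int((~keep).sum()))
    mat = mat[keep] / sums[keep, None]
    out = df.loc[keep].reset_index(drop=True)
    out[cols] = mat
    return ProfileTable(out, level=table.level, state="row_normalized")


def filter_low_abundance(
    table: ProfileTable,
    config: FilterConfig,
    condition: str,
    sample_totals: pd.DataFrame | None = None,
) -> tuple[ProfileTable, pd.DataFrame]:
    """Discard features with low or sporadic expression in ``condition``.

    A feature's per-sample abundance is its summed TPM across fractions of
    each replicate library set (or ``sample_totals`` if per-sample totals are
    supplied directly: feature_id x sample columns). A feature fails if its
    mean across samples is below ``min_mean_abundance`` or it is zero in at
    least ``max_zero_share`` of samples. Returns the filtered table and a
    per-rule removal report.
    """
    df = table.data
    if sample_totals is None:
        cols = fraction_columns(df)
        sub = df[df["condition"] == condition]
        totals = (
            sub.assign(total=sub[cols].sum(axis=1))
            .pivot_table(index="feature_id", columns="replicate", values="total",
                         aggfunc="sum", fill_value=0.0)
        )
    else:
        totals = sample_totals.set_index("feature_id") \
            if "feature_id" in sample_totals.columns else sample_totals
    mean_ok = totals.mean(axis=1) >= config.min_mean_abundance
    zero_share = (totals == 0).mean(axis=1)
    zeros_ok = zero_share < config.max_zero_share
    keep_ids = set(totals.index[mean_ok & zeros_ok])
    report = pd.DataFrame(
        {
            "rule": ["low_mean", "zero_share"],
            "n_removed": [int((~mean_ok).sum()), int((~zeros_ok).sum())],
        }
    )
    out = df[df["feature_id"].isin(keep_ids) | (df["condition"] != condition)]
    if out.empty:
        warnings.warn("filter_low_abundance removed every feature", stacklevel=2)
    return (
        ProfileTable(out.reset_index(drop=True), level=table.level, state=table.state),
        report,
    )


def exclude_neighbor_lncrnas(
    feature_list: Sequence[str],
    gene_annotation: pd.DataFrame,
    downstream_window: int = 15_000,
    upstream_window: int = 30_000,
) -> list[str]:
    """Drop lncRNAs with a protein-coding gene close enough to bridge reads.

    ``gene_annotation`` needs columns gene_id, chromosome, strand, start, end,
    biotype (0-based half-open intervals). A lncRNA is removed when the gap to
    the nearest protein-coding gene edge is at most ``downstream_window``
    downstream or ``upstream_window`` upstream, with orientation taken from
    the lncRNA's strand. Overlapping genes (gap 0) always trigger removal.
    Non-lncRNA features pass through untouched.
    """
    ann = gene_annotation.set_index("gene_id") \
        if "gene_id" in gene_annotation.columns else gene_annotation
    if ann["strand"].isna().any():
        raise ValueError("gene annotation has missing strand values")
    pc = ann[ann["biotype"] == "protein_coding"]
    keep: list[str] = []
    for fid in feature_list:
        if fid not in ann.index or ann.at[fid, "biotype"] != "lncRNA":
            keep.append(fid)
            continue
        row = ann.loc[fid]
        near = pc[pc["chromosome"] == row["chromosome"]]
        excluded = False
        for _, g in near.iterrows():
            if g["end"] <= row["start"]:
                gap = row["start"] - g["end"]
                side = "upstream" if row["strand"] == "+" else "downstream"
            elif g["start"] >= row["end"]:
                gap = g["start"] - row["end"]
                side = "downstream" if row["strand"] == "+" else "upstream"
            else:
                excluded = True  # overlap
                break
            window = downstream_window if side == "downstream" else upstream_window
            if gap <= window:
                excluded = True
                break
        if not excluded:
            keep.append(fid)
    return keep
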