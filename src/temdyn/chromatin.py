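"""Associating siRNA output with chromatin state.

Groups long heterochromatic TEs by nucleosome-occupancy profile shape
(k-means, groups renumbered by descending mean occupancy so group 1 is
the most nucleosome-dense), ranks TEs into percentiles by their siRNA
output in a mutant, computes length-normalized heterochromatic vs
euchromatic siRNA enrichment, TE-family observed/expected enrichment on
DMRs (Fisher's exact), and the small comparison statistics used
throughout (Mann-Whitney U, z-scores, Pearson correlation tables).
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .sirna import ProfileMatrix

logger = logging.getLogger(__name__)


class ChromatinError(ValueError):
    """Raised for invalid chromatin-association inputs."""


# ---------------------------------------------------------------------------
# nucleosome profile groups
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    region_ids: list[str]
    group: np.ndarray          # 1-based, 1 = highest mean occupancy
    inertia: float
    group_means: np.ndarray    # per-group mean occupancy, descending


def kmeans_profiles(
    matrix: ProfileMatrix,
    k: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
) -> GroupAssignment:
    """Best-of-restarts k-means on profile rows, relabeled by occupancy.

    Regions with all-zero signal must be removed beforehand (they are
    rejected here). Groups are renumbered so group 1 has the highest
    mean signal, matching the field's "group 1 = dense nucleosomes"
    convention.
    """
    X = np.asarray(matrix.values, dtype=float)
    if k > X.shape[0]:
        raise ChromatinError(f"k={k} exceeds number of regions {X.shape[0]}")
    if (X.sum(axis=1) == 0).any():
        raise ChromatinError("remove all-zero regions before clustering")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    if len(np.unique(raw)) < k:
        logger.warning("k-means produced an empty cluster (identical rows?)")
    means = np.array([
        X[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)
    ])
    order = np.argsort(means)[::-1]          # descending occupancy
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return GroupAssignment(
        region_ids=list(matrix.region_ids),
        group=relabel[raw],
        inertia=float(km.inertia_),
        group_means=means[order],
    )


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    ratio: float | None
    het_rpm: float
    eu_rpm: float
    het_bp: int
    eu_bp: int
    statistic: float | None = None
    p_value: float | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def enrichment_het_vs_eu(
    quant: pd.Series,
    labels: pd.Series,
    lengths: pd.Series,
) -> EnrichmentResult:
    """Length-normalized heterochromatic (class B) vs euchromatic
    (class A) 24-nt siRNA enrichment for one sample:

        (sum RPM over B / sum bp of B) / (sum RPM over A / sum bp of A)
    """
    idx = quant.index
    het = labels.reindex(idx) == "B"
    eu = labels.reindex(idx) == "A"
    het_bp = int(lengths.reindex(idx)[het].sum())
    eu_bp = int(lengths.reindex(idx)[eu].sum())
    if het_bp == 0 or eu_bp == 0:
        raise ChromatinError("both classes must be non-empty with positive total length")
    het_rpm = float(quant[het].sum())
    eu_rpm = float(quant[eu].sum())
    eu_density = eu_rpm / eu_bp
    if eu_density == 0:
        logger.warning("euchromatic density is zero; enrichment undefined")
        return EnrichmentResult(None, het_rpm, eu_rpm, het_bp, eu_bp)
    return EnrichmentResult((het_rpm / het_bp) / eu_density, het_rpm, eu_rpm, het_bp, eu_bp)


def enrichment_series(
    quant_reps: pd.DataFrame,
    labels: pd.Series,
    lengths: pd.Series,
) -> pd.DataFrame:
    """Replicate-level enrichment per (sample, replicate) column, plus
    Welch's t is left to the caller on these replicate values."""
    rows = []
    for col in quant_reps.columns:
        res = enrichment_het_vs_eu(quant_reps[col], labels, lengths)
        sample, rep = col if isinstance(col, tuple) else (col, 0)
        rows.append({"sample": sample, "replicate": rep, "ratio": res.ratio})
    return pd.DataFrame(rows)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sample t on replicate-level enrichment values."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def family_enrichment(
    dmr_te_ids: set[str] | list[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-family log2 observed/expected enrichment among DMR-overlapping
    TEs, with a two-sided Fisher's exact test on the 2x2 overlap table.

    O = fraction of DMR-overlapping TEs in the family; E = the family's
    fraction of all annotated TEs. A family absent from the overlapping
    set reports log2_oe = NaN (sentinel), with the p-value still given.
    """
    overlapping = set(dmr_te_ids)
    total = len(annotation)
    n_overlap = annotation["te_id"].isin(overlapping).sum()
    if total == 0 or n_overlap == 0:
        raise ChromatinError("no TEs / no DMR-overlapping TEs")
    rows = []
    for fam, sub in annotation.groupby("family", sort=True):
        fam_total = len(sub)
        fam_overlap = sub["te_id"].isin(overlapping).sum()
        observed = fam_overlap / n_overlap
        expected = fam_total / total
        log2_oe = math.log2(observed / expected) if observed > 0 else np.nan
        table = [
            [fam_overlap, fam_total - fam_overlap],
            [n_overlap - fam_overlap, (total - fam_total) - (n_overlap - fam_overlap)],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"family": fam, "n_in_family": fam_total,
                     "n_overlapping": fam_overlap, "observed": observed,
                     "expected": expected, "log2_oe": log2_oe, "p_value": float(p)})
    return pd.DataFrame(rows).set_index("family")


def overlapping_te_ids(dmrs: pd.DataFrame, annotation: pd.DataFrame) -> set[str]:
    """TE ids whose interval overlaps any DMR interval (>= 1 bp)."""
    hit = set()
    for chrom, sub in dmrs.groupby("chrom"):
        tes = annotation[annotation["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            m = (tes["start"] < e) & (tes["end"] > s)
            hit.update(tes.loc[m, "te_id"])
    return hit


# ---------------------------------------------------------------------------
# percentile ranking
# ---------------------------------------------------------------------------

def percentile_rank_overlay(
    quant_mutant: pd.Series,
    labels: pd.Series,
    tracks: dict[str, pd.Series] | None = None,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Rank TEs by mutant siRNA level, cut into equal-count percentile
    bins (ties broken by stable te_id order), and summarize each bin's
    class composition and mean per-TE track values."""
    tracks = tracks or {}
    df = pd.DataFrame({"rpm": quant_mutant}).sort_index(kind="stable")
    df = df.sort_values("rpm", kind="stable")
    if n_bins > len(df):
        raise ChromatinError("more bins than TEs")
    splits = np.array_split(np.arange(len(df)), n_bins)
    rows = []
    lab = labels.reindex(df.index)
    for b, idx in enumerate(splits):
        ids = df.index[idx]
        sub = lab.loc[ids]
        row = {"bin": b, "n": len(ids), "mean_rpm": float(df["rpm"].iloc[idx].mean())}
        for cls in ("A", "B", "depleted"):
            row[f"frac_{cls}"] = float((sub == cls).mean())
        for name, tr in tracks.items():
            row[f"mean_{name}"] = float(tr.reindex(ids).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact by enumeration of all C(n+m, n) group assignments when
    n + m <= 12 (ties handled with half counts); normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ChromatinError("both samples must be non-empty")
    n, m = len(a), len(b)

    def u_of(x, y):
        gt = (x[:, None] > y[None, :]).sum()
        eq = (x[:, None] == y[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = float(u_of(a, b))
    if n + m <= 12:
        pooled = np.concatenate([a, b])
        us = []
        for comb in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            us.append(u_of(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        lo = (us <= u_obs + 1e-12).mean()
        hi = (us >= u_obs - 1e-12).mean()
        return u_obs, float(min(1.0, 2.0 * min(lo, hi)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def zscore_series(values) -> tuple[np.ndarray, bool]:
    """Sample-sd z-scores; a constant series returns zeros with a flag."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ChromatinError("need >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("constant series: z-scores undefined, returning zeros")
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def pearson_matrix(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between rows of X and rows of Y over matched
    sample columns; zero-variance rows give NaN."""
    cols = [c for c in X.columns if c in Y.columns]
    if len(cols) < 2:
        raise ChromatinError("need >= 2 matched sample columns")
    Xa = X[cols].to_numpy(dtype=float)
    Ya = Y[cols].to_numpy(dtype=float)
    out = np.full((len(X), len(Y)), np.nan)
    for i in range(len(X)):
        for j in range(len(Y)):
            if Xa[i].std() > 0 and Ya[j].std() > 0:
                out[i, j] = np.corrcoef(Xa[i], Ya[j])[0, 1]
    return pd.DataFrame(out, index=X.index, columns=Y.index)
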