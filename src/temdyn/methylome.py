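"""Weighted methylation, RMS differential-methylation testing, DMRs.

Methylation levels are always coverage-weighted (sum of methylated read
counts over sum of total read counts), never means of per-site ratios.
Differentially methylated sites (DMSs) between pooled samples are found
with a root-mean-square goodness-of-fit statistic on the 2 x S table of
(methylated, unmethylated) counts, with a Monte-Carlo null resampled
from the pooled proportion and an add-one-corrected p-value, followed by
Benjamini-Hochberg FDR control. Significant sites within 100 bp are
chained into regions, which survive only with >= 4 DMSs and a weighted
CHH methylation difference of >= 20 percentage points.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

logger = logging.getLogger(__name__)

PURINES_W = ("A", "T")


class MethylationError(ValueError):
    """Raised for invalid methylome inputs."""


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def context_from_tri(tri: str) -> tuple[str, str]:
    """(context, subcontext) from a strand-oriented 5'->3' trinucleotide.

    CG if the next base is G; CHG if the base after next is G; CHH
    otherwise. CHH splits into CWA (C-[A/T]-A, the CMT2-preferred motif)
    and nonCWA.
    """
    if len(tri) != 3 or tri[0] != "C":
        raise MethylationError(f"not a cytosine trinucleotide: {tri!r}")
    if tri[1] == "G":
        return "CG", "n/a"
    if tri[2] == "G":
        return "CHG", "n/a"
    sub = "CWA" if tri[1] in PURINES_W and tri[2] == "A" else "nonCWA"
    return "CHH", sub


def classify_context(sequence: str, pos: int, strand: str) -> tuple[str, str]:
    """Context of the cytosine at 0-based ``pos`` on ``strand``.

    The two downstream bases are read 5'->3' on the site's own strand
    (reverse complement for minus-strand sites). A site within 2 bp of
    its strand's 3' end has no defined context; it is reported as
    ("undefined", "n/a") and should be skipped by callers.
    """
    if strand == "+":
        if pos > len(sequence) - 3:
            logger.info("skipping site %d: too close to 3' end", pos)
            return "undefined", "n/a"
        tri = sequence[pos:pos + 3]
    elif strand == "-":
        if pos < 2:
            logger.info("skipping site %d: too close to 3' end", pos)
            return "undefined", "n/a"
        tri = "".join(_COMP[b] for b in sequence[pos - 2:pos + 1][::-1])
    else:
        raise MethylationError(f"bad strand {strand!r}")
    if tri[0] != "C":
        raise MethylationError(f"no cytosine at position {pos} on strand {strand}")
    return context_from_tri(tri)


# ---------------------------------------------------------------------------
# weighted methylation
# ---------------------------------------------------------------------------

def weighted_methylation(
    sites: pd.DataFrame,
    region: tuple[str, int, int] | None = None,
    context: str | None = None,
    subcontext: str | None = None,
) -> float | None:
    """Coverage-weighted methylation rate over qualifying sites.

    ``region`` is (chrom, start, end), 0-based half-open over 1-based
    site positions. Returns None (an explicit "no data" result) when no
    covered site qualifies.
    """
    sel = sites
    if region is not None:
        chrom, start, end = region
        sel = sel[(sel["chrom"] == chrom) & (sel["pos"] > start) & (sel["pos"] <= end)]
    if context is not None:
        sel = sel[sel["context"] == context]
    if subcontext is not None:
        sel = sel[sel["subcontext"] == subcontext]
    total = sel["cov"].sum()
    if total == 0:
        return None
    return float(sel["mc"].sum() / total)


def conversion_rate(control_sites: pd.DataFrame) -> float:
    """Bisulfite conversion percentage from an unmethylated control:
    100 * (1 - sum(mc) / sum(cov))."""
    total = control_sites["cov"].sum()
    if total == 0:
        raise MethylationError("no coverage on conversion control")
    return 100.0 * (1.0 - control_sites["mc"].sum() / total)


def pool_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum mc and cov per site across replicate tables."""
    cat = pd.concat(replicates, ignore_index=True)
    keys = ["chrom", "pos", "strand", "tri", "context", "subcontext"]
    return cat.groupby(keys, as_index=False, sort=True)[["mc", "cov"]].sum()


def make_comparison(samples: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-sample (mc, cov) on sites covered in every sample.

    Output columns: site keys plus mc_<sample>, cov_<sample>.
    """
    if len(samples) < 2:
        raise MethylationError("a comparison needs >= 2 samples")
    keys = ["chrom", "pos", "strand", "context", "subcontext"]
    merged: pd.DataFrame | None = None
    for name, df in samples.items():
        part = df[keys + ["mc", "cov"]].rename(columns={"mc": f"mc_{name}", "cov": f"cov_{name}"})
        merged = part if merged is None else merged.merge(part, on=keys, how="inner")
    return merged.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# RMS test
# ---------------------------------------------------------------------------

def _rms_stat(mc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Root-mean-square of (observed - expected)/N over 2 x S cells.

    Rows may be batched: mc, cov of shape (n, S).
    """
    mc = np.atleast_2d(mc).astype(float)
    cov = np.atleast_2d(cov).astype(float)
    N = cov.sum(axis=1, keepdims=True)
    p = mc.sum(axis=1, keepdims=True) / N
    exp_m = p * cov
    exp_u = (1 - p) * cov
    dev = np.concatenate([(mc - exp_m) / N, ((cov - mc) - exp_u) / N], axis=1)
    return np.sqrt((dev ** 2).mean(axis=1))


def rms_test(
    mc, cov, n_sim: int = 3000, seed: int = 0
) -> tuple[float, float]:
    """RMS homogeneity test for one site across S pooled samples.

    The null resamples each sample's methylated count from
    Binomial(cov_s, pooled proportion); p = (b + 1) / (n_sim + 1) where
    b counts null statistics >= the observed one.
    """
    mc = np.asarray(mc, dtype=int)
    cov = np.asarray(cov, dtype=int)
    if mc.ndim != 1 or len(mc) < 2:
        raise MethylationError("rms_test needs >= 2 samples")
    if (cov <= 0).any():
        raise MethylationError("all samples must have coverage > 0")
    if (mc > cov).any() or (mc < 0).any():
        raise MethylationError("require 0 <= mc <= cov")
    obs = float(_rms_stat(mc, cov)[0])
    if obs == 0.0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    p_pool = mc.sum() / cov.sum()
    sim_mc = rng.binomial(cov, p_pool, size=(n_sim, len(cov)))
    stats = _rms_stat(sim_mc, np.broadcast_to(cov, sim_mc.shape))
    b = int((stats >= obs - 1e-15).sum())
    return obs, (b + 1) / (n_sim + 1)


def rms_null_enumeration(mc, cov) -> tuple[float, float]:
    """Exact null tail probability by enumerating all tables with the
    observed per-sample coverages under the pooled binomial null.
    Oracle for small tables; O(prod(cov+1))."""
    from scipy.stats import binom

    mc = np.asarray(mc, dtype=int)
    cov = np.asarray(cov, dtype=int)
    obs = float(_rms_stat(mc, cov)[0])
    p_pool = mc.sum() / cov.sum()
    grids = [np.arange(c + 1) for c in cov]
    total = 0.0
    for combo in itertools.product(*grids):
        combo = np.array(combo)
        stat = float(_rms_stat(combo, cov)[0])
        if stat >= obs - 1e-15:
            prob = np.prod([binom.pmf(m, c, p_pool) for m, c in zip(combo, cov)])
            total += float(prob)
    return obs, total


#: A site stops refining once this many null exceedances were observed;
#: its p-value estimate is then already accurate in relative terms.
_LADDER_MIN_HITS = 10


def _mc_pvalues_batch(mc: np.ndarray, cov: np.ndarray, n_sim: int, seed: int) -> np.ndarray:
    """Monte-Carlo RMS p-values for many sites, sequentially refined.

    Simulation counts climb a ladder (300, 3000, 30000, ..., n_sim);
    a site keeps climbing only while fewer than 10 null statistics at
    least as extreme as its observed one have been seen, so clearly
    null sites exit cheaply with a conservative interim p while
    candidate DMSs get the full ``n_sim`` resolution.
    """
    n = len(mc)
    pvals = np.ones(n)
    obs = _rms_stat(mc, cov)
    active = obs > 0
    if not active.any():
        return pvals
    rng = np.random.default_rng(seed)
    p_pool = mc.sum(axis=1) / cov.sum(axis=1)

    def run(idx: np.ndarray, nsims: int) -> np.ndarray:
        b = np.zeros(len(idx), dtype=int)
        chunk = max(1, int(2e6 // max(nsims, 1)))
        for lo in range(0, len(idx), chunk):
            sub = idx[lo:lo + chunk]
            draws = rng.binomial(
                cov[sub][:, None, :], p_pool[sub][:, None, None],
                size=(len(sub), nsims, cov.shape[1]),
            )
            stats = _rms_stat(
                draws.reshape(-1, cov.shape[1]),
                np.repeat(cov[sub], nsims, axis=0),
            ).reshape(len(sub), nsims)
            b[lo:lo + chunk] = (stats >= obs[sub][:, None] - 1e-15).sum(axis=1)
        return b

    ladder = [s for s in (300, 3000, 30000, 300000) if s < n_sim] + [n_sim]
    idx = np.flatnonzero(active)
    hits = np.zeros(len(idx), dtype=int)
    done_sims = 0
    for target in ladder:
        batch = target - done_sims
        live = hits < _LADDER_MIN_HITS
        if batch <= 0 or not live.any():
            continue
        hits[live] += run(idx[live], batch)
        done_sims = target
        pvals[idx[live]] = (hits[live] + 1) / (target + 1)
    return pvals


def call_dms(
    comparison: pd.DataFrame,
    samples: list[str],
    fdr: float = 0.01,
    min_cov: dict[str, int] | None = None,
    n_sim: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Differentially methylated sites at BH FDR <= ``fdr``.

    Coverage filtering happens per sample before any testing: the
    default floor is 4 overlapping reads, 3 for preglobular ("pg").
    Returns the tested table with statistic, p, q and a ``dms`` flag.
    """
    if comparison.empty:
        return comparison.assign(statistic=[], p_value=[], q_value=[], dms=[])
    from .config import RunConfig

    rc = RunConfig()
    if min_cov is None:
        min_cov = {s: rc.min_cov(s) for s in samples}
    keep = np.ones(len(comparison), dtype=bool)
    for s in samples:
        keep &= comparison[f"cov_{s}"].to_numpy() >= min_cov.get(s, rc.min_cov_default)
    tested = comparison[keep].reset_index(drop=True)
    if tested.empty:
        return tested.assign(statistic=[], p_value=[], q_value=[], dms=[])
    mc = tested[[f"mc_{s}" for s in samples]].to_numpy(dtype=int)
    cov = tested[[f"cov_{s}" for s in samples]].to_numpy(dtype=int)
    stats = _rms_stat(mc, cov)
    pvals = _mc_pvalues_batch(mc, cov, n_sim=n_sim, seed=seed)
    qvals = false_discovery_control(pvals, method="bh")
    out = tested.assign(statistic=stats, p_value=pvals, q_value=qvals,
                        dms=qvals <= fdr)
    return out


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

def collapse_dmrs(dms: pd.DataFrame, max_gap: int = 100) -> pd.DataFrame:
    """Chain DMSs <= ``max_gap`` bp apart into regions (single linkage).

    Input needs chrom and pos (1-based) of significant sites. Output
    intervals are 0-based half-open spanning the first..last DMS.
    """
    rows = []
    for chrom, sub in dms.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].unique())
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            rows.append((chrom, int(pos[a]) - 1, int(pos[b]), int(b - a + 1)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dms"])


def filter_dmrs(
    regions: pd.DataFrame,
    comparison: pd.DataFrame,
    samples: list[str],
    min_dms: int = 4,
    min_diff_pp: float = 20.0,
    context: str = "CHH",
) -> pd.DataFrame:
    """Keep regions with >= ``min_dms`` DMSs AND a max pairwise weighted
    methylation difference of >= ``min_diff_pp`` percentage points
    between the compared samples."""
    if regions.empty:
        return regions.assign(max_diff_pp=[])
    ctx = comparison[comparison["context"] == context] if "context" in comparison.columns else comparison
    kept = []
    for _, r in regions.iterrows():
        if r["n_dms"] < min_dms:
            continue
        sel = ctx[(ctx["chrom"] == r["chrom"]) & (ctx["pos"] > r["start"]) & (ctx["pos"] <= r["end"])]
        rates = {}
        for s in samples:
            tot = sel[f"cov_{s}"].sum()
            if tot > 0:
                rates[s] = sel[f"mc_{s}"].sum() / tot
        if len(rates) < 2:
            continue
        vals = np.array(list(rates.values()))
        diff_pp = 100.0 * (vals.max() - vals.min())
        if diff_pp >= min_diff_pp:
            row = dict(r)
            row["max_diff_pp"] = diff_pp
            for s, v in rates.items():
                row[f"wmeth_{s}"] = v
            kept.append(row)
    if not kept:
        return pd.DataFrame(columns=list(regions.columns) + ["max_diff_pp"])
    return pd.DataFrame(kept).reset_index(drop=True)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals; overlapping or bookended intervals merge."""
    if intervals.empty:
        return intervals[["chrom", "start", "end"]].copy()
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        rows.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge_pairwise_dmrs(dmr_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """BEDtools-merge-style union of per-comparison DMR sets."""
    nonempty = [d[["chrom", "start", "end"]] for d in dmr_sets if len(d)]
    if not nonempty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.concat(nonempty, ignore_index=True))


def pairwise_dmr_pipeline(
    sample_sites: dict[str, pd.DataFrame],
    fdr: float = 0.01,
    max_gap: int = 100,
    min_dms: int = 4,
    min_diff_pp: float = 20.0,
    n_sim: int = 3000,
    seed: int = 0,
    context: str = "CHH",
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """CHH DMRs from all pairwise stage comparisons, merged.

    For S stages this enumerates C(S, 2) comparisons (10 for the five
    embryonic stages), calls DMSs per comparison, collapses and filters
    them, and merges the per-comparison DMRs into one interval set.
    """
    stages = list(sample_sites)
    per_comparison = []
    for i, (a, b) in enumerate(itertools.combinations(stages, 2)):
        comp = make_comparison({a: sample_sites[a], b: sample_sites[b]})
        comp = comp[comp["context"] == context].reset_index(drop=True)
        tested = call_dms(comp, [a, b], fdr=fdr, n_sim=n_sim, seed=seed + 7919 * i)
        dms = tested[tested["dms"]]
        regions = collapse_dmrs(dms, max_gap=max_gap)
        dmrs = filter_dmrs(regions, comp, [a, b], min_dms=min_dms,
                           min_diff_pp=min_diff_pp, context=context)
        per_comparison.append(dmrs)
    return merge_pairwise_dmrs(per_comparison), per_comparison
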