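"""Synthetic miniature genome with ground truth for pipeline testing.

The generator emulates the measured world of the study at desk scale: a
few hundred TEs on two small chromosomes, ten sample types x three
replicates of small-RNA libraries, per-cytosine methylomes for five
embryonic stages, and a nucleosome-occupancy track. Latent structure is
recorded as ground truth so every downstream stage can be scored:

* class A TEs: short, dispersed along chromosome arms; their 24-nt
  siRNAs are low in early embryos, rise mid-embryogenesis, and jump at
  the mature green stage, staying high in leaves and floral buds.
* class B TEs: long, concentrated in centromeric heterochromatin;
  siRNAs are already high at preglobular, peak mid-embryogenesis, and
  collapse at maturity and in post-embryonic tissues.
* siRNA-depleted TEs emit essentially no reads.
* planted CHH DMRs gain methylation along a preglobular -> mature ramp.
* long class B TEs carry one of three nucleosome archetypes: (1) high
  occupancy throughout, (2) low edges / high body, (3) low throughout.

Everything is driven by one integer seed; identical configs give
identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import METH_STAGES, STAGE_RAMP, SimConfig
from .sirna import AlignmentTable, SignalTrack

#: Relative per-stage siRNA output per class (shape-only idealizations;
#: the study prints no numeric profile). Class B's mature-green / late-heart
#: ratio is < 1 and class A's is > 1 by construction.
STAGE_TEMPLATES: dict[str, dict[str, float]] = {
    "A": {"fb": 1.00, "pg": 0.10, "gl": 0.30, "eh": 0.35, "lh": 0.40,
          "et": 0.40, "lt": 0.45, "bc": 0.50, "mg": 1.00, "lf": 1.00},
    "B": {"fb": 0.15, "pg": 0.80, "gl": 0.90, "eh": 1.00, "lh": 1.00,
          "et": 1.00, "lt": 0.90, "bc": 0.85, "mg": 0.15, "lf": 0.10},
    "depleted": {s: 1e-4 for s in
                 ("fb", "pg", "gl", "eh", "lh", "et", "lt", "bc", "mg", "lf")},
}

#: TE family pools per latent class, mirroring which superfamilies the
#: field associates with euchromatic (RdDM) vs heterochromatic (CMT2) TEs.
FAMILY_POOLS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "A": (("HAT", "SINE", "SADHU", "LINE", "Harbinger"), (0.30, 0.25, 0.15, 0.15, 0.15)),
    "B": (("Gypsy", "Copia", "MuDR", "EnSpm"), (0.40, 0.20, 0.25, 0.15)),
    "depleted": (("Helitron", "HAT", "SINE", "LINE"), (0.50, 0.20, 0.20, 0.10)),
}

#: Observed nucleosome group shares among long heterochromatic TEs.
ARCHETYPE_PROBS = (0.567, 0.331, 0.102)

#: Read-length distribution for TE-derived reads (24-nt modal) and for
#: background (non-TE) reads.
TE_LENGTH_PMF = {24: 0.75, 23: 0.08, 25: 0.05, 22: 0.04, 21: 0.03, 26: 0.02,
                 20: 0.01, 27: 0.005, 28: 0.005, 18: 0.0025, 19: 0.0025,
                 29: 0.0015, 30: 0.0035}
BG_LENGTH_PMF = {n: 1 / 13 for n in range(18, 31)}

#: First-base adenosine bias of 24-nt siRNAs.
P_FIRST_A_24 = 0.55

MIN_TE_LEN = 50


class SimulationError(RuntimeError):
    """Raised when a synthetic world cannot be constructed as configured."""


@dataclass
class GenomeAnnotation:
    """TE intervals (0-based half-open, non-overlapping) plus sequences."""

    tes: pd.DataFrame  # te_id, chrom, start, end, strand, family
    chrom_sizes: dict[str, int]
    sequences: dict[str, str]

    def lengths(self) -> pd.Series:
        return pd.Series(
            (self.tes["end"] - self.tes["start"]).to_numpy(),
            index=pd.Index(self.tes["te_id"], name="te_id"),
        )


@dataclass
class GroundTruth:
    """Latent labels the pipeline is asked to recover."""

    te_class: dict[str, str] = field(default_factory=dict)
    dmr_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    nucleosome_archetype: dict[str, int] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, int]] = field(default_factory=dict)


def _rng(config: SimConfig, *streams: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose...)."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *streams]))


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def _place_in_region(rng, lo: int, hi: int, lengths: np.ndarray) -> np.ndarray:
    """Non-overlapping left-to-right placement with random gaps."""
    total = int(lengths.sum())
    free = (hi - lo) - total
    if free < 0:
        raise SimulationError(
            f"infeasible packing: {total} bp of TEs into {hi - lo} bp region"
        )
    if len(lengths) == 0:
        return np.array([], dtype=int)
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
    starts_f = lo + np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return np.floor(starts_f).astype(int)


def generate_genome(config: SimConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Random genome sequence plus a classed, non-overlapping TE annotation.

    Class B TEs are preferentially packed into the centromeric window of
    each chromosome (midpoint +/- ``centromere_half_width``); class A and
    depleted TEs are dispersed along the arms. Class B lengths are drawn
    from a longer log-normal than class A.
    """
    rng = _rng(config, 1)
    chroms = config.chrom_names()

    # random nucleotide sequence, Arabidopsis-like 36% GC
    sequences = {}
    for c in chroms:
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                           size=config.chrom_length, p=[0.32, 0.18, 0.18, 0.32])
        sequences[c] = bases.tobytes().decode("ascii")

    rows: list[tuple] = []
    te_entries: list[tuple[str, int, str]] = []  # (class, length, family)
    for cls in ("A", "B", "depleted"):
        n = config.n_te_per_class[cls]
        med, sig = config.length_params[cls]
        lengths = np.maximum(
            np.round(med * np.exp(rng.normal(0.0, sig, size=n))).astype(int), MIN_TE_LEN
        )
        fams, probs = FAMILY_POOLS[cls]
        families = rng.choice(fams, size=n, p=probs)
        te_entries.extend((cls, int(l), f) for l, f in zip(lengths, families))

    # region assignment: class B mostly centromeric, others on the arms
    mid = config.chrom_length // 2
    hw = config.centromere_half_width
    regions = {c: {"cen": (mid - hw, mid + hw),
                   "left": (0, mid - hw), "right": (mid + hw, config.chrom_length)}
               for c in chroms}
    buckets: dict[tuple[str, str], list[int]] = {
        (c, r): [] for c in chroms for r in ("cen", "left", "right")
    }
    for i, (cls, length, _fam) in enumerate(te_entries):
        chrom = chroms[rng.integers(len(chroms))]
        if cls == "B":
            region = "cen" if rng.random() < 0.85 else ("left", "right")[rng.integers(2)]
        else:
            region = "cen" if rng.random() < 0.10 else ("left", "right")[rng.integers(2)]
        buckets[(chrom, region)].append(i)

    placements: dict[int, tuple[str, int]] = {}
    for (chrom, region), idxs in buckets.items():
        lo, hi = regions[chrom][region]
        order = [idxs[j] for j in rng.permutation(len(idxs))]
        lens = np.array([te_entries[i][1] for i in order], dtype=int)
        starts = _place_in_region(rng, lo, hi, lens)
        for i, s in zip(order, starts):
            placements[i] = (chrom, int(s))

    for i, (cls, length, fam) in enumerate(te_entries):
        chrom, start = placements[i]
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, start + length, strand, fam, cls))

    tes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family", "te_class"])
    tes = tes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    tes.insert(0, "te_id", [f"TE{i + 1:05d}" for i in range(len(tes))])

    truth = GroundTruth(te_class=dict(zip(tes["te_id"], tes["te_class"])))
    annotation = GenomeAnnotation(
        tes=tes.drop(columns="te_class"),
        chrom_sizes=config.chrom_sizes(),
        sequences=sequences,
    )

    truth.dmr_truth = _plant_dmrs(config, annotation, truth, rng)
    truth.nucleosome_archetype = _assign_archetypes(annotation, truth, rng)
    return annotation, truth


def _plant_dmrs(config, annotation, truth, rng) -> pd.DataFrame:
    """Plant CHH DMR intervals inside class A/B TEs with a stage ramp."""
    cand = [t for t in annotation.tes["te_id"] if truth.te_class[t] in ("A", "B")]
    if not cand or config.n_dmr == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "te_id"])
    chosen = rng.choice(cand, size=min(config.n_dmr, len(cand)), replace=False)
    tes = annotation.tes.set_index("te_id")
    base = config.meth_baseline.get("CHH", 0.0)
    rows = []
    for te_id in sorted(chosen):
        te = tes.loc[te_id]
        length = min(config.dmr_length, int(te["end"] - te["start"]))
        slack = int(te["end"] - te["start"]) - length
        start = int(te["start"]) + (int(rng.integers(slack + 1)) if slack > 0 else 0)
        row = {"chrom": te["chrom"], "start": start, "end": start + length, "te_id": te_id}
        for s in METH_STAGES:
            row[f"level_{s}"] = base + config.dmr_effect * STAGE_RAMP[s]
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _assign_archetypes(annotation, truth, rng) -> dict[str, int]:
    """Long class-B TEs get nucleosome archetypes 1-3 at observed shares."""
    from .config import LENGTH_MEDIUM_MAX

    tes = annotation.tes
    long_b = [
        t for t, s, e in zip(tes["te_id"], tes["start"], tes["end"])
        if truth.te_class[t] == "B" and (e - s) > LENGTH_MEDIUM_MAX
    ]
    labels = rng.choice([1, 2, 3], size=len(long_b), p=ARCHETYPE_PROBS)
    return {t: int(a) for t, a in zip(long_b, labels)}


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

def _complement_intervals(tes: pd.DataFrame, chrom_sizes) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = tes[tes["chrom"] == chrom].sort_values("start")
        pos = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > pos:
                rows.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            rows.append((chrom, pos, size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _sample_lengths(rng, n, pmf) -> np.ndarray:
    keys = np.array(sorted(pmf))
    p = np.array([pmf[k] for k in keys], dtype=float)
    return rng.choice(keys, size=n, p=p / p.sum())


def _sample_first_base(rng, lengths) -> np.ndarray:
    bases = np.array(["A", "C", "G", "T"])
    out = bases[rng.integers(4, size=len(lengths))]
    is24 = lengths == 24
    n24 = int(is24.sum())
    if n24:
        p = [P_FIRST_A_24] + [(1 - P_FIRST_A_24) / 3] * 3
        out[is24] = rng.choice(bases, size=n24, p=p)
    return out


def simulate_sirna_reads(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    stage: str,
    replicate: int,
    config: SimConfig,
    record_origins: bool = False,
) -> AlignmentTable:
    """One sRNA-seq library: exactly ``reads_per_library`` collapsed reads.

    Expected per-TE 24-nt output follows the class stage template scaled
    by TE length, with gamma multipliers giving negative-binomial-like
    overdispersion per (TE, library). A ``frac_multimapping`` share of TE
    reads carries ``multimap_family_size`` candidate loci drawn from TEs
    of the same family; the true origin is recorded (``true_idx`` column,
    and ``truth.read_origin`` when ``record_origins``). Background reads
    fall uniformly in non-TE space. Read lengths are 18-30 nt with a
    24-nt mode and an elevated 5' adenosine frequency at 24 nt.
    """
    if stage not in config.stages:
        raise SimulationError(f"unknown stage label {stage!r}")
    rng = _rng(config, 2, config.stages.index(stage), replicate)
    tes = annotation.tes
    n_reads = config.reads_per_library
    empty_reads = pd.DataFrame(columns=["read_id", "length", "first_base", "count", "true_idx"])
    empty_cands = pd.DataFrame(columns=["read_idx", "chrom", "start", "strand"])
    if n_reads == 0 or len(tes) == 0:
        if n_reads and len(tes) == 0:
            raise SimulationError("cannot simulate reads without an annotation")
        return AlignmentTable(reads=empty_reads, cands=empty_cands)

    lengths_bp = (tes["end"] - tes["start"]).to_numpy()
    classes = np.array([truth.te_class[t] for t in tes["te_id"]])
    template = np.array([STAGE_TEMPLATES[c][stage] for c in classes])
    weights = lengths_bp * template
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        weights = weights * rng.gamma(shape, 1.0 / shape, size=len(weights))
    p_te = weights / weights.sum() * (1.0 - config.background_frac)
    probs = np.concatenate([p_te, [config.background_frac]])
    counts = rng.multinomial(n_reads, probs)
    te_counts, n_bg = counts[:-1], counts[-1]

    te_idx = np.repeat(np.arange(len(tes)), te_counts)
    te_read_len = _sample_lengths(rng, len(te_idx), TE_LENGTH_PMF)
    te_span = lengths_bp[te_idx] - te_read_len
    te_start = tes["start"].to_numpy()[te_idx] + np.where(
        te_span > 0, rng.integers(0, np.maximum(te_span, 1) + 1), 0
    )
    te_chrom = tes["chrom"].to_numpy()[te_idx]

    bg = _complement_intervals(tes, annotation.chrom_sizes)
    bg_len = (bg["end"] - bg["start"]).to_numpy()
    bg_read_len = _sample_lengths(rng, n_bg, BG_LENGTH_PMF)
    if len(bg) and n_bg:
        which = rng.choice(len(bg), size=n_bg, p=bg_len / bg_len.sum())
        span = np.maximum(bg_len[which] - bg_read_len, 1)
        bg_start = bg["start"].to_numpy()[which] + rng.integers(0, span)
        bg_chrom = bg["chrom"].to_numpy()[which]
    else:
        bg_start = np.array([], dtype=int)
        bg_chrom = np.array([], dtype=object)
        bg_read_len = bg_read_len[:0]

    read_len = np.concatenate([te_read_len, bg_read_len]).astype(int)
    read_chrom = np.concatenate([te_chrom, bg_chrom])
    read_start = np.concatenate([te_start, bg_start]).astype(int)
    n_total = len(read_len)
    first = _sample_first_base(rng, read_len)
    strand = np.where(rng.random(n_total) < 0.5, "+", "-")
    read_ids = np.array([f"{stage}{replicate}_{i:06d}" for i in range(n_total)])

    # multimapping: TE reads only, candidates within the repeat family
    is_te = np.arange(n_total) < len(te_idx)
    multi = is_te & (rng.random(n_total) < config.frac_multimapping)
    fam_members: dict[str, np.ndarray] = {
        fam: np.asarray(idx) for fam, idx in tes.groupby("family").indices.items()
    }
    families = tes["family"].to_numpy()
    te_starts_all = tes["start"].to_numpy()

    cand_read_idx = [np.arange(n_total)]
    cand_chrom = [read_chrom]
    cand_start = [read_start]
    cand_strand = [strand]
    true_idx = np.zeros(n_total, dtype=int)

    extra_per_read = config.multimap_family_size - 1
    midx = np.flatnonzero(multi)
    if len(midx):
        for i in midx:
            t = te_idx[i]
            pool = fam_members[families[t]]
            pool = pool[pool != t]
            if len(pool) < extra_per_read:
                # top up from same-class TEs when the repeat family is small
                extra = np.flatnonzero(classes == classes[t])
                extra = extra[(extra != t) & ~np.isin(extra, pool)]
                pool = np.concatenate([pool, extra])
            if len(pool) == 0:
                multi[i] = False
                continue
            decoys = rng.choice(pool, size=min(extra_per_read, len(pool)), replace=False)
            for d in decoys:
                span = max(int(lengths_bp[d]) - int(read_len[i]), 0)
                s = int(te_starts_all[d]) + (int(rng.integers(span + 1)) if span > 0 else 0)
                cand_read_idx.append(np.array([i]))
                cand_chrom.append(np.array([tes["chrom"].iat[d]]))
                cand_start.append(np.array([s]))
                cand_strand.append(np.array([strand[i]]))

    cands = pd.DataFrame({
        "read_idx": np.concatenate(cand_read_idx),
        "chrom": np.concatenate(cand_chrom),
        "start": np.concatenate(cand_start).astype(int),
        "strand": np.concatenate(cand_strand),
    }).sort_values("read_idx", kind="stable").reset_index(drop=True)

    # shuffle candidate order within multimapping reads so the true locus
    # is not always listed first, then record its position
    n_cand = np.bincount(cands["read_idx"].to_numpy(), minlength=n_total)
    offsets = np.concatenate([[0], np.cumsum(n_cand)])
    perm = np.arange(len(cands))
    for i in np.flatnonzero(n_cand > 1):
        lo, hi = offsets[i], offsets[i + 1]
        block = perm[lo:hi].copy()
        rng.shuffle(block)
        perm[lo:hi] = block
        true_idx[i] = int(np.flatnonzero(block == lo)[0])
    cands = cands.iloc[perm].reset_index(drop=True)
    cands["read_idx"] = np.repeat(np.arange(n_total), n_cand)

    reads = pd.DataFrame({
        "read_id": read_ids,
        "length": read_len,
        "first_base": first,
        "count": np.ones(n_total, dtype=int),
        "true_idx": true_idx,
    })
    if record_origins:
        for rid, c, s in zip(read_ids, read_chrom, read_start):
            truth.read_origin[rid] = (c, int(s))
    return AlignmentTable(reads=reads, cands=cands)


def expected_template_table(config: SimConfig) -> pd.DataFrame:
    """Per-class expected relative siRNA output per stage (the templates)."""
    return pd.DataFrame(STAGE_TEMPLATES).T[list(config.stages)]


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _cytosine_sites(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions, strands, and downstream dinucleotide bases of all
    context-resolvable cytosines on both strands (0-based positions)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}

    plus = np.flatnonzero(arr == b"C")
    plus = plus[plus < len(arr) - 2]  # need two downstream bases
    b1p, b2p = arr[plus + 1], arr[plus + 2]

    minus = np.flatnonzero(arr == b"G")
    minus = minus[minus >= 2]
    # downstream on the minus strand runs leftwards, complemented
    b1m = np.array([comp[b] for b in arr[minus - 1]], dtype="S1")
    b2m = np.array([comp[b] for b in arr[minus - 2]], dtype="S1")

    pos = np.concatenate([plus, minus])
    strands = np.array(["+"] * len(plus) + ["-"] * len(minus))
    b1 = np.concatenate([b1p, b1m])
    b2 = np.concatenate([b2p, b2m])
    order = np.argsort(pos, kind="stable")
    return pos[order], strands[order], b1[order], b2[order]


def _context_arrays(b1: np.ndarray, b2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    context = np.where(
        b1 == b"G", "CG", np.where(b2 == b"G", "CHG", "CHH")
    )
    cwa = ((b1 == b"A") | (b1 == b"T")) & (b2 == b"A")
    subcontext = np.where(context == "CHH", np.where(cwa, "CWA", "nonCWA"), "n/a")
    return context, subcontext


def simulate_methylome(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    stage: str,
    config: SimConfig,
    replicate: int = 1,
) -> pd.DataFrame:
    """Per-cytosine methylated/total counts for one replicate methylome.

    mc ~ Binomial(cov, p) with p = context baseline, plus the planted DMR
    effect scaled by the stage ramp at CHH sites inside DMR intervals,
    plus the bisulfite conversion error everywhere. cov ~ Poisson(depth);
    uncovered sites are dropped. Columns: chrom, pos (1-based), strand,
    tri (trinucleotide), context, subcontext, mc, cov. Replicates differ
    only in their sampling stream; downstream analysis pools them.
    """
    if stage not in STAGE_RAMP:
        raise SimulationError(f"no methylome stage {stage!r} (expected one of {METH_STAGES})")
    rng = _rng(config, 3, METH_STAGES.index(stage), replicate)
    frames = []
    ramp = STAGE_RAMP[stage]
    dmrs = truth.dmr_truth
    for chrom, seq in annotation.sequences.items():
        pos, strand, b1, b2 = _cytosine_sites(seq)
        if config.coverage_per_cytosine == 0 or len(pos) == 0:
            continue
        context, subcontext = _context_arrays(b1, b2)
        p = np.array([config.meth_baseline.get(c, 0.0) for c in ("CG", "CHG", "CHH")])
        p_site = np.select(
            [context == "CG", context == "CHG"], [p[0], p[1]], default=p[2]
        ).astype(float)
        if len(dmrs):
            sub = dmrs[dmrs["chrom"] == chrom]
            in_dmr = np.zeros(len(pos), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                in_dmr |= (pos >= s) & (pos < e)
            p_site = np.where(in_dmr & (context == "CHH"),
                              p_site + config.dmr_effect * ramp, p_site)
        p_obs = np.clip(p_site + config.conversion_error * (1.0 - p_site), 0.0, 1.0)
        cov = rng.poisson(config.coverage_per_cytosine, size=len(pos))
        keep = cov > 0
        if not keep.any():
            continue
        mc = rng.binomial(cov[keep], p_obs[keep])
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        tri = _trinucleotides(arr, pos[keep], strand[keep])
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos[keep] + 1,
            "strand": strand[keep],
            "tri": tri,
            "context": context[keep],
            "subcontext": subcontext[keep],
            "mc": mc,
            "cov": cov[keep],
        }))
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "tri", "context", "subcontext", "mc", "cov"]
        )
    return pd.concat(frames, ignore_index=True)


def _trinucleotides(arr: np.ndarray, pos: np.ndarray, strand: np.ndarray) -> np.ndarray:
    comp = {65: "T", 67: "G", 71: "C", 84: "A"}  # A C G T codes
    codes = arr.view(np.uint8)
    out = np.empty(len(pos), dtype=object)
    plus = strand == "+"
    for i in np.flatnonzero(plus):
        p = pos[i]
        out[i] = chr(codes[p]) + chr(codes[p + 1]) + chr(codes[p + 2])
    for i in np.flatnonzero(~plus):
        p = pos[i]
        out[i] = comp[codes[p]] + comp[codes[p - 1]] + comp[codes[p - 2]]
    return out.astype(str)


# ---------------------------------------------------------------------------
# nucleosome occupancy track
# ---------------------------------------------------------------------------

#: (edge level, body level) per archetype; edges are the outer 15% of a TE.
ARCHETYPE_LEVELS = {1: (1.0, 1.0), 2: (0.2, 1.0), 3: (0.1, 0.1)}
NUC_BASELINE = 0.3
NUC_NOISE_SD = 0.25
EDGE_FRAC = 0.15


def simulate_nucleosome_signal(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    noise_sd: float = NUC_NOISE_SD,
    seed: int = 0,
) -> SignalTrack:
    """Smooth noisy per-base nucleosome occupancy over the genome.

    Long class-B TEs follow their archetype: (1) high edges and body,
    (2) low edges / high body, (3) low everywhere. Elsewhere the track
    sits at a euchromatic baseline. Noise is Gaussian, then smoothed
    with a 50-bp moving average and clipped at zero.
    """
    from scipy.ndimage import uniform_filter1d

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    values = {}
    tes = annotation.tes.set_index("te_id")
    for chrom, size in annotation.chrom_sizes.items():
        arr = np.full(size, NUC_BASELINE)
        for te_id, arch in truth.nucleosome_archetype.items():
            te = tes.loc[te_id]
            if te["chrom"] != chrom:
                continue
            s, e = int(te["start"]), int(te["end"])
            edge_lvl, body_lvl = ARCHETYPE_LEVELS[arch]
            k = max(1, int(round((e - s) * EDGE_FRAC)))
            arr[s:e] = body_lvl
            arr[s:s + k] = edge_lvl
            arr[e - k:e] = edge_lvl
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=size)
            arr = uniform_filter1d(arr, size=50)
        values[chrom] = np.clip(arr, 0.0, None)
    return SignalTrack(values=values)
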