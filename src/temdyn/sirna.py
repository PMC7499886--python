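"""Small-RNA signal: multimapper reassignment, RPM tracks, per-TE counts.

Collapsed 18-30-nt reads arrive with one or more candidate loci.
Multi-mapping reads are fractionally assigned by a "rich-get-richer"
fixed point: each candidate's weight is proportional to the total
coverage (unique reads plus current fractional multimapper mass) in a
window around its footprint, renormalized per read, iterated to
convergence. Assigned mass is then normalized to reads per million
genome-matching reads (RPM), deposited at alignment start positions,
and summed over TE intervals or binned into scale-regions metaplot
matrices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_READ_LEN = 18
MAX_READ_LEN = 30

READ_COLUMNS = ["read_id", "length", "first_base", "count", "true_idx"]
CAND_COLUMNS = ["read_idx", "chrom", "start", "strand"]


class AlignmentError(ValueError):
    """Raised for malformed alignment inputs."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One collapsed small-RNA read with its candidate loci."""

    read_id: str
    length: int
    first_base: str
    count: int
    candidates: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise AlignmentError(f"read {self.read_id}: empty candidate list")
        if self.count < 1:
            raise AlignmentError(f"read {self.read_id}: count must be >= 1")
        if not MIN_READ_LEN <= self.length <= MAX_READ_LEN:
            raise AlignmentError(
                f"read {self.read_id}: length {self.length} outside "
                f"[{MIN_READ_LEN}, {MAX_READ_LEN}]"
            )


@dataclass(frozen=True)
class WeightedAlignment:
    """Fractional locus weights for one read; weights sum to 1."""

    read_id: str
    weights: tuple[float, ...]
    record: AlignmentRecord

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise AlignmentError(f"read {self.read_id}: weights do not sum to 1")


@dataclass
class AlignmentTable:
    """Columnar alignment container (one row per read / per candidate).

    ``reads``: read_id, length, first_base, count, true_idx (index into
    this read's candidates of the simulated true origin; -1 if unknown).
    ``cands``: read_idx, chrom, start, strand, rows grouped by read in
    candidate order, plus a ``weight`` column once reassigned.
    """

    reads: pd.DataFrame
    cands: pd.DataFrame

    def __post_init__(self) -> None:
        self.reads = self.reads.reset_index(drop=True)
        self.cands = self.cands.reset_index(drop=True)
        n = len(self.reads)
        counts = np.bincount(self.cands["read_idx"].to_numpy(), minlength=n) if n else np.array([])
        if n and (counts == 0).any():
            bad = int(np.flatnonzero(counts == 0)[0])
            raise AlignmentError(f"read {self.reads['read_id'].iat[bad]}: empty candidate list")
        if n:
            lengths = self.reads["length"].to_numpy()
            if lengths.min() < MIN_READ_LEN or lengths.max() > MAX_READ_LEN:
                raise AlignmentError("read length outside [18, 30]")
            if self.reads["count"].to_numpy().min() < 1:
                raise AlignmentError("read count must be >= 1")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_candidates(self) -> np.ndarray:
        return np.bincount(self.cands["read_idx"].to_numpy(), minlength=len(self.reads))

    def total_count(self) -> int:
        return int(self.reads["count"].sum())

    @classmethod
    def from_records(cls, records: Iterable[AlignmentRecord]) -> "AlignmentTable":
        rows, crows = [], []
        for i, rec in enumerate(records):
            rows.append((rec.read_id, rec.length, rec.first_base, rec.count, -1))
            for chrom, start, strand in rec.candidates:
                crows.append((i, chrom, start, strand))
        reads = pd.DataFrame(rows, columns=READ_COLUMNS)
        cands = pd.DataFrame(crows, columns=CAND_COLUMNS)
        return cls(reads=reads, cands=cands)

    def to_records(self) -> list[AlignmentRecord]:
        out = []
        grouped = self.cands.groupby("read_idx", sort=True)
        cand_map = {
            idx: tuple(zip(g["chrom"], g["start"].astype(int), g["strand"]))
            for idx, g in grouped
        }
        for i, row in self.reads.iterrows():
            out.append(
                AlignmentRecord(
                    read_id=row["read_id"],
                    length=int(row["length"]),
                    first_base=row["first_base"],
                    count=int(row["count"]),
                    candidates=cand_map[i],
                )
            )
        return out


@dataclass
class SignalTrack:
    """Per-chromosome per-base signal (read mass at alignment starts,
    or any genomic score such as nucleosome occupancy)."""

    values: dict[str, np.ndarray]
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise AlignmentError(f"{chrom}: non-finite track values")
            if (arr < 0).any():
                raise AlignmentError(f"{chrom}: negative track values")
            self.values[chrom] = arr

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


# ---------------------------------------------------------------------------
# rich-get-richer multimapper reassignment
# ---------------------------------------------------------------------------

def _genome_layout(cands: pd.DataFrame, chrom_sizes: Mapping[str, int] | None,
                   lengths: np.ndarray, window: int):
    """Map (chrom, pos) to one concatenated coordinate axis."""
    if chrom_sizes is None:
        ends = cands["start"].to_numpy() + lengths + window + 1
        chrom_sizes = {
            c: int(ends[(cands["chrom"] == c).to_numpy()].max())
            for c in pd.unique(cands["chrom"])
        }
    names = list(chrom_sizes)
    offsets = np.concatenate([[0], np.cumsum([chrom_sizes[c] for c in names])])
    index = {c: i for i, c in enumerate(names)}
    chrom_idx = cands["chrom"].map(index)
    if chrom_idx.isna().any():
        missing = cands.loc[chrom_idx.isna(), "chrom"].iloc[0]
        raise AlignmentError(f"candidate on unknown chromosome {missing!r}")
    gpos = offsets[chrom_idx.to_numpy(dtype=int)] + cands["start"].to_numpy()
    return gpos.astype(np.int64), int(offsets[-1])


def reassign_multimappers(
    alignments: "AlignmentTable | Sequence[AlignmentRecord]",
    chrom_sizes: Mapping[str, int] | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    window: int = 25,
):
    """Fixed-point fractional assignment of multi-mapping reads.

    Unique reads keep weight 1. Multimapper candidate weights are
    iterated proportional to total assigned coverage in the candidate
    footprint extended by ``window`` bp on each side, renormalized per
    read, until the largest per-candidate change drops below ``tol``.
    Total read mass is conserved exactly. If no coverage exists anywhere
    near any candidate of a read, its weights fall back to uniform.

    Returns an :class:`AlignmentTable` whose ``cands`` carry a
    ``weight`` column, or a list of :class:`WeightedAlignment` when
    called with records.
    """
    records_in = not isinstance(alignments, AlignmentTable)
    table = AlignmentTable.from_records(alignments) if records_in else alignments
    if len(table) == 0:
        out = AlignmentTable(reads=table.reads.copy(), cands=table.cands.assign(weight=[]))
        return [] if records_in else out

    cands = table.cands
    read_idx = cands["read_idx"].to_numpy()
    order = np.argsort(read_idx, kind="stable")  # group candidates per read
    cands = cands.iloc[order].reset_index(drop=True)
    read_idx = cands["read_idx"].to_numpy()
    n_cand_per_read = np.bincount(read_idx, minlength=len(table))
    starts_of_read = np.concatenate([[0], np.cumsum(n_cand_per_read)])[:-1]

    lengths = table.reads["length"].to_numpy()[read_idx]
    counts = table.reads["count"].to_numpy().astype(float)
    gpos, genome_len = _genome_layout(cands, chrom_sizes, lengths, window)
    fp_end = np.minimum(gpos + lengths, genome_len)  # footprints may hang off the end
    lo = np.maximum(gpos - window, 0)
    hi = np.minimum(gpos + lengths + window, genome_len)

    multi = n_cand_per_read > 1
    is_multi_cand = multi[read_idx]
    w = np.where(is_multi_cand, 1.0 / n_cand_per_read[read_idx], 1.0)

    # Coverage contributed by unique reads never changes.
    unique_diff = np.zeros(genome_len + 1)
    um = ~is_multi_cand
    np.add.at(unique_diff, gpos[um], counts[read_idx[um]])
    np.add.at(unique_diff, fp_end[um], -counts[read_idx[um]])
    unique_cov = np.cumsum(unique_diff)[:-1]

    mm = is_multi_cand
    mm_reads = read_idx[mm]
    if not mm.any():
        converged = True
    else:
        converged = False
        for _ in range(max_iter):
            diff = np.zeros(genome_len + 1)
            np.add.at(diff, gpos[mm], w[mm] * counts[mm_reads])
            np.add.at(diff, fp_end[mm], -w[mm] * counts[mm_reads])
            cov = unique_cov + np.cumsum(diff)[:-1]
            prefix = np.concatenate([[0.0], np.cumsum(cov)])
            score = prefix[hi] - prefix[lo]
            score[~mm] = 1.0  # unique reads untouched
            denom = np.add.reduceat(score, starts_of_read)[read_idx]
            zero = denom[mm] <= 0
            new_w = w.copy()
            new_w[mm] = np.where(
                zero, 1.0 / n_cand_per_read[mm_reads], score[mm] / np.where(denom[mm] > 0, denom[mm], 1.0)
            )
            delta = np.abs(new_w - w).max()
            w = new_w
            if delta < tol:
                converged = True
                break
    if not converged:
        logger.warning("reassignment stopped at max_iter=%d without reaching tol", max_iter)

    # Kill floating-point drift so per-read sums are exactly 1.
    sums = np.add.reduceat(w, starts_of_read)[read_idx]
    w = w / sums

    out_cands = cands.assign(weight=w)
    # restore original candidate row order
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    out_cands = out_cands.iloc[inverse].reset_index(drop=True)
    out = AlignmentTable(reads=table.reads.copy(), cands=out_cands)
    if records_in:
        recs = table.to_records()
        weighted = []
        grouped = out.cands.groupby("read_idx", sort=True)["weight"]
        for i, rec in enumerate(recs):
            weighted.append(
                WeightedAlignment(read_id=rec.read_id,
                                  weights=tuple(grouped.get_group(i)), record=rec)
            )
        return weighted
    return out


# ---------------------------------------------------------------------------
# normalization, quantification, composition
# ---------------------------------------------------------------------------

def total_genome_matching(table: AlignmentTable) -> int:
    """RPM denominator: every genome-matching read of any length 18-30 nt."""
    return table.total_count()


def _as_weighted_table(weighted) -> AlignmentTable:
    if isinstance(weighted, AlignmentTable):
        if "weight" not in weighted.cands.columns:
            raise AlignmentError("alignments must be reassigned before normalization")
        return weighted
    table = AlignmentTable.from_records([w.record for w in weighted])
    table.cands["weight"] = np.concatenate([np.asarray(w.weights) for w in weighted])
    return table


def normalize_rpm(
    weighted,
    total_genome_matching: int,
    chrom_sizes: Mapping[str, int],
    size_range: tuple[int, int] | None = None,
) -> SignalTrack:
    """Deposit count x weight x 1e6 / total at each assigned start position."""
    if total_genome_matching <= 0:
        raise AlignmentError("total_genome_matching must be > 0")
    table = _as_weighted_table(weighted)
    scale = 1e6 / total_genome_matching
    values = {c: np.zeros(size) for c, size in chrom_sizes.items()}
    cands = table.cands
    read_idx = cands["read_idx"].to_numpy()
    lengths = table.reads["length"].to_numpy()[read_idx]
    mask = np.ones(len(cands), dtype=bool)
    if size_range is not None:
        lo, hi = size_range
        if lo > hi:
            raise AlignmentError("inverted size range")
        mask = (lengths >= lo) & (lengths <= hi)
    mass = cands["weight"].to_numpy() * table.reads["count"].to_numpy()[read_idx] * scale
    for chrom, arr in values.items():
        sel = mask & (cands["chrom"] == chrom).to_numpy()
        np.add.at(arr, cands["start"].to_numpy()[sel], mass[sel])
    return SignalTrack(values=values, size_range=size_range)


def quantify_te(
    track: SignalTrack,
    annotation: pd.DataFrame,
    size_range: tuple[int, int] = (24, 24),
) -> pd.Series:
    """Sum normalized read mass whose alignment start lies in [start, end).

    ``annotation`` needs columns te_id, chrom, start, end. The 24-nt
    siRNA class uses (24, 24); precursor quantification uses (25, 30).
    """
    lo, hi = size_range
    if lo > hi or lo < MIN_READ_LEN or hi > MAX_READ_LEN:
        raise AlignmentError(f"invalid size range {size_range}")
    if track.size_range is not None and tuple(track.size_range) != (lo, hi):
        raise AlignmentError(
            f"track was built for sizes {track.size_range}, requested {size_range}"
        )
    prefix = {c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in track.values.items()}
    out = np.zeros(len(annotation))
    for i, (chrom, start, end) in enumerate(
        zip(annotation["chrom"], annotation["start"], annotation["end"])
    ):
        p = prefix.get(chrom)
        if p is None:
            continue
        a = min(max(int(start), 0), len(p) - 1)
        b = min(max(int(end), 0), len(p) - 1)
        if b > a:
            out[i] = p[b] - p[a]
    return pd.Series(out, index=pd.Index(annotation["te_id"], name="te_id"))


def first_base_composition(alignments, length: int) -> dict[str, float]:
    """Count-weighted first-base fractions among reads of one length."""
    if not MIN_READ_LEN <= length <= MAX_READ_LEN:
        raise AlignmentError(f"length {length} outside [18, 30]")
    table = alignments if isinstance(alignments, AlignmentTable) else AlignmentTable.from_records(alignments)
    sel = table.reads[table.reads["length"] == length]
    if sel.empty:
        return {}
    totals = sel.groupby("first_base")["count"].sum()
    return (totals / totals.sum()).to_dict()


# ---------------------------------------------------------------------------
# scale-regions metaplot matrices
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Regions x bins mean signal with fixed flank / scaled body geometry."""

    values: np.ndarray
    region_ids: list[str]
    bin_size: int
    n_upstream: int
    n_body: int
    n_downstream: int

    @property
    def n_bins(self) -> int:
        return self.n_upstream + self.n_body + self.n_downstream

    def body_slice(self) -> slice:
        return slice(self.n_upstream, self.n_upstream + self.n_body)

    def edge_columns(self, frac: float = 0.15) -> np.ndarray:
        k = max(1, int(round(self.n_body * frac)))
        body = np.arange(self.n_upstream, self.n_upstream + self.n_body)
        return np.concatenate([body[:k], body[-k:]])


def metaplot_matrix(
    track: SignalTrack,
    regions: pd.DataFrame,
    bin_size: int = 5,
    body_length: int = 4000,
    upstream: int = 2000,
    downstream: int = 2000,
) -> ProfileMatrix:
    """Scale-regions profile matrix (deepTools computeMatrix geometry).

    Bodies are rescaled to ``body_length / bin_size`` bins; flanks are
    binned natively at ``bin_size``. Defaults (5, 4000, 2000, 2000) give
    400 + 800 + 400 = 1600 columns. Bin value is the mean per-base
    signal (off-chromosome bases contribute 0). Minus-strand regions are
    reported 5'->3', i.e. column-reversed relative to the genome.
    Regions shorter than one bin are handled by fractional rescaling
    (each body bin covers length/n_body bases), never an error.
    """
    for name, span in (("body_length", body_length), ("upstream", upstream),
                       ("downstream", downstream)):
        if span % bin_size:
            raise AlignmentError(f"bin_size must divide {name}")
    n_body = body_length // bin_size
    n_up = upstream // bin_size
    n_down = downstream // bin_size

    prefix = {}
    for chrom, vals in track.values.items():
        prefix[chrom] = np.concatenate([[0.0], np.cumsum(vals)])

    def prefix_at(p: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Linearly interpolated cumulative signal at fractional positions."""
        x = np.clip(x, 0.0, len(p) - 1)
        i = np.minimum(x.astype(int), len(p) - 2)
        return p[i] + (x - i) * (p[i + 1] - p[i])

    rows = np.zeros((len(regions), n_up + n_body + n_down))
    strands = regions["strand"] if "strand" in regions.columns else pd.Series("+", index=regions.index)
    for i, (chrom, start, end, strand) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"], strands)
    ):
        p = prefix.get(chrom)
        if p is None:
            continue
        edges = np.concatenate([
            start - upstream + bin_size * np.arange(n_up),
            start + (end - start) * np.arange(n_body + 1) / n_body,
            end + bin_size * np.arange(1, n_down + 1),
        ])
        sums = np.diff(prefix_at(p, edges))
        widths = np.diff(edges)
        row = np.divide(sums, widths, out=np.zeros_like(sums), where=widths > 0)
        if strand == "-":
            row = row[::-1]
        rows[i] = row

    ids = list(regions["te_id"]) if "te_id" in regions.columns else [str(i) for i in regions.index]
    return ProfileMatrix(values=rows, region_ids=ids, bin_size=bin_size,
                         n_upstream=n_up, n_body=n_body, n_downstream=n_down)


# ---------------------------------------------------------------------------
# multi-library bookkeeping
# ---------------------------------------------------------------------------

def build_quant_table(per_library: Mapping[tuple[str, int], pd.Series]) -> pd.DataFrame:
    """Assemble replicate-level TE x (sample, replicate) RPM table."""
    df = pd.DataFrame(per_library)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return df


def replicate_mean(quant: pd.DataFrame, stage_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Arithmetic mean over replicates, columns ordered by stage."""
    mean = quant.T.groupby(level="sample").mean().T
    if stage_order is not None:
        mean = mean[[s for s in stage_order if s in mean.columns]]
    return mean
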