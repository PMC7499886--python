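"""Readers and writers for the pipeline's text formats.

BED6 TE annotations, allc-style per-cytosine tables, the alignment TSV
dialect emitted by the simulator (candidates as semicolon-joined
chrom:start:strand), bedGraph signal tracks, and JSON ground truth.
Parsers reject malformed input with line numbers rather than coercing;
writers are deterministic (sorted, %.6g floats, UTF-8, tab-separated,
'#'-prefixed headers).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import context_from_tri
from .sirna import AlignmentTable, SignalTrack


class FormatError(ValueError):
    """Raised on malformed input files."""


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 (0-based half-open) -> annotation table."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 6):
                raise FormatError(f"{path}:{lineno}: expected 3 or 6 BED fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) == 6 else f"region{lineno}"
            strand = parts[5] if len(parts) == 6 else "+"
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((name, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["te_id", "chrom", "start", "end", "strand"])


def write_bed(annotation: pd.DataFrame, path) -> None:
    df = annotation.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w", encoding="utf-8") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['te_id']}\t0\t{r['strand']}\n")


# ---------------------------------------------------------------------------
# allc
# ---------------------------------------------------------------------------

ALLC_COLUMNS = ["chrom", "pos", "strand", "tri", "mc", "cov"]


def read_allc(path) -> pd.DataFrame:
    """allc-style TSV (chrom, 1-based pos, strand, trinucleotide, mc, cov)
    -> site table with derived context and subcontext."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 allc fields")
            chrom, pos, strand, tri, mc, cov = parts
            try:
                pos, mc, cov = int(pos), int(mc), int(cov)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if mc > cov or mc < 0:
                raise FormatError(
                    f"{path}:{lineno}: mc={mc} > cov={cov} at {chrom}:{pos}"
                )
            context, subcontext = context_from_tri(tri)
            rows.append((chrom, pos, strand, tri, context, subcontext, mc, cov))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "tri", "context", "subcontext", "mc", "cov"],
    )


def write_allc(sites: pd.DataFrame, path) -> None:
    df = sites.sort_values(["chrom", "pos", "strand"], kind="stable")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tmc\tcov\n")
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.tri}\t{r.mc}\t{r.cov}\n")


# ---------------------------------------------------------------------------
# alignment TSV
# ---------------------------------------------------------------------------

def write_alignments(table: AlignmentTable, path) -> None:
    """read_id, length, first_base, count, candidates; optional weights."""
    has_w = "weight" in table.cands.columns
    grouped = table.cands.groupby("read_idx", sort=True)
    with open(path, "w", encoding="utf-8") as fh:
        header = "#read_id\tlength\tfirst_base\tcount\tcandidates"
        fh.write(header + ("\tweights\n" if has_w else "\n"))
        for i, r in table.reads.iterrows():
            g = grouped.get_group(i)
            cand = ";".join(
                f"{c}:{s}:{st}" for c, s, st in zip(g["chrom"], g["start"], g["strand"])
            )
            line = f"{r['read_id']}\t{r['length']}\t{r['first_base']}\t{r['count']}\t{cand}"
            if has_w:
                line += "\t" + ";".join(_fmt(w) for w in g["weight"])
            fh.write(line + "\n")


def read_alignments(path) -> AlignmentTable:
    reads, cands = [], []
    weights = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (5, 6):
                raise FormatError(f"{path}:{lineno}: expected 5 or 6 fields")
            rid, length, first, count, cand = parts[:5]
            try:
                length, count = int(length), int(count)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            i = len(reads)
            reads.append((rid, length, first, count, -1))
            cand_list = cand.split(";")
            for token in cand_list:
                try:
                    chrom, start, strand = token.rsplit(":", 2)
                    cands.append((i, chrom, int(start), strand))
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad candidate {token!r}") from None
            if len(parts) == 6:
                ws = [float(w) for w in parts[5].split(";")]
                if len(ws) != len(cand_list):
                    raise FormatError(f"{path}:{lineno}: weight/candidate count mismatch")
                weights.extend(ws)
    table = AlignmentTable(
        reads=pd.DataFrame(reads, columns=["read_id", "length", "first_base", "count", "true_idx"]),
        cands=pd.DataFrame(cands, columns=["read_idx", "chrom", "start", "strand"]),
    )
    if weights:
        table.cands["weight"] = weights
    return table


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: SignalTrack, path) -> None:
    """Run-length-encoded per-base values; zero runs are omitted."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v[s])}\n")


def bedgraph_extent(path) -> dict[str, int]:
    """Per-chromosome maximum end coordinate seen in a bedGraph."""
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) == 4:
                sizes[parts[0]] = max(sizes.get(parts[0], 0), int(parts[2]))
    return sizes


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> SignalTrack:
    if chrom_sizes is None:
        chrom_sizes = bedgraph_extent(path)
    values = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = parts
            try:
                start, end, value = int(start), int(end), float(value)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if chrom not in values:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= len(values[chrom]):
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            values[chrom][start:end] = value
    return SignalTrack(values=values)


# ---------------------------------------------------------------------------
# ground truth / generic tables
# ---------------------------------------------------------------------------

def write_ground_truth(truth, path) -> None:
    payload = {
        "te_class": truth.te_class,
        "dmr_truth": truth.dmr_truth.to_dict(orient="records"),
        "nucleosome_archetype": truth.nucleosome_archetype,
        "read_origin": {k: list(v) for k, v in truth.read_origin.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def read_ground_truth(path):
    from .synthetic import GroundTruth

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        te_class=payload["te_class"],
        dmr_truth=pd.DataFrame(payload["dmr_truth"]),
        nucleosome_archetype={k: int(v) for k, v in payload["nucleosome_archetype"].items()},
        read_origin={k: tuple(v) for k, v in payload["read_origin"].items()},
    )


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
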