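"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: rMATS-style per-type junction-count tables ("rmats-jc"
dialect), the package's own round-trippable TSV ("native-tsv"), GMT gene-set
collections, TSV sample sheets and indexed FASTA genomes (via pyfaidx; plain
``{chrom: sequence}`` mappings are accepted everywhere a genome is needed).

rMATS exon coordinate columns named ``*_0base`` are already 0-based half-open
and are ingested unchanged; paired-column conventions (e.g. ``upstreamES`` /
``upstreamEE``) are 0-based half-open as documented by that tool.  Flanking
exons are re-assigned to transcript orientation from coordinates and strand,
so the reader does not depend on the tool's own upstream/downstream naming.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .events import (
    EventCountsTable,
    GeneSetCollection,
    GenomicInterval,
    SampleTable,
    SplicingEvent,
    reverse_complement,
)


class ParseError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


def one_based_to_zero(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


def zero_to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def _split_counts(field: str, lineno: int) -> list[float]:
    out: list[float] = []
    for tok in field.split(","):
        tok = tok.strip()
        if tok in ("", "NA", "na", "NaN", "nan", "."):
            out.append(np.nan)
            continue
        try:
            val = float(tok)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad count field {tok!r}") from exc
        if val < 0 or val != int(val):
            raise ParseError(f"line {lineno}: counts must be non-negative integers, got {tok!r}")
        out.append(val)
    return out


# --------------------------------------------------------------------------
# rMATS-dialect per-type junction-count tables
# --------------------------------------------------------------------------

_RMATS_SIGNATURES = {
    "SE": ("exonStart_0base", "exonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"),
    "MXE": ("1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
            "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"),
    "A5SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"),
    "A3SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE", "flankingES", "flankingEE"),
    "RI": ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"),
}


def _infer_rmats_type(header: Sequence[str]) -> str:
    cols = set(header)
    if "riExonStart_0base" in cols:
        return "RI"
    if "1stExonStart_0base" in cols:
        return "MXE"
    if "exonStart_0base" in cols:
        return "SE"
    if "longExonStart_0base" in cols:
        raise ParseError(
            "A5SS and A3SS tables share a column signature; pass event_type explicitly"
        )
    raise ParseError("not a recognised rMATS junction-count table")


def _assign_flanks(
    strand: str, left: GenomicInterval, right: GenomicInterval
) -> tuple[GenomicInterval, GenomicInterval]:
    """Return (flank_up, flank_down) in transcript orientation."""
    if left.start > right.start:
        left, right = right, left
    return (left, right) if strand == "+" else (right, left)


def _rmats_event(row: Mapping[str, str], event_type: str, lineno: int) -> SplicingEvent:
    chrom = row["chr"]
    strand = row["strand"]
    gene_id = row.get("GeneID", "").strip('"')
    symbol = row.get("geneSymbol", "").strip('"').upper()
    ivl = lambda s, e: GenomicInterval(chrom, int(s), int(e), strand)
    if event_type in ("SE", "RI"):
        if event_type == "SE":
            alt = ivl(row["exonStart_0base"], row["exonEnd"])
        else:
            # retained intron: the alternative segment is the intron itself
            alt = ivl(row["upstreamEE"], row["downstreamES"])
        fu, fd = _assign_flanks(
            strand,
            ivl(row["upstreamES"], row["upstreamEE"]),
            ivl(row["downstreamES"], row["downstreamEE"]),
        )
        alts: tuple[GenomicInterval, ...] = (alt,)
    elif event_type == "MXE":
        e1 = ivl(row["1stExonStart_0base"], row["1stExonEnd"])
        e2 = ivl(row["2ndExonStart_0base"], row["2ndExonEnd"])
        alts = tuple(sorted((e1, e2), key=lambda e: e.start))
        fu, fd = _assign_flanks(
            strand,
            ivl(row["upstreamES"], row["upstreamEE"]),
            ivl(row["downstreamES"], row["downstreamEE"]),
        )
    elif event_type in ("A5SS", "A3SS"):
        long = ivl(row["longExonStart_0base"], row["longExonEnd"])
        short = ivl(row["shortES"], row["shortEE"])
        flank = ivl(row["flankingES"], row["flankingEE"])
        # alternative segment = long-exon extension beyond the short exon
        if long.start == short.start:
            alt = ivl(short.end, long.end)
        elif long.end == short.end:
            alt = ivl(long.start, short.start)
        else:
            raise ParseError(f"line {lineno}: long/short exons share neither boundary")
        fu, fd = _assign_flanks(strand, short, flank)
        alts = (alt,)
    else:  # pragma: no cover
        raise ParseError(f"line {lineno}: unknown event type {event_type}")
    event_id = f"{event_type}_{row['ID']}"
    return SplicingEvent(event_id, event_type, gene_id, symbol, alts, fu, fd)


def _read_rmats(
    path: Path,
    event_type: str | None,
    sample_ids: Sequence[str] | None,
) -> tuple[list[SplicingEvent], EventCountsTable | None]:
    events: list[SplicingEvent] = []
    inc_rows: list[list[float]] = []
    skip_rows: list[list[float]] = []
    inc_len: list[float] = []
    skip_len: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return [], None
        etype = event_type or _infer_rmats_type(reader.fieldnames)
        missing = [c for c in _RMATS_SIGNATURES[etype] if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"missing {etype} columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                events.append(_rmats_event(row, etype, lineno))
                i1 = _split_counts(row["IJC_SAMPLE_1"], lineno)
                s1 = _split_counts(row["SJC_SAMPLE_1"], lineno)
                i2 = _split_counts(row["IJC_SAMPLE_2"], lineno)
                s2 = _split_counts(row["SJC_SAMPLE_2"], lineno)
            except ParseError:
                raise
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"line {lineno}: malformed row ({exc})") from exc
            if len(i1) != len(s1) or len(i2) != len(s2):
                raise ParseError(f"line {lineno}: inclusion/skipping count arity mismatch")
            inc_rows.append(i1 + i2)
            skip_rows.append(s1 + s2)
            inc_len.append(float(row["IncFormLen"]))
            skip_len.append(float(row["SkipFormLen"]))
    if not events:
        return [], None
    n1 = len(inc_rows[0])
    if any(len(r) != n1 for r in inc_rows):
        raise ParseError("inconsistent replicate count arity across rows")
    if sample_ids is None:
        sample_ids = [f"SAMPLE_{i + 1}" for i in range(n1)]
    elif len(sample_ids) != n1:
        raise ParseError(
            f"count columns carry {n1} samples but {len(sample_ids)} sample ids were supplied"
        )
    counts = EventCountsTable(
        [e.event_id for e in events], list(sample_ids),
        np.array(inc_rows), np.array(skip_rows), np.array(inc_len), np.array(skip_len),
    )
    return events, counts


# --------------------------------------------------------------------------
# native TSV (round-trippable)
# --------------------------------------------------------------------------

_NATIVE_FIXED = [
    "event_id", "event_type", "gene_id", "gene_symbol", "chrom", "strand",
    "alt_starts", "alt_ends", "flank_up_start", "flank_up_end",
    "flank_down_start", "flank_down_end", "inc_len", "skip_len",
]


def _read_native(path: Path) -> tuple[list[SplicingEvent], EventCountsTable | None]:
    events: list[SplicingEvent] = []
    inc_rows, skip_rows, inc_len, skip_len = [], [], [], []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines or not lines[0].strip():
        return [], None
    reader = csv.DictReader(lines, delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in _NATIVE_FIXED if c not in header]
    if missing:
        raise ParseError(f"missing native-tsv columns: {missing}")
    sample_ids = [c[4:] for c in header if c.startswith("IJC:")]
    for lineno, row in enumerate(reader, start=2):
        try:
            chrom, strand = row["chrom"], row["strand"]
            starts = [int(x) for x in row["alt_starts"].split(",")]
            ends = [int(x) for x in row["alt_ends"].split(",")]
            alts = tuple(GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends))
            fu = GenomicInterval(chrom, int(row["flank_up_start"]), int(row["flank_up_end"]), strand)
            fd = GenomicInterval(chrom, int(row["flank_down_start"]), int(row["flank_down_end"]), strand)
            events.append(SplicingEvent(
                row["event_id"], row["event_type"], row["gene_id"],
                row["gene_symbol"].upper(), alts, fu, fd,
            ))
            inc_rows.append([_split_counts(row[f"IJC:{s}"], lineno)[0] for s in sample_ids])
            skip_rows.append([_split_counts(row[f"SJC:{s}"], lineno)[0] for s in sample_ids])
            inc_len.append(float(row["inc_len"]))
            skip_len.append(float(row["skip_len"]))
        except ParseError:
            raise
        except (KeyError, ValueError, TypeError) as exc:
            raise ParseError(f"line {lineno}: malformed row ({exc})") from exc
    counts = None
    if sample_ids:
        counts = EventCountsTable(
            [e.event_id for e in events], sample_ids,
            np.array(inc_rows), np.array(skip_rows), np.array(inc_len), np.array(skip_len),
        )
    return events, counts


def read_events_table(
    path: str | Path,
    dialect: str = "native-tsv",
    event_type: str | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[SplicingEvent], EventCountsTable | None]:
    """Read an event/count table.

    ``dialect`` is ``"rmats-jc"`` (per-type junction-count tables with
    comma-separated replicate fields) or ``"native-tsv"``.  Returns the events
    and, when count columns are present, an :class:`EventCountsTable`.
    An empty file yields an empty event list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "rmats-jc":
        return _read_rmats(path, event_type, sample_ids)
    if dialect == "native-tsv":
        return _read_native(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events_table(
    events: Sequence[SplicingEvent],
    counts: EventCountsTable | None,
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write events (and optional counts) as native TSV with a fixed column order."""
    path = Path(path)
    sample_ids = counts.sample_ids if counts is not None else []
    by_id = {}
    if counts is not None:
        by_id = {eid: i for i, eid in enumerate(counts.event_ids)}
    cols = _NATIVE_FIXED + [f"{p}:{s}" for s in sample_ids for p in ("IJC", "SJC")]
    with open(path, "w", newline="") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for ev in events:
            row = [
                ev.event_id, ev.event_type, ev.gene_id, ev.gene_symbol,
                ev.chrom, ev.strand,
                ",".join(str(e.start) for e in ev.alt_exons),
                ",".join(str(e.end) for e in ev.alt_exons),
                ev.flank_up.start, ev.flank_up.end,
                ev.flank_down.start, ev.flank_down.end,
            ]
            if counts is not None:
                i = by_id[ev.event_id]
                row += [_fmt_len(counts.inc_len[i]), _fmt_len(counts.skip_len[i])]
                for j in range(len(sample_ids)):
                    row.append(_fmt_count(counts.inclusion[i, j]))
                    row.append(_fmt_count(counts.skipping[i, j]))
            else:
                row += ["1", "1"]
            w.writerow(row)


def _fmt_count(v: float) -> str:
    return "NA" if not np.isfinite(v) else str(int(v))


def _fmt_len(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# --------------------------------------------------------------------------
# GMT gene sets, sample sheets
# --------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, then tab-separated symbols)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: GMT lines need >= 3 tab-separated fields")
            name, desc, *symbols = parts
            if name in sets:
                raise ParseError(f"line {lineno}: duplicate gene-set name {name!r}")
            sets[name] = symbols
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(collection[name])) + "\n")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a TSV sample sheet: sample_id, group, then numeric covariates."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
    return SampleTable(frame)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.frame.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# --------------------------------------------------------------------------
# genome access
# --------------------------------------------------------------------------

def fetch_sequence(genome, interval: GenomicInterval) -> str:
    """Sense-strand sequence for ``interval``.

    ``genome`` is a pyfaidx.Fasta or any mapping of chromosome name to
    sequence string.  The reference slice is uppercased with U converted to T
    and reverse-complemented when the interval is on the minus strand.
    Raises ``KeyError`` for an unknown chromosome and ``IndexError`` when the
    interval exceeds the chromosome bounds.
    """
    try:
        chrom_seq = genome[interval.chrom]
    except KeyError:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    if interval.end > len(chrom_seq):
        raise IndexError(
            f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    raw = str(chrom_seq[interval.start:interval.end])
    seq = raw.upper().replace("U", "T")
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write a genome mapping as FASTA and build a .fai index next to it."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path), rebuild=True)
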