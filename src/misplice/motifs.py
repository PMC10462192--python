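"""Gapped degenerate motif grammars and splice-site-anchored window scanning.

Grammars combine IUPAC degenerate blocks with bounded gaps, e.g. the
high-affinity MBNL-binding patterns ``YGCYGCY`` and ``YGCY(N)0-5YGCY``
(Y = C/U) or the composite ``TGCT(N)3TGCT(N)13-18TGCY``.  Gap syntax accepts
``(N)min-max``, ``(N)k`` (fixed) and ``N{min,max}``.

Scanning reports every distinct (start, end) realisation, including
overlapping matches, in deterministic left-to-right, shortest-first order.
Pre-mRNA is single-stranded, so scanning is sense-strand only; minus-strand
genes are reverse-complemented at window extraction.

Windows are the two intronic flanks abutting the alternative exon (up to
``width`` nt each, truncated at the neighbouring constitutive exon), i.e. the
+/- ``width`` bp intronic context of the alternative exon's splice sites.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .enrich import ContingencyTable2x2, EnrichmentResult, _result
from .events import GenomicInterval, SplicingEvent
from .io import fetch_sequence

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class GrammarError(ValueError):
    """Malformed motif pattern; message names the offending token."""


@dataclass(frozen=True)
class Block:
    """A run of IUPAC letters matched literally (degenerately)."""

    letters: str


@dataclass(frozen=True)
class Gap:
    """A bounded run of arbitrary bases, N{lo..hi}."""

    lo: int
    hi: int


@dataclass(frozen=True)
class MotifGrammar:
    """Parsed gapped degenerate motif pattern."""

    pattern: str
    tokens: tuple
    name: str

    @property
    def min_length(self) -> int:
        return sum(len(t.letters) if isinstance(t, Block) else t.lo for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(len(t.letters) if isinstance(t, Block) else t.hi for t in self.tokens)


@dataclass(frozen=True)
class MotifHit:
    """One motif realisation inside a scanned window (0-based, sense offsets)."""

    window_id: str | None
    start: int
    end: int
    matched: str
    grammar: str


@dataclass(frozen=True)
class SpliceWindow:
    """Intronic scan window abutting one splice site of an alternative exon."""

    event_id: str
    side: str  # "upstream-intron" | "downstream-intron"
    interval: GenomicInterval
    sequence: str

    @property
    def window_id(self) -> str:
        return f"{self.event_id}:{self.side}"


_GAP_RE = re.compile(r"\(N\)(\d+)(?:[-–](\d+))?|N\{(\d+),(\d+)\}")


def parse_grammar(pattern: str, name: str | None = None) -> MotifGrammar:
    """Parse a motif pattern string into a :class:`MotifGrammar`.

    Examples: ``"YGCY"`` (one degenerate block), ``"YGCY(N)0-5YGCY"``
    (block, gap 0..5, block), ``"TGCT(N)3TGCT(N)13-18TGCY"`` (fixed gap 3).
    """
    tokens: list = []
    buf: list[str] = []
    pos = 0
    raw = pattern.strip()

    def flush() -> None:
        if buf:
            tokens.append(Block("".join(buf)))
            buf.clear()

    while pos < len(raw):
        m = _GAP_RE.match(raw, pos)
        if m:
            flush()
            if m.group(1) is not None:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
            else:
                lo, hi = int(m.group(3)), int(m.group(4))
            if lo > hi:
                raise GrammarError(f"gap bounds out of order in {m.group(0)!r}")
            tokens.append(Gap(lo, hi))
            pos = m.end()
            continue
        ch = raw[pos].upper()
        if ch not in IUPAC:
            raise GrammarError(f"unknown letter {raw[pos]!r} at position {pos} in {pattern!r}")
        buf.append("T" if ch == "U" else ch)
        pos += 1
    flush()
    if not tokens or not isinstance(tokens[0], Block) or not isinstance(tokens[-1], Block):
        raise GrammarError(f"pattern {pattern!r} must start and end with IUPAC blocks")
    return MotifGrammar(raw, tuple(tokens), name or raw)


def _block_regex(letters: str) -> str:
    out = []
    for ch in letters:
        bases = IUPAC[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


@lru_cache(maxsize=256)
def _compiled_realizations(grammar: MotifGrammar) -> tuple[tuple[int, re.Pattern], ...]:
    """One overlap-tolerant lookahead regex per gap-length combination."""
    ranges = [
        [len(t.letters)] if isinstance(t, Block) else list(range(t.lo, t.hi + 1))
        for t in grammar.tokens
    ]
    out = []
    for combo in itertools.product(*ranges):
        parts = []
        total = 0
        for tok, ln in zip(grammar.tokens, combo):
            if isinstance(tok, Block):
                parts.append(_block_regex(tok.letters))
            else:
                parts.append(f"[ACGT]{{{ln}}}" if ln else "")
            total += ln
        out.append((total, re.compile(f"(?=({''.join(parts)}))")))
    return tuple(out)


def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan(sequence: str, grammar: MotifGrammar, window_id: str | None = None) -> list[MotifHit]:
    """All matches of ``grammar`` in ``sequence``.

    Every distinct (start, end) realisation is reported (overlaps included;
    gap splits yielding the same span are collapsed), ordered left-to-right
    and shortest-first at equal start.
    """
    seq = normalize_sequence(sequence)
    spans: set[tuple[int, int]] = set()
    for total_len, rx in _compiled_realizations(grammar):
        for m in rx.finditer(seq):
            spans.add((m.start(), m.start() + total_len))
    return [
        MotifHit(window_id, s, e, seq[s:e], grammar.name)
        for s, e in sorted(spans)
    ]


def extract_windows(
    event: SplicingEvent, genome, width: int = 500
) -> list[SpliceWindow]:
    """Up to two intronic windows abutting the alternative exon of an SE event.

    The upstream-intron window covers the ``width`` intronic nt immediately
    preceding the exon's 3'SS, the downstream-intron window the ``width`` nt
    immediately following its 5'SS (transcript orientation, so mirrored on
    the minus strand); each is truncated at the neighbouring exon.  A
    zero-length intron omits its window with a warning.
    """
    if event.event_type != "SE":
        raise ValueError(f"windows are defined for SE events, not {event.event_type}")
    windows: list[SpliceWindow] = []
    for side, intron in (
        ("upstream-intron", event.intron_upstream),
        ("downstream-intron", event.intron_downstream),
    ):
        if intron is None:
            logger.warning("event %s: zero-length %s, window omitted", event.event_id, side)
            continue
        # take the `width` intronic nt adjacent to the alternative exon
        exon_left = intron.end == event.alt_start  # intron genomically left of exon
        if exon_left:
            s, e = max(intron.start, intron.end - width), intron.end
        else:
            s, e = intron.start, min(intron.end, intron.start + width)
        iv = GenomicInterval(event.chrom, s, e, event.strand)
        windows.append(SpliceWindow(event.event_id, side, iv, fetch_sequence(genome, iv)))
    return windows


def event_has_motif(
    event: SplicingEvent, genome, grammars: Sequence[MotifGrammar], width: int = 500
) -> bool | None:
    """True if any grammar hits either intronic window; None if no window exists."""
    windows = extract_windows(event, genome, width=width)
    if not windows:
        return None
    for w in windows:
        for g in grammars:
            if scan(w.sequence, g, w.window_id):
                return True
    return False


def motif_enrichment(
    foreground_events: Sequence[SplicingEvent],
    background_events: Sequence[SplicingEvent],
    genome,
    grammars: Sequence[MotifGrammar],
    width: int = 500,
    name: str = "motif",
    correction: str = "on-zero",
) -> EnrichmentResult:
    """Motif presence/absence enrichment in foreground vs background SE events.

    An event is motif-positive when >= 1 hit of ANY grammar occurs in EITHER
    of its intronic windows.  Background events that also appear in the
    foreground are excluded from the background; events with no windows at
    all are excluded with a warning.
    """
    fg_ids = {e.event_id for e in foreground_events}
    bg = [e for e in background_events if e.event_id not in fg_ids]
    counts = {"fg": [0, 0], "bg": [0, 0]}
    n_skipped = 0
    for label, group in (("fg", foreground_events), ("bg", bg)):
        for ev in group:
            pos = event_has_motif(ev, genome, grammars, width=width)
            if pos is None:
                n_skipped += 1
                continue
            counts[label][0 if pos else 1] += 1
    if n_skipped:
        logger.warning("excluded %d events without scan windows", n_skipped)
    a, b = counts["fg"]
    c, d = counts["bg"]
    table = ContingencyTable2x2(a, b, c, d)
    return _result(name, table, correction=correction, degenerate=table.has_zero_cell)


def srrm4_site_present(
    event: SplicingEvent, genome, window: tuple[int, int] = (-25, -6)
) -> bool:
    """TGC presence just upstream of an SE exon's 3'SS (intronic side).

    True when a ``TGC`` occurs with its 3' end at an offset within ``window``
    relative to the exon start (offset -1 = last intronic base).  The search
    is truncated when the upstream intron is shorter than ``|window[0]|``.
    """
    intron = event.intron_upstream
    if intron is None:
        return False
    span = min(len(intron), -window[0])
    if event.strand == "+":
        iv = GenomicInterval(event.chrom, intron.end - span, intron.end, "+")
    else:
        iv = GenomicInterval(event.chrom, intron.start, intron.start + span, "-")
    seq = fetch_sequence(genome, iv)
    L = len(seq)
    for i in range(L - 2):
        if seq[i:i + 3] == "TGC":
            offset = (i + 2) - L  # 3' end offset; last base of seq is -1
            if window[0] <= offset <= window[1]:
                return True
    return False


def hits_to_bed(window: SpliceWindow, hits: Iterable[MotifHit]) -> list[str]:
    """BED6 lines (genome coordinates) for hits found in ``window``."""
    lines = []
    iv = window.interval
    for h in hits:
        if iv.strand == "+":
            gs, ge = iv.start + h.start, iv.start + h.end
        else:
            gs, ge = iv.end - h.end, iv.end - h.start
        lines.append(f"{iv.chrom}\t{gs}\t{ge}\t{h.grammar}\t0\t{iv.strand}")
    return lines


def windows_to_bed(windows: Iterable[SpliceWindow]) -> list[str]:
    return [
        f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t{w.window_id}\t0\t{w.interval.strand}"
        for w in windows
    ]
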