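"""Core data model for alternative-splicing events and their junction counts.

Coordinates are 0-based half-open throughout the package; conversions from
1-based inclusive conventions (GTF-style) happen only at I/O boundaries.
Five basic event classes are modelled: skipped exons (SE), mutually exclusive
exons (MXE), alternative 5'/3' splice sites (A5SS/A3SS) and retained introns
(RI).  Only SE events carry a meaningful alternative-exon length, which is
what the microexon classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T on the way back)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SplicingEvent:
    """One alternative-splicing event.

    ``flank_up`` / ``flank_down`` are the flanking constitutive exons in
    *transcript* orientation: on the minus strand the upstream flank lies
    genomically to the right of the alternative exon(s).
    """

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    alt_exons: tuple[GenomicInterval, ...]
    flank_up: GenomicInterval
    flank_down: GenomicInterval

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        n_alt = len(self.alt_exons)
        if self.event_type == "MXE":
            if n_alt != 2:
                raise ValueError("MXE events need exactly 2 alternative exons")
            a, b = sorted(self.alt_exons, key=lambda e: e.start)
            if a.end > b.start:
                raise ValueError("MXE alternative exons must not overlap")
        elif n_alt != 1:
            raise ValueError(f"{self.event_type} events need exactly 1 alternative exon")
        chroms = {e.chrom for e in self.alt_exons} | {self.flank_up.chrom, self.flank_down.chrom}
        if len(chroms) != 1:
            raise ValueError("all intervals of an event must share one chromosome")
        strands = {e.strand for e in self.alt_exons} | {self.flank_up.strand, self.flank_down.strand}
        if len(strands) != 1:
            raise ValueError("all intervals of an event must share one strand")
        # transcript order: flank_up -> alt exon(s) -> flank_down
        if self.strand == "+":
            ok = self.flank_up.end <= self.alt_start and self.alt_end <= self.flank_down.start
        else:
            ok = self.flank_down.end <= self.alt_start and self.alt_end <= self.flank_up.start
        if not ok:
            raise ValueError(f"event {self.event_id}: flanking exons do not bracket the alternative exon(s)")

    @property
    def chrom(self) -> str:
        return self.flank_up.chrom

    @property
    def strand(self) -> str:
        return self.flank_up.strand

    @property
    def alt_start(self) -> int:
        return min(e.start for e in self.alt_exons)

    @property
    def alt_end(self) -> int:
        return max(e.end for e in self.alt_exons)

    @property
    def alt_exon_length(self) -> int:
        """Length of the (single) alternative exon; for MXE the first exon."""
        return len(self.alt_exons[0])

    @property
    def intron_upstream(self) -> GenomicInterval | None:
        """Transcript-upstream intron (abutting the alt exon's 3'SS); None if empty."""
        if self.strand == "+":
            s, e = self.flank_up.end, self.alt_start
        else:
            s, e = self.alt_end, self.flank_up.start
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, self.strand)

    @property
    def intron_downstream(self) -> GenomicInterval | None:
        """Transcript-downstream intron (abutting the alt exon's 5'SS); None if empty."""
        if self.strand == "+":
            s, e = self.alt_end, self.flank_down.start
        else:
            s, e = self.flank_down.end, self.alt_start
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, self.strand)


@dataclass
class EventCountsTable:
    """Per-sample inclusion/skipping junction counts for a set of events.

    Counts are stored as floats with NaN marking missing samples ("NA" in the
    input); zero is an informative observation and is never conflated with
    missingness.  ``inc_len`` / ``skip_len`` are the effective lengths of the
    inclusion and skipping isoform junction sets used for PSI normalisation.
    """

    event_ids: list[str]
    sample_ids: list[str]
    inclusion: np.ndarray
    skipping: np.ndarray
    inc_len: np.ndarray
    skip_len: np.ndarray

    def __post_init__(self) -> None:
        self.inclusion = np.asarray(self.inclusion, dtype=float)
        self.skipping = np.asarray(self.skipping, dtype=float)
        self.inc_len = np.asarray(self.inc_len, dtype=float)
        self.skip_len = np.asarray(self.skip_len, dtype=float)
        ne, ns = len(self.event_ids), len(self.sample_ids)
        if self.inclusion.shape != (ne, ns) or self.skipping.shape != (ne, ns):
            raise ValueError("count matrices must be (n_events, n_samples)")
        if self.inc_len.shape != (ne,) or self.skip_len.shape != (ne,):
            raise ValueError("effective length vectors must be (n_events,)")
        if len(set(self.event_ids)) != ne:
            raise ValueError("event ids must be unique")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("sample ids must be unique")
        for name, m in (("inclusion", self.inclusion), ("skipping", self.skipping)):
            vals = m[np.isfinite(m)]
            if vals.size and (vals < 0).any():
                raise ValueError(f"{name} counts must be non-negative")
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{name} counts must be integers")
        if (self.inc_len < 1).any() or (self.skip_len < 1).any():
            raise ValueError("effective lengths must be >= 1")

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in counts table: {missing}")
        return np.array([pos[s] for s in sample_ids], dtype=int)


class SampleTable:
    """Sample sheet: group labels plus named numeric covariates."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if "group" not in frame.columns:
            raise ValueError("sample table needs a 'group' column")
        self.frame = frame

    @classmethod
    def from_records(
        cls,
        sample_ids: Sequence[str],
        groups: Sequence[str],
        covariates: Mapping[str, Sequence[float]] | None = None,
    ) -> "SampleTable":
        data: dict[str, Sequence] = {"group": list(groups)}
        for name, vals in (covariates or {}).items():
            data[name] = list(vals)
        return cls(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def group(self, label: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == label])

    def covariate(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"covariate {name!r} not in sample table")
        return pd.to_numeric(self.frame[name])


class GeneSetCollection:
    """Named gene sets with case-normalised (uppercase) symbols."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self.sets: dict[str, frozenset[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, symbols in sets.items():
            if name in self.sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            normalised = frozenset(s.strip().upper() for s in symbols if s.strip())
            if not normalised:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = normalised
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()
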