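"""Ground-truth simulator for the whole pipeline.

Generates splicing events with genomic structure, replicate junction counts,
gene sets, intronic sequences with planted RNA-binding-protein motifs and
per-sample covariates — everything the analysis stages consume — together
with a truth table, so recovery and calibration are testable end to end
without external data.

Counting model (hierarchical, per event x sample):

    total junction reads  T ~ NegativeBinomial(mean, dispersion)
    inclusion reads       I ~ BetaBinomial(T, q, precision),  S = T - I

where q = psi*lI / (psi*lI + (1 - psi)*lS) is the inclusion-read fraction
implied by the true PSI and the effective junction lengths, so the PSI
length-normalisation path is exercised non-trivially.  The beta-binomial
precision (default 50) emulates biological overdispersion between
replicates; ``bb_precision=None`` gives a pure binomial for exactness tests.

True effects are placed by exact-count allocation within strata (e.g. genes
inside vs outside an enriched set, microexon vs other SE events): the base
odds are solved so the stratum odds ratios hit the configured multiplier and
counts are rounded by largest remainder.  This makes the planted odds ratio
a controlled ground truth instead of a Bernoulli average.

Genomes put half the genes on the minus strand to exercise strand handling.
The two intronic scan windows of each SE event are scrubbed of chance motif
matches before planting, so the per-event motif-positive truth flag is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .events import (
    EventCountsTable,
    GeneSetCollection,
    GenomicInterval,
    SampleTable,
    SplicingEvent,
)
from .io import write_events_table, write_fasta, write_gene_sets, write_sample_table
from .motifs import Block, IUPAC, MotifGrammar, parse_grammar, scan
from .psi import MICROEXON_MAX, MICROEXON_MIN, classify_microexon

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: effective junction lengths (inclusion, skipping) per event type; SE counts
#: two inclusion junctions against one skipping junction.
EFFECTIVE_LENGTHS = {
    "SE": (98.0, 49.0),
    "MXE": (98.0, 98.0),
    "A5SS": (98.0, 49.0),
    "A3SS": (98.0, 49.0),
    "RI": (147.0, 49.0),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    n_genes: int = 500
    events_per_gene_mean: float = 2.0  # count = 1 + Poisson(mean - 1)
    type_mixture: dict = field(
        default_factory=lambda: {"SE": 0.7, "MXE": 0.1, "A5SS": 0.08, "A3SS": 0.08, "RI": 0.04}
    )
    mie_fraction: float = 0.05  # fraction of SE events drawn 3-33 nt (exact count)
    n_case: int = 21  # DM1-style design: 21 cases vs 8 controls
    n_ctrl: int = 8
    frac_mis_spliced: float = 0.05
    effect_low: float = 0.15
    effect_high: float = 0.5
    effect_sign: str = "random"  # "random" | "negative"
    psi0_mis_range: tuple[float, float] = (0.25, 0.75)
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0  # NB shape; var = mu + mu^2 / shape
    bb_precision: float | None = 50.0
    effect_unit: str = "event"  # "event" | "gene"
    # gene-set design
    n_sets: int = 0
    set_size: int = 25
    n_enriched_sets: int = 0
    set_odds_multiplier: float = 1.0
    # microexon disproportion design
    mie_odds_multiplier: float = 1.0
    # genome / motif design
    with_genome: bool = False
    motif_p_fg: float = 0.7
    motif_p_bg: float = 0.2
    planted_grammar: str = "YGCYGCY"
    scan_grammars: tuple[str, ...] = ("YGCYGCY", "YGCY(N)0-5YGCY")
    window_width: int = 500
    # dose-response design
    dose_response: bool = False
    covariate_name: str = "CTG_length"
    covariate_range: tuple[float, float] = (200.0, 800.0)
    # structure
    flank_len: int = 150
    intron_range: tuple[int, int] = (620, 1100)
    short_intron_prob: float = 0.05
    short_intron_range: tuple[int, int] = (60, 450)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("n_genes and group sizes must be positive")
        if abs(sum(self.type_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("event-type mixture must sum to 1")
        for name, p in (
            ("mie_fraction", self.mie_fraction),
            ("frac_mis_spliced", self.frac_mis_spliced),
            ("motif_p_fg", self.motif_p_fg),
            ("motif_p_bg", self.motif_p_bg),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.effect_low <= self.effect_high <= 1:
            raise ValueError("effect bounds must satisfy 0 < low <= high <= 1")
        if self.effect_sign not in ("random", "negative"):
            raise ValueError("effect_sign must be 'random' or 'negative'")
        if self.effect_unit not in ("event", "gene"):
            raise ValueError("effect_unit must be 'event' or 'gene'")
        if self.set_odds_multiplier <= 0 or self.mie_odds_multiplier <= 0:
            raise ValueError("odds multipliers must be positive")
        if self.n_sets and self.set_size > self.n_genes:
            raise ValueError("set_size exceeds the number of genes")
        if self.n_enriched_sets > self.n_sets:
            raise ValueError("n_enriched_sets exceeds n_sets")
        if self.bb_precision is not None and self.bb_precision <= 0:
            raise ValueError("bb_precision must be positive (or None for binomial)")


@dataclass
class SimulatedDataset:
    """One simulated dataset plus its ground truth."""

    config: SimConfig
    events: list[SplicingEvent]
    counts: EventCountsTable
    samples: SampleTable
    gene_sets: GeneSetCollection | None
    genome: dict[str, str] | None
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Emit the exact input formats the pipeline reads, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_events_table(self.events, self.counts, outdir / "events.tsv",
                           header_comments=[f"seed={self.config.seed}"])
        write_sample_table(self.samples, outdir / "samples.tsv")
        if self.gene_sets is not None:
            write_gene_sets(self.gene_sets, outdir / "gene_sets.gmt")
        if self.genome is not None:
            write_fasta(self.genome, outdir / "genome.fa")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", na_rep="NA")


# --------------------------------------------------------------------------
# event structure
# --------------------------------------------------------------------------

def _draw_intron(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.short_intron_prob:
        lo, hi = cfg.short_intron_range
    else:
        lo, hi = cfg.intron_range
    return int(rng.integers(lo, hi + 1))


def _build_event(
    rng: np.random.Generator,
    cfg: SimConfig,
    event_id: str,
    etype: str,
    gene_id: str,
    symbol: str,
    chrom: str,
    strand: str,
    cursor: int,
    alt_len: int,
) -> tuple[SplicingEvent, int]:
    """Lay one event cassette down at ``cursor``; return the event and new cursor."""
    F = cfg.flank_len
    iv = lambda s, e: GenomicInterval(chrom, s, e, strand)
    if etype in ("SE", "MXE"):
        i_a = _draw_intron(rng, cfg)
        i_b = _draw_intron(rng, cfg)
        left = iv(cursor, cursor + F)
        p = cursor + F + i_a
        if etype == "SE":
            alts = (iv(p, p + alt_len),)
            p += alt_len
        else:
            l2 = int(rng.integers(80, 151))
            mid = int(rng.integers(150, 401))
            e1 = iv(p, p + alt_len)
            e2 = iv(p + alt_len + mid, p + alt_len + mid + l2)
            alts = (e1, e2)
            p = e2.end
        right = iv(p + i_b, p + i_b + F)
        cursor = right.end + 100
        fu, fd = (left, right) if strand == "+" else (right, left)
    elif etype in ("A5SS", "A3SS"):
        i_a = int(rng.integers(300, 801))
        # alt region abuts the transcript-upstream flank for A5SS,
        # the transcript-downstream flank for A3SS
        alt_at_up = (etype == "A5SS")
        alt_left = alt_at_up if strand == "+" else not alt_at_up
        if alt_left:
            first = iv(cursor, cursor + F)
            alt = iv(cursor + F, cursor + F + alt_len)
            second = iv(alt.end + i_a, alt.end + i_a + F)
        else:
            first = iv(cursor, cursor + F)
            alt = iv(cursor + F + i_a, cursor + F + i_a + alt_len)
            second = iv(alt.end, alt.end + F)
        cursor = second.end + 100
        fu, fd = (first, second) if strand == "+" else (second, first)
        alts = (alt,)
    else:  # RI
        left = iv(cursor, cursor + F)
        alt = iv(left.end, left.end + alt_len)  # the retained intron
        right = iv(alt.end, alt.end + F)
        cursor = right.end + 100
        fu, fd = (left, right) if strand == "+" else (right, left)
        alts = (alt,)
    return SplicingEvent(event_id, etype, gene_id, symbol, alts, fu, fd), cursor


def _generate_events(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[list[SplicingEvent], dict[str, int]]:
    """Events for all genes; returns events and chromosome lengths."""
    types = list(cfg.type_mixture)
    probs = np.array([cfg.type_mixture[t] for t in types])
    n_per_gene = 1 + rng.poisson(max(cfg.events_per_gene_mean - 1.0, 0.0), cfg.n_genes)
    gene_strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    etypes: list[str] = []
    gene_of: list[int] = []
    for g in range(cfg.n_genes):
        for _ in range(n_per_gene[g]):
            etypes.append(types[rng.choice(len(types), p=probs)])
            gene_of.append(g)
    se_idx = [i for i, t in enumerate(etypes) if t == "SE"]
    n_mie = int(round(cfg.mie_fraction * len(se_idx)))
    mie_set = set(rng.choice(se_idx, size=n_mie, replace=False)) if n_mie else set()
    alt_lens = []
    for i, t in enumerate(etypes):
        if t == "SE":
            if i in mie_set:
                alt_lens.append(int(rng.integers(MICROEXON_MIN, MICROEXON_MAX + 1)))
            else:
                alt_lens.append(int(np.clip(rng.normal(120, 40), MICROEXON_MAX + 1, 300)))
        elif t == "MXE":
            alt_lens.append(int(rng.integers(80, 151)))
        elif t in ("A5SS", "A3SS"):
            alt_lens.append(int(rng.integers(20, 101)))
        else:
            alt_lens.append(int(rng.integers(200, 601)))
    events: list[SplicingEvent] = []
    chrom_lens: dict[str, int] = {}
    cursor = 0
    current_gene = -1
    chrom = ""
    for i, (t, g) in enumerate(zip(etypes, gene_of)):
        if g != current_gene:
            if current_gene >= 0:
                chrom_lens[chrom] = cursor + 100
            current_gene = g
            chrom = f"chr_g{g:05d}"
            cursor = 100
        ev, cursor = _build_event(
            rng, cfg, f"{t}_{i:06d}", t, f"g{g:05d}", f"GENE{g:05d}",
            chrom, str(gene_strands[g]), cursor, alt_lens[i],
        )
        events.append(ev)
    if chrom:
        chrom_lens[chrom] = cursor + 100
    return events, chrom_lens


# --------------------------------------------------------------------------
# effect placement
# --------------------------------------------------------------------------

def _allocate_exact(
    rng: np.random.Generator,
    stratum_of: np.ndarray,
    weights: dict[int, float],
    n_target: int,
) -> np.ndarray:
    """Pick exactly ``n_target`` items so stratum odds hit the configured ratios.

    Solves the base odds o0 with stratum odds w_s * o0, then rounds expected
    stratum counts by largest remainder.  Raises when the allocation is
    infeasible (a stratum would need more items than it has).
    """
    n = len(stratum_of)
    flags = np.zeros(n, dtype=bool)
    if n_target == 0:
        return flags
    if n_target > n:
        raise ValueError(f"cannot place {n_target} effects among {n} items")
    strata, counts = np.unique(stratum_of, return_counts=True)
    w = np.array([weights.get(int(s), 1.0) for s in strata])

    def total(o0: float) -> float:
        ps = w * o0 / (1.0 + w * o0)
        return float((counts * ps).sum()) - n_target

    if n_target == n:
        expected = counts.astype(float)
    else:
        o0 = brentq(total, 1e-12, 1e12)
        expected = counts * (w * o0 / (1.0 + w * o0))
    base = np.floor(expected).astype(int)
    rem = n_target - int(base.sum())
    if rem > 0:
        order = np.argsort(-(expected - base), kind="stable")
        base[order[:rem]] += 1
    if (base > counts).any():
        raise ValueError("infeasible effect allocation: stratum smaller than its quota")
    for s, k in zip(strata, base):
        if k:
            members = np.flatnonzero(stratum_of == s)
            flags[rng.choice(members, size=int(k), replace=False)] = True
    return flags


def _place_effects(
    rng: np.random.Generator,
    cfg: SimConfig,
    events: Sequence[SplicingEvent],
    enriched_genes: frozenset[str],
) -> np.ndarray:
    n = len(events)
    if cfg.effect_unit == "gene":
        genes = sorted({e.gene_symbol for e in events})
        stratum = np.array([1 if g in enriched_genes else 0 for g in genes])
        n_target = int(round(cfg.frac_mis_spliced * len(genes)))
        flags = _allocate_exact(rng, stratum, {1: cfg.set_odds_multiplier}, n_target)
        chosen = {g for g, f in zip(genes, flags) if f}
        return np.array([e.gene_symbol in chosen for e in events])
    stratum = np.array([
        1 if (e.event_type == "SE" and classify_microexon(e)) else 0 for e in events
    ])
    n_target = int(round(cfg.frac_mis_spliced * n))
    return _allocate_exact(rng, stratum, {1: cfg.mie_odds_multiplier}, n_target)


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator,
    cfg: SimConfig,
    psi_true: np.ndarray,
    inc_len: np.ndarray,
    skip_len: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    mu, shape = cfg.coverage_mean, cfg.coverage_dispersion
    T = rng.negative_binomial(shape, shape / (shape + mu), size=psi_true.shape)
    q = psi_true * inc_len[:, None]
    q = q / (q + (1.0 - psi_true) * skip_len[:, None])
    q = np.clip(q, 1e-9, 1.0 - 1e-9)
    if cfg.bb_precision is None:
        p = q
    else:
        rho = cfg.bb_precision
        p = rng.beta(q * rho, (1.0 - q) * rho)
    I = rng.binomial(T, p)
    return I.astype(float), (T - I).astype(float)


# --------------------------------------------------------------------------
# genome + motif planting
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _sense_set(seq: list[str], iv: GenomicInterval, offset: int, base: str) -> None:
    if iv.strand == "+":
        seq[iv.start + offset] = base
    else:
        seq[iv.end - 1 - offset] = _COMP[base]


def _sense_get(seq: list[str], iv: GenomicInterval) -> str:
    s = "".join(seq[iv.start:iv.end])
    if iv.strand == "-":
        s = "".join(_COMP[c] for c in reversed(s))
    return s


def _scan_window_intervals(event: SplicingEvent, width: int) -> list[GenomicInterval]:
    out = []
    for intron in (event.intron_upstream, event.intron_downstream):
        if intron is None:
            continue
        if intron.end == event.alt_start:
            s, e = max(intron.start, intron.end - width), intron.end
        else:
            s, e = intron.start, min(intron.end, intron.start + width)
        out.append(GenomicInterval(event.chrom, s, e, event.strand))
    return out


def _scrub(seq: list[str], iv: GenomicInterval, grammars: Sequence[MotifGrammar]) -> None:
    """Remove every grammar hit from a window by blanking first-block spans to A.

    A matches none of the grammar block letters used here (they all require
    C/G/T subsets), so blanking strictly destroys matches and creates none;
    the loop terminates.
    """
    for _ in range(10_000):
        s = _sense_get(seq, iv)
        hit = None
        for g in grammars:
            hits = scan(s, g)
            if hits:
                hit = (hits[0], g)
                break
        if hit is None:
            return
        h, g = hit
        block0 = next(t for t in g.tokens if isinstance(t, Block))
        for k in range(len(block0.letters)):
            _sense_set(seq, iv, h.start + k, "A")
    raise RuntimeError("motif scrubbing did not converge")  # pragma: no cover


def _realize(rng: np.random.Generator, grammar: MotifGrammar) -> str:
    out = []
    for tok in grammar.tokens:
        if isinstance(tok, Block):
            for ch in tok.letters:
                out.append(str(rng.choice(list(IUPAC[ch]))))
        else:
            ln = int(rng.integers(tok.lo, tok.hi + 1))
            out.extend(rng.choice(_BASES, size=ln).tolist())
    return "".join(out)


def _build_genome(
    rng: np.random.Generator,
    cfg: SimConfig,
    events: Sequence[SplicingEvent],
    chrom_lens: dict[str, int],
    mis_flags: np.ndarray,
) -> tuple[dict[str, str], np.ndarray, np.ndarray]:
    """Random genome with per-event motif planting in scrubbed scan windows.

    Returns (genome, motif_positive (object: True/False/NaN), planted genomic
    start (-1 when nothing planted)).
    """
    seqs: dict[str, list[str]] = {
        c: rng.choice(_BASES, size=n).tolist() for c, n in chrom_lens.items()
    }
    grammars = [parse_grammar(p) for p in cfg.scan_grammars]
    planted_grammar = parse_grammar(cfg.planted_grammar)
    if cfg.planted_grammar not in cfg.scan_grammars:
        grammars.append(planted_grammar)
    positive = np.full(len(events), np.nan, dtype=object)
    planted_at = np.full(len(events), -1, dtype=int)
    for i, ev in enumerate(events):
        if ev.event_type != "SE":
            continue
        wins = _scan_window_intervals(ev, cfg.window_width)
        if not wins:
            positive[i] = False
            continue
        for iv in wins:
            _scrub(seqs[ev.chrom], iv, grammars)
        p = cfg.motif_p_fg if mis_flags[i] else cfg.motif_p_bg
        plant = bool(rng.random() < p)
        positive[i] = plant
        if plant:
            # plant into the transcript-downstream window when it exists
            target = wins[-1]
            real = _realize(rng, planted_grammar)
            if len(real) > len(target):
                target = max(wins, key=len)
            start = int(rng.integers(0, len(target) - len(real) + 1))
            for k, base in enumerate(real):
                _sense_set(seqs[ev.chrom], target, start + k, base)
            planted_at[i] = (
                target.start + start if target.strand == "+"
                else target.end - start - len(real)
            )
    genome = {c: "".join(s) for c, s in seqs.items()}
    return genome, positive, planted_at


# --------------------------------------------------------------------------
# top-level simulation
# --------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    events, chrom_lens = _generate_events(rng, config)
    n = len(events)
    gene_symbols = sorted({e.gene_symbol for e in events})

    gene_sets = None
    enriched_genes: frozenset[str] = frozenset()
    if config.n_sets:
        sets = {}
        for k in range(config.n_sets):
            members = rng.choice(gene_symbols, size=config.set_size, replace=False)
            sets[f"SET{k + 1:02d}"] = list(members)
        gene_sets = GeneSetCollection(
            sets, {name: "simulated gene set" for name in sets}
        )
        enriched = [f"SET{k + 1:02d}" for k in range(config.n_enriched_sets)]
        enriched_genes = frozenset().union(*(gene_sets[e] for e in enriched)) if enriched else frozenset()

    mis = _place_effects(rng, config, events, enriched_genes)

    psi0 = rng.uniform(0.05, 0.95, size=n)
    lo, hi = config.psi0_mis_range
    psi0[mis] = rng.uniform(lo, hi, size=int(mis.sum()))
    delta = np.zeros(n)
    if mis.any():
        mag = rng.uniform(config.effect_low, config.effect_high, size=int(mis.sum()))
        if config.effect_sign == "negative":
            # forced exclusion: keep the sign, clip the magnitude at the floor
            target = np.clip(psi0[mis] - mag, 0.02, 0.98)
        else:
            sign = rng.choice([-1.0, 1.0], size=int(mis.sum()))
            target = psi0[mis] + sign * mag
            flip = (target < 0.02) | (target > 0.98)
            sign[flip] *= -1.0
            target = np.clip(psi0[mis] + sign * mag, 0.02, 0.98)
        delta[mis] = target - psi0[mis]
    psi_case = psi0 + delta

    case_ids = [f"CASE{i + 1:02d}" for i in range(config.n_case)]
    ctrl_ids = [f"CTRL{i + 1:02d}" for i in range(config.n_ctrl)]
    if config.dose_response:
        cov = np.linspace(*config.covariate_range, config.n_case)
        scale = cov / cov.max()
        covariates = {config.covariate_name: list(cov) + [np.nan] * config.n_ctrl}
    else:
        scale = np.ones(config.n_case)
        covariates = {}
    samples = SampleTable.from_records(
        case_ids + ctrl_ids,
        ["case"] * config.n_case + ["control"] * config.n_ctrl,
        covariates,
    )

    psi_true = np.empty((n, config.n_case + config.n_ctrl))
    psi_true[:, config.n_case:] = psi0[:, None]
    psi_true[:, :config.n_case] = np.clip(
        psi0[:, None] + delta[:, None] * scale[None, :], 0.01, 0.99
    )
    inc_len = np.array([EFFECTIVE_LENGTHS[e.event_type][0] for e in events])
    skip_len = np.array([EFFECTIVE_LENGTHS[e.event_type][1] for e in events])
    I, S = _draw_counts(rng, config, psi_true, inc_len, skip_len)
    counts = EventCountsTable(
        [e.event_id for e in events], case_ids + ctrl_ids, I, S, inc_len, skip_len
    )

    genome = None
    motif_pos = np.full(n, np.nan, dtype=object)
    planted_at = np.full(n, -1, dtype=int)
    if config.with_genome:
        genome, motif_pos, planted_at = _build_genome(rng, config, events, chrom_lens, mis)

    truth = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "gene_symbol": [e.gene_symbol for e in events],
            "event_type": [e.event_type for e in events],
            "alt_exon_length": [e.alt_exon_length for e in events],
            "is_microexon_true": [classify_microexon(e) for e in events],
            "is_mis_spliced_true": mis,
            "psi_ctrl_true": psi0,
            "psi_case_true": psi_case,
            "true_dpsi": np.where(mis, psi_case - psi0, 0.0),
            "motif_positive": motif_pos,
            "planted_start": planted_at,
        },
        index=pd.Index([e.event_id for e in events], name="event_id"),
    )
    return SimulatedDataset(config, events, counts, samples, gene_sets, genome, truth)


def simulate_null(config: SimConfig) -> SimulatedDataset:
    """Same generative process with all effects zeroed and uniform motif planting."""
    null_cfg = replace(
        config,
        frac_mis_spliced=0.0,
        dose_response=False,
        motif_p_fg=config.motif_p_bg,
        set_odds_multiplier=1.0,
        mie_odds_multiplier=1.0,
    )
    return simulate_dataset(null_cfg)


@dataclass
class DevelopmentDataset:
    """Per-time-point PSI with a rising regulator-expression covariate."""

    events: list[SplicingEvent]
    psi_by_timepoint: pd.DataFrame
    expression: pd.Series
    truth: pd.DataFrame


def simulate_development(
    config: SimConfig,
    n_timepoints: int = 9,
    n_replicates: int = 2,
) -> DevelopmentDataset:
    """Monotone developmental PSI trajectories for a subset of events.

    Affected events shift from psi0 to psi0 + delta along a linear ramp over
    the ordered time points, mimicking splicing transitions that track a
    splicing factor whose expression rises with maturation; the returned
    ``expression`` covariate follows the same ramp.
    """
    config.validate()
    if n_timepoints < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(config.seed)
    events, _ = _generate_events(rng, config)
    n = len(events)
    mis = _place_effects(rng, config, events, frozenset())
    psi0 = rng.uniform(0.05, 0.95, size=n)
    lo, hi = config.psi0_mis_range
    psi0[mis] = rng.uniform(lo, hi, size=int(mis.sum()))
    delta = np.zeros(n)
    if mis.any():
        mag = rng.uniform(config.effect_low, config.effect_high, size=int(mis.sum()))
        sign = np.where(psi0[mis] > 0.5, -1.0, 1.0)
        delta[mis] = sign * mag
    ramp = np.linspace(0.0, 1.0, n_timepoints)
    inc_len = np.array([EFFECTIVE_LENGTHS[e.event_type][0] for e in events])
    skip_len = np.array([EFFECTIVE_LENGTHS[e.event_type][1] for e in events])
    tp_names = [f"T{t:02d}" for t in range(n_timepoints)]
    cols = {}
    from .psi import compute_psi

    for t, f in zip(tp_names, ramp):
        psi_t = np.clip(psi0 + delta * f, 0.01, 0.99)
        reps = np.repeat(psi_t[:, None], n_replicates, axis=1)
        I, S = _draw_counts(rng, config, reps, inc_len, skip_len)
        psi_hat = compute_psi(I, S, inc_len[:, None], skip_len[:, None])
        cols[t] = np.nanmean(psi_hat, axis=1)
    psi_by_tp = pd.DataFrame(
        cols, index=pd.Index([e.event_id for e in events], name="event_id")
    )
    expression = pd.Series(5.0 + 45.0 * ramp, index=tp_names, name="mbnl_expression")
    truth = pd.DataFrame(
        {
            "is_mis_spliced_true": mis,
            "psi_start_true": psi0,
            "true_dpsi": delta,
        },
        index=psi_by_tp.index,
    )
    return DevelopmentDataset(events, psi_by_tp, expression, truth)
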