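"""Simulation studies: oracle agreement, null calibration and effect recovery.

Each function here runs one scenario of the package's validation suite under
fixed study conditions and returns the measured quantities.  The scenarios
are sized for a single CPU: a DM1-style case/control design (21 vs 8
samples) for recovery scenarios, a 3 vs 3 design for the null calibration
(matching the small mouse cohorts the exact permutation test is meant for),
and ~500-2,000 events per dataset.

The oracles used for agreement checks are deliberately independent of the
implementation they test: the Fisher oracle enumerates hypergeometric point
probabilities in exact rational arithmetic, the permutation oracle
enumerates label assignments with ``itertools.combinations``, and the motif
oracle tests every substring against the grammar with a recursive
backtracking matcher.
"""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np

from .covariates import burden_covariate_correlation, case_burden_from_results
from .enrich import (
    ContingencyTable2x2,
    fisher_exact_2x2,
    gene_set_enrichment,
    microexon_enrichment,
)
from .events import GenomicInterval, SplicingEvent
from .motifs import Block, IUPAC, motif_enrichment, normalize_sequence, parse_grammar, scan
from .psi import classify_microexon, mis_spliced_genes, psi_matrix, run_differential
from .simulate import SimConfig, simulate_dataset, simulate_null

#: the three grammar patterns exercised throughout
GRAMMAR_PATTERNS = ("YGCYGCY", "YGCY(N)0-5YGCY", "TGCT(N)3TGCT(N)13-18TGCY")


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# --------------------------------------------------------------------------
# Fisher oracle agreement
# --------------------------------------------------------------------------

def fisher_p_rational(a: int, b: int, c: int, d: int, tie_tol: float = 1e-7) -> float:
    """Two-sided Fisher p in exact rational arithmetic (enumeration oracle)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    denom = comb(n, row1)
    pmf = {
        x: Fraction(comb(col1, x) * comb(n - col1, row1 - x), denom)
        for x in range(lo, hi + 1)
    }
    cut = pmf[a] * (1 + Fraction(tie_tol))
    p = sum(q for q in pmf.values() if q <= cut)
    return float(min(p, Fraction(1)))


def fisher_agreement(n_tables: int = 1000, max_margin: int = 30, seed: int = 0) -> dict:
    """Max |p_impl - p_oracle| over random 2x2 tables with margins <= max_margin."""
    rng = np.random.default_rng(seed)
    half = max_margin // 2
    worst = 0.0
    done = 0
    while done < n_tables:
        a, b, c, d = (int(x) for x in rng.integers(0, half + 1, size=4))
        if a + b + c + d == 0:
            continue
        p_impl = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        p_ref = fisher_p_rational(a, b, c, d)
        worst = max(worst, abs(p_impl - p_ref))
        done += 1
    return {"max_abs_diff": worst, "n": n_tables}


# --------------------------------------------------------------------------
# permutation-test exactness
# --------------------------------------------------------------------------

def _exhaustive_perm_p(case_vals: np.ndarray, ctrl_vals: np.ndarray) -> float:
    """Two-sided permutation p by full enumeration of label assignments."""
    vals = np.concatenate([case_vals, ctrl_vals])
    m, m_case = len(vals), len(case_vals)
    obs = case_vals.mean() - ctrl_vals.mean()
    count = total = 0
    for idx in combinations(range(m), m_case):
        sel = np.zeros(m, dtype=bool)
        sel[list(idx)] = True
        stat = vals[sel].mean() - vals[~sel].mean()
        count += abs(stat) >= abs(obs) - 1e-12
        total += 1
    return count / total


def permutation_agreement(n_events: int = 100, seed: int = 0) -> dict:
    """Implementation p vs enumeration oracle for random 3v3 events."""
    from .events import EventCountsTable, SampleTable

    rng = np.random.default_rng(seed)
    n_samples = 6
    I = rng.integers(0, 120, size=(n_events, n_samples)).astype(float)
    S = rng.integers(0, 120, size=(n_events, n_samples)).astype(float)
    low = (I + S) < 10
    I[low] += 10  # keep every sample informative
    ids = [f"E{i}" for i in range(n_events)]
    counts = EventCountsTable(
        ids, [f"S{j}" for j in range(n_samples)], I, S,
        np.full(n_events, 98.0), np.full(n_events, 49.0),
    )
    samples = SampleTable.from_records(
        [f"S{j}" for j in range(n_samples)], ["case"] * 3 + ["control"] * 3
    )
    from .psi import compute_psi, differential_splicing

    res = differential_splicing(counts, samples, "case", "control", seed=seed)
    psi = compute_psi(I, S, np.full((n_events, 1), 98.0), np.full((n_events, 1), 49.0))
    worst = 0.0
    for i, eid in enumerate(ids):
        p_ref = _exhaustive_perm_p(psi[i, :3], psi[i, 3:])
        worst = max(worst, abs(res.loc[eid, "p_value"] - p_ref))
    return {"max_abs_diff": worst, "n": n_events}


# --------------------------------------------------------------------------
# null calibration
# --------------------------------------------------------------------------

def _null_config(seed: int, **overrides) -> SimConfig:
    base = SimConfig(
        seed=seed, n_genes=1000, events_per_gene_mean=2.0,
        n_case=3, n_ctrl=3, coverage_mean=100.0,
    )
    return replace(base, **overrides)


def null_event_calibration(n_seeds: int = 5, seed: int = 0) -> dict:
    """Fraction of events flagged mis-spliced on effect-free data (3v3, ~2,000 events)."""
    pcts = []
    n_events = 0
    for s in child_seeds(seed, n_seeds):
        ds = simulate_null(_null_config(s))
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        evaluable = res["fdr"].notna()
        n_events = int(evaluable.sum())
        pcts.append(100.0 * res.loc[evaluable, "is_mis_spliced"].mean())
    return {"flagged_pct": pcts, "max_pct": max(pcts), "mean_pct": float(np.mean(pcts)),
            "n": n_events}


def null_gene_set_calibration(n_seeds: int = 50, seed: int = 0) -> dict:
    """Gene-set false-flag rate (FDR < 0.05) on effect-free pipeline output."""
    fracs = []
    for s in child_seeds(seed, n_seeds):
        ds = simulate_null(_null_config(s, n_sets=38, set_size=25))
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        mis, universe = mis_spliced_genes(res)
        enr = gene_set_enrichment(mis, universe, ds.gene_sets)
        fracs.append(100.0 * float((enr["fdr"] < 0.05).mean()))
    return {"flagged_pct": fracs, "mean_pct": float(np.mean(fracs)), "n": 38}


def null_gene_set_random_foreground(
    n_seeds: int = 50,
    n_genes: int = 1000,
    frac_foreground: float = 0.07,
    n_sets: int = 38,
    set_size: int = 25,
    seed: int = 0,
) -> dict:
    """Gene-set calibration with a uniformly random foreground (no pipeline).

    Exercises the Fisher/BH machinery itself: the foreground is drawn
    uniformly from the universe, so no set is truly enriched.
    """
    fracs, medians = [], []
    universe = [f"GENE{i:05d}" for i in range(n_genes)]
    for s in child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        fg = rng.choice(universe, size=int(round(frac_foreground * n_genes)), replace=False)
        sets = {
            f"SET{k:02d}": rng.choice(universe, size=set_size, replace=False).tolist()
            for k in range(n_sets)
        }
        enr = gene_set_enrichment(set(fg), universe, sets.items())
        fracs.append(100.0 * float((enr["fdr"] < 0.05).mean()))
        medians.append(float(enr["odds_ratio"].median()))
    return {
        "flagged_pct": fracs, "mean_pct": float(np.mean(fracs)),
        "median_or": medians, "median_or_overall": float(np.median(medians)),
        "n": n_sets,
    }


# --------------------------------------------------------------------------
# effect recovery
# --------------------------------------------------------------------------

def effect_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """DPSI estimation error and sensitivity for planted |DPSI| = 0.3 effects.

    21 vs 8 samples, per-sample coverage ~200 junction reads, ~500 events of
    which 20% carry a true effect of exactly 0.3 (random sign).
    """
    errors, sens = [], []
    for s in child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=s, n_genes=250, events_per_gene_mean=2.0,
            frac_mis_spliced=0.2, effect_low=0.3, effect_high=0.3,
            psi0_mis_range=(0.35, 0.65), coverage_mean=200.0,
        )
        ds = simulate_dataset(cfg)
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        truth = ds.truth.loc[res.index]
        planted = truth["is_mis_spliced_true"].to_numpy()
        est = res["dpsi"].to_numpy()
        ok = planted & np.isfinite(est)
        errors.append(float(np.mean(np.abs(est[ok] - truth.loc[ok, "true_dpsi"].to_numpy()))))
        sens.append(100.0 * float(res.loc[planted, "is_mis_spliced"].mean()))
    return {
        "abs_error": errors, "mean_abs_error": float(np.mean(errors)),
        "sensitivity_pct": sens, "mean_sensitivity_pct": float(np.mean(sens)),
        "n": 500,
    }


def gene_set_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of a gene-set enrichment planted at odds ratio 4.

    500 genes, 38 sets of 100 genes; effects are placed on genes with the
    focal set's odds multiplied by 4 over a base rate of 8% mis-spliced genes.
    """
    ors, fdrs = [], []
    for s in child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=s, n_genes=500, events_per_gene_mean=2.0,
            frac_mis_spliced=0.08, effect_unit="gene",
            n_sets=38, set_size=100, n_enriched_sets=1, set_odds_multiplier=4.0,
            coverage_mean=100.0,
        )
        ds = simulate_dataset(cfg)
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        mis, universe = mis_spliced_genes(res)
        enr = gene_set_enrichment(mis, universe, ds.gene_sets)
        ors.append(float(enr.loc["SET01", "odds_ratio"]))
        fdrs.append(float(enr.loc["SET01", "fdr"]))
    return {"odds_ratio": ors, "median_or": float(np.median(ors)),
            "fdr": fdrs, "n": n_seeds}


def mie_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of microexon disproportion among mis-spliced SE events.

    Effects are placed on events with microexon odds multiplied by 5 over a
    10% base rate (~2,000 events, 5% of SE are microexons).  The measured
    table follows the convention background = all evaluable SE events, which
    attenuates the observed OR relative to the planted conditional odds
    ratio (expected ~3.7 at these rates).
    """
    ors, ps = [], []
    for s in child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=s, n_genes=1000, events_per_gene_mean=2.0,
            frac_mis_spliced=0.1, mie_odds_multiplier=5.0,
            coverage_mean=100.0,
        )
        ds = simulate_dataset(cfg)
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        r = microexon_enrichment(res)
        ors.append(r.odds_ratio)
        ps.append(r.p_value)
    return {"odds_ratio": ors, "median_or": float(np.median(ors)), "p_value": ps,
            "n": n_seeds}


def motif_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of intronic motif enrichment planted at 0.7 vs 0.2 positivity.

    1,000 single-SE genes with genomes; 20% of events carry true effects and
    get a planted YGCYGCY site with probability 0.7 (0.2 otherwise).
    Foreground = detected mis-spliced events; background = all evaluable
    events (the test itself excludes the foreground from the background).
    """
    ors, ci_lows, ps = [], [], []
    grammars = [parse_grammar(p) for p in ("YGCYGCY", "YGCY(N)0-5YGCY")]
    for s in child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=s, n_genes=1000, events_per_gene_mean=1.0,
            type_mixture={"SE": 1.0}, frac_mis_spliced=0.2,
            with_genome=True, motif_p_fg=0.7, motif_p_bg=0.2,
            coverage_mean=100.0,
        )
        ds = simulate_dataset(cfg)
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        by_id = {e.event_id: e for e in ds.events}
        fg = [by_id[i] for i in res.index[res["is_mis_spliced"]]]
        bg = [by_id[i] for i in res.index[res["fdr"].notna()]]
        r = motif_enrichment(fg, bg, ds.genome, grammars)
        ors.append(r.odds_ratio)
        ci_lows.append(r.ci_low)
        ps.append(r.p_value)
    return {"odds_ratio": ors, "median_or": float(np.median(ors)),
            "ci_low": ci_lows, "p_value": ps, "n": n_seeds}


# --------------------------------------------------------------------------
# motif scanner oracle agreement
# --------------------------------------------------------------------------

def _brute_match(s: str, tokens: tuple, i: int = 0, ti: int = 0) -> bool:
    """Recursive full-match of a token tuple against a substring (oracle)."""
    if ti == len(tokens):
        return i == len(s)
    tok = tokens[ti]
    if isinstance(tok, Block):
        L = len(tok.letters)
        if i + L > len(s):
            return False
        for ch, base in zip(tok.letters, s[i:i + L]):
            if base not in IUPAC[ch]:
                return False
        return _brute_match(s, tokens, i + L, ti + 1)
    for g in range(tok.lo, tok.hi + 1):
        if i + g <= len(s) and all(b in "ACGT" for b in s[i:i + g]):
            if _brute_match(s, tokens, i + g, ti + 1):
                return True
    return False


def brute_force_hits(sequence: str, grammar) -> list[tuple[int, int]]:
    """All (start, end) spans matched by ``grammar``, by exhaustive substring test."""
    seq = normalize_sequence(sequence)
    out = set()
    for start in range(len(seq)):
        for L in range(grammar.min_length, grammar.max_length + 1):
            if start + L <= len(seq) and _brute_match(seq[start:start + L], grammar.tokens):
                out.add((start, start + L))
    return sorted(out)


def scanner_agreement(n_seq: int = 500, max_len: int = 300, seed: int = 0) -> dict:
    """Hit-set agreement between scan() and the brute-force oracle."""
    rng = np.random.default_rng(seed)
    grammars = [parse_grammar(p) for p in GRAMMAR_PATTERNS]
    bases = np.array(list("ACGT"))
    probs = np.array([0.1, 0.3, 0.25, 0.35])  # pyrimidine/GC-rich, dense in hits
    mismatches = 0
    total_hits = 0
    for _ in range(n_seq):
        L = int(rng.integers(30, max_len + 1))
        seq = "".join(rng.choice(bases, size=L, p=probs))
        for g in grammars:
            impl = [(h.start, h.end) for h in scan(seq, g)]
            ref = brute_force_hits(seq, g)
            if impl != ref:
                mismatches += 1
            total_hits += len(ref)
    return {"n_mismatched_scans": mismatches, "n_hits": total_hits,
            "n": n_seq * len(grammars)}


def mutation_disruption() -> dict:
    """Planted-site disruption by the minigene-style TGCT -> GGCT/TGAT/TGTT edits.

    A composite high-affinity site TGCT(N)3TGCT(N)15TGCT (gaps filled with A)
    is embedded in an inert background; the triple mutation must remove
    every YGCY-family hit at the locus.
    """
    site = "TGCT" + "AAA" + "TGCT" + "A" * 15 + "TGCT"
    mutant = "GGCT" + "AAA" + "TGAT" + "A" * 15 + "TGTT"
    background = "A" * 60
    grammars = [parse_grammar(p) for p in GRAMMAR_PATTERNS]
    before = sum(len(scan(background + site + background, g)) for g in grammars)
    after = sum(len(scan(background + mutant + background, g)) for g in grammars)
    return {"hits_before": before, "hits_after": after}


# --------------------------------------------------------------------------
# microexon boundaries
# --------------------------------------------------------------------------

def microexon_boundary() -> dict:
    """Classifier decisions at the 3-33 nt boundaries, plus the non-SE rule."""
    def se_event(length: int) -> SplicingEvent:
        return SplicingEvent(
            f"SE_len{length}", "SE", "g1", "GENE1",
            (GenomicInterval("chr1", 1000, 1000 + length),),
            GenomicInterval("chr1", 500, 650),
            GenomicInterval("chr1", 2000, 2150),
        )

    lengths = [2, 3, 12, 32, 33, 34]
    expected = [False, True, True, True, True, False]
    got = [classify_microexon(se_event(n)) for n in lengths]
    mxe = SplicingEvent(
        "MXE_1", "MXE", "g1", "GENE1",
        (GenomicInterval("chr1", 1000, 1012), GenomicInterval("chr1", 1500, 1600)),
        GenomicInterval("chr1", 500, 650),
        GenomicInterval("chr1", 2000, 2150),
    )
    errors = sum(g != e for g, e in zip(got, expected)) + int(classify_microexon(mxe))
    return {"lengths": lengths, "flags": got, "non_se_flag": classify_microexon(mxe),
            "errors": errors}


# --------------------------------------------------------------------------
# dose-response recovery
# --------------------------------------------------------------------------

def dose_response_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Correlation between a dose covariate and per-sample mis-splicing burden.

    8 case samples whose true effect scale is proportional to a covariate
    spanning a 4x range (CTG-repeat-like, 200-800), coverage ~200; burden is
    the mean |PSI - control mean| over the detected mis-spliced events.
    """
    rs = []
    for s in child_seeds(seed, n_seeds):
        cfg = SimConfig(
            seed=s, n_genes=150, events_per_gene_mean=2.0,
            frac_mis_spliced=0.3, n_case=8, n_ctrl=8,
            coverage_mean=200.0, dose_response=True,
        )
        ds = simulate_dataset(cfg)
        res = run_differential(ds.events, ds.counts, ds.samples, "case", "control", seed=s)
        psi = psi_matrix(ds.counts, min_reads=10)
        burden = case_burden_from_results(psi, res, ds.samples, "case", "control")
        corr = burden_covariate_correlation(burden, ds.samples.covariate(cfg.covariate_name))
        rs.append(corr.r)
    return {"pearson_r": rs, "median_r": float(np.median(rs)), "n": n_seeds}
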