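"""Motif grammar parsing, scanning, window extraction and motif enrichment."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from misplice import (
    GenomicInterval,
    SplicingEvent,
    extract_windows,
    fetch_sequence,
    motif_enrichment,
    parse_grammar,
    scan,
    srrm4_site_present,
)
from misplice.calibration import _brute_match, brute_force_hits
from misplice.motifs import Block, Gap, GrammarError, hits_to_bed

YGCYGCY = parse_grammar("YGCYGCY")
GAPPED = parse_grammar("YGCY(N)0-5YGCY")
COMPOSITE = parse_grammar("TGCT(N)3TGCT(N)13-18TGCY")


class TestParseGrammar:
    def test_single_block(self):
        g = parse_grammar("YGCY")
        assert g.tokens == (Block("YGCY"),)
        assert [h.matched for h in scan("ATGCTA", g)] == ["TGCT"]

    def test_gapped_pattern(self):
        assert GAPPED.tokens == (Block("YGCY"), Gap(0, 5), Block("YGCY"))
        assert (GAPPED.min_length, GAPPED.max_length) == (8, 13)

    def test_fixed_gap_and_composite(self):
        assert COMPOSITE.tokens == (
            Block("TGCT"), Gap(3, 3), Block("TGCT"), Gap(13, 18), Block("TGCY")
        )

    def test_curly_gap_syntax(self):
        assert parse_grammar("YGCYN{0,5}YGCY").tokens == GAPPED.tokens

    def test_u_is_t(self):
        assert parse_grammar("UGCU").tokens == (Block("TGCT"),)

    @pytest.mark.parametrize("bad", ["YGXY", "YGCY(N)5-2YGCY", "(N)3YGCY", "YGCY(N)3"])
    def test_errors_name_the_offender(self, bad):
        with pytest.raises(GrammarError):
            parse_grammar(bad)


class TestScan:
    def test_single_hit_at_origin(self):
        hits = scan("TGCTGCT", YGCYGCY)
        assert [(h.start, h.end) for h in hits] == [(0, 7)]

    def test_gap_realisation_spans_whole_string(self):
        hits = scan("TGCTAAATGCT", GAPPED)
        assert [(h.start, h.end) for h in hits] == [(0, 11)]

    def test_gap_bound_exceeded_gives_no_hit(self):
        assert scan("TGCTAAAAAATGCT", GAPPED) == []

    def test_overlapping_hits_are_all_reported(self):
        hits = scan("TGCTGCTGCT", YGCYGCY)
        assert [h.start for h in hits] == [0, 3]

    def test_u_and_case_normalisation(self):
        assert len(scan("ugcugcu", YGCYGCY)) == 1

    @pytest.mark.parametrize("grammar", [YGCYGCY, GAPPED, COMPOSITE],
                             ids=["heptamer", "gapped", "composite"])
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_matches_brute_force_oracle(self, grammar, seq):
        impl = [(h.start, h.end) for h in scan(seq, grammar)]
        assert impl == brute_force_hits(seq, grammar)

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    def test_every_hit_rematches_in_isolation(self, seq):
        for g in (YGCYGCY, GAPPED):
            for h in scan(seq, g):
                assert _brute_match(h.matched, g.tokens)


def _se_event(strand="+", up_intron=800, dn_intron=800, exon_len=50, chrom="c"):
    flank = 150
    s0 = 100
    left = GenomicInterval(chrom, s0, s0 + flank, strand)
    alt = GenomicInterval(chrom, left.end + up_intron, left.end + up_intron + exon_len, strand)
    right = GenomicInterval(chrom, alt.end + dn_intron, alt.end + dn_intron + flank, strand)
    if strand == "+":
        return SplicingEvent("se", "SE", "g", "G", (alt,), left, right)
    return SplicingEvent("se", "SE", "g", "G", (alt,), right, left)


class TestExtractWindows:
    def _genome_for(self, event, rng):
        n = event.flank_down.end + event.flank_up.end + 500
        return {"c": "".join(rng.choice(list("ACGT"), size=n))}

    def test_long_introns_give_two_full_width_windows(self, rng):
        ev = _se_event()
        genome = self._genome_for(ev, rng)
        wins = extract_windows(ev, genome, width=500)
        assert [w.side for w in wins] == ["upstream-intron", "downstream-intron"]
        assert all(len(w.sequence) == 500 for w in wins)
        up, dn = wins
        assert up.interval.end == ev.alt_start  # abuts the 3'SS
        assert dn.interval.start == ev.alt_end  # abuts the 5'SS

    def test_short_intron_truncates_window(self, rng):
        ev = _se_event(dn_intron=300)
        wins = extract_windows(ev, self._genome_for(ev, rng), width=500)
        assert len(wins[1].sequence) == 300

    def test_minus_strand_windows_mirror_plus_extraction(self, rng):
        plus = _se_event("+")
        minus = _se_event("-")
        genome = self._genome_for(plus, rng)
        w_plus = {w.side: w for w in extract_windows(plus, genome, width=120)}
        w_minus = {w.side: w for w in extract_windows(minus, genome, width=120)}
        # same genomic gene model: the '-' upstream window sits where the '+'
        # downstream window sits, with the reverse-complemented sequence
        from misplice import reverse_complement

        assert w_minus["upstream-intron"].interval.start == plus.alt_end
        assert w_minus["upstream-intron"].sequence == reverse_complement(
            fetch_sequence(genome, GenomicInterval("c", plus.alt_end, plus.alt_end + 120, "+"))
        )
        assert w_minus["downstream-intron"].interval.end == plus.alt_start
        assert w_plus["upstream-intron"].interval.end == plus.alt_start

    def test_zero_length_intron_omits_window(self, rng):
        flank = GenomicInterval("c", 100, 250)
        alt = GenomicInterval("c", 250, 300)  # abuts the upstream flank
        right = GenomicInterval("c", 900, 1050)
        ev = SplicingEvent("se", "SE", "g", "G", (alt,), flank, right)
        wins = extract_windows(ev, self._genome_for(ev, rng), width=500)
        assert [w.side for w in wins] == ["downstream-intron"]

    def test_windows_stay_clear_of_the_events_own_exons(self, small_dataset):
        by_id = {e.event_id: e for e in small_dataset.events}
        for ev in small_dataset.events:
            if ev.event_type != "SE":
                continue
            for w in extract_windows(ev, small_dataset.genome):
                exons = list(ev.alt_exons) + [ev.flank_up, ev.flank_down]
                for ex in exons:
                    assert w.interval.end <= ex.start or w.interval.start >= ex.end

    def test_non_se_event_rejected(self):
        left = GenomicInterval("c", 100, 250)
        right = GenomicInterval("c", 500, 650)
        alt = GenomicInterval("c", 250, 500)  # retained intron
        ev = SplicingEvent("ri", "RI", "g", "G", (alt,), left, right)
        with pytest.raises(ValueError, match="SE"):
            extract_windows(ev, {}, width=10)


class TestSrrm4Site:
    def _genome_with_tgc_at(self, offset, strand="+"):
        """Place TGC so its 3' end sits at `offset` upstream of the exon start."""
        ev = _se_event(strand)
        n = max(ev.flank_down.end, ev.flank_up.end) + 500
        seq = ["A"] * n
        intron = ev.intron_upstream
        # sense position of the last intronic base is -1
        sense_idx = len(intron) + offset - 2  # start of TGC in sense intron coords
        for k, base in enumerate("TGC"):
            if strand == "+":
                seq[intron.start + sense_idx + k] = base
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                seq[intron.end - 1 - (sense_idx + k)] = comp
        return ev, {"c": "".join(seq)}

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_tgc_inside_window_detected(self, strand):
        ev, genome = self._genome_with_tgc_at(-12, strand)
        assert srrm4_site_present(ev, genome)

    def test_tgc_too_close_to_exon_rejected(self):
        ev, genome = self._genome_with_tgc_at(-2)
        assert not srrm4_site_present(ev, genome)

    def test_no_tgc_anywhere(self):
        ev = _se_event()
        genome = {"c": "A" * (ev.flank_down.end + 500)}
        assert not srrm4_site_present(ev, genome)


def test_hits_to_bed_round_trips_through_the_genome(small_dataset):
    ds = small_dataset
    for ev in ds.events:
        if ev.event_type != "SE":
            continue
        for w in extract_windows(ev, ds.genome):
            hits = scan(w.sequence, YGCYGCY, w.window_id)
            for line, hit in zip(hits_to_bed(w, hits), hits):
                chrom, s, e, name, _, strand = line.split("\t")
                iv = GenomicInterval(chrom, int(s), int(e), strand)
                assert fetch_sequence(ds.genome, iv) == hit.matched


def test_null_motif_enrichment_ci_contains_one():
    """With identical foreground/background planting the CI should cover OR = 1."""
    from misplice import SimConfig, simulate_dataset

    grammars = [YGCYGCY, GAPPED]
    covered = 0
    n_seeds = 10
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=1000 + s, n_genes=150, events_per_gene_mean=1.0,
            type_mixture={"SE": 1.0}, frac_mis_spliced=0.0,
            with_genome=True, motif_p_fg=0.3, motif_p_bg=0.3,
            n_case=3, n_ctrl=3,
        )
        ds = simulate_dataset(cfg)
        fg, bg = ds.events[:50], ds.events
        r = motif_enrichment(fg, bg, ds.genome, grammars)
        covered += r.ci_low <= 1.0 <= r.ci_high
    assert covered >= 9
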