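"""Response-element scanning: half-site scoring, arrangements, strands."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promtile import (
    DR4,
    ArrangementSpec,
    HalfSiteMotif,
    reverse_complement,
    scan_gene_set,
    scan_sequence,
    score_halfsite,
)

CONSENSUS = "AGGTCA"

# functional DR4 elements reported for these promoters, with the mismatch
# count of each hexamer half-site against the AGGTCA consensus
REPORTED_ELEMENTS = {
    "MBD3": ("GGGTCAGATGGGGACA", 1, 2),
    "PPM1B": ("AGGTCATTTGAGGCCG", 0, 2),
    "PGPEP1": ("GGTGCATGTCAGGACA", 3, 1),
    "JUNB": ("GGGTAATGTAGGGTCA", 2, 1),
    "BEND7": ("AGTTCAGGGCAGGTCA", 1, 0),
}


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def oracle_scan(seq, consensus=CONSENSUS, spacer_range=(4, 4), max_half=3, max_total=4,
                both_strands=True, kind="DR"):
    """Brute-force double loop over every (offset, spacer, strand)."""
    def halves(c):
        if kind == "DR":
            return c, c
        if kind == "IR":
            return c, reverse_complement(c)
        return reverse_complement(c), c

    hits = set()
    strands = [("+", seq.upper())] + ([("-", reverse_complement(seq).upper())] if both_strands else [])
    for strand, s in strands:
        c1, c2 = halves(consensus)
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            span = 12 + spacer
            for i in range(len(s) - span + 1):
                m1 = hamming(s[i : i + 6], c1)
                m2 = hamming(s[i + 6 + spacer : i + 12 + spacer], c2)
                if m1 <= max_half and m2 <= max_half and m1 + m2 <= max_total:
                    start = i if strand == "+" else len(s) - (i + span)
                    hits.add((start, strand, spacer, m1, m2))
    return hits


class TestScoreHalfsite:
    @pytest.mark.parametrize(
        "hexamer,expected",
        [("AGGTCA", 0), ("GGGTCA", 1), ("GGTGCA", 3), ("NGGTCA", 1), ("NNNNNN", 6)],
    )
    def test_mismatch_counts(self, hexamer, expected):
        assert score_halfsite(hexamer) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="6 bp"):
            score_halfsite("AGGTC")

    def test_log_odds_prefers_consensus(self):
        matrix = np.full((4, 6), 0.1)
        for j, base in enumerate(CONSENSUS):
            matrix["ACGT".index(base), j] = 0.7
        motif = HalfSiteMotif(CONSENSUS, matrix, "log-odds")
        assert score_halfsite("AGGTCA", motif) > score_halfsite("GGGTCA", motif)


class TestScanSequence:
    def test_reported_element_found_with_audited_mismatches(self):
        hits = scan_sequence(REPORTED_ELEMENTS["PPM1B"][0])
        plus = hits[hits["strand"] == "+"]
        assert len(plus) == 1
        row = plus.iloc[0]
        assert (row["start"], row["spacer"], row["mm1"], row["mm2"]) == (0, 4, 0, 2)

    def test_no_half_sites_no_hits(self):
        assert scan_sequence("C" * 16).empty

    def test_reverse_complement_hits_minus_strand_with_same_score(self):
        seq = REPORTED_ELEMENTS["PPM1B"][0]
        fwd = scan_sequence(seq)
        rev = scan_sequence(reverse_complement(seq))
        minus = rev[rev["strand"] == "-"]
        assert len(minus) == 1
        assert minus.iloc[0]["total_score"] == fwd[fwd["strand"] == "+"].iloc[0]["total_score"]
        assert minus.iloc[0]["start"] == 0

    def test_strand_involution_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = scan_sequence(seq)
        rev = scan_sequence(reverse_complement(seq))
        flipped = {
            (len(seq) - (r["start"] + 12 + r["spacer"]), {"+": "-", "-": "+"}[r["strand"]],
             r["spacer"], r["mm1"], r["mm2"])
            for _, r in rev.iterrows()
        }
        original = {
            (r["start"], r["strand"], r["spacer"], r["mm1"], r["mm2"]) for _, r in fwd.iterrows()
        }
        assert flipped == original

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGT"), 100))
            hits = scan_sequence(seq, arrangement=ArrangementSpec("DR", 2, 6))
            got = {
                (r["start"], r["strand"], r["spacer"], r["mm1"], r["mm2"])
                for _, r in hits.iterrows()
            }
            assert got == oracle_scan(seq, spacer_range=(2, 6))

    @settings(max_examples=50, derandomize=True)
    @given(max_half=st.integers(0, 3), max_total=st.integers(0, 4))
    def test_tightening_mismatch_budgets_never_adds_hits(self, max_half, max_total):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 200))
        lax = scan_sequence(seq, max_mm_per_half=3, max_mm_total=4)
        tight = scan_sequence(seq, max_mm_per_half=max_half, max_mm_total=max_total)
        assert len(tight) <= len(lax)

    def test_inverted_and_everted_arrangements(self):
        # IR0: palindrome AGGTCA TGACCT; ER with spacer 4
        ir_seq = "AGGTCATGACCT"
        hits = scan_sequence(
            ir_seq, arrangement=ArrangementSpec("IR", 0, 0), max_mm_per_half=0, max_mm_total=0
        )
        assert (hits["strand"] == "+").sum() == 1
        er_seq = reverse_complement(CONSENSUS) + "TTTT" + CONSENSUS
        hits = scan_sequence(
            er_seq, arrangement=ArrangementSpec("ER", 4, 4), max_mm_per_half=0, max_mm_total=0
        )
        assert len(hits) >= 1 and 0 in set(hits["start"])

    def test_spacer_range_validation(self):
        with pytest.raises(ValueError, match="spacer"):
            ArrangementSpec("DR", 0, 50)


class TestScanGeneSet:
    def test_all_reported_elements_qualify_under_defaults(self):
        sequences = {name: seq for name, (seq, _, _) in REPORTED_ELEMENTS.items()}
        per_gene, hits, summary = scan_gene_set(sequences)
        assert summary["n_with_hit"] == 5 and summary["n_genes"] == 5
        for name, (_, mm1, mm2) in REPORTED_ELEMENTS.items():
            plus = hits[(hits["sequence_id"] == name) & (hits["strand"] == "+")]
            assert (int(plus.iloc[0]["mm1"]), int(plus.iloc[0]["mm2"])) == (mm1, mm2)

    def test_empty_input_gives_empty_table(self):
        per_gene, hits, summary = scan_gene_set({})
        assert per_gene.empty and hits.empty and summary["n_genes"] == 0

    def test_duplicate_ids_rejected(self):
        # dict keys are unique, so duplicates can only arrive via a list-like
        with pytest.raises(ValueError, match="duplicate"):
            scan_gene_set(DuplicateKeys())

    def test_embedded_elements_recovered_at_manifest_offsets(self, small_experiment):
        from promtile import window_sequences

        truth = small_experiment["truth"]
        cfg = small_experiment["config"]
        windows = window_sequences(
            small_experiment["genome"], small_experiment["genes"], cfg.upstream, cfg.downstream
        )
        with_tre = truth[truth["tre_offset"].notna()]
        assert len(with_tre) > 0
        per_gene, hits, _ = scan_gene_set(
            {g: windows[g] for g in with_tre["gene_id"]}
        )
        assert (per_gene["n_hits"] > 0).all()
        gene_info = truth.set_index("gene_id")
        for gid in with_tre["gene_id"]:
            strand = gene_info.at[gid, "strand"]
            offset = int(gene_info.at[gid, "tre_offset"])
            # window-relative plus-strand start of the embedded element
            if strand == "+":
                expected = cfg.upstream + offset
            else:
                expected = cfg.downstream - offset - len(cfg.tre_sequence)
            g_hits = hits[hits["sequence_id"] == gid]
            assert expected in set(g_hits["start"])


class DuplicateKeys:
    """Minimal mapping-like object presenting a duplicated sequence id."""

    def __iter__(self):
        return iter(["a", "a"])

    def items(self):
        return [("a", "ACGT"), ("a", "ACGT")]
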