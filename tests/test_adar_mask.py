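import math

import numpy as np
import pytest

from sigmapop.adar_mask import (
    AlignmentError,
    classify_preferred_sites,
    call_edits,
    fisher_overrepresentation,
    majority_consensus,
    mask_preferred_sites,
    run_adar_pipeline,
)
from sigmapop.core_io import SequenceAlignment, Sense
from sigmapop.synthetic_data import (
    SimulationConfig,
    inject_adar_tracts,
    simulate_coalescent,
)


class TestConsensus:
    def test_majority_column(self, make_alignment):
        aln = make_alignment(["A", "A", "G"])
        assert majority_consensus(aln).seq == "A"

    def test_tie_gives_n(self, make_alignment):
        aln = make_alignment(["A", "A", "G", "G"])
        assert majority_consensus(aln).seq == "N"

    def test_identical_sequences(self, make_alignment):
        aln = make_alignment(["ACGT"] * 3)
        assert majority_consensus(aln).seq == "ACGT"

    def test_gap_and_n_excluded_from_denominator(self, make_alignment):
        # 2 A of 3 informative characters: 2/3 > 0.5
        aln = make_alignment(["A", "A", "G", "-", "N"])
        assert majority_consensus(aln).seq == "A"

    def test_all_gap_column(self, make_alignment):
        aln = make_alignment(["-", "-"])
        assert majority_consensus(aln).seq == "N"


class TestClassifyPreferred:
    def _flags(self, consensus_str):
        aln = SequenceAlignment(("x",), (consensus_str,))
        return classify_preferred_sites(majority_consensus(aln), Sense.MRNA)

    def test_stored_sense_preferred(self):
        flags = self._flags("TAG")
        assert flags.preferred_stored[1]

    def test_stored_sense_not_preferred_after_c(self):
        flags = self._flags("CAG")
        assert flags.eligible_stored[1] and not flags.preferred_stored[1]

    def test_opposite_sense_preferred(self):
        # "GTA": reverse complement is "TAC"; stored column 1 (T) is the
        # middle A of the opposite strand with 5' neighbour complement(A)=T
        flags = self._flags("GTA")
        assert flags.eligible_opposite[1] and flags.preferred_opposite[1]

    def test_terminal_columns_non_preferred(self):
        flags = self._flags("AT")
        assert not flags.preferred_stored[0]  # A at column 0 has no 5' neighbour
        assert not flags.preferred_opposite[1]  # T at last column: no 3' neighbour

    def test_never_eligible_both_senses(self, random_alignment):
        aln = random_alignment(6, 200, seed=3)
        flags = classify_preferred_sites(majority_consensus(aln), Sense.MRNA)
        assert not (flags.eligible_stored & flags.eligible_opposite).any()

    def test_partition_conserves_columns(self, random_alignment):
        aln = random_alignment(6, 200, seed=4)
        flags = classify_preferred_sites(majority_consensus(aln), Sense.MRNA)
        c = flags.counts()
        assert c["preferred"] + c["non_preferred_eligible"] + c["ineligible"] == c["L"]


class TestCallEdits:
    def test_stored_sense_edit(self, make_alignment):
        aln = make_alignment(["TAG", "TAG", "TGG"])
        consensus = majority_consensus(aln)
        flags = classify_preferred_sites(consensus, aln.sense)
        edits = call_edits(aln, consensus, flags)
        assert len(edits) == 1
        e = edits[0]
        assert (e.column, e.seq_id, e.preferred) == (1, "s2", True)
        assert (e.consensus_base, e.observed_base) == ("A", "G")

    def test_opposite_sense_edit(self, make_alignment):
        # consensus GTA: column 1 is an opposite-sense preferred A-site;
        # T->C in stored orientation is A->G on the opposite strand
        aln = make_alignment(["GTA", "GTA", "GCA"])
        consensus = majority_consensus(aln)
        flags = classify_preferred_sites(consensus, aln.sense)
        edits = call_edits(aln, consensus, flags)
        assert len(edits) == 1
        assert edits[0].sense == "genome"  # stored mrna => opposite is genome
        assert edits[0].preferred

    def test_a_to_c_is_not_a_candidate(self, make_alignment):
        aln = make_alignment(["TAG", "TAG", "TCG"])
        consensus = majority_consensus(aln)
        flags = classify_preferred_sites(consensus, aln.sense)
        assert call_edits(aln, consensus, flags) == []


def enumeration_fisher_oracle(a, b, c, d):
    """One-sided Fisher p by explicit enumeration of at-least-as-extreme tables."""
    n_pref, n_non = a + c, b + d
    n_mut = a + b
    total = math.comb(n_pref + n_non, n_mut)
    p = 0.0
    for x in range(a, min(n_pref, n_mut) + 1):
        if n_mut - x <= n_non:
            p += math.comb(n_pref, x) * math.comb(n_non, n_mut - x) / total
    return p


class _FakeFlags:
    """Minimal site-flag stand-in for direct Fisher-table tests."""

    def __init__(self, preferred_cols, eligible_cols, L):
        self.preferred_stored = np.zeros(L, dtype=bool)
        self.preferred_stored[list(preferred_cols)] = True
        self.preferred_opposite = np.zeros(L, dtype=bool)
        self.eligible_stored = np.zeros(L, dtype=bool)
        self.eligible_stored[list(eligible_cols)] = True
        self.eligible_opposite = np.zeros(L, dtype=bool)
        self.stored_sense_label = "antigenome"
        self.opposite_sense_label = "genome"
        self.preferred_any = self.preferred_stored
        self.eligible_any = self.eligible_stored


class _FakeEdit:
    def __init__(self, column):
        self.column = column


class TestFisher:
    def test_matches_enumeration_oracle(self):
        # 40 preferred (8 mutated), 60 non-preferred (2 mutated)
        L = 100
        flags = _FakeFlags(range(40), range(100), L)
        edits = [_FakeEdit(c) for c in list(range(8)) + [50, 51]]
        res = fisher_overrepresentation(edits, flags)
        assert res.table.tolist() == [[8, 2], [32, 58]]
        assert res.p == pytest.approx(enumeration_fisher_oracle(8, 2, 32, 58), rel=1e-9)

    def test_no_mutations_p_one(self):
        flags = _FakeFlags(range(10), range(30), 30)
        res = fisher_overrepresentation([], flags)
        assert res.p == 1.0

    def test_all_mutated_preferred_significant(self):
        flags = _FakeFlags(range(20), range(40), 40)
        edits = [_FakeEdit(c) for c in range(6)]
        res = fisher_overrepresentation(edits, flags)
        assert res.p < 0.05 and res.over_represented

    def test_zero_eligible_is_error(self):
        flags = _FakeFlags([], [], 10)
        with pytest.raises(AlignmentError, match="no eligible"):
            fisher_overrepresentation([], flags)

    def test_exhaustive_small_margins_against_oracle(self):
        # every consistent table with eligible-site total <= 12
        for total in range(1, 13):
            for n_pref in range(0, total + 1):
                for n_mut in range(0, total + 1):
                    for a in range(max(0, n_mut - (total - n_pref)), min(n_pref, n_mut) + 1):
                        b = n_mut - a
                        c = n_pref - a
                        d = (total - n_pref) - b
                        L = total
                        flags = _FakeFlags(range(n_pref), range(total), L)
                        edits = [_FakeEdit(x) for x in range(a)] + [
                            _FakeEdit(n_pref + x) for x in range(b)
                        ]
                        res = fisher_overrepresentation(edits, flags)
                        assert res.p == pytest.approx(
                            enumeration_fisher_oracle(a, b, c, d), abs=1e-12
                        )


class TestMasking:
    def test_mask_counts(self, make_alignment):
        # TAA: col1 preferred (5'T), col2 preferred (5'A)
        aln = make_alignment(["TAACCCCGGG"] * 3)
        flags = classify_preferred_sites(majority_consensus(aln), aln.sense)
        masked = mask_preferred_sites(aln, flags)
        n_pref = int(flags.preferred_any.sum())
        assert masked.alignment.L == 10 - n_pref
        assert len(masked.column_map) == masked.alignment.L
        assert list(masked.column_map) == sorted(masked.column_map)

    def test_no_preferred_identity(self, make_alignment):
        aln = make_alignment(["CGCGCG"] * 3)
        flags = classify_preferred_sites(majority_consensus(aln), aln.sense)
        masked = mask_preferred_sites(aln, flags)
        assert masked.alignment.seqs == aln.seqs

    def test_masking_idempotent(self, random_alignment):
        # only A/T-consensus columns are ever removed, so a surviving
        # eligible site keeps its blocking C/G neighbour: a second pass
        # must remove nothing
        aln = random_alignment(8, 300, seed=5)
        flags = classify_preferred_sites(majority_consensus(aln), aln.sense)
        masked = mask_preferred_sites(aln, flags)
        flags2 = classify_preferred_sites(
            majority_consensus(masked.alignment), masked.alignment.sense
        )
        assert int(flags2.preferred_any.sum()) == 0
        remaining_original = set(masked.column_map)
        assert remaining_original.isdisjoint(set(np.flatnonzero(flags.preferred_any)))

    def test_injected_tracts_fully_masked(self):
        cfg = SimulationConfig(n=30, L=600, theta=4.0, seed=21)
        ds = simulate_coalescent(cfg)
        edited, truth = inject_adar_tracts(ds.alignment, n_events=3, tract_mean=6.0, seed=22)
        assert truth, "injection produced no edits"
        report = run_adar_pipeline(edited)
        masked_original_cols = set(report.masked.column_map)
        for _, col, _ in truth:
            assert col not in masked_original_cols
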