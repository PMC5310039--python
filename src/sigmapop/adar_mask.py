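"""ADAR hyper-mutation detection and masking in viral alignments.

ADARs (adenosine deaminases acting on RNA) deaminate A to inosine in
double-stranded RNA; inosine pairs as G, so editing events read as A→G
substitutions.  ADAR prefers adenosines whose 5′ neighbour is A or U,
and single editing events produce clusters of mutations.  Because a
negative-sense virus is sequenced together with its positive-sense
replication intermediate, editing can appear on either strand: A→G in
the stored orientation, or T→C (an A→G on the complementary strand).

The procedure implemented here:

1. build a 50% majority-rule consensus of the alignment;
2. classify every consensus A (stored sense) and T (opposite sense)
   column as ADAR-preferred or not from its 5′ neighbour context;
3. call candidate edits — per-sequence A→G / T→C differences from the
   consensus at eligible columns;
4. test whether mutated sites are over-represented among preferred
   sites with a one-sided Fisher exact test at the site level;
5. mask (remove) every preferred column, whether or not an edit was
   observed there, so the downstream statistics never see sites where
   mutations may be non-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_io import AlignmentError, SequenceAlignment, Sense

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
_PREFERRED_5P = frozenset("AT")  # A = U > C > G: A and U jointly preferred


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority-rule consensus with per-column base frequencies.

    A column's consensus base must be strictly more frequent than
    ``threshold`` among its non-gap, non-N characters; otherwise
    (including ties at exactly the threshold, and all-gap/N columns)
    the column is N.
    """

    seq: str
    frequencies: np.ndarray  # (L, 4) counts over A,C,G,T
    threshold: float

    def __len__(self) -> int:
        return len(self.seq)


def majority_consensus(
    alignment: SequenceAlignment, threshold: float = 0.5
) -> ConsensusSequence:
    arr = alignment.to_array()
    L = alignment.L
    counts = np.zeros((L, 4), dtype=np.int64)
    for k, b in enumerate("ACGT"):
        counts[:, k] = (arr == b.encode()).sum(axis=0)
    informative = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    best_count = counts.max(axis=1)
    consensus = np.full(L, "N", dtype="U1")
    ok = (informative > 0) & (best_count > threshold * informative)
    consensus[ok] = np.array(list("ACGT"))[best[ok]]
    return ConsensusSequence("".join(consensus), counts, threshold)


@dataclass(frozen=True)
class SiteFlags:
    """Per-column eligibility and ADAR preference, on both senses.

    ``stored`` refers to the orientation of the stored sequences;
    ``opposite`` to its reverse complement.  A column is an eligible
    A-site on the stored sense iff the consensus base is A, and on the
    opposite sense iff it is T; it can never be eligible on both.
    Preferred means the 5′ neighbour, read in the edit's sense, is A or
    T(U).  Terminal columns lacking the neighbour are non-preferred.
    """

    eligible_stored: np.ndarray
    preferred_stored: np.ndarray
    eligible_opposite: np.ndarray
    preferred_opposite: np.ndarray
    stored_sense_label: str
    opposite_sense_label: str

    @property
    def preferred_any(self) -> np.ndarray:
        return self.preferred_stored | self.preferred_opposite

    @property
    def eligible_any(self) -> np.ndarray:
        return self.eligible_stored | self.eligible_opposite

    def counts(self) -> dict[str, int]:
        L = len(self.eligible_stored)
        pref = int(self.preferred_any.sum())
        elig = int(self.eligible_any.sum())
        return {
            "L": L,
            "eligible": elig,
            "preferred": pref,
            "non_preferred_eligible": elig - pref,
            "ineligible": L - elig,
        }


def _sense_labels(stored: Sense) -> tuple[str, str]:
    # mRNA and antigenome share the positive-sense orientation.
    if stored is Sense.GENOME:
        return "genome", "antigenome"
    return "antigenome", "genome"


def classify_preferred_sites(
    consensus: ConsensusSequence, stored_sense: Sense | str = Sense.MRNA
) -> SiteFlags:
    """Flag ADAR-preferred columns on the stored and opposite senses.

    Stored sense: column i is an A-site iff consensus[i] == 'A';
    preferred iff consensus[i-1] in {A, T}.  Opposite sense: column i is
    an A-site iff consensus[i] == 'T' (an A on the complement); its 5′
    neighbour on that strand is the complement of consensus[i+1], so the
    column is preferred iff consensus[i+1] in {A, T} (the set {A, T} is
    closed under complementation).  N consensus columns are ineligible.
    """
    c = np.frombuffer(consensus.seq.encode(), dtype="S1")
    L = len(c)
    is_a = c == b"A"
    is_t = c == b"T"
    neigh_at_left = np.zeros(L, dtype=bool)
    neigh_at_left[1:] = (c[:-1] == b"A") | (c[:-1] == b"T")
    neigh_at_right = np.zeros(L, dtype=bool)
    neigh_at_right[:-1] = (c[1:] == b"A") | (c[1:] == b"T")
    stored_label, opposite_label = _sense_labels(Sense(stored_sense))
    return SiteFlags(
        eligible_stored=is_a,
        preferred_stored=is_a & neigh_at_left,
        eligible_opposite=is_t,
        preferred_opposite=is_t & neigh_at_right,
        stored_sense_label=stored_label,
        opposite_sense_label=opposite_label,
    )


@dataclass(frozen=True)
class EditCandidate:
    """A single putative ADAR editing observation.

    Bases are reported in the stored orientation; ``sense`` names the
    strand on which the change is an A→G.
    """

    column: int
    seq_id: str
    sense: str
    consensus_base: str
    observed_base: str
    five_prime: str
    preferred: bool


def call_edits(
    alignment: SequenceAlignment,
    consensus: ConsensusSequence,
    flags: SiteFlags,
) -> list[EditCandidate]:
    """Call per-sequence A→G (stored) and T→C (opposite-sense A→G) changes."""
    arr = alignment.to_array()
    cons = np.frombuffer(consensus.seq.encode(), dtype="S1")
    out: list[EditCandidate] = []
    stored_cols = np.flatnonzero(flags.eligible_stored)
    opp_cols = np.flatnonzero(flags.eligible_opposite)
    for cols, obs_base, sense_label, pref in (
        (stored_cols, b"G", flags.stored_sense_label, flags.preferred_stored),
        (opp_cols, b"C", flags.opposite_sense_label, flags.preferred_opposite),
    ):
        if cols.size == 0:
            continue
        hits = arr[:, cols] == obs_base
        for row, k in zip(*np.nonzero(hits)):
            col = int(cols[k])
            if sense_label == flags.stored_sense_label:
                five = consensus.seq[col - 1] if col > 0 else ""
            else:
                nxt = consensus.seq[col + 1] if col + 1 < alignment.L else ""
                five = _COMPLEMENT.get(nxt, "") if nxt else ""
            out.append(
                EditCandidate(
                    column=col,
                    seq_id=alignment.ids[row],
                    sense=sense_label,
                    consensus_base=cons[col].decode(),
                    observed_base=obs_base.decode(),
                    five_prime=five,
                    preferred=bool(pref[col]),
                )
            )
    out.sort(key=lambda e: (e.column, e.seq_id))
    return out


@dataclass(frozen=True)
class AdarTestResult:
    """Site-level 2×2 over-representation test of A→G changes.

    Rows: site mutated (≥1 sequence carries an A→G/T→C change there)
    yes/no; columns: site ADAR-preferred yes/no; universe: all eligible
    A-sites on both senses.  ``p`` is the one-sided Fisher exact
    probability of at least as many mutated preferred sites, computed by
    hypergeometric tail summation.
    """

    mutated_preferred: int
    mutated_nonpreferred: int
    unmutated_preferred: int
    unmutated_nonpreferred: int
    p: float
    alpha: float
    preferred_columns: tuple[int, ...]
    mutated_columns: tuple[int, ...]

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.mutated_preferred, self.mutated_nonpreferred],
                [self.unmutated_preferred, self.unmutated_nonpreferred],
            ]
        )

    @property
    def eligible_total(self) -> int:
        return int(self.table.sum())

    @property
    def preferred_total(self) -> int:
        return self.mutated_preferred + self.unmutated_preferred

    @property
    def over_represented(self) -> bool:
        return self.p < self.alpha


def fisher_overrepresentation(
    candidates: Sequence[EditCandidate],
    flags: SiteFlags,
    alpha: float = 0.05,
) -> AdarTestResult:
    n_eligible = int(flags.eligible_any.sum())
    if n_eligible == 0:
        raise AlignmentError("no eligible A-sites")
    n_pref = int(flags.preferred_any.sum())
    mutated_cols = sorted({e.column for e in candidates})
    mutated = np.zeros(len(flags.eligible_stored), dtype=bool)
    mutated[mutated_cols] = True
    a = int((mutated & flags.preferred_any).sum())  # mutated, preferred
    b = int((mutated & flags.eligible_any & ~flags.preferred_any).sum())
    c = n_pref - a
    d = (n_eligible - n_pref) - b
    # one-sided: P(X >= a) for X ~ Hypergeom(N=eligible, K=preferred, n=mutated)
    n_mut = a + b
    p = float(hypergeom.sf(a - 1, n_eligible, n_pref, n_mut)) if n_mut else 1.0
    return AdarTestResult(
        mutated_preferred=a,
        mutated_nonpreferred=b,
        unmutated_preferred=c,
        unmutated_nonpreferred=d,
        p=min(p, 1.0),
        alpha=alpha,
        preferred_columns=tuple(int(i) for i in np.flatnonzero(flags.preferred_any)),
        mutated_columns=tuple(mutated_cols),
    )


@dataclass(frozen=True)
class MaskedAlignment:
    """Alignment with all ADAR-preferred columns removed."""

    alignment: SequenceAlignment
    column_map: tuple[int, ...]  # new index -> original index, strictly increasing
    removed_columns: tuple[int, ...]


def mask_preferred_sites(
    alignment: SequenceAlignment, flags: SiteFlags
) -> MaskedAlignment:
    """Remove every column preferred on either sense.

    All preferred sites are excluded, not only those with an observed
    edit: an unedited preferred site in this sample remains a likely
    editing target, and retaining it would leave the remaining columns'
    mutations non-independent.
    """
    keep = np.flatnonzero(~flags.preferred_any)
    if keep.size == 0:
        raise AlignmentError("empty alignment after masking")
    removed = np.flatnonzero(flags.preferred_any)
    return MaskedAlignment(
        alignment=alignment.select_columns(keep),
        column_map=tuple(int(i) for i in keep),
        removed_columns=tuple(int(i) for i in removed),
    )


@dataclass(frozen=True)
class AdarReport:
    consensus: ConsensusSequence
    flags: SiteFlags
    candidates: tuple[EditCandidate, ...]
    test: AdarTestResult
    masked: MaskedAlignment


def run_adar_pipeline(
    alignment: SequenceAlignment,
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> AdarReport:
    """Consensus → site classification → edit calling → Fisher test → mask."""
    consensus = majority_consensus(alignment, threshold)
    flags = classify_preferred_sites(consensus, alignment.sense)
    candidates = call_edits(alignment, consensus, flags)
    test = fisher_overrepresentation(candidates, flags, alpha)
    masked = mask_preferred_sites(alignment, flags)
    return AdarReport(consensus, flags, tuple(candidates), test, masked)
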