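"""Diversity and neutrality statistics for viral alignments.

Implements the classical summaries of within-population variation —
segregating sites S, singleton count, nucleotide diversity π, Watterson's
θ_W — and Tajima's D with two significance routes:

* a coalescent null: neutral constant-size genealogies with no
  recombination, conditioned on the observed number of segregating
  sites (exactly S mutations dropped on branches proportional to
  length), as DnaSP does for "all sites" tests;
* Tajima's (1989) beta approximation, used for synonymous-site tests
  where the coalescent null's fixed-S conditioning is less natural.

All statistics use complete deletion: every column containing a gap or
an ambiguous base is removed first, so π, S and D share one fixed
denominator (the "sites examined").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import beta as beta_dist

from .core_io import AlignmentError, SequenceAlignment

_BYTES = (b"A", b"C", b"G", b"T")


# ---------------------------------------------------------------------------
# column filtering

def filter_columns(alignment: SequenceAlignment) -> tuple[SequenceAlignment, tuple[int, ...]]:
    """Complete deletion: drop every column containing '-' or 'N'.

    Returns the filtered alignment and the strictly increasing map from
    new to original column indices.
    """
    arr = alignment.to_array()
    bad = (arr == b"-").any(axis=0) | (arr == b"N").any(axis=0)
    keep = np.flatnonzero(~bad)
    if keep.size == 0:
        raise AlignmentError("no columns remain after complete deletion")
    if keep.size == alignment.L:
        return alignment, tuple(range(alignment.L))
    return alignment.select_columns(keep), tuple(int(i) for i in keep)


# ---------------------------------------------------------------------------
# core summaries

def _base_counts(arr: np.ndarray) -> np.ndarray:
    """(L, 4) allele counts over A,C,G,T for an (n, L) byte array."""
    return np.stack([(arr == b).sum(axis=0) for b in _BYTES], axis=1)


def segregating_sites(alignment: SequenceAlignment) -> tuple[int, int]:
    """Return (S, singleton sites).

    A column is segregating if ≥2 bases are observed.  It is a singleton
    site if every non-major allele there is carried by exactly one
    sequence (so with >2 alleles, all minor alleles must be unique).
    """
    counts = _base_counts(alignment.to_array())
    n_alleles = (counts > 0).sum(axis=1)
    seg = n_alleles >= 2
    # non-major allele counts must all equal 1
    major = counts.max(axis=1)
    minor_total = counts.sum(axis=1) - major
    singleton = seg & (minor_total == (n_alleles - 1))
    return int(seg.sum()), int(singleton.sum())


def pairwise_difference_matrix(alignment: SequenceAlignment) -> np.ndarray:
    """(n, n) matrix of pairwise Hamming difference counts."""
    arr = alignment.to_array()
    counts = _base_counts(arr)
    seg = np.flatnonzero((counts > 0).sum(axis=1) >= 2)
    n = alignment.n
    if seg.size == 0:
        return np.zeros((n, n))
    sub = arr[:, seg]
    same = np.zeros((n, n))
    for b in _BYTES:
        x = (sub == b).astype(np.float64)
        same += x @ x.T
    diff = seg.size - same
    np.fill_diagonal(diff, 0.0)
    return diff


def mean_pairwise_differences(alignment: SequenceAlignment) -> float:
    """k̄: mean Hamming difference count over all unordered pairs."""
    n = alignment.n
    if n < 2:
        raise AlignmentError("need at least 2 sequences")
    d = pairwise_difference_matrix(alignment)
    return float(d.sum() / (n * (n - 1)))


def nucleotide_diversity(alignment: SequenceAlignment) -> float:
    """π per site: mean pairwise differences divided by alignment length."""
    return mean_pairwise_differences(alignment) / alignment.L


def variance_pairwise_differences(alignment: SequenceAlignment) -> float:
    """Variance of the pairwise difference counts (ABC summary)."""
    d = pairwise_difference_matrix(alignment)
    iu = np.triu_indices(alignment.n, k=1)
    return float(np.var(d[iu]))


# ---------------------------------------------------------------------------
# Tajima's D

@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) a1,a2,b1,b2,c1,c2,e1,e2 as functions of n alone."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_D_from_counts(n: int, S: int, kbar: float) -> float | None:
    """D from (n, S, mean pairwise differences); None when S == 0."""
    if S == 0:
        return None
    c = tajima_constants(n)
    denom = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return float((kbar - S / c["a1"]) / denom)


def tajimas_D(alignment: SequenceAlignment) -> float | None:
    """Tajima's D; None (not applicable) when there is no polymorphism."""
    if alignment.n < 4:
        raise AlignmentError("Tajima's D requires n >= 4")
    S, _ = segregating_sites(alignment)
    kbar = mean_pairwise_differences(alignment)
    return tajimas_D_from_counts(alignment.n, S, kbar)


@dataclass(frozen=True)
class DiversityStats:
    n: int
    L_used: int
    S: int
    singletons: int
    pi: float          # per site
    theta_w: float     # per site, S / (a1 * L_used)
    kbar: float        # mean pairwise difference count
    constants: dict[str, float] = field(repr=False)


def diversity_stats(alignment: SequenceAlignment) -> DiversityStats:
    if alignment.n < 2:
        raise AlignmentError("need at least 2 sequences")
    S, singles = segregating_sites(alignment)
    kbar = mean_pairwise_differences(alignment)
    c = tajima_constants(alignment.n)
    return DiversityStats(
        n=alignment.n,
        L_used=alignment.L,
        S=S,
        singletons=singles,
        pi=kbar / alignment.L,
        theta_w=S / (c["a1"] * alignment.L),
        kbar=kbar,
        constants=c,
    )


# ---------------------------------------------------------------------------
# coalescent null for D (fixed-S conditioning, no recombination)

def simulate_null_D(n: int, S: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of D for n samples conditioned on S mutations.

    Each replicate draws a neutral constant-size coalescent genealogy
    and places exactly S mutations on branches with probability
    proportional to branch length; each mutation's derived-allele count
    is the number of leaves below its branch (no recombination, each
    mutation at its own site).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    c = tajima_constants(n)
    denom = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    expected = S / c["a1"]
    pair_norm = 2.0 / (n * (n - 1))
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    out = np.empty(reps)
    for r in range(reps):
        waits = rng.exponential(1.0 / rates)
        totals = ks * waits  # total branch length contributed per interval
        # composition of lineage sizes during each interval
        sizes = [1] * n
        comps = []
        u = rng.random((len(ks), 2))
        for lvl, k in enumerate(ks):
            comps.append(list(sizes))
            i = int(u[lvl, 0] * k)
            j = int(u[lvl, 1] * (k - 1))
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            sizes[i] += sizes[j]
            del sizes[j]
        probs = totals / totals.sum()
        muts = rng.multinomial(S, probs)
        kbar = 0.0
        for lvl, m in enumerate(muts):
            if m == 0:
                continue
            comp = comps[lvl]
            k = len(comp)
            picks = rng.integers(0, k, size=m)
            for t in picks:
                d = comp[t]
                kbar += d * (n - d)
        kbar *= pair_norm
        out[r] = (kbar - expected) / denom
    return out


def coalescent_pvalue_D(
    d_obs: float,
    n: int,
    S: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-tailed coalescent-simulation p-value for an observed D.

    Uses the (b+1)/(m+1) permutation-style estimator in each tail and
    doubles the smaller tail, capped at 1.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    null = simulate_null_D(n, S, reps, rng)
    lo = (np.sum(null <= d_obs) + 1) / (reps + 1)
    hi = (np.sum(null >= d_obs) + 1) / (reps + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# beta approximation for D (Tajima 1989)

def tajima_D_bounds(n: int) -> tuple[float, float]:
    """(D_min, D_max) in the large-S limit.

    D is minimal when every mutation is a singleton and maximal when
    derived alleles sit at intermediate frequency (n/2, parity-dependent).
    """
    c = tajima_constants(n)
    a1, e2 = c["a1"], c["e2"]
    d_min = (2.0 / n - 1.0 / a1) / np.sqrt(e2)
    if n % 2 == 0:
        d_max = (n / (2.0 * (n - 1)) - 1.0 / a1) / np.sqrt(e2)
    else:
        d_max = ((n + 1) / (2.0 * n) - 1.0 / a1) / np.sqrt(e2)
    return float(d_min), float(d_max)


def beta_pvalue_D(d: float, n: int) -> float:
    """Two-tailed p for D under Tajima's rescaled beta approximation.

    D is assumed beta-distributed on [D_min, D_max] with mean 0 and
    variance 1; the shape parameters follow from those constraints.
    """
    if n < 4:
        raise ValueError("beta approximation requires n >= 4")
    d_min, d_max = tajima_D_bounds(n)
    if d < d_min or d > d_max:
        warnings.warn(
            f"D={d:.3f} outside the attainable range [{d_min:.3f}, {d_max:.3f}]; clamped",
            stacklevel=2,
        )
        d = min(max(d, d_min), d_max)
    span = d_max - d_min
    alpha_shape = -(1.0 + d_min * d_max) * d_max / span
    beta_shape = (1.0 + d_min * d_max) * d_min / span
    # density ∝ (D_max-D)^(α-1) (D-D_min)^(β-1): lower-end exponent is β
    dist = beta_dist(beta_shape, alpha_shape, loc=d_min, scale=span)
    p = 2.0 * min(dist.cdf(d), dist.sf(d))
    return float(min(1.0, max(p, 0.0)))


# ---------------------------------------------------------------------------
# synonymous-site restriction

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float | None:
    """Nei–Gojobori synonymous-site content of one codon (None for stops/ambiguous)."""
    table = _codon_table()
    aa = table.get(codon)
    if aa is None or aa == "*":
        return None
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if table.get(mut) == aa:
                s += 1.0 / 3.0
    return s


@dataclass(frozen=True)
class SynonymousAnalysis:
    frame: int
    n_codons: int
    synonymous_site_count: float   # Nei–Gojobori, per-sequence averaged
    synonymous_columns: tuple[int, ...]
    S_syn: int
    singletons_syn: int
    kbar_syn: float
    D: float | None


def synonymous_restriction(
    alignment: SequenceAlignment, frame: int = 0
) -> SynonymousAnalysis:
    """Restrict the neutrality test to synonymous variation.

    A segregating site is synonymous iff every observed base there,
    substituted into the majority-consensus codon (other positions held
    at consensus), encodes the same amino acid.  The synonymous site
    count is the Nei–Gojobori per-codon fraction, averaged over
    sequences.  Codons containing N or '-' in a sequence are skipped for
    that sequence; codons with an ambiguous consensus are excluded from
    site classification.
    """
    from .adar_mask import majority_consensus

    table = _codon_table()
    L = alignment.L
    usable = L - frame - (L - frame) % 3
    if usable < 3:
        raise AlignmentError("no complete codons in the chosen frame")
    cons = majority_consensus(alignment).seq

    # per-sequence Nei-Gojobori synonymous site totals
    totals = []
    for seq in alignment.seqs:
        tot = 0.0
        for start in range(frame, frame + usable, 3):
            frac = _syn_fraction(seq[start : start + 3])
            if frac is not None:
                tot += frac
        totals.append(tot)
    syn_sites = float(np.mean(totals))

    arr = alignment.to_array()
    counts = _base_counts(arr)
    seg_cols = np.flatnonzero((counts > 0).sum(axis=1) >= 2)
    syn_cols: list[int] = []
    for col in seg_cols:
        if col < frame or col >= frame + usable:
            continue
        codon_start = frame + ((col - frame) // 3) * 3
        codon = cons[codon_start : codon_start + 3]
        if any(ch not in "ACGT" for ch in codon):
            continue
        pos = col - codon_start
        observed = [b.decode() for k, b in enumerate(_BYTES) if counts[col, k] > 0]
        aas = set()
        ok = True
        for b in observed:
            mut = codon[:pos] + b + codon[pos + 1 :]
            aa = table.get(mut)
            if aa is None:
                ok = False
                break
            aas.add(aa)
        if ok and len(aas) == 1 and "*" not in aas:
            syn_cols.append(int(col))
        if "*" in table.get(codon, ""):
            warnings.warn(f"stop codon in consensus at column {codon_start}", stacklevel=2)

    n = alignment.n
    if syn_cols:
        sub = alignment.select_columns(syn_cols)
        S_syn, singles = segregating_sites(sub)
        kbar = mean_pairwise_differences(sub)
        d = tajimas_D_from_counts(n, S_syn, kbar)
    else:
        S_syn, singles, kbar, d = 0, 0, 0.0, None
    return SynonymousAnalysis(
        frame=frame,
        n_codons=usable // 3,
        synonymous_site_count=syn_sites,
        synonymous_columns=tuple(syn_cols),
        S_syn=S_syn,
        singletons_syn=singles,
        kbar_syn=kbar,
        D=d,
    )


# ---------------------------------------------------------------------------
# combined report

@dataclass(frozen=True)
class NeutralityTest:
    D: float | None
    p_coalescent: float | None
    p_beta: float | None
    site_class: str
    reps: int | None = None
    seed: int | None = None


def neutrality_test(
    alignment: SequenceAlignment,
    reps: int = 10_000,
    seed: int | None = None,
    site_class: str = "all",
    frame: int = 0,
) -> NeutralityTest:
    """Tajima's D with coalescent and beta p-values on a filtered alignment."""
    if site_class == "synonymous":
        syn = synonymous_restriction(alignment, frame)
        d, S = syn.D, syn.S_syn
    else:
        d = tajimas_D(alignment)
        S, _ = segregating_sites(alignment)
    if d is None:
        return NeutralityTest(None, None, None, site_class, reps, seed)
    p_coal = coalescent_pvalue_D(d, alignment.n, S, reps, seed)
    p_beta = beta_pvalue_D(d, alignment.n)
    return NeutralityTest(d, p_coal, p_beta, site_class, reps, seed)
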