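"""Synthetic data generators with the statistical structure the analysis assumes.

The centrepiece is a neutral n-coalescent simulator with finite-sites
Jukes–Cantor mutation, supporting

* constant population size,
* exponential growth (population N(t) = N0·e^(-r·t) looking backwards,
  sampled exactly through the closed-form time change of the
  coalescence rate), and
* a two-deme clean split (no migration, demes merge at time tau).

Time is measured in coalescent units in which a pair of lineages
coalesces at rate 1; mutations fall on branches as a Poisson process at
rate theta/2 per lineage per unit time, each hitting a uniformly chosen
column and changing the current base to one of the other three
(finite-sites, so back-mutation and multi-allelic sites occur).  With a
molecular clock of ``clock_rate`` substitutions/site/year and sequence
length L, one coalescent unit equals theta / (2 · clock_rate · L)
years, which converts simulated TMRCAs to calendar time.

Also provided: an ADAR hyper-mutation tract injector with a truth table
(consumed by the masking pipeline's recovery tests), and binomial
simulators for transmission crosses and prevalence tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import SequenceAlignment, Sense
from .transmission import CrossRecord, PrevalenceTable

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class NonCoalescingError(RuntimeError):
    """The genealogy failed to coalesce (declining-population pathology)."""


# ---------------------------------------------------------------------------
# genealogies

@dataclass(frozen=True)
class Genealogy:
    """Rooted binary tree over n leaves: parent pointers and node times.

    Nodes 0..n-1 are leaves at time 0; internal nodes are numbered in
    coalescence order; node 2n-2 is the root.  Times are in coalescent
    units and non-decreasing toward the root.
    """

    parent: np.ndarray  # int, len 2n-1, root has -1
    time: np.ndarray    # float, len 2n-1
    n: int

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (len 2n-2)."""
        p = self.parent[:-1]
        return self.time[p] - self.time[:-1]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for v in range(2 * self.n - 2):
            out[self.parent[v]].append(v)
        return out

    def leaf_counts(self) -> np.ndarray:
        counts = np.zeros(2 * self.n - 1, dtype=np.int64)
        counts[: self.n] = 1
        for v in range(2 * self.n - 2):
            counts[self.parent[v]] += counts[v]
        return counts


def _exponential_wait(k: int, t0: float, growth: float, rng: np.random.Generator) -> float:
    """Waiting time to the next coalescence among k lineages.

    Under N(t) = N0·e^(-growth·t) backwards, the pairwise rate at time t
    is e^(growth·t); inverting the cumulative rate gives the wait in
    closed form.  A negative growth rate leaves a finite total rate, so
    the event may never happen; that raises NonCoalescingError.
    """
    pairs = k * (k - 1) / 2.0
    e = rng.exponential()
    if abs(growth) < 1e-12:
        return e / pairs
    arg = np.exp(growth * t0) + growth * e / pairs
    if arg <= 0.0:
        raise NonCoalescingError("lineages never coalesce under declining population")
    return float(np.log(arg) / growth - t0)


def simulate_genealogy(
    n: int,
    rng: np.random.Generator,
    growth: float = 0.0,
    deme_sizes: tuple[int, int] | None = None,
    split_time: float | None = None,
) -> Genealogy:
    """Draw one genealogy under the chosen demography.

    ``growth`` is the exponential growth rate in coalescent time units.
    With ``deme_sizes`` = (n1, n2) and ``split_time`` tau, the two demes
    coalesce independently (constant size, no migration) until tau, at
    which point the remaining lineages merge into one pool.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    nxt = n
    t = 0.0

    if deme_sizes is not None:
        n1, n2 = deme_sizes
        if n1 + n2 != n or split_time is None:
            raise ValueError("deme sizes must sum to n and split_time must be set")
        if growth != 0.0:
            raise ValueError("growth is not supported in the two-deme model")
        pools = [list(range(n1)), list(range(n1, n))]
        while sum(len(p) for p in pools) > 1:
            rates = [len(p) * (len(p) - 1) / 2.0 for p in pools]
            total = sum(rates)
            w = rng.exponential(1.0 / total) if total > 0.0 else np.inf
            if len(pools) == 2 and t + w >= split_time:
                t = split_time
                pools = [pools[0] + pools[1]]
                continue
            t += w
            u = rng.random() * total
            pool = pools[0] if (len(pools) == 1 or u < rates[0]) else pools[1]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = int(pool[i]), int(pool[j])
            parent[a] = parent[b] = nxt
            time[nxt] = t
            pool[min(i, j)] = nxt
            del pool[max(i, j)]
            nxt += 1
        return Genealogy(parent, time, n)

    active = list(range(n))
    for k in range(n, 1, -1):
        w = _exponential_wait(k, t, growth, rng)
        t += w
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active[min(i, j)] = nxt
        del active[max(i, j)]
        nxt += 1
    return Genealogy(parent, time, n)


# ---------------------------------------------------------------------------
# mutations

@dataclass(frozen=True)
class MutationRecord:
    """Poisson mutations on a genealogy: branch node, column, age, base shift."""

    node: np.ndarray   # branch above this node
    column: np.ndarray
    age: np.ndarray    # time of the event (coalescent units)
    shift: np.ndarray  # 1..3, new base = (current + shift) % 4

    def __len__(self) -> int:
        return len(self.node)


def place_mutations(
    genealogy: Genealogy, theta: float, L: int, rng: np.random.Generator
) -> MutationRecord:
    """Drop Poisson(theta/2 · total branch length) mutations on the tree."""
    bl = genealogy.branch_lengths()
    total = bl.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        empty = np.empty(0, dtype=np.int64)
        return MutationRecord(empty, empty, np.empty(0), empty)
    cum = np.cumsum(bl)
    nodes = np.searchsorted(cum, rng.random(n_mut) * total)
    cols = rng.integers(0, L, size=n_mut)
    ages = genealogy.time[nodes] + rng.random(n_mut) * bl[nodes]
    shifts = rng.integers(1, 4, size=n_mut)
    return MutationRecord(nodes.astype(np.int64), cols.astype(np.int64), ages, shifts)


def resolve_variant_matrix(
    genealogy: Genealogy,
    mutations: MutationRecord,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply mutations down the tree; return (columns, root bases, leaf matrix).

    ``columns`` are the distinct mutated columns (sorted), root bases
    are uniform draws for those columns, and the leaf matrix is an
    (n, len(columns)) array of base codes 0..3.  Mutations on one branch
    apply oldest-first; each changes the current base by its shift.
    """
    cols = np.unique(mutations.column)
    v = len(cols)
    n = genealogy.n
    root_bases = rng.integers(0, 4, size=v)
    if v == 0:
        return cols, root_bases, np.empty((n, 0), dtype=np.int64)
    col_index = {int(c): k for k, c in enumerate(cols)}
    per_node: dict[int, list[tuple[float, int, int]]] = {}
    for nd, c, age, sh in zip(mutations.node, mutations.column, mutations.age, mutations.shift):
        per_node.setdefault(int(nd), []).append((float(age), col_index[int(c)], int(sh)))
    for lst in per_node.values():
        lst.sort(key=lambda x: -x[0])  # oldest (largest age) applied first

    children = genealogy.children()
    state = root_bases.copy()
    matrix = np.empty((n, v), dtype=np.int64)
    root = 2 * n - 2
    # iterative DFS with undo on backtrack
    stack: list[tuple[int, list[tuple[int, int]] | None]] = [(root, None)]
    while stack:
        node, undo = stack.pop()
        if undo is not None:  # backtrack marker
            for k, old in undo:
                state[k] = old
            continue
        my_undo: list[tuple[int, int]] = []
        if node != root:
            for _, k, sh in per_node.get(node, ()):
                my_undo.append((k, int(state[k])))
                state[k] = (state[k] + sh) % 4
        if node < n:
            matrix[node] = state
            for k, old in my_undo:
                state[k] = old
            continue
        stack.append((node, my_undo))
        for ch in children[node]:
            stack.append((ch, None))
    return cols, root_bases, matrix


# ---------------------------------------------------------------------------
# configuration and full datasets

DEFAULT_CLOCK_RATE = 9.9e-5  # substitutions/site/year (sigma-virus molecular clock)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one coalescent simulation.

    ``growth_rate`` is per year and is converted internally to
    coalescent units through the clock; ``split_time`` is in coalescent
    units.  ``theta`` is the population-scaled mutation rate per
    sequence (2·N·mu_seq for a haploid virus).
    """

    n: int
    L: int
    theta: float
    model: str = "constant"  # constant | exponential | split
    growth_rate: float = 0.0           # per year
    clock_rate: float = DEFAULT_CLOCK_RATE
    deme_sizes: tuple[int, int] | None = None
    split_time: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.L <= 0 or self.theta <= 0:
            raise ValueError("require n >= 2, L > 0, theta > 0")
        if self.model not in ("constant", "exponential", "split"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "split" and (self.deme_sizes is None or self.split_time is None):
            raise ValueError("split model needs deme_sizes and split_time")

    @property
    def years_per_coal_unit(self) -> float:
        return self.theta / (2.0 * self.clock_rate * self.L)

    @property
    def growth_coal(self) -> float:
        if self.model != "exponential":
            return 0.0
        return self.growth_rate * self.years_per_coal_unit


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: SequenceAlignment
    genealogy: Genealogy
    mutations: MutationRecord
    config: SimulationConfig
    adar_truth: tuple[tuple[str, int, str], ...] = field(default_factory=tuple)

    @property
    def tmrca(self) -> float:
        return self.genealogy.tmrca

    @property
    def tmrca_years(self) -> float:
        return self.tmrca * self.config.years_per_coal_unit

    @property
    def population_labels(self) -> list[str] | None:
        if self.config.deme_sizes is None:
            return None
        n1, n2 = self.config.deme_sizes
        return ["deme1"] * n1 + ["deme2"] * n2


def simulate_coalescent(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a full alignment under the configured demography."""
    rng = np.random.default_rng(config.seed)
    gen = simulate_genealogy(
        config.n,
        rng,
        growth=config.growth_coal,
        deme_sizes=config.deme_sizes if config.model == "split" else None,
        split_time=config.split_time if config.model == "split" else None,
    )
    muts = place_mutations(gen, config.theta, config.L, rng)
    cols, _roots, matrix = resolve_variant_matrix(gen, muts, rng)
    codes = np.tile(rng.integers(0, 4, size=config.L), (config.n, 1))
    if cols.size:
        codes[:, cols] = matrix
    seqs = tuple(row.tobytes().decode() for row in _BASES[codes])
    ids = tuple(f"s{i:03d}" for i in range(config.n))
    return SimulatedDataset(
        SequenceAlignment(ids, seqs, Sense.MRNA), gen, muts, config
    )


def simulate_variant_matrix(
    n: int,
    L: int,
    theta: float,
    rng: np.random.Generator,
    growth: float = 0.0,
) -> tuple[Genealogy, np.ndarray]:
    """Fast path for inference loops: genealogy + (n, V) variant-column codes.

    Statistically identical to ``simulate_coalescent`` but skips
    materializing the monomorphic background, which no summary uses.
    """
    gen = simulate_genealogy(n, rng, growth=growth)
    muts = place_mutations(gen, theta, L, rng)
    _, _, matrix = resolve_variant_matrix(gen, muts, rng)
    return gen, matrix


# ---------------------------------------------------------------------------
# ADAR tract injection

def inject_adar_tracts(
    alignment: SequenceAlignment,
    n_events: int,
    tract_mean: float = 6.0,
    sense_probabilities: tuple[float, float] = (0.5, 0.5),
    window: int = 200,
    seed: int | None = None,
) -> tuple[SequenceAlignment, tuple[tuple[str, int, str], ...]]:
    """Inject clustered A→G hyper-mutation tracts at ADAR-preferred sites.

    Each event picks one sequence and one sense (stored vs opposite,
    weighted by ``sense_probabilities``), then converts a geometric-length
    run of consecutive preferred-context sites, all within a ``window``-
    column span, from A to G in that sense (T→C in stored orientation
    for the opposite sense).  Preferred-site context is classified from
    the input alignment's majority consensus, so every entry of the
    returned truth table satisfies the masking pipeline's predicate.
    Non-preferred sites are never touched.

    Returns (edited alignment, truth table of (seq id, column, sense)).
    """
    from .adar_mask import classify_preferred_sites, majority_consensus

    rng = np.random.default_rng(seed)
    consensus = majority_consensus(alignment)
    flags = classify_preferred_sites(consensus, alignment.sense)
    seqs = [list(s) for s in alignment.seqs]
    truth: list[tuple[str, int, str]] = []
    injected = 0
    for _ in range(n_events):
        use_stored = rng.random() < sense_probabilities[0] / sum(sense_probabilities)
        if use_stored:
            pref, src, dst, label = flags.preferred_stored, "A", "G", flags.stored_sense_label
        else:
            pref, src, dst, label = flags.preferred_opposite, "T", "C", flags.opposite_sense_label
        row = int(rng.integers(alignment.n))
        candidates = [
            c for c in np.flatnonzero(pref) if seqs[row][c] == src
        ]
        if not candidates:
            warnings.warn("insufficient eligible preferred sites; event skipped", stacklevel=2)
            continue
        start_idx = int(rng.integers(len(candidates)))
        length = int(rng.geometric(min(1.0, 1.0 / tract_mean)))
        start_col = candidates[start_idx]
        tract = [
            c
            for c in candidates[start_idx : start_idx + length]
            if c - start_col < window
        ]
        for c in tract:
            seqs[row][c] = dst
            truth.append((alignment.ids[row], int(c), label))
            injected += 1
    edited = SequenceAlignment(
        alignment.ids, tuple("".join(s) for s in seqs), alignment.sense
    )
    return edited, tuple(truth)


# ---------------------------------------------------------------------------
# crosses and prevalence

def simulate_crosses(
    n_maternal: int,
    n_paternal: int,
    n_control: int,
    maternal_rate: float,
    paternal_rate: float,
    offspring_per_cross: int | tuple[int, int] = (4, 8),
    sex_ratio: float = 0.5,
    seed: int | None = None,
) -> list[CrossRecord]:
    """Simulate transmission crosses with binomial offspring infection.

    Offspring of infected mothers are infected independently at
    ``maternal_rate``, of infected fathers at ``paternal_rate``, and of
    double-uninfected control pairs never.  Sexes are Bernoulli(sex_ratio)
    female.  Defaults mirror the scale of real cross designs (a handful
    of scored offspring per cross).
    """
    for r in (maternal_rate, paternal_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    crosses: list[CrossRecord] = []
    classes = (
        [("maternal", True, False, maternal_rate)] * n_maternal
        + [("paternal", False, True, paternal_rate)] * n_paternal
        + [("control", False, False, 0.0)] * n_control
    )
    for k, (cls, mom, dad, rate) in enumerate(classes):
        if isinstance(offspring_per_cross, tuple):
            lo, hi = offspring_per_cross
            n_off = int(rng.integers(lo, hi + 1))
        else:
            n_off = int(offspring_per_cross)
        offspring = tuple(
            ("F" if rng.random() < sex_ratio else "M", bool(rng.random() < rate))
            for _ in range(n_off)
        )
        crosses.append(CrossRecord(f"{cls}_{k:03d}", mom, dad, offspring))
    return crosses


def simulate_prevalence(
    populations: dict[str, tuple[float, int]],
    seed: int | None = None,
) -> PrevalenceTable:
    """Binomial prevalence draws: population -> (true prevalence, n tested)."""
    rng = np.random.default_rng(seed)
    counts = {}
    for pop, (prev, n) in populations.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"prevalence out of range for {pop!r}")
        counts[pop] = (n, int(rng.binomial(n, prev)))
    return PrevalenceTable(counts)
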