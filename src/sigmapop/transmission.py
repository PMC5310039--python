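"""Vertical-transmission cross analysis and field prevalence.

Sigma viruses are transmitted through both eggs and sperm.  The cross
design pairs infected/uninfected mothers and fathers and scores a
sample of offspring for infection.  The analysis unit is the per-cross
proportion of infected offspring (not pooled offspring, which would
pseudo-replicate); maternal and paternal transmission rates are
compared with an exact Wilcoxon rank-sum test, as are infection rates
of daughters versus sons.  Field prevalence differences between
populations are tested with a Pearson chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, rankdata


class TransmissionError(ValueError):
    pass


@dataclass(frozen=True)
class CrossRecord:
    """One cross: parental infection status and scored offspring."""

    cross_id: str
    mother_infected: bool
    father_infected: bool
    offspring: tuple[tuple[str, bool], ...]  # (sex 'F'/'M', infected)

    @property
    def parental_class(self) -> str:
        if self.mother_infected and self.father_infected:
            return "both"
        if self.mother_infected:
            return "maternal"
        if self.father_infected:
            return "paternal"
        return "control"

    @property
    def proportion_infected(self) -> float:
        if not self.offspring:
            raise TransmissionError(f"cross {self.cross_id} has no offspring")
        return sum(inf for _, inf in self.offspring) / len(self.offspring)

    def proportion_by_sex(self, sex: str) -> float | None:
        subset = [inf for s, inf in self.offspring if s == sex]
        return sum(subset) / len(subset) if subset else None


_TRUTHY = {"1", "true", "infected", "yes", "i"}
_FALSY = {"0", "false", "uninfected", "no", "u"}


def _as_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise TransmissionError(f"cannot interpret infection status {value!r}")


def read_crosses(path: str | Path) -> list[CrossRecord]:
    """Read long-format cross records.

    Columns: cross_id, mother_status, father_status, offspring_sex,
    offspring_status (one row per offspring).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cross_id", "mother_status", "father_status", "offspring_sex", "offspring_status"}
    missing = required - set(df.columns)
    if missing:
        raise TransmissionError(f"crosses file missing columns: {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cross_id", sort=True):
        mother = {_as_bool(v) for v in grp["mother_status"]}
        father = {_as_bool(v) for v in grp["father_status"]}
        if len(mother) != 1 or len(father) != 1:
            raise TransmissionError(f"inconsistent parental status in cross {cid!r}")
        offspring = tuple(
            (str(s).strip().upper()[0], _as_bool(st))
            for s, st in zip(grp["offspring_sex"], grp["offspring_status"])
        )
        out.append(CrossRecord(str(cid), mother.pop(), father.pop(), offspring))
    return out


@dataclass(frozen=True)
class TransmissionSummary:
    per_cross: Mapping[str, float]          # cross id -> proportion infected
    per_cross_class: Mapping[str, str]
    maternal_mean: float | None
    paternal_mean: float | None
    control_contamination: int              # infected offspring in control crosses
    excluded_crosses: tuple[str, ...]

    def proportions(self, parental_class: str) -> list[float]:
        return [
            p
            for cid, p in self.per_cross.items()
            if self.per_cross_class[cid] == parental_class
        ]


def summarize_crosses(crosses: Sequence[CrossRecord]) -> TransmissionSummary:
    """Per-cross infected proportions and unweighted group means."""
    per_cross: dict[str, float] = {}
    per_class: dict[str, str] = {}
    excluded = []
    contamination = 0
    for cr in crosses:
        if not cr.offspring:
            warnings.warn(f"cross {cr.cross_id} has no offspring; excluded", stacklevel=2)
            excluded.append(cr.cross_id)
            continue
        per_cross[cr.cross_id] = cr.proportion_infected
        per_class[cr.cross_id] = cr.parental_class
        if cr.parental_class == "control":
            contamination += sum(inf for _, inf in cr.offspring)
    def mean_of(cls: str) -> float | None:
        vals = [p for cid, p in per_cross.items() if per_class[cid] == cls]
        return float(np.mean(vals)) if vals else None

    return TransmissionSummary(
        per_cross=per_cross,
        per_cross_class=per_class,
        maternal_mean=mean_of("maternal"),
        paternal_mean=mean_of("paternal"),
        control_contamination=contamination,
        excluded_crosses=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum test

@dataclass(frozen=True)
class WilcoxonResult:
    W: float               # rank-sum of the first group
    p: float               # two-sided
    n1: int
    n2: int
    method: str            # 'exact' or 'permutation'
    seed: int | None = None


def _exact_ranksum_distribution(n1: int, n_total: int) -> np.ndarray:
    """Counts of subsets of {1..n_total} of size n1 by rank sum (index = sum)."""
    max_sum = sum(range(n_total - n1 + 1, n_total + 1))
    # dp[j][s] = number of j-subsets of ranks seen so far with sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        upper = min(rank, n1)
        for j in range(upper, 0, -1):
            dp[j, rank:] += dp[j - 1, : max_sum + 1 - rank]
    return dp[n1]


def wilcoxon_exact(
    x: Sequence[float],
    y: Sequence[float],
    seed: int | None = None,
    n_permutations: int = 10_000,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test, exact where feasible.

    W is the rank-sum of the first group.  With no ties and
    n1 + n2 <= 16 the p-value is exact, from full enumeration of the
    rank-sum null distribution; otherwise ties get mid-ranks and the
    p-value is a seeded Monte-Carlo permutation estimate using the
    (b+1)/(m+1) correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise TransmissionError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w_obs = float(ranks[:n1].sum())
    has_ties = len(np.unique(combined)) < len(combined)
    n_total = n1 + n2

    if not has_ties and n_total <= 16:
        dist = _exact_ranksum_distribution(n1, n_total)
        total = dist.sum()
        w_int = int(round(w_obs))
        p_low = dist[: w_int + 1].sum() / total
        p_high = dist[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(w_obs, float(p), n1, n2, "exact")

    rng = np.random.default_rng(seed)
    eps = 1e-9
    b_low = b_high = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ranks)
        w = perm[:n1].sum()
        if w <= w_obs + eps:
            b_low += 1
        if w >= w_obs - eps:
            b_high += 1
    p_low = (b_low + 1) / (n_permutations + 1)
    p_high = (b_high + 1) / (n_permutations + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return WilcoxonResult(w_obs, float(p), n1, n2, "permutation", seed)


def maternal_paternal_test(
    crosses: Sequence[CrossRecord], seed: int | None = None
) -> WilcoxonResult:
    """Compare maternal vs paternal per-cross transmission proportions."""
    summary = summarize_crosses(crosses)
    x = summary.proportions("maternal")
    y = summary.proportions("paternal")
    if not x or not y:
        raise TransmissionError("need both maternal and paternal crosses")
    return wilcoxon_exact(x, y, seed=seed)


def sex_difference_test(
    crosses: Sequence[CrossRecord], seed: int | None = None
) -> WilcoxonResult:
    """Compare per-cross infection proportions of daughters vs sons.

    Uses transmission crosses (at least one infected parent) in which
    both sexes were scored.
    """
    daughters, sons = [], []
    for cr in crosses:
        if cr.parental_class == "control" or not cr.offspring:
            continue
        pf = cr.proportion_by_sex("F")
        pm = cr.proportion_by_sex("M")
        if pf is None or pm is None:
            continue
        daughters.append(pf)
        sons.append(pm)
    if not daughters:
        raise TransmissionError("no cross has offspring of both sexes")
    return wilcoxon_exact(daughters, sons, seed=seed)


# ---------------------------------------------------------------------------
# prevalence heterogeneity

@dataclass(frozen=True)
class PrevalenceTable:
    counts: Mapping[str, tuple[int, int]]  # population -> (n tested, n infected)

    def __post_init__(self) -> None:
        for pop, (tested, infected) in self.counts.items():
            if tested < 0 or infected < 0 or infected > tested:
                raise TransmissionError(f"invalid counts for population {pop!r}")

    @property
    def mean_prevalence(self) -> float:
        tested = sum(t for t, _ in self.counts.values())
        infected = sum(i for _, i in self.counts.values())
        return infected / tested if tested else float("nan")


def read_prevalence(path: str | Path) -> PrevalenceTable:
    """Read a prevalence TSV with columns population, n_tested, n_infected."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "n_tested", "n_infected"}
    missing = required - set(df.columns)
    if missing:
        raise TransmissionError(f"prevalence file missing columns: {sorted(missing)}")
    return PrevalenceTable(
        {
            str(row.population): (int(row.n_tested), int(row.n_infected))
            for row in df.itertuples()
        }
    )


@dataclass(frozen=True)
class ChiSqResult:
    chi2: float
    df: int
    p: float
    low_expected_warning: bool


def prevalence_chisq(table: PrevalenceTable) -> ChiSqResult:
    """Pearson chi-squared heterogeneity test across populations (df = k-1)."""
    pops = sorted(table.counts)
    if len(pops) < 2:
        raise TransmissionError("need at least 2 populations")
    rows = []
    for pop in pops:
        tested, infected = table.counts[pop]
        if tested == 0:
            raise TransmissionError(f"population {pop!r} has zero tested individuals")
        rows.append([infected, tested - infected])
    observed = np.array(rows)
    chi2, p, df, expected = chi2_contingency(observed, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("some expected counts are below 5", stacklevel=2)
    return ChiSqResult(float(chi2), int(df), float(p), low)
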