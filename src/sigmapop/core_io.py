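"""Core data model and standard-format I/O.

The central container is :class:`SequenceAlignment`, a validated set of
equal-length nucleotide sequences.  All downstream statistics (diversity,
differentiation, ADAR masking, demographic inference) operate on it.
Sample metadata (population labels, coordinates, collection year) travel
separately in :class:`SampleMetadata` and are joined by sample id.

Alignment columns are 0-based throughout; exported site lists use
half-open intervals.  ``N`` and ``-`` are distinct symbols: both are
preserved on read/write and both trigger column exclusion in the
statistics modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT-N")
_BASES = "ACGT"


class Sense(str, Enum):
    """Strand convention of stored sequences.

    Sigma viruses are negative-sense: the packaged genome is the negative
    strand, the replication intermediate / mRNA the positive strand.
    Sanger products do not record strand, so the convention is supplied by
    the user (default ``mrna``).
    """

    GENOME = "genome"
    ANTIGENOME = "antigenome"
    MRNA = "mrna"


class AlignmentError(ValueError):
    """Raised when an alignment violates its invariants."""


@dataclass(frozen=True)
class SequenceAlignment:
    """Equal-length nucleotide sequences with unique sample ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    sense: Sense = Sense.MRNA

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise AlignmentError(f"duplicate sequence id: {i!r}")
                seen.add(i)
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            offender = next(
                i for i, s in zip(self.ids, self.seqs) if len(s) != len(self.seqs[0])
            )
            raise AlignmentError(
                f"unequal sequence lengths (first offending id: {offender!r})"
            )
        if lengths == {0}:
            raise AlignmentError("zero-length sequences")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - ALPHABET
            if bad:
                pos = next(k for k, c in enumerate(s) if c in bad)
                raise AlignmentError(
                    f"illegal character {s[pos]!r} in sequence {sid!r} at column {pos}"
                )
        if not isinstance(self.sense, Sense):
            object.__setattr__(self, "sense", Sense(self.sense))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """Return an (n, L) array of single-byte characters (dtype 'S1')."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n, self.L
        )

    def select_columns(self, columns: Sequence[int]) -> "SequenceAlignment":
        arr = self.to_array()[:, list(columns)]
        seqs = tuple(row.tobytes().decode() for row in arr)
        return SequenceAlignment(self.ids, seqs, self.sense)

    def select_samples(self, ids: Iterable[str]) -> "SequenceAlignment":
        wanted = list(ids)
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        return SequenceAlignment(
            tuple(wanted),
            tuple(self.seqs[index[i]] for i in wanted),
            self.sense,
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta_alignment(path: str | Path, sense: Sense | str = Sense.MRNA) -> SequenceAlignment:
    """Read a pre-aligned FASTA file into a validated alignment.

    Lowercase is normalized to uppercase and U to T.  Unequal lengths,
    illegal characters and duplicate ids are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalize(str(r.seq)) for r in records)
    return SequenceAlignment(ids, seqs, Sense(sense))


def write_fasta_alignment(alignment: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample population labels and optional coordinates / years."""

    population: Mapping[str, str]
    latitude: Mapping[str, float] = field(default_factory=dict)
    longitude: Mapping[str, float] = field(default_factory=dict)
    year: Mapping[str, int] = field(default_factory=dict)

    def labels_for(self, alignment: SequenceAlignment) -> list[str]:
        """Population labels in alignment order; missing ids are an error."""
        missing = [i for i in alignment.ids if i not in self.population]
        if missing:
            raise KeyError(f"samples without population labels: {missing}")
        return [self.population[i] for i in alignment.ids]


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (sample_id, population[, latitude, longitude, year])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id in metadata: {dup!r}")
    if df["population"].isna().any() or (df["population"].str.strip() == "").any():
        raise ValueError("empty population label in metadata")
    pop = dict(zip(df["sample_id"], df["population"]))
    out = {"population": pop}
    for col, key in (("latitude", "latitude"), ("longitude", "longitude"), ("year", "year")):
        if col in df.columns:
            sub = df.dropna(subset=[col])
            out[key] = dict(zip(sub["sample_id"], sub[col]))
    return SampleMetadata(**out)


def check_metadata_coverage(
    alignment: SequenceAlignment, metadata: SampleMetadata
) -> list[str]:
    """Warn about metadata ids absent from the alignment; return them."""
    extra = [i for i in metadata.population if i not in set(alignment.ids)]
    if extra:
        warnings.warn(
            f"{len(extra)} metadata ids not present in the alignment: {extra[:5]}...",
            stacklevel=2,
        )
    return extra


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    members: tuple[str, ...]
    counts_by_population: Mapping[str, int]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with their carriers, as drawn in haplotype networks.

    Node size in a haplotype network is the number of samples carrying that
    exact sequence; gap and N characters are compared literally.
    """

    haplotypes: tuple[Haplotype, ...]

    @property
    def n(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(
    alignment: SequenceAlignment, metadata: SampleMetadata | None = None
) -> HaplotypeTable:
    """Group identical sequences into haplotypes with per-population counts.

    Ordering is deterministic: descending carrier count, then ascending
    smallest member id.
    """
    groups: dict[str, list[str]] = {}
    for sid, seq in zip(alignment.ids, alignment.seqs):
        groups.setdefault(seq, []).append(sid)
    haps = []
    for seq, members in groups.items():
        if metadata is not None:
            pops: dict[str, int] = {}
            for m in members:
                p = metadata.population.get(m, "unknown")
                pops[p] = pops.get(p, 0) + 1
        else:
            pops = {"all": len(members)}
        haps.append(Haplotype(seq, tuple(members), pops))
    haps.sort(key=lambda h: (-h.count, min(h.members)))
    return HaplotypeTable(tuple(haps))
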