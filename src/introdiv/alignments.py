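"""Per-locus alignment containers, FASTA I/O and site-filtering policies.

Sequences arrive pre-aligned, one multi-FASTA per locus.  Population labels
are supplied through a sidecar two-column TSV (seq_id <TAB> population) rather
than parsed out of FASTA headers.  Internally all coordinates are 0-based
half-open; report writers convert to 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset(b"ACGT-N")
_NUCLEOTIDES = frozenset(b"ACGT")


class AlignmentError(ValueError):
    """Records in a locus FASTA do not form a valid alignment."""


class PopulationMapError(KeyError):
    """A sequence id has no population assignment."""


@dataclass(frozen=True)
class PopulationMap:
    """Mapping of sequence ids to population labels.

    ``populations`` fixes a stable label order used everywhere downstream
    (tables, distance matrices, pair definitions).
    """

    assignments: Mapping[str, str]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        used = set(self.assignments.values())
        missing = [p for p in self.populations if p not in used]
        if missing:
            raise ValueError(f"declared populations never used: {missing}")
        unknown = used - set(self.populations)
        if unknown:
            raise ValueError(f"assignments use undeclared populations: {sorted(unknown)}")

    def __getitem__(self, seq_id: str) -> str:
        try:
            return self.assignments[seq_id]
        except KeyError as exc:
            raise PopulationMapError(f"sequence {seq_id!r} missing from population map") from exc


def read_popmap(path: str | Path, populations: Sequence[str] | None = None) -> PopulationMap:
    """Read a two-column (seq_id, population) TSV into a :class:`PopulationMap`."""
    assignments: dict[str, str] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed popmap line: {line!r}")
        seq_id, pop = parts
        assignments[seq_id] = pop
        if pop not in order:
            order.append(pop)
    if not assignments:
        raise ValueError(f"empty population map: {path}")
    pops = tuple(populations) if populations is not None else tuple(order)
    return PopulationMap(assignments=assignments, populations=pops)


def _normalize(seq: str) -> str:
    """Uppercase and collapse anything outside {A,C,G,T,-} to N."""
    up = seq.upper()
    if set(up.encode()) <= VALID_RESIDUES:
        return up
    return "".join(c if c in "ACGT-" else "N" for c in up)


@dataclass(frozen=True)
class LocusAlignment:
    """One locus: aligned sequences with population labels and kept columns.

    ``kept_sites`` holds the (strictly increasing) column indices that survive
    site filtering; every downstream statistic is computed on this column set.
    """

    locus_name: str
    ids: tuple[str, ...]
    populations: tuple[str, ...]
    sequences: tuple[str, ...]
    kept_sites: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise AlignmentError(f"{self.locus_name}: duplicate sequence ids")
        if len({len(s) for s in self.sequences}) > 1:
            raise AlignmentError(f"{self.locus_name}: records have unequal aligned lengths")
        if len(self.ids) != len(self.sequences) or len(self.ids) != len(self.populations):
            raise AlignmentError(f"{self.locus_name}: ids/populations/sequences length mismatch")
        kept = self.kept_sites
        if kept is None:
            kept = np.arange(self.length)
        kept = np.asarray(kept, dtype=np.intp)
        if kept.size and (np.any(np.diff(kept) <= 0) or kept[0] < 0 or kept[-1] >= self.length):
            raise AlignmentError(f"{self.locus_name}: kept_sites not strictly increasing in range")
        object.__setattr__(self, "kept_sites", kept)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.ids)

    def matrix(self, kept_only: bool = True) -> np.ndarray:
        """Residues as a (n, columns) uint8 matrix of ASCII codes."""
        full = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        full = full.reshape(self.n, self.length)
        return full[:, self.kept_sites] if kept_only else full

    def subset_population(self, population: str) -> "LocusAlignment":
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise ValueError(f"{self.locus_name}: no sequences for population {population!r}")
        return self.subset_indices(idx)

    def subset_indices(self, indices: Iterable[int]) -> "LocusAlignment":
        idx = list(indices)
        return replace(
            self,
            ids=tuple(self.ids[i] for i in idx),
            populations=tuple(self.populations[i] for i in idx),
            sequences=tuple(self.sequences[i] for i in idx),
        )

    def population_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.populations:
            counts[p] = counts.get(p, 0) + 1
        return counts


def read_locus_alignment(
    fasta_path: str | Path,
    popmap: PopulationMap,
    locus_name: str | None = None,
) -> LocusAlignment:
    """Read one locus multi-FASTA, attaching population labels from *popmap*.

    Residues are uppercased and non-ACGT/- characters become N.  The returned
    alignment keeps all columns; apply :func:`filter_sites` afterwards.
    """
    path = Path(fasta_path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"empty or unreadable FASTA: {path}")
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 aligned records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: records have unequal lengths {sorted(lengths)}")
    ids = tuple(r.id for r in records)
    pops = tuple(popmap[i] for i in ids)
    seqs = tuple(_normalize(str(r.seq)) for r in records)
    return LocusAlignment(
        locus_name=locus_name or path.stem, ids=ids, populations=pops, sequences=seqs
    )


def filter_sites(aln: LocusAlignment, policy: str = "complete-deletion") -> LocusAlignment:
    """Apply a site-filtering policy, returning a new alignment.

    ``complete-deletion`` removes every column containing a gap or N in any
    sequence, the single consistent site universe used by all downstream
    statistics.  ``none`` keeps the current ``kept_sites``.
    """
    if policy == "none":
        return aln
    if policy != "complete-deletion":
        raise ValueError(f"unknown site-filtering policy: {policy!r}")
    full = aln.matrix(kept_only=False)
    clean = ~np.any((full == ord("-")) | (full == ord("N")), axis=0)
    kept = np.intersect1d(aln.kept_sites, np.flatnonzero(clean))
    if kept.size == 0:
        warnings.warn(
            f"{aln.locus_name}: complete deletion removed every column", stacklevel=2
        )
    return replace(aln, kept_sites=kept)


def write_locus_alignment(aln: LocusAlignment, fasta_path: str | Path, kept_only: bool = False) -> None:
    """Write the alignment back to FASTA (optionally only kept columns)."""
    records = []
    for sid, seq in zip(aln.ids, aln.sequences):
        if kept_only:
            seq = "".join(seq[i] for i in aln.kept_sites)
        records.append(SeqRecord(Seq(seq), id=sid, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    lines = [f"{sid}\t{pop}" for sid, pop in popmap.assignments.items()]
    Path(path).write_text("\n".join(lines) + "\n")
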