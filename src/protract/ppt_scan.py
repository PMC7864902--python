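"""Detection and per-protein profiling of poly-proline tracts (PPTs).

A PPT is a maximal run of consecutive proline residues of at least
``min_tract_len`` residues (default 3, the length at which stalled
ribosomes require eIF5A for elongation). Scanning is case-insensitive;
any non-proline character — including ambiguity codes (X, B, Z, U) and the
stop symbol ``*`` — terminates a run, so tracts never bridge across them.
Coordinates are 0-based, half-open ``[start, start + length)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRACT_LEN = 3


@dataclass(frozen=True, order=True)
class ProlineTract:
    """A maximal proline run: 0-based ``start`` and residue ``length``."""

    start: int
    length: int

    @property
    def end(self) -> int:
        """Exclusive end offset."""
        return self.start + self.length


@dataclass(frozen=True)
class PPTProfile:
    """Per-protein summary of poly-proline-tract content.

    ``total_prolines`` counts prolines inside tracts only; isolated
    prolines and sub-threshold runs do not contribute.
    """

    protein_id: str
    seq_length: int
    n_tracts: int
    longest_tract: int
    total_prolines: int

    def sort_key(self) -> tuple:
        """Ranking key: PPT proline content desc, longest desc, count desc, id asc."""
        return (-self.total_prolines, -self.longest_tract, -self.n_tracts, self.protein_id)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene/protein identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Read one identifier per line; ``#`` starts a comment; blanks ignored."""
        path = Path(path)
        members = []
        for line in path.read_text().splitlines():
            ident = line.split("#", 1)[0].strip()
            if ident:
                members.append(ident)
        if len(members) != len(set(members)):
            dupes = sorted({m for m in members if members.count(m) > 1})
            raise ValueError(f"duplicate identifiers in gene set: {dupes[:5]}")
        return cls(name=name or path.stem, members=frozenset(members))


def _validate_sequence(sequence: str) -> None:
    if not isinstance(sequence, str):
        raise TypeError(f"sequence must be a string, got {type(sequence).__name__}")
    body = sequence[:-1] if sequence.endswith("*") else sequence
    if body and not body.isalpha():
        bad = sorted({c for c in body if not c.isalpha()})
        raise ValueError(f"sequence contains non-letter characters: {bad}")


def find_ppts(sequence: str, min_tract_len: int = DEFAULT_MIN_TRACT_LEN) -> list[ProlineTract]:
    """Return all maximal proline runs of length >= ``min_tract_len``.

    Parameters
    ----------
    sequence
        Amino-acid string; letters only, with an optional trailing ``*``
        stop symbol. Case-insensitive. An empty string yields an empty
        list.
    min_tract_len
        Minimum run length to report (>= 2).

    Returns
    -------
    list of :class:`ProlineTract`, sorted by start, non-overlapping.
    """
    if min_tract_len < 2:
        raise ValueError(f"min_tract_len must be >= 2, got {min_tract_len}")
    _validate_sequence(sequence)
    tracts: list[ProlineTract] = []
    run_start = None
    for i, ch in enumerate(sequence):
        if ch in ("P", "p"):
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= min_tract_len:
                tracts.append(ProlineTract(run_start, i - run_start))
            run_start = None
    if run_start is not None and len(sequence) - run_start >= min_tract_len:
        tracts.append(ProlineTract(run_start, len(sequence) - run_start))
    return tracts


def profile_protein(
    protein_id: str, sequence: str, min_tract_len: int = DEFAULT_MIN_TRACT_LEN
) -> PPTProfile:
    """Summarise a protein's PPT content from its tract list."""
    tracts = find_ppts(sequence, min_tract_len)
    lengths = [t.length for t in tracts]
    seq_length = len(sequence) - (1 if sequence.endswith("*") else 0)
    return PPTProfile(
        protein_id=protein_id,
        seq_length=seq_length,
        n_tracts=len(tracts),
        longest_tract=max(lengths, default=0),
        total_prolines=sum(lengths),
    )


def scan_proteome(
    fasta_path: str | Path, min_tract_len: int = DEFAULT_MIN_TRACT_LEN
) -> list[PPTProfile]:
    """Profile every record of a multi-FASTA file, preserving input order.

    Raises on duplicate record identifiers and on empty records, naming
    the offending record.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")
    profiles: list[PPTProfile] = []
    seen: set[str] = set()
    for idx, record in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"record #{idx} ({record.id!r}) has an empty sequence")
        if record.id in seen:
            raise ValueError(f"duplicate identifier in FASTA: {record.id!r}")
        seen.add(record.id)
        try:
            profiles.append(profile_protein(record.id, seq, min_tract_len))
        except ValueError as exc:
            raise ValueError(f"record #{idx} ({record.id!r}): {exc}") from exc
    if not profiles:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    n_with = sum(1 for p in profiles if p.n_tracts > 0)
    logger.info(
        "scanned %d records (min_tract_len=%d): %d with >=1 PPT",
        len(profiles), min_tract_len, n_with,
    )
    return profiles


def rank_by_ppt_content(
    profiles: Sequence[PPTProfile], gene_set: GeneSet
) -> list[tuple[int, PPTProfile]]:
    """Rank gene-set members by proline content in PPTs.

    Sort keys, in order: ``total_prolines`` descending, ``longest_tract``
    descending, ``n_tracts`` descending, identifier ascending. Ranks are
    1-based and consecutive. Gene-set members missing from ``profiles``
    are logged and skipped; an empty intersection is an error.
    """
    members = [p for p in profiles if p.protein_id in gene_set.members]
    missing = gene_set.members - {p.protein_id for p in members}
    if missing:
        logger.warning(
            "%d gene-set members absent from profiles (e.g. %s)",
            len(missing), sorted(missing)[:5],
        )
    if not members:
        raise ValueError(
            f"no members of gene set {gene_set.name!r} found among the profiles"
        )
    members.sort(key=PPTProfile.sort_key)
    return [(rank, profile) for rank, profile in enumerate(members, start=1)]


def profiles_by_id(profiles: Iterable[PPTProfile]) -> dict[str, PPTProfile]:
    """Index profiles by identifier, rejecting duplicates."""
    index: dict[str, PPTProfile] = {}
    for p in profiles:
        if p.protein_id in index:
            raise ValueError(f"duplicate protein identifier: {p.protein_id!r}")
        index[p.protein_id] = p
    return index
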