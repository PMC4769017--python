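"""Sequence and alignment I/O.

Protein sequences are read from FASTA into :class:`ProteinRecord` objects;
gapped (aligned) FASTA is read into :class:`Alignment`. Consensus annotation
follows the two-level convention of multiple-alignment viewers: a column is
"high" consensus when the modal residue reaches the high threshold (default
90%) of the non-gap entries, "low" between the two thresholds (default 50%),
and "none" otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted in input; treated as missing data by the
#: evolution statistics.
AMBIGUOUS = "XBZ"
GAP = "-"
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS + AMBIGUOUS)
GAPPED_ALPHABET = RESIDUE_ALPHABET | {GAP}


class FastaFormatError(ValueError):
    """Malformed FASTA / alignment input."""


@dataclass(frozen=True)
class TaxonInfo:
    genus: str = ""
    species_epithet: str = ""
    division: str = ""


@dataclass(frozen=True)
class ProteinRecord:
    """One unaligned protein sequence with optional taxon metadata."""

    id: str
    residues: str
    genus: str = ""
    species_epithet: str = ""
    division: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        residues = self.residues.upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if not residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        for pos, ch in enumerate(residues, start=1):
            if ch not in RESIDUE_ALPHABET:
                raise FastaFormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(
    path: str | Path,
    metadata: Mapping[str, TaxonInfo] | None = None,
) -> list[ProteinRecord]:
    """Read unaligned protein FASTA into a list of :class:`ProteinRecord`.

    ``metadata`` optionally maps record ids to :class:`TaxonInfo`; terminal
    ``*`` stop characters are stripped and residues upper-cased. Duplicate
    ids, illegal characters and empty files raise :class:`FastaFormatError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaFormatError(f"duplicate record id {entry.id!r}")
        seen.add(entry.id)
        taxon = (metadata or {}).get(entry.id, TaxonInfo())
        records.append(
            ProteinRecord(
                id=entry.id,
                residues=str(entry.seq),
                genus=taxon.genus,
                species_epithet=taxon.species_epithet,
                division=taxon.division,
            )
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(entries, str(path), "fasta")


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped amino-acid sequences.

    ``records`` is an ordered tuple of ``(id, gapped_residues)``; gaps are
    ``-`` and ambiguity codes X/B/Z are allowed.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FastaFormatError("alignment needs at least 2 sequences")
        normalized = []
        n = len(self.records[0][1])
        seen: set[str] = set()
        for rid, seq in self.records:
            seq = seq.upper()
            if rid in seen:
                raise FastaFormatError(f"duplicate record id {rid!r}")
            seen.add(rid)
            if len(seq) != n:
                raise FastaFormatError(
                    f"ragged alignment: {rid!r} has length {len(seq)}, expected {n}"
                )
            for pos, ch in enumerate(seq, start=1):
                if ch not in GAPPED_ALPHABET:
                    raise FastaFormatError(
                        f"record {rid!r}: illegal character {ch!r} at position {pos}"
                    )
            normalized.append((rid, seq))
        if n < 1:
            raise FastaFormatError("alignment has zero columns")
        object.__setattr__(self, "records", tuple(normalized))

    @property
    def n_sites(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        """Residues of 0-based column ``j``, in record order."""
        return "".join(seq[j] for _, seq in self.records)

    def take(self, column_indices: Sequence[int]) -> "Alignment":
        """New alignment keeping only the 0-based columns given, in order."""
        return Alignment(
            tuple(
                (rid, "".join(seq[j] for j in column_indices))
                for rid, seq in self.records
            )
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA; all sequences must share one length."""
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return Alignment(tuple((e.id, str(e.seq)) for e in entries))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    entries = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    SeqIO.write(entries, str(path), "fasta")


@dataclass(frozen=True)
class ConsensusAnnotation:
    """Per-column consensus symbols: 'high', 'low' or 'none'."""

    symbols: tuple[str, ...]
    high_level: float
    low_level: float

    def __post_init__(self) -> None:
        if not (self.high_level > self.low_level > 0):
            raise ValueError("need high_level > low_level > 0")
        if any(s not in ("high", "low", "none") for s in self.symbols):
            raise ValueError("symbols must be 'high', 'low' or 'none'")


def consensus_annotation(
    aln: Alignment, high_level: float = 0.90, low_level: float = 0.50
) -> ConsensusAnnotation:
    """Two-level consensus over the non-gap residues of each column.

    The modal residue's frequency f (denominator: non-gap entries; ties broken
    toward the alphabetically smallest residue) maps to 'high' when
    f >= high_level, 'low' when low_level <= f < high_level, else 'none'.
    All-gap columns are 'none'.
    """
    symbols = []
    for j in range(aln.n_sites):
        col = [ch for ch in aln.column(j) if ch != GAP]
        if not col:
            symbols.append("none")
            continue
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        f = counts[best] / len(col)
        if f >= high_level:
            symbols.append("high")
        elif f >= low_level:
            symbols.append("low")
        else:
            symbols.append("none")
    return ConsensusAnnotation(tuple(symbols), high_level, low_level)


def write_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a TSV report: one header line, rows in input order.

    ``columns`` is required when ``rows`` is empty; otherwise it defaults to
    the key order of the first row.
    """
    if columns is None:
        if not rows:
            raise ValueError("columns required to write an empty report")
        columns = list(rows[0].keys())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in columns})


def read_report(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV report written by :func:`write_report`."""
    with open(path, newline="", encoding="utf-8") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]
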