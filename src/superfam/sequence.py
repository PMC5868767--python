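"""Sequence and family data model.

Protein records, TCDB-style identifiers, FASTA I/O and the seeded
composition-preserving shuffle that underlies every shuffle-calibrated
statistic in the package.

Coordinate convention: all in-memory coordinates are 0-based, half-open.
File outputs and reports use 1-based inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted at parse time. ``X`` (unknown) is allowed and flagged;
#: ambiguity codes B/Z/U/O are rejected because hydropathy scales are
#: undefined for them.
ALPHABET = frozenset(CANONICAL_AA + "X")

GAP = "-"

_TCDB_RE = re.compile(r"^(\d+)\.([A-Z])\.(\d+)\.(\d+)\.(\d+)$")


class SequenceError(ValueError):
    """Malformed sequence input (illegal residue, duplicate id, ...)."""


@dataclass(frozen=True)
class TcdbId:
    """A five-component transporter-classification identifier, e.g. 1.A.17.5.10.

    The first four components (class, subclass, family, subfamily) define the
    family prefix. Prefix comparison is component-wise, never substring based,
    so 1.A.17.1 does not match members of 1.A.17.10.
    """

    class_: str
    subclass: str
    family: str
    subfamily: str
    system: str

    @classmethod
    def parse(cls, text: str) -> "TcdbId":
        m = _TCDB_RE.match(text)
        if m is None:
            raise SequenceError(f"not a TCDB identifier: {text!r}")
        return cls(*m.groups())

    @classmethod
    def try_parse(cls, text: str) -> "TcdbId | None":
        m = _TCDB_RE.match(text)
        return cls(*m.groups()) if m else None

    @property
    def family_prefix(self) -> str:
        return ".".join((self.class_, self.subclass, self.family, self.subfamily))

    def in_family(self, prefix: str) -> bool:
        """Component-wise family-prefix match against e.g. ``"1.A.17.5"``."""
        return self.family_prefix.split(".") == prefix.split(".")

    def __str__(self) -> str:
        return ".".join(
            (self.class_, self.subclass, self.family, self.subfamily, self.system)
        )


@dataclass
class ProteinRecord:
    """One protein sequence with optional family label.

    ``seq`` is uppercase over the 20-letter alphabet plus ``X``; anything else
    is rejected at construction time.
    """

    id: str
    seq: str
    family: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        for pos, ch in enumerate(self.seq):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at position "
                    f"{pos + 1}"
                )
        if self.family is None:
            tc = TcdbId.try_parse(self.id)
            if tc is not None:
                self.family = tc.family_prefix

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_unknown_residues(self) -> bool:
        return "X" in self.seq


@dataclass
class FamilySet:
    """An ordered set of proteins sharing one family label."""

    label: str
    members: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate member ids in family {self.label!r}: {dupes}")
        for m in self.members:
            tc = TcdbId.try_parse(m.id)
            if tc is not None and not tc.in_family(self.label):
                raise SequenceError(
                    f"member {m.id!r} does not belong to family {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Ids are the first whitespace-delimited header token; the family label is
    inferred when the id is TCDB-structured. Duplicate ids and residues
    outside the alphabet are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, seq=str(rec.seq), description=desc))
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise SequenceError(f"duplicate ids in {path}: {dupes}")
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as multi-line FASTA; inverse of :func:`read_fasta`."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


def shuffle_sequence(seq: str, seed: int) -> str:
    """Return a uniformly random permutation of the residues of ``seq``.

    Composition-preserving Fisher–Yates shuffle; identical ``(seq, seed)``
    pairs give identical output. Seeds are always explicit — no global state.
    """
    if not seq:
        raise SequenceError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return rng.permutation(chars).tobytes().decode("ascii")


@dataclass
class Msa:
    """A rectangular multiple sequence alignment (rows may contain ``-``)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows differ in length")
        if not self.rows:
            raise SequenceError("empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise SequenceError("alignment is not rectangular")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, ref_id: str) -> str:
        try:
            return self.rows[self.ids.index(ref_id)]
        except ValueError:
            raise SequenceError(f"id {ref_id!r} not in alignment") from None

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord]) -> "Msa":
        raise TypeError("use Msa.read / Msa(ids, rows); records disallow gaps")

    @classmethod
    def read(cls, path: str | Path) -> "Msa":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        msa = cls(ids, rows)
        for rid, row in zip(ids, rows):
            bad = set(row) - ALPHABET - {GAP}
            if bad:
                raise SequenceError(f"row {rid!r}: illegal characters {sorted(bad)}")
        return msa

    def write(self, path: str | Path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), line_width):
                    fh.write(row[i : i + line_width] + "\n")
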