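"""Reading, validating and writing protein sequences and annotation tables.

This module is the boundary between standard file formats (FASTA, TSV) and
the in-memory data model used by the rest of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in the fixed alphabet order used throughout.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Validation policies for non-canonical residues.
POLICIES = ("reject", "drop_residue")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty record, missing header)."""


class AnnotationParseError(ValueError):
    """Raised for malformed annotation tables."""


class ValidationError(ValueError):
    """Raised when a sequence fails residue validation."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with identity metadata.

    Parameters
    ----------
    id:
        Unique identifier (FASTA header token before the first whitespace).
    residues:
        Amino-acid string; canonical after :func:`validate_sequence`.
    description:
        Free text (rest of the FASTA header).
    name:
        Optional protein name, used for grouping same-named proteins of
        different species origin.
    species:
        Optional species tag.
    """

    id: str
    residues: str
    description: str = ""
    name: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinSequence.id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def group_name(self) -> str:
        """Name used for same-name grouping; falls back to the id."""
        return self.name if self.name is not None else self.id


@dataclass(frozen=True)
class FamilyAnnotation:
    """A (protein_id, family_id) membership pair."""

    protein_id: str
    family_id: str


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    The header token before the first whitespace becomes the id, the
    remainder the description. Records appear in file order.

    Raises
    ------
    FastaParseError
        If a record has an empty sequence or sequence data precedes the
        first header; the error message names the offending line.
    """
    path = Path(path)
    _scan_fasta_structure(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if rec.id in seen:
            raise FastaParseError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        name, species, desc = _parse_metadata_tokens(desc)
        out.append(
            ProteinSequence(
                id=rec.id,
                residues=str(rec.seq),
                description=desc,
                name=name,
                species=species,
            )
        )
    return out


def _parse_metadata_tokens(description: str) -> tuple[str | None, str | None, str]:
    """Extract leading ``name=``/``species=`` tokens from a FASTA description."""
    name = species = None
    rest: list[str] = []
    for token in description.split():
        if token.startswith("name=") and name is None:
            name = token[len("name="):]
        elif token.startswith("species=") and species is None:
            species = token[len("species="):]
        else:
            rest.append(token)
    return name, species, " ".join(rest)


def _scan_fasta_structure(path: Path) -> None:
    """Cheap structural pre-scan so parse errors can name a line number."""
    header_line: int | None = None
    have_residues = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not have_residues:
                    raise FastaParseError(
                        f"{path}:{header_line}: record has an empty sequence"
                    )
                if stripped == ">":
                    raise FastaParseError(f"{path}:{lineno}: record has no header token")
                header_line = lineno
                have_residues = False
            else:
                if header_line is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                have_residues = True
    if header_line is not None and not have_residues:
        raise FastaParseError(f"{path}:{header_line}: record has an empty sequence")


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-record FASTA (line-wrapped at ``width``).

    Name and species metadata are serialized as ``name=``/``species=``
    description tokens so that :func:`read_fasta` round-trips them.
    """
    records = []
    for s in sequences:
        parts = []
        if s.name is not None:
            parts.append(f"name={s.name}")
        if s.species is not None:
            parts.append(f"species={s.species}")
        if s.description:
            parts.append(s.description)
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=" ".join(parts)))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def validate_sequence(seq: ProteinSequence, policy: str = "drop_residue") -> ProteinSequence:
    """Validate (and optionally clean) a sequence against the canonical alphabet.

    Lowercase residues are uppercased first. Under ``reject``, any
    non-canonical character (B, Z, X, U, O, ``*``, gaps, ...) raises
    :class:`ValidationError`; under ``drop_residue`` such characters are
    removed with a logged count.

    The operation is idempotent: validating an already-valid sequence
    returns it unchanged.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    residues = seq.residues.upper()
    if policy == "reject":
        bad = sorted({c for c in residues if c not in _CANONICAL_SET})
        if bad:
            raise ValidationError(
                f"sequence {seq.id!r} contains non-canonical residues {''.join(bad)!r}"
            )
    else:
        cleaned = "".join(c for c in residues if c in _CANONICAL_SET)
        n_dropped = len(residues) - len(cleaned)
        if n_dropped:
            logger.warning(
                "sequence %s: dropped %d non-canonical residue(s)", seq.id, n_dropped
            )
        residues = cleaned
    if not residues:
        raise ValidationError(f"sequence {seq.id!r} is empty after cleaning")
    if residues == seq.residues:
        return seq
    return replace(seq, residues=residues)


def read_annotations(path: str | Path) -> list[FamilyAnnotation]:
    """Read a two-column TSV (protein_id, family_id) into annotations.

    A header row ``protein_id<TAB>family_id`` is optional. Duplicate rows
    are collapsed (order of first appearance kept) with a logged count.

    Raises
    ------
    AnnotationParseError
        On a row with a missing column; the message names the row number.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {stripped!r}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    if pairs and pairs[0] == ("protein_id", "family_id"):
        pairs = pairs[1:]
    seen: set[tuple[str, str]] = set()
    out: list[FamilyAnnotation] = []
    for pair in pairs:
        if pair in seen:
            continue
        seen.add(pair)
        out.append(FamilyAnnotation(*pair))
    n_dup = len(pairs) - len(out)
    if n_dup:
        logger.info("collapsed %d duplicate annotation row(s) from %s", n_dup, path)
    return out


def write_annotations(annotations: Iterable[FamilyAnnotation], path: str | Path) -> None:
    """Write annotations as a headered two-column TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_id\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.family_id}\n")


def check_unique_ids(sequences: Sequence[ProteinSequence]) -> None:
    """Raise ValueError if any id occurs more than once."""
    seen: set[str] = set()
    for s in sequences:
        if s.id in seen:
            raise ValueError(f"duplicate protein id {s.id!r} in collection")
        seen.add(s.id)
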