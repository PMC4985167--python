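"""Per-family dataset construction: positive grouping and splitting,
domain-family-based negative sampling, and cross-split deduplication.

The protocol mirrors the staged construction used by the classifiers:
same-named proteins of different species origin are grouped, group members
are distributed round-robin over the train/test/independent partitions,
negatives are drawn from domain families that contain no positive member
(three representatives per family, one per partition), and exact duplicate
sequences are removed within and across partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import FamilyAnnotation, ProteinSequence

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "test", "independent")


@dataclass
class DatasetSplit:
    """Positive/negative protein ids assigned to the three partitions."""

    family_id: str
    positives: dict[str, list[str]] = field(
        default_factory=lambda: {p: [] for p in PARTITIONS}
    )
    negatives: dict[str, list[str]] = field(
        default_factory=lambda: {p: [] for p in PARTITIONS}
    )
    negative_provenance: dict[str, str] = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        out: list[str] = []
        for part in PARTITIONS:
            out.extend(self.positives[part])
            out.extend(self.negatives[part])
        return out

    def validate(self) -> None:
        ids = self.all_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("a protein id appears more than once in the split")
        pos = {i for p in PARTITIONS for i in self.positives[p]}
        neg = {i for p in PARTITIONS for i in self.negatives[p]}
        if pos & neg:
            raise ValueError("a protein id is both positive and negative")
        missing = neg - set(self.negative_provenance)
        if missing:
            raise ValueError(f"negatives without provenance: {sorted(missing)[:5]}")


def group_members(positives: Sequence[ProteinSequence]) -> list[list[ProteinSequence]]:
    """Group same-named proteins (different species origin) together.

    Returns groups ordered lexicographically by group name; a protein
    without a name falls back to its id.
    """
    by_name: dict[str, list[ProteinSequence]] = {}
    for seq in positives:
        by_name.setdefault(seq.group_name, []).append(seq)
    return [by_name[name] for name in sorted(by_name)]


def assign_positive_splits(
    groups: Sequence[Sequence[ProteinSequence]], seed: int
) -> dict[str, list[str]]:
    """Distribute each group's members round-robin over the partitions.

    Members are shuffled within each group with the seed, then assigned
    cycling train -> test -> independent (the cycle restarts at train for
    every group), so per-group partition sizes differ by at most one.
    """
    total = sum(len(g) for g in groups)
    if total < 3:
        raise ValueError(
            f"need at least 3 positive members to populate three partitions, got {total}"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {p: [] for p in PARTITIONS}
    for group in groups:
        ids = [s.id for s in group]
        order = rng.permutation(len(ids))
        for slot, j in enumerate(order):
            out[PARTITIONS[slot % 3]].append(ids[j])
    return out


def sample_negatives(
    positive_ids: Iterable[str],
    domain_map: Sequence[FamilyAnnotation],
    all_protein_ids: Iterable[str],
    per_family: int = 3,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Sample negatives from domain families containing no positive member.

    Domain families with at least one positive are excluded entirely; from
    every remaining family min(per_family, size) members are drawn
    uniformly without replacement and distributed one per partition,
    cycling train -> test -> independent. Returns (partitions, provenance).
    """
    positive_ids = set(positive_ids)
    available = set(all_protein_ids)
    families: dict[str, list[str]] = {}
    for ann in domain_map:
        if ann.protein_id in available:
            families.setdefault(ann.family_id, []).append(ann.protein_id)
    negative_families = {
        fam: members
        for fam, members in families.items()
        if not (set(members) & positive_ids)
    }
    if not negative_families:
        raise ValueError("no negative domain families available for sampling")
    rng = np.random.default_rng(seed)
    partitions: dict[str, list[str]] = {p: [] for p in PARTITIONS}
    provenance: dict[str, str] = {}
    for fam in sorted(negative_families):
        members = sorted(negative_families[fam])
        n_take = min(per_family, len(members))
        chosen = rng.choice(len(members), size=n_take, replace=False)
        for slot, j in enumerate(chosen):
            pid = members[j]
            if pid in provenance:  # protein already sampled via another domain
                continue
            partitions[PARTITIONS[slot % 3]].append(pid)
            provenance[pid] = fam
    return partitions, provenance


def deduplicate(
    split: DatasetSplit, sequences: Mapping[str, ProteinSequence]
) -> DatasetSplit:
    """Remove proteins with identical residue strings within and across partitions.

    When duplicates span partitions, the copy in the highest-priority
    partition (train > test > independent) is kept; within a partition the
    first-listed copy wins (positives before negatives). Removal counts are
    logged.
    """
    seen: set[str] = set()
    out = DatasetSplit(family_id=split.family_id)
    n_removed = 0
    for part in PARTITIONS:  # priority order
        for kind in ("positives", "negatives"):
            src = getattr(split, kind)[part]
            dst = getattr(out, kind)[part]
            for pid in src:
                residues = sequences[pid].residues
                if residues in seen:
                    n_removed += 1
                    continue
                seen.add(residues)
                dst.append(pid)
                if kind == "negatives":
                    out.negative_provenance[pid] = split.negative_provenance[pid]
    if n_removed:
        logger.info(
            "deduplicate: removed %d duplicate protein(s) from family %s",
            n_removed,
            split.family_id,
        )
    return out


def build_family_split(
    family_id: str,
    sequences: Sequence[ProteinSequence],
    family_annotations: Sequence[FamilyAnnotation],
    domain_annotations: Sequence[FamilyAnnotation],
    per_family: int = 3,
    seed: int = 0,
) -> DatasetSplit:
    """End-to-end split construction for one functional family."""
    by_id = {s.id: s for s in sequences}
    positive_ids = [
        a.protein_id
        for a in family_annotations
        if a.family_id == family_id and a.protein_id in by_id
    ]
    if not positive_ids:
        raise ValueError(f"no positive members found for family {family_id!r}")
    positives = [by_id[i] for i in positive_ids]
    groups = group_members(positives)
    pos_parts = assign_positive_splits(groups, seed=seed)
    neg_parts, provenance = sample_negatives(
        positive_ids,
        domain_annotations,
        by_id.keys(),
        per_family=per_family,
        seed=seed,
    )
    split = DatasetSplit(
        family_id=family_id,
        positives=pos_parts,
        negatives=neg_parts,
        negative_provenance=provenance,
    )
    split = deduplicate(split, by_id)
    split.validate()
    return split


def write_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Write the split as a TSV: protein_id, partition, label, provenance_family."""
    with open(path, "w") as fh:
        fh.write("protein_id\tpartition\tlabel\tprovenance_family\n")
        for part in PARTITIONS:
            for pid in split.positives[part]:
                fh.write(f"{pid}\t{part}\tpos\t-\n")
            for pid in split.negatives[part]:
                fh.write(f"{pid}\t{part}\tneg\t{split.negative_provenance[pid]}\n")


def read_manifest(path: str | Path, family_id: str = "") -> DatasetSplit:
    """Read a split manifest written by :func:`write_manifest`."""
    split = DatasetSplit(family_id=family_id)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: missing manifest header")
        for line in fh:
            if not line.strip():
                continue
            pid, part, label, prov = line.rstrip("\n").split("\t")
            if part not in PARTITIONS:
                raise ValueError(f"{path}: unknown partition {part!r}")
            if label == "pos":
                split.positives[part].append(pid)
            else:
                split.negatives[part].append(pid)
                split.negative_provenance[pid] = prov
    return split
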