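"""Synthetic protein families with controllable physicochemical separation.

Sequences are sampled residue-by-residue: with probability ``noise`` a
residue is drawn uniformly from the 20 canonical amino acids, otherwise a
class is drawn from the profile's class bias over a designated anchor
grouping and an amino acid is drawn uniformly within that class. Family
members therefore share a composition signature under the anchor property
that downstream descriptor/classifier stages can learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .descriptors import PropertyGrouping, load_groupings
from .sequence_io import CANONICAL_AA, FamilyAnnotation, ProteinSequence


@dataclass(frozen=True)
class FamilyProfile:
    """Sampling profile for one synthetic family.

    ``class_bias`` is a probability triple over the three classes of
    ``anchor_property``; ``noise`` is the per-residue probability of
    ignoring the bias and drawing uniformly.
    """

    family_id: str
    class_bias: tuple[float, float, float]
    anchor_property: str = "hydrophobicity"
    length_range: tuple[int, int] = (50, 120)
    noise: float = 0.1

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        bias = np.asarray(self.class_bias, dtype=float)
        if bias.shape != (3,) or np.any(bias < 0) or not np.isclose(bias.sum(), 1.0):
            raise ValueError("class_bias must be a probability triple summing to 1")
        lo, hi = self.length_range
        if lo < 30 or lo > hi:
            raise ValueError("length_range must satisfy 30 <= min <= max")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")


def _class_alphabets(grouping: PropertyGrouping) -> list[str]:
    return [
        "".join(aa for aa in CANONICAL_AA if grouping.class_of[aa] == c)
        for c in (1, 2, 3)
    ]


def generate_family(
    profile: FamilyProfile,
    n: int,
    seed: int,
    groupings: Mapping[str, PropertyGrouping] | None = None,
) -> list[ProteinSequence]:
    """Generate ``n`` member sequences of a profile, reproducibly by seed.

    Every third member shares a name (species varies) so that the
    same-name grouping step of dataset construction has non-trivial groups.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    groupings = load_groupings() if groupings is None else groupings
    grouping = groupings[profile.anchor_property]
    alphabets = _class_alphabets(grouping)
    rng = np.random.default_rng(seed)
    bias = np.asarray(profile.class_bias, dtype=float)
    lo, hi = profile.length_range
    out: list[ProteinSequence] = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        residues = []
        for _ in range(L):
            if rng.random() < profile.noise:
                residues.append(CANONICAL_AA[rng.integers(20)])
            else:
                cls = rng.choice(3, p=bias)
                alpha = alphabets[cls]
                residues.append(alpha[rng.integers(len(alpha))])
        out.append(
            ProteinSequence(
                id=f"{profile.family_id}_{i:04d}",
                residues="".join(residues),
                name=f"{profile.family_id}_p{i // 3}",
                species=f"sp{i % 3}",
                description=f"synthetic member of {profile.family_id}",
            )
        )
    return out


def default_benchmark_profiles(noise: float = 0.1) -> list[FamilyProfile]:
    """One member profile plus four background profiles with distinct biases."""
    return [
        FamilyProfile("memberfam", (0.85, 0.10, 0.05), noise=noise),
        FamilyProfile("bgfam1", (0.05, 0.85, 0.10), noise=noise),
        FamilyProfile("bgfam2", (0.05, 0.10, 0.85), noise=noise),
        FamilyProfile("bgfam3", (0.10, 0.60, 0.30), noise=noise),
        FamilyProfile("bgfam4", (0.10, 0.30, 0.60), noise=noise),
    ]


def generate_benchmark(
    profiles: Sequence[FamilyProfile],
    n_pos: int,
    n_neg: int,
    seed: int,
    groupings: Mapping[str, PropertyGrouping] | None = None,
    domain_chunk: int = 3,
) -> tuple[list[ProteinSequence], list[FamilyAnnotation], list[FamilyAnnotation]]:
    """Generate a labelled benchmark: members, background, and annotations.

    Returns (sequences, functional-family annotations, domain-family
    annotations). ``n_pos`` members come from the first profile; ``n_neg``
    background proteins are apportioned round-robin over the remaining
    profiles. Synthetic domain families are assigned in chunks of
    ``domain_chunk`` consecutive proteins per source family so that
    negative sampling (3 representatives per domain family) can use the
    whole background set.
    """
    if len(profiles) < 2:
        raise ValueError("need a member profile and at least one background profile")
    groupings = load_groupings() if groupings is None else groupings
    member, *background = profiles
    rng = np.random.default_rng(seed)
    sequences = generate_family(member, n_pos, int(rng.integers(2**31)), groupings)
    counts = [n_neg // len(background)] * len(background)
    for i in range(n_neg - sum(counts)):
        counts[i] += 1
    for prof, cnt in zip(background, counts):
        if cnt:
            sequences.extend(generate_family(prof, cnt, int(rng.integers(2**31)), groupings))

    family_annotations = [
        FamilyAnnotation(s.id, member.family_id)
        for s in sequences[:n_pos]
    ]
    # synthetic domain families: chunks of consecutive proteins per source family
    domain_annotations: list[FamilyAnnotation] = []
    by_source: dict[str, list[str]] = {}
    for s in sequences:
        by_source.setdefault(s.id.rsplit("_", 1)[0], []).append(s.id)
    for source, ids in by_source.items():
        for chunk_i in range(0, len(ids), domain_chunk):
            dom = f"dom_{source}_{chunk_i // domain_chunk:03d}"
            for pid in ids[chunk_i : chunk_i + domain_chunk]:
                domain_annotations.append(FamilyAnnotation(pid, dom))
    return sequences, family_annotations, domain_annotations


def write_benchmark_manifest(
    profiles: Sequence[FamilyProfile], n_pos: int, n_neg: int, seed: int, path: str | Path
) -> None:
    """Record the generating profiles and seed as JSON."""
    payload = {
        "seed": seed,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "profiles": [
            {
                "family_id": p.family_id,
                "class_bias": list(p.class_bias),
                "anchor_property": p.anchor_property,
                "length_range": list(p.length_range),
                "noise": p.noise,
            }
            for p in profiles
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
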