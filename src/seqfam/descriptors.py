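"""Sequence-derived structural and physicochemical descriptors.

Implements the protein representation used by the family classifiers:
amino-acid composition, composition/transition/distribution (CTD) encodings
under three-class physicochemical groupings, Moreau-Broto autocorrelation of
amino-acid indices, and pseudo-amino-acid composition, concatenated into a
fixed-layout feature vector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import CANONICAL_AA, ProteinSequence

#: Order of unordered class pairs in the transition block.
CLASS_PAIRS = ((1, 2), (1, 3), (2, 3))

#: Quantile fractions for the distribution block.
_D_FRACTIONS = (0.25, 0.50, 0.75)

#: Default grouped properties, in feature-layout order.
DEFAULT_PROPERTIES = (
    "polarity",
    "hydrophobicity",
    "surface_tension",
    "charge",
    "normalized_vdw_volume",
    "polarizability",
    "secondary_structure",
    "solvent_accessibility",
    "molecular_weight",
    "solubility",
    "hbond_donors",
    "hbond_acceptors",
)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class PropertyGrouping:
    """Three-class partition of the 20 amino acids for one property."""

    property_name: str
    class_of: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.class_of)
        if missing:
            raise ValueError(
                f"grouping {self.property_name!r} misses amino acids {sorted(missing)}"
            )
        used = set(self.class_of.values())
        if not used <= {1, 2, 3}:
            raise ValueError(f"grouping {self.property_name!r} has class indices outside 1..3")
        if used != {1, 2, 3}:
            raise ValueError(f"grouping {self.property_name!r} leaves a class empty")

    def class_array(self) -> np.ndarray:
        """Class index (1..3) per amino acid in canonical alphabet order."""
        return np.array([self.class_of[aa] for aa in CANONICAL_AA], dtype=np.int8)


@dataclass(frozen=True)
class PropertyScale:
    """Real-valued amino-acid index for one property."""

    property_name: str
    value_of: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.value_of)
        if missing:
            raise ValueError(
                f"scale {self.property_name!r} misses amino acids {sorted(missing)}"
            )
        vals = np.array([self.value_of[aa] for aa in CANONICAL_AA], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"scale {self.property_name!r} has non-finite values")

    def values(self) -> np.ndarray:
        return np.array([self.value_of[aa] for aa in CANONICAL_AA], dtype=float)

    def normalized_values(self) -> np.ndarray:
        """Zero-mean, unit-standard-deviation values over the 20 amino acids."""
        v = self.values()
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd


@dataclass(frozen=True)
class CTDDescriptor:
    """C/T/D encoding of one sequence under one three-class grouping."""

    property_name: str
    C: tuple[float, float, float]
    T: tuple[float, float, float]
    D: tuple[float, ...]  # 15 values, class-major: 5 quantiles x 3 classes

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.C, self.T, self.D])

    def __len__(self) -> int:
        return 21


# ---------------------------------------------------------------------------
# packaged property tables


def _data_path(name: str) -> Path:
    return Path(str(resources.files("seqfam").joinpath("data", name)))


def load_groupings(path: str | Path | None = None) -> dict[str, PropertyGrouping]:
    """Load property groupings from a TSV (packaged table by default).

    Columns: property_name, amino_acid, class_index.
    """
    path = _data_path("property_groupings.tsv") if path is None else Path(path)
    table: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("property_name"):
            raise ValueError(f"{path}: expected header starting with 'property_name'")
        for line in fh:
            if not line.strip():
                continue
            prop, aa, cls = line.rstrip("\n").split("\t")
            table.setdefault(prop, {})[aa] = int(cls)
    return {name: PropertyGrouping(name, mapping) for name, mapping in table.items()}


def load_scales(path: str | Path | None = None) -> dict[str, PropertyScale]:
    """Load property scales from a TSV (packaged table by default).

    Columns: property_name, amino_acid, value.
    """
    path = _data_path("property_scales.tsv") if path is None else Path(path)
    table: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("property_name"):
            raise ValueError(f"{path}: expected header starting with 'property_name'")
        for line in fh:
            if not line.strip():
                continue
            prop, aa, value = line.rstrip("\n").split("\t")
            table.setdefault(prop, {})[aa] = float(value)
    return {name: PropertyScale(name, mapping) for name, mapping in table.items()}


# ---------------------------------------------------------------------------
# elementary descriptors


def _residue_indices(seq: ProteinSequence) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq.residues], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"sequence {seq.id!r} contains non-canonical residue {exc.args[0]!r}; "
            "validate it first"
        ) from None


def aa_composition(seq: ProteinSequence) -> np.ndarray:
    """Fraction of each of the 20 amino acids, in ``CANONICAL_AA`` order."""
    idx = _residue_indices(seq)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(idx)


def _classes(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    return grouping.class_array()[_residue_indices(seq)]


def ctd_composition(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Class fractions: count of residues in each class divided by length."""
    cls = _classes(seq, grouping)
    counts = np.bincount(cls, minlength=4)[1:4].astype(float)
    return counts / len(cls)


def ctd_transition(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Adjacent class-pair change frequencies for pairs (1,2), (1,3), (2,3).

    Each value is the number of adjacent positions whose classes are the
    pair in either order, divided by L-1. A length-1 sequence yields zeros.
    """
    cls = _classes(seq, grouping)
    if len(cls) < 2:
        return np.zeros(3)
    a, b = cls[:-1], cls[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = np.empty(3)
    for i, (r, s) in enumerate(CLASS_PAIRS):
        out[i] = np.count_nonzero((lo == r) & (hi == s))
    return out / (len(cls) - 1)


def _quantile_positions(n: int) -> tuple[int, ...]:
    """1-based occurrence indices for (first, 25%, 50%, 75%, 100%) of n hits."""
    return (1,) + tuple(max(1, int(np.floor(f * n))) for f in _D_FRACTIONS) + (n,)


def ctd_distribution(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Fractional chain positions of class-occurrence quantiles.

    For each class with n > 0 occurrences the five values are
    pos(k)/L for k in the quantile index rule (1, max(1, floor(0.25 n)),
    max(1, floor(0.50 n)), max(1, floor(0.75 n)), n), where pos(k) is the
    1-based position of the k-th occurrence. Absent classes give five zeros.
    Output is class-major: class 1's quintuple, then class 2's, then class 3's.
    """
    cls = _classes(seq, grouping)
    L = len(cls)
    out = np.zeros(15)
    for j, c in enumerate((1, 2, 3)):
        positions = np.flatnonzero(cls == c) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        for q, k in enumerate(_quantile_positions(n)):
            out[5 * j + q] = positions[k - 1] / L
    return out


def ctd(seq: ProteinSequence, grouping: PropertyGrouping) -> CTDDescriptor:
    """Full 21-element C/T/D descriptor for one grouped property."""
    return CTDDescriptor(
        property_name=grouping.property_name,
        C=tuple(ctd_composition(seq, grouping)),
        T=tuple(ctd_transition(seq, grouping)),
        D=tuple(ctd_distribution(seq, grouping)),
    )


def moreau_broto(seq: ProteinSequence, scale: PropertyScale, max_lag: int = 30) -> np.ndarray:
    """Normalized Moreau-Broto autocorrelation for lags 1..max_lag.

    AC(d) = (1/(L-d)) * sum_i p(i) p(i+d) with p the zero-mean,
    unit-variance normalization of the scale over the 20 amino acids.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    L = len(seq)
    if max_lag >= L:
        raise ValueError(
            f"max_lag={max_lag} must be smaller than sequence length {L}; "
            "use a smaller lag or a longer sequence"
        )
    p = scale.normalized_values()[_residue_indices(seq)]
    out = np.empty(max_lag)
    for d in range(1, max_lag + 1):
        out[d - 1] = np.dot(p[:-d], p[d:]) / (L - d)
    return out


def pseaac(
    seq: ProteinSequence,
    scales: Sequence[PropertyScale],
    lam: int = 10,
    w: float = 0.05,
) -> np.ndarray:
    """Pseudo-amino-acid composition (classic form), 20 + lam components.

    The first 20 components are f_a / (sum(f) + w * sum(theta)); the next
    lam are w * theta_k / (sum(f) + w * sum(theta)). theta_k is the mean
    over positions i of the averaged squared normalized-scale difference
    between residues i and i+k across the supplied scales. Components sum
    to 1.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    L = len(seq)
    if lam >= L:
        raise ValueError(f"lam={lam} must be smaller than sequence length {L}")
    if lam > 0 and not scales:
        raise ValueError("at least one scale is required when lam > 0")
    f = aa_composition(seq)
    theta = np.zeros(lam)
    if lam > 0:
        idx = _residue_indices(seq)
        norm = np.stack([s.normalized_values() for s in scales])  # (S, 20)
        p = norm[:, idx]  # (S, L)
        for k in range(1, lam + 1):
            diffs = (p[:, :-k] - p[:, k:]) ** 2  # (S, L-k)
            theta[k - 1] = diffs.mean(axis=0).mean()
    denom = f.sum() + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


# ---------------------------------------------------------------------------
# feature-vector assembly


@dataclass(frozen=True)
class FeatureVector:
    """A concatenated descriptor vector with block provenance."""

    values: np.ndarray
    blocks: tuple[tuple[str, int, int], ...]  # (block_name, start, length)
    config_digest: str

    def __post_init__(self) -> None:
        pos = 0
        for name, start, length in self.blocks:
            if start != pos:
                raise ValueError(f"block {name!r} starts at {start}, expected {pos}")
            pos += length
        if pos != len(self.values):
            raise ValueError(f"blocks cover {pos} values, array has {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def block(self, name: str) -> np.ndarray:
        for bname, start, length in self.blocks:
            if bname == name:
                return self.values[start : start + length]
        raise KeyError(name)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for bname, _, length in self.blocks:
            names.extend(f"{bname}[{i}]" for i in range(length))
        return names


@dataclass(frozen=True)
class DescriptorConfig:
    """Which descriptor blocks to compute, and with what parameters.

    The default layout is the 20-dim amino-acid composition plus one
    21-element CTD block per grouped property (12 properties -> 272 dims).
    Autocorrelation and pseudo-amino-acid composition blocks are opt-in.
    """

    include_aac: bool = True
    properties: tuple[str, ...] = DEFAULT_PROPERTIES
    autocorr_scales: tuple[str, ...] = ()
    max_lag: int = 30
    include_pseaac: bool = False
    pseaac_scales: tuple[str, ...] = ("hydrophobicity_kd", "hydrophilicity_hw", "residue_mass")
    lam: int = 10
    w: float = 0.05

    def dimension(self) -> int:
        dim = 20 if self.include_aac else 0
        dim += 21 * len(self.properties)
        dim += self.max_lag * len(self.autocorr_scales)
        if self.include_pseaac:
            dim += 20 + self.lam
        return dim

    def min_length(self) -> int:
        """Minimum sequence length accepted by :func:`featurize`."""
        need = 2 if self.properties else 1
        if self.autocorr_scales:
            need = max(need, self.max_lag + 1)
        if self.include_pseaac:
            need = max(need, self.lam + 1)
        return need

    def digest(
        self,
        groupings: Mapping[str, PropertyGrouping],
        scales: Mapping[str, PropertyScale],
    ) -> str:
        """Digest of the configuration *and* the table contents it uses."""
        payload = {
            "include_aac": self.include_aac,
            "properties": [
                [p, [groupings[p].class_of[aa] for aa in CANONICAL_AA]]
                for p in self.properties
            ],
            "autocorr_scales": [
                [s, [scales[s].value_of[aa] for aa in CANONICAL_AA]]
                for s in self.autocorr_scales
            ],
            "max_lag": self.max_lag,
            "include_pseaac": self.include_pseaac,
            "pseaac_scales": [
                [s, [scales[s].value_of[aa] for aa in CANONICAL_AA]]
                for s in (self.pseaac_scales if self.include_pseaac else ())
            ],
            "lam": self.lam,
            "w": self.w,
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "include_aac": self.include_aac,
            "properties": list(self.properties),
            "autocorr_scales": list(self.autocorr_scales),
            "max_lag": self.max_lag,
            "include_pseaac": self.include_pseaac,
            "pseaac_scales": list(self.pseaac_scales),
            "lam": self.lam,
            "w": self.w,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DescriptorConfig":
        return cls(
            include_aac=bool(d.get("include_aac", True)),
            properties=tuple(d.get("properties", DEFAULT_PROPERTIES)),
            autocorr_scales=tuple(d.get("autocorr_scales", ())),
            max_lag=int(d.get("max_lag", 30)),
            include_pseaac=bool(d.get("include_pseaac", False)),
            pseaac_scales=tuple(
                d.get("pseaac_scales", ("hydrophobicity_kd", "hydrophilicity_hw", "residue_mass"))
            ),
            lam=int(d.get("lam", 10)),
            w=float(d.get("w", 0.05)),
        )


def featurize(
    seq: ProteinSequence,
    config: DescriptorConfig = DescriptorConfig(),
    groupings: Mapping[str, PropertyGrouping] | None = None,
    scales: Mapping[str, PropertyScale] | None = None,
) -> FeatureVector:
    """Assemble the configured descriptor blocks into one feature vector.

    Deterministic and pure: the same sequence and configuration always
    produce a bitwise-identical vector.
    """
    groupings = load_groupings() if groupings is None else groupings
    scales = load_scales() if scales is None else scales
    L = len(seq)
    parts: list[np.ndarray] = []
    blocks: list[tuple[str, int, int]] = []
    pos = 0

    def add(name: str, arr: np.ndarray) -> None:
        nonlocal pos
        parts.append(arr)
        blocks.append((name, pos, len(arr)))
        pos += len(arr)

    if config.include_aac:
        add("aac", aa_composition(seq))
    for prop in config.properties:
        if L < 2:
            raise ValueError(
                f"block ctd:{prop} requires sequence length >= 2, got {L}"
            )
        add(f"ctd:{prop}", ctd(seq, groupings[prop]).to_array())
    for sname in config.autocorr_scales:
        if L <= config.max_lag:
            raise ValueError(
                f"block autocorr:{sname} requires sequence length > max_lag="
                f"{config.max_lag}, got {L}"
            )
        add(f"autocorr:{sname}", moreau_broto(seq, scales[sname], config.max_lag))
    if config.include_pseaac:
        if L <= config.lam:
            raise ValueError(
                f"block pseaac requires sequence length > lam={config.lam}, got {L}"
            )
        add(
            "pseaac",
            pseaac(seq, [scales[s] for s in config.pseaac_scales], config.lam, config.w),
        )
    values = np.concatenate(parts) if parts else np.empty(0)
    return FeatureVector(
        values=values,
        blocks=tuple(blocks),
        config_digest=config.digest(groupings, scales),
    )


def feature_matrix(
    sequences: Sequence[ProteinSequence],
    config: DescriptorConfig = DescriptorConfig(),
    groupings: Mapping[str, PropertyGrouping] | None = None,
    scales: Mapping[str, PropertyScale] | None = None,
) -> np.ndarray:
    """Stack featurized sequences into an (n, dim) matrix."""
    groupings = load_groupings() if groupings is None else groupings
    scales = load_scales() if scales is None else scales
    return np.stack(
        [featurize(s, config, groupings, scales).values for s in sequences]
    )
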