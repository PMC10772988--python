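"""Featurization of substrates, enzymes and temperatures.

Substrates arrive as SMILES strings and become molecular graphs (atoms as
vertices, bonds as undirected edges) plus 1024-bit circular (ECFP-style)
fingerprints, both via RDKit.  Enzymes arrive as amino-acid sequences and
become overlapping 3-mer token sequences.  Temperatures (degrees Celsius in
input files) are converted to Kelvin and min-max normalized together with
their reciprocals, mirroring the Arrhenius form k = A*exp(-Ea/RT) in which
1/T is the physically linear covariate of log10(kcat).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

KELVIN_OFFSET = 273.15
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

UNK_TOKEN = "<unk>"


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""


class MutationError(ValueError):
    """Base class for malformed or inconsistent mutation specifications."""


class MutationFormatError(MutationError):
    pass


class MutationMismatchError(MutationError):
    pass


class MutationRangeError(MutationError):
    pass


class TokenVocab:
    """Mutable token -> index map with a dedicated UNK index (0).

    While unfrozen, unseen tokens extend the vocabulary; once frozen (e.g.
    at inference time against a trained checkpoint) unseen tokens map to UNK.
    """

    def __init__(self, mapping: dict[str, int] | None = None, frozen: bool = False):
        self._map: dict[str, int] = {UNK_TOKEN: 0}
        if mapping:
            self._map.update(mapping)
            if self._map[UNK_TOKEN] != 0:
                raise ValueError("UNK token must have index 0")
        self.frozen = frozen

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, token: str) -> bool:
        return token in self._map

    @property
    def unk_index(self) -> int:
        return 0

    def lookup(self, token: str) -> int:
        idx = self._map.get(token)
        if idx is None:
            if self.frozen:
                return self.unk_index
            idx = len(self._map)
            self._map[token] = idx
        return idx

    def freeze(self) -> None:
        self.frozen = True

    def to_dict(self) -> dict[str, int]:
        return dict(self._map)

    @classmethod
    def from_dict(cls, mapping: dict[str, int], frozen: bool = True) -> "TokenVocab":
        return cls(mapping, frozen=frozen)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self._map, fh, indent=1)

    @classmethod
    def load(cls, path, frozen: bool = True) -> "TokenVocab":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh), frozen=frozen)


@dataclass
class CompoundGraph:
    """Molecular graph: per-atom vocabulary tokens, undirected bond edges
    and a 1024-bit circular fingerprint."""

    atom_tokens: list[int]
    edges: list[tuple[int, int]]
    fingerprint: np.ndarray
    n_atoms: int

    def __post_init__(self):
        assert len(self.atom_tokens) == self.n_atoms
        assert self.fingerprint.shape == (1024,)
        for i, j in self.edges:
            assert 0 <= i < self.n_atoms and 0 <= j < self.n_atoms and i != j


@dataclass
class ProteinTokens:
    """Overlapping k-mer token indices of an amino-acid sequence."""

    kmer_tokens: list[int]
    n_kmers: int

    def __post_init__(self):
        assert len(self.kmer_tokens) == self.n_kmers


@dataclass
class ThermoFeatures:
    """Normalized temperature features: min-max scaled T and 1/T (Kelvin)."""

    t_norm: float
    invt_norm: float
    t_kelvin: float


@dataclass
class NormalizationStats:
    """Min-max bounds for T (Kelvin) and 1/T, fitted on training data only."""

    t_min: float
    t_max: float
    invt_min: float
    invt_max: float

    def to_dict(self) -> dict[str, float]:
        return {"t_min": self.t_min, "t_max": self.t_max,
                "invt_min": self.invt_min, "invt_max": self.invt_max}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NormalizationStats":
        return cls(d["t_min"], d["t_max"], d["invt_min"], d["invt_max"])


def _atom_key(atom: Chem.Atom) -> str:
    """Atom token key: element symbol, aromaticity, heavy-atom degree.

    Hydrogens are implicit; the key deliberately ignores charge/chirality to
    keep the vocabulary compact."""
    return f"{atom.GetSymbol()}|{int(atom.GetIsAromatic())}|{atom.GetDegree()}"


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def compute_fingerprint(smiles: str, radius: int = 2, nbits: int = 1024) -> np.ndarray:
    """Circular (Morgan/ECFP) fingerprint of length `nbits` as a 0/1 array."""
    mol = _parse_smiles(smiles)
    if radius == 2 and nbits == 1024:
        gen = _MORGAN
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.float64)


def smiles_to_graph(smiles: str, atom_vocab: TokenVocab,
                    fp_radius: int = 2) -> CompoundGraph:
    """Convert a SMILES string into a `CompoundGraph`.

    One vertex per heavy atom, one undirected edge per bond; new atom keys
    extend `atom_vocab` unless it is frozen (then they map to UNK).
    """
    mol = _parse_smiles(smiles)
    tokens = [atom_vocab.lookup(_atom_key(a)) for a in mol.GetAtoms()]
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    fp = compute_fingerprint(smiles, radius=fp_radius)
    return CompoundGraph(atom_tokens=tokens, edges=edges, fingerprint=fp,
                         n_atoms=mol.GetNumAtoms())


def protein_to_kmers(sequence: str, kmer_vocab: TokenVocab, k: int = 3) -> ProteinTokens:
    """Split `sequence` into overlapping k-mers (stride 1) and tokenize.

    k-mers containing any non-standard residue letter map to UNK so that
    real database sequences (selenocysteine U, ambiguity codes B/J/X/Z, ...)
    pass without error.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    tokens = []
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i:i + k]
        if set(kmer) <= STANDARD_RESIDUES:
            tokens.append(kmer_vocab.lookup(kmer))
        else:
            tokens.append(kmer_vocab.unk_index)
    return ProteinTokens(kmer_tokens=tokens, n_kmers=len(tokens))


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def apply_mutations(wild_type: str, spec: str) -> str:
    """Apply point substitutions like "Y227C" or "A240D/E277G" (1-based).

    The reference letter of every substitution is checked against the
    wild-type sequence before any edit is made.  Insertions/deletions and
    other non-substitution specs are rejected.
    """
    wild_type = wild_type.strip().upper()
    seq = list(wild_type)
    edits: list[tuple[int, str]] = []
    for token in spec.strip().split("/"):
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if not m:
            raise MutationFormatError(
                f"unsupported mutation spec {token!r}: only single-residue "
                f"substitutions of the form RefPosAlt are supported")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if not (1 <= pos <= len(seq)):
            raise MutationRangeError(
                f"position {pos} out of range for sequence of length {len(seq)}")
        found = wild_type[pos - 1]
        if found != ref:
            raise MutationMismatchError(
                f"reference mismatch at position {pos}: spec says {ref}, "
                f"sequence has {found}")
        edits.append((pos - 1, alt))
    for i, alt in edits:
        seq[i] = alt
    return "".join(seq)


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + KELVIN_OFFSET


def fit_thermo_stats(temps_celsius) -> NormalizationStats:
    """Fit min-max bounds for Kelvin temperature and its reciprocal.

    Called on training-set temperatures only, so validation/test features
    carry no information about their own split.
    """
    t_k = np.asarray([celsius_to_kelvin(t) for t in temps_celsius], dtype=float)
    if t_k.size < 2 or np.isclose(t_k.min(), t_k.max()):
        raise ValueError("need >=2 distinct temperatures to fit normalization stats")
    if np.any(t_k <= 0):
        raise ValueError("absolute temperature must be positive")
    inv = 1.0 / t_k
    return NormalizationStats(t_min=float(t_k.min()), t_max=float(t_k.max()),
                              invt_min=float(inv.min()), invt_max=float(inv.max()))


def normalize_temperature(t_celsius: float, stats: NormalizationStats) -> ThermoFeatures:
    """Min-max normalize T (Kelvin) and 1/T against fitted stats.

    Values outside the fitted range are extrapolated (not clipped) and
    logged at debug level.
    """
    t_k = celsius_to_kelvin(t_celsius)
    t_norm = (t_k - stats.t_min) / (stats.t_max - stats.t_min)
    invt_norm = (1.0 / t_k - stats.invt_min) / (stats.invt_max - stats.invt_min)
    if not (0.0 <= t_norm <= 1.0):
        logger.debug("temperature %.2f C outside fitted range; extrapolating", t_celsius)
    return ThermoFeatures(t_norm=float(t_norm), invt_norm=float(invt_norm),
                          t_kelvin=t_k)


def denormalize_temperature(t_norm: float, stats: NormalizationStats) -> float:
    """Inverse of the T-channel min-max map; returns Kelvin."""
    return stats.t_min + t_norm * (stats.t_max - stats.t_min)
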