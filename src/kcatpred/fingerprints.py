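"""Binary reaction fingerprints built from circular substructures.

Three schemes encode a reaction as fixed-length binary vectors:

* **structural** (4096 bits): the substrate side and the product side are
  each folded into 2048 bits (one bit per hashed circular substructure)
  and concatenated substrate-half ∥ product-half. Encodes what is
  present on each side.
* **differential** (2048 bits): substructure *counts* from each side are
  accumulated into hashed bins; a bit is set wherever the signed
  product-minus-substrate bin difference is nonzero. Encodes where the
  two sides differ, multiplicity-sensitively.
* **difference** (DRFP-style, 2048 bits): the symmetric difference of
  the substructure identifier *sets* of the two sides; each surviving
  identifier sets one hashed bit. Encodes which environments appear on
  exactly one side, ignoring multiplicity.

Substructures are atom-centred circular environments (Morgan-style) at
radii 0..r, identified by the canonical fragment SMILES of the
environment prefixed with its radius, so identifiers are invariant to
molecule input order and to SMILES rewriting. Identifiers map to bits
through a 64-bit FNV-1a hash — stable across platforms and processes.
Agents (the middle component of ``a>x>b``) are excluded throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ._hash import hash_to_bit
from .data import Reaction
from .errors import ParameterError
from .io import mol_from_smiles


def _is_power_of_two(x: int) -> bool:
    return x > 0 and (x & (x - 1)) == 0


@dataclass(frozen=True)
class FingerprintConfig:
    """Bit sizes, radii and hash scheme for all three fingerprints."""

    bits_per_side: int = 2048
    diff_bits: int = 2048
    drfp_bits: int = 2048
    radius: int = 2
    drfp_radii: frozenset[int] = field(default_factory=lambda: frozenset({0, 1, 2}))
    hash_scheme: str = "fnv1a-64"

    def __post_init__(self) -> None:
        for label, bits in (
            ("bits_per_side", self.bits_per_side),
            ("diff_bits", self.diff_bits),
            ("drfp_bits", self.drfp_bits),
        ):
            if not _is_power_of_two(bits):
                raise ParameterError(f"{label} must be a power of two, got {bits}")
        if self.radius < 1:
            raise ParameterError(f"radius must be ≥ 1, got {self.radius}")
        if self.hash_scheme != "fnv1a-64":
            raise ParameterError(f"unknown hash scheme {self.hash_scheme!r}")
        object.__setattr__(self, "drfp_radii", frozenset(self.drfp_radii))


@dataclass
class SubstructureMultiset:
    """Canonical substructure identifiers with multiplicities."""

    entries: dict[str, int]
    radii: frozenset[int]

    def identifier_set(self) -> frozenset[str]:
        return frozenset(self.entries)


def _environment_identifier(mol: Chem.Mol, atom_idx: int, radius: int) -> str | None:
    """Canonical identifier of the radius-r environment centred on one atom.

    Returns None when the molecule has no environment of that radius
    around the atom (e.g. radius 2 on a terminal atom of a short chain),
    mirroring the usual circular-fingerprint convention of skipping
    non-growing environments.
    """
    if radius == 0:
        frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], canonical=True)
        return f"0|{frag}"
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    if not bonds:
        return None
    atoms = {atom_idx}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    frag = Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds), canonical=True
    )
    return f"{radius}|{frag}"


def substructure_multiset(
    molecules: list[str], radii: set[int] | frozenset[int]
) -> SubstructureMultiset:
    """Union, over molecules and radii, of circular environments with counts.

    Invariant to molecule input order (a Counter union is commutative) and
    to SMILES rewriting (identifiers are canonical fragment SMILES).
    """
    if not radii or min(radii) < 0:
        raise ParameterError(f"radii must be a non-empty set of ≥0 integers: {radii}")
    counts: Counter[str] = Counter()
    for smiles in molecules:
        mol = mol_from_smiles(smiles)
        for radius in sorted(radii):
            for atom in mol.GetAtoms():
                ident = _environment_identifier(mol, atom.GetIdx(), radius)
                if ident is not None:
                    counts[ident] += 1
    return SubstructureMultiset(entries=dict(counts), radii=frozenset(radii))


def _side_radii(cfg: FingerprintConfig) -> frozenset[int]:
    return frozenset(range(cfg.radius + 1))


def _fold_set(identifiers, n_bits: int) -> np.ndarray:
    vec = np.zeros(n_bits, dtype=np.uint8)
    for ident in identifiers:
        vec[hash_to_bit(ident, n_bits)] = 1
    return vec


def _fold_counts(entries: dict[str, int], n_bits: int) -> np.ndarray:
    vec = np.zeros(n_bits, dtype=np.int64)
    for ident, count in entries.items():
        vec[hash_to_bit(ident, n_bits)] += count
    return vec


def structural_fingerprint(
    rxn: Reaction, cfg: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Substrate-side ∥ product-side hashed substructure bits (default 4096)."""
    radii = _side_radii(cfg)
    sub = substructure_multiset(rxn.substrates, radii)
    prod = substructure_multiset(rxn.products, radii)
    return np.concatenate(
        [
            _fold_set(sub.entries, cfg.bits_per_side),
            _fold_set(prod.entries, cfg.bits_per_side),
        ]
    )


def differential_fingerprint(
    rxn: Reaction, cfg: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Bits where hashed product counts differ from hashed substrate counts."""
    radii = _side_radii(cfg)
    sub = _fold_counts(substructure_multiset(rxn.substrates, radii).entries, cfg.diff_bits)
    prod = _fold_counts(substructure_multiset(rxn.products, radii).entries, cfg.diff_bits)
    return (prod != sub).astype(np.uint8)


def difference_fingerprint(
    rxn: Reaction, cfg: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """DRFP-style set symmetric difference of the two sides, hashed to bits."""
    sub = substructure_multiset(rxn.substrates, cfg.drfp_radii).identifier_set()
    prod = substructure_multiset(rxn.products, cfg.drfp_radii).identifier_set()
    return _fold_set(sub ^ prod, cfg.drfp_bits)
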