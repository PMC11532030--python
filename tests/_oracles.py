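"""Independent oracles used by the test suite.

These deliberately re-derive quantities through routes separate from the
package implementation: a standalone FNV-1a copy, a brute-force circular
environment enumerator built directly on RDKit primitives, and a dense
grid search over the probability simplex. They must stay independent of
the code paths they check.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


def fnv1a_64_oracle(text: str) -> int:
    h = 0xCBF29CE484222325
    for byte in text.encode("utf-8"):
        h ^= byte
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def enumerate_environments(smiles_list, radii):
    """Brute-force multiset of canonical environment identifiers.

    For every molecule, atom and radius: radius 0 uses the single-atom
    fragment SMILES; radius ≥ 1 collects the bond environment and takes
    the canonical fragment SMILES over its atoms and bonds. Identifiers
    are prefixed with the radius.
    """
    counts: dict[str, int] = {}
    for smiles in smiles_list:
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, smiles
        for radius in sorted(radii):
            for atom in mol.GetAtoms():
                if radius == 0:
                    frag = Chem.MolFragmentToSmiles(
                        mol, atomsToUse=[atom.GetIdx()], canonical=True
                    )
                else:
                    bonds = Chem.FindAtomEnvironmentOfRadiusN(
                        mol, radius, atom.GetIdx()
                    )
                    if not bonds:
                        continue
                    atoms = {atom.GetIdx()}
                    for b in bonds:
                        bond = mol.GetBondWithIdx(b)
                        atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
                    frag = Chem.MolFragmentToSmiles(
                        mol,
                        atomsToUse=sorted(atoms),
                        bondsToUse=list(bonds),
                        canonical=True,
                    )
                key = f"{radius}|{frag}"
                counts[key] = counts.get(key, 0) + 1
    return counts


def simplex_grid(m: int, step: float) -> np.ndarray:
    """All weight vectors on the m-simplex with the given grid step."""
    k = int(round(1.0 / step))
    if m == 1:
        return np.array([[1.0]])
    if m == 2:
        a = np.arange(k + 1) / k
        return np.column_stack([a, 1.0 - a])
    if m == 3:
        rows = []
        for i in range(k + 1):
            j = np.arange(k - i + 1)
            block = np.column_stack(
                [np.full(len(j), i), j, k - i - j]
            )
            rows.append(block)
        return np.vstack(rows) / k
    raise NotImplementedError("grid oracle supports m ≤ 3")


def grid_search_weights(preds: np.ndarray, y: np.ndarray, step: float = 0.001):
    """Best simplex weights by exhaustive grid evaluation (chunked)."""
    W = simplex_grid(preds.shape[1], step)
    best_loss, best_w = np.inf, None
    for start in range(0, len(W), 20000):
        chunk = W[start : start + 20000]
        err = preds @ chunk.T - y[:, None]
        losses = np.mean(err * err, axis=0)
        i = int(np.argmin(losses))
        if losses[i] < best_loss:
            best_loss, best_w = float(losses[i]), chunk[i]
    return best_w, best_loss
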