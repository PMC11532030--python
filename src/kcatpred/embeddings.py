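"""Protein-sequence embedding providers and design-matrix assembly.

Real protein-language-model embedders (the base transformer and its
task-fine-tuned variant, each emitting 1280-dimensional vectors per
sequence) plug in behind the :class:`EmbeddingProvider` protocol.
Because those weights are multi-gigabyte downloads, the package ships a
deterministic surrogate: a hashed bag of overlapping 3-mers pushed
through a salt-seeded random projection and L2-normalised. It preserves
the contracts that matter downstream — fixed dimensionality, determinism,
and sensitivity to point mutations — without any network access.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from ._hash import fnv1a_64
from .data import BLOCK_DIMS, FeatureBlock, FeatureStore, KcatDataset, is_valid_sequence
from .errors import AlphabetError, KcatPredError, ShapeError
from .fingerprints import (
    FingerprintConfig,
    difference_fingerprint,
    differential_fingerprint,
    structural_fingerprint,
)
from .io import parse_reaction

EMBED_DIM = 1280  # per-sequence embedding length of both providers


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Anything that maps an amino-acid sequence to a fixed-length vector."""

    provider_id: str
    dim: int
    deterministic: bool

    def embed(self, sequence: str) -> np.ndarray: ...


def surrogate_embed(sequence: str, dim: int = EMBED_DIM, salt: int = 0) -> np.ndarray:
    """Deterministic sequence embedding from hashed 3-mer counts.

    Overlapping 3-mers (the whole sequence if shorter than 3) are
    counted; each distinct k-mer contributes its count times a fixed
    Gaussian direction seeded from (salt, k-mer hash); the sum is
    L2-normalised. Fully determined by (sequence, dim, salt).
    """
    if not is_valid_sequence(sequence):
        raise AlphabetError(
            f"sequence empty or outside amino-acid alphabet: {sequence[:30]!r}"
        )
    kmers: dict[str, int] = {}
    if len(sequence) < 3:
        kmers[sequence] = 1
    else:
        for i in range(len(sequence) - 2):
            k = sequence[i : i + 3]
            kmers[k] = kmers.get(k, 0) + 1
    vec = np.zeros(dim, dtype=np.float64)
    for kmer, count in kmers.items():
        seed = (fnv1a_64(f"{salt}|{kmer}")) % (2**63)
        rng = np.random.Generator(np.random.PCG64(seed))
        vec += count * rng.standard_normal(dim)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


@dataclass
class SurrogateProvider:
    """Download-free :class:`EmbeddingProvider` built on :func:`surrogate_embed`.

    Distinct salts stand in for distinct pretrained models (base vs
    fine-tuned), giving correlated-but-different feature blocks.
    """

    salt: int = 0
    dim: int = EMBED_DIM
    provider_id: str = "surrogate"
    deterministic: bool = True

    def embed(self, sequence: str) -> np.ndarray:
        return surrogate_embed(sequence, dim=self.dim, salt=self.salt)


def combined_embedding(e_base: np.ndarray, e_ft: np.ndarray) -> np.ndarray:
    """Elementwise product of the base and fine-tuned embeddings."""
    e_base = np.asarray(e_base, dtype=float)
    e_ft = np.asarray(e_ft, dtype=float)
    if e_base.shape != e_ft.shape:
        raise ShapeError(
            f"embedding length mismatch: {e_base.shape} vs {e_ft.shape}"
        )
    return e_base * e_ft


_FP_BUILDERS: dict[str, Callable] = {
    "fp_structural": structural_fingerprint,
    "fp_differential": differential_fingerprint,
    "fp_difference": difference_fingerprint,
}


def assemble_feature_store(
    ds: KcatDataset,
    base_provider: EmbeddingProvider | None = None,
    finetuned_provider: EmbeddingProvider | None = None,
    fp_cfg: FingerprintConfig | None = None,
) -> FeatureStore:
    """Featurize every record into the six aligned feature blocks.

    Emits ``emb_base``, ``emb_finetuned``, ``emb_combined`` (elementwise
    product of the first two) and the three reaction fingerprints, all
    row-aligned to the dataset's record order. Per-record failures are
    aggregated into a single error listing the offending record ids.
    """
    base_provider = base_provider or SurrogateProvider(salt=1, provider_id="surrogate-base")
    finetuned_provider = finetuned_provider or SurrogateProvider(
        salt=2, provider_id="surrogate-finetuned"
    )
    fp_cfg = fp_cfg or FingerprintConfig()

    n = len(ds)
    ids = ds.record_ids
    emb_base = np.zeros((n, base_provider.dim))
    emb_ft = np.zeros((n, finetuned_provider.dim))
    fps = {name: np.zeros((n, BLOCK_DIMS[name]), dtype=np.uint8) for name in _FP_BUILDERS}
    failures: list[tuple[str, str]] = []

    for i, rec in enumerate(ds):
        try:
            emb_base[i] = base_provider.embed(rec.sequence)
            emb_ft[i] = finetuned_provider.embed(rec.sequence)
            rxn = parse_reaction(rec.reaction)
            for name, build in _FP_BUILDERS.items():
                fps[name][i] = build(rxn, fp_cfg)
        except KcatPredError as exc:
            failures.append((rec.record_id, str(exc)))
    if failures:
        detail = "; ".join(f"{rid}: {msg}" for rid, msg in failures[:10])
        raise KcatPredError(
            f"featurization failed for {len(failures)} record(s): {detail}"
        )

    store = FeatureStore(sample_ids=ids)
    store.add(FeatureBlock("emb_base", emb_base, ids))
    store.add(FeatureBlock("emb_finetuned", emb_ft, ids))
    store.add(FeatureBlock("emb_combined", combined_embedding(emb_base, emb_ft), ids))
    for name in _FP_BUILDERS:
        store.add(FeatureBlock(name, fps[name], ids))
    return store
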