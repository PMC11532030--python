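"""Domain data model: kcat records, reactions and aligned feature matrices.

The unit of all modelling is one enzyme–reaction pair with a turnover
number (kcat, s⁻¹). Features live in named, sample-aligned blocks whose
dimensionality is fixed by the block name:

====================  =====  ==========================================
block name              dim  contents
====================  =====  ==========================================
``emb_base``           1280  protein-language-model embedding (base)
``emb_finetuned``      1280  embedding from the task-fine-tuned variant
``emb_combined``       1280  elementwise product of the two embeddings
``fp_structural``      4096  substrate‖product binary fingerprint
``fp_differential``    2048  signed-count-difference binary fingerprint
``fp_difference``      2048  set-symmetric-difference binary fingerprint
====================  =====  ==========================================
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError, ShapeError

#: Canonical amino-acid alphabet; X is permitted as an unknown-residue marker.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_RE = re.compile(f"^[{AMINO_ACIDS}X]+$")

#: Fixed dimensionality per feature-block name.
BLOCK_DIMS: dict[str, int] = {
    "emb_base": 1280,
    "emb_finetuned": 1280,
    "emb_combined": 1280,
    "fp_structural": 4096,
    "fp_differential": 2048,
    "fp_difference": 2048,
}

#: Block names holding binary fingerprints (values constrained to {0,1}).
BINARY_BLOCKS = frozenset({"fp_structural", "fp_differential", "fp_difference"})


def is_valid_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and uses only the 20 canonical letters + X."""
    return bool(seq) and _SEQ_RE.match(seq) is not None


@dataclass
class KcatRecord:
    """One enzyme–reaction pair with an optional kcat label.

    ``kcat`` is in s⁻¹ and must be finite and positive when present;
    ``None`` is the missing-value marker (removal is preprocessing's job,
    not the reader's).
    """

    record_id: str
    sequence: str
    reaction: str
    kcat: float | None
    split_label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.sequence):
            raise ValueError(
                f"record {self.record_id!r}: sequence empty or outside "
                f"alphabet [{AMINO_ACIDS}X]"
            )
        if self.kcat is not None:
            if not math.isfinite(self.kcat) or self.kcat <= 0:
                raise ValueError(
                    f"record {self.record_id!r}: kcat must be finite and > 0, "
                    f"got {self.kcat}"
                )
        if self.split_label is not None and self.split_label not in ("train", "test"):
            raise ValueError(
                f"record {self.record_id!r}: split label must be 'train' or "
                f"'test', got {self.split_label!r}"
            )


@dataclass
class KcatDataset:
    """Ordered collection of :class:`KcatRecord` with unique ids."""

    records: list[KcatRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise IntegrityError(f"duplicate record_id {dup!r} in dataset")
        labelled = [r for r in self.records if r.split_label is not None]
        if labelled and len(labelled) != len(self.records):
            raise IntegrityError(
                "split labels must be present for all records or for none"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def has_split_labels(self) -> bool:
        return bool(self.records) and self.records[0].split_label is not None

    def kcat_values(self) -> np.ndarray:
        """kcat per record as float array; missing values become NaN."""
        return np.array(
            [r.kcat if r.kcat is not None else np.nan for r in self.records],
            dtype=float,
        )

    def subset(self, record_ids) -> "KcatDataset":
        wanted = set(record_ids)
        return KcatDataset(
            records=[r for r in self.records if r.record_id in wanted],
            provenance=self.provenance,
        )


@dataclass
class Reaction:
    """Parsed reaction SMILES: substrate, agent and product molecule lists.

    Component order is preserved verbatim; order-insensitivity is a
    property of the downstream canonicalised fingerprints, not of this
    container.
    """

    substrates: list[str]
    agents: list[str]
    products: list[str]

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError("reaction needs at least one substrate and one product")

    def reversed(self) -> "Reaction":
        return Reaction(
            substrates=list(self.products),
            agents=list(self.agents),
            products=list(self.substrates),
        )


@dataclass
class FeatureBlock:
    """A named n_samples × dim matrix aligned to sample ids."""

    name: str
    matrix: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ShapeError(f"block {self.name!r}: matrix must be 2-D")
        if self.name in BLOCK_DIMS and self.matrix.shape[1] != BLOCK_DIMS[self.name]:
            raise ShapeError(
                f"block {self.name!r}: expected dim {BLOCK_DIMS[self.name]}, "
                f"got {self.matrix.shape[1]}"
            )
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ShapeError(
                f"block {self.name!r}: {self.matrix.shape[0]} rows vs "
                f"{len(self.sample_ids)} sample ids"
            )
        if self.name in BINARY_BLOCKS:
            vals = np.unique(self.matrix)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"block {self.name!r}: fingerprint values must be 0/1")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FeatureStore:
    """Map of block name → :class:`FeatureBlock`, all sharing one id order."""

    blocks: dict[str, FeatureBlock] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, block in self.blocks.items():
            if block.sample_ids != self.sample_ids:
                raise IntegrityError(
                    f"block {name!r} sample ids differ from the store's"
                )

    def add(self, block: FeatureBlock) -> None:
        if not self.sample_ids and not self.blocks:
            self.sample_ids = list(block.sample_ids)
        if block.sample_ids != self.sample_ids:
            raise IntegrityError(
                f"block {block.name!r} sample ids differ from the store's"
            )
        self.blocks[block.name] = block

    def __contains__(self, name: str) -> bool:
        return name in self.blocks

    def __getitem__(self, name: str) -> FeatureBlock:
        return self.blocks[name]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, record_ids) -> "FeatureStore":
        """Row-subset every block to ``record_ids`` (given order)."""
        index = {rid: i for i, rid in enumerate(self.sample_ids)}
        rows = [index[r] for r in record_ids]
        ids = list(record_ids)
        out = FeatureStore(sample_ids=ids)
        for name, block in self.blocks.items():
            out.blocks[name] = FeatureBlock(name, block.matrix[rows], ids)
        return out
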