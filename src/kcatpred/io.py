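"""Readers and writers: kcat tables, FASTA, reaction SMILES, feature stores.

The kcat table is a comma- or tab-delimited text file with required
columns ``id, sequence, reaction, kcat`` and an optional ``split`` column
holding ``train``/``test`` labels. The delimiter is auto-detected from
the extension (``.tsv``/``.tab`` → tab, else comma) unless given
explicitly. Feature stores persist to an HDF5 container with one dataset
per block plus the shared sample-id table, so round-trips are bit-exact.
"""

from __future__ import annotations

import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .data import BINARY_BLOCKS, FeatureBlock, FeatureStore, KcatDataset, KcatRecord, Reaction
from .errors import (
    ChemistryError,
    FormatError,
    IntegrityError,
    ReactionParseError,
    RowError,
    SchemaError,
)

RDLogger.DisableLog("rdApp.*")

REQUIRED_COLUMNS = ("id", "sequence", "reaction", "kcat")


def _detect_delimiter(path: str | Path, dialect: str | None) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect in ("csv", "comma"):
        return ","
    if dialect in ("tsv", "tab"):
        return "\t"
    if dialect is not None:
        raise SchemaError(f"unknown table dialect {dialect!r}")
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_kcat_table(path: str | Path, dialect: str | None = None) -> KcatDataset:
    """Read a kcat table into a :class:`KcatDataset`.

    Missing kcat cells become ``None`` (the missing-value marker), never
    silent zeros. Raises :class:`SchemaError` for missing columns,
    :class:`IntegrityError` for duplicate ids, and :class:`RowError`
    (with the 1-based data line number) for unparseable rows.
    """
    sep = _detect_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"kcat table {path} missing required columns: {missing}")
    has_split = "split" in df.columns
    has_source = "source" in df.columns

    records: list[KcatRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        raw_kcat = getattr(row, "kcat").strip()
        if raw_kcat == "":
            kcat: float | None = None
        else:
            try:
                kcat = float(raw_kcat)
            except ValueError as exc:
                raise RowError(f"kcat {raw_kcat!r} is not a number", line) from exc
            if not math.isfinite(kcat):
                raise RowError(f"kcat {raw_kcat!r} is not finite", line)
        try:
            records.append(
                KcatRecord(
                    record_id=getattr(row, "id"),
                    sequence=getattr(row, "sequence"),
                    reaction=getattr(row, "reaction"),
                    kcat=kcat,
                    split_label=(getattr(row, "split") or None) if has_split else None,
                    source=(getattr(row, "source") or None) if has_source else None,
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from exc
    return KcatDataset(records=records, provenance=str(path))


def write_kcat_table(ds: KcatDataset, path: str | Path, dialect: str | None = None) -> None:
    """Write a dataset back out in the table schema of :func:`read_kcat_table`."""
    sep = _detect_delimiter(path, dialect)
    rows = {
        "id": [r.record_id for r in ds],
        "sequence": [r.sequence for r in ds],
        "reaction": [r.reaction for r in ds],
        "kcat": [("" if r.kcat is None else repr(r.kcat)) for r in ds],
    }
    if ds.has_split_labels:
        rows["split"] = [r.split_label for r in ds]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse one molecule SMILES, raising :class:`ChemistryError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"molecule SMILES failed to parse: {smiles!r}")
    return mol


def parse_reaction(reaction_smiles: str, validate_molecules: bool = True) -> Reaction:
    """Split a reaction SMILES into substrate / agent / product lists.

    Accepts the two-part ``substrates>>products`` and three-part
    ``substrates>agents>products`` conventions; components within a side
    split on ``.``. With ``validate_molecules`` every component must
    parse under RDKit.
    """
    parts = reaction_smiles.split(">")
    if len(parts) == 3:
        sub_s, agent_s, prod_s = parts
    else:
        raise ReactionParseError(
            f"reaction SMILES needs the form 'a>>b' or 'a>x>b': {reaction_smiles!r}"
        )
    if not sub_s or not prod_s:
        raise ReactionParseError(
            f"reaction SMILES has an empty substrate or product side: "
            f"{reaction_smiles!r}"
        )

    def split_side(side: str) -> list[str]:
        return [c for c in side.split(".") if c] if side else []

    rxn = Reaction(
        substrates=split_side(sub_s),
        agents=split_side(agent_s),
        products=split_side(prod_s),
    )
    if validate_molecules:
        for component in (*rxn.substrates, *rxn.agents, *rxn.products):
            mol_from_smiles(component)
    return rxn


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; id is the first token after '>'.

    Multi-line sequences are concatenated. A body line before any header
    or an empty sequence raises :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    current: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if current is not None:
            seq = "".join(parts)
            if not seq:
                raise FormatError(f"FASTA record {current!r} has an empty sequence")
            if current in sequences:
                raise FormatError(f"duplicate FASTA id {current!r}")
            sequences[current] = seq

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise FormatError("FASTA header with no id")
                parts = []
            else:
                if current is None:
                    raise FormatError("sequence data before any FASTA header")
                parts.append(line)
    flush()
    return sequences


def save_feature_store(store: FeatureStore, path: str | Path) -> None:
    """Persist a feature store to an HDF5 container.

    Layout: ``/sample_ids`` (variable-length UTF-8) plus one
    ``/blocks/<name>`` dataset per block. Binary blocks are stored as
    uint8; embeddings at their native float precision.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "sample_ids",
            data=np.array(store.sample_ids, dtype=h5py.string_dtype("utf-8")),
        )
        grp = f.create_group("blocks")
        for name, block in store.blocks.items():
            data = block.matrix
            if name in BINARY_BLOCKS:
                data = data.astype(np.uint8)
            grp.create_dataset(name, data=data)


def load_feature_store(
    path: str | Path, expected_blocks: list[str] | None = None
) -> FeatureStore:
    """Load a feature store written by :func:`save_feature_store`.

    If ``expected_blocks`` is given, a missing block raises
    :class:`IntegrityError`.
    """
    with h5py.File(path, "r") as f:
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][()]]
        store = FeatureStore(sample_ids=sample_ids)
        present = set(f["blocks"].keys()) if "blocks" in f else set()
        if expected_blocks is not None:
            missing = sorted(set(expected_blocks) - present)
            if missing:
                raise IntegrityError(f"feature store {path} missing blocks: {missing}")
        for name in sorted(present):
            matrix = f["blocks"][name][()]
            store.blocks[name] = FeatureBlock(name, matrix, sample_ids)
    return store
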