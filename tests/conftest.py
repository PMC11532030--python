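import numpy as np
import pytest

from kcatpred import KcatDataset, KcatRecord


@pytest.fixture()
def three_row_table(tmp_path):
    """Hand-written kcat table fixture with known float values."""
    path = tmp_path / "kcat.csv"
    path.write_text(
        "id,sequence,reaction,kcat\n"
        "r1,MKVLAYTTRE,CCO>>CC=O,1.5\n"
        "r2,ACDEFGHIKL,CC(=O)O.OCC>>CC(=O)OCC.O,0.02\n"
        "r3,MMMMKKKKLL,O=C=O.O>>C(=O)O,300\n"
    )
    return path


@pytest.fixture()
def small_dataset():
    rng = np.random.default_rng(42)
    records = []
    for i in range(8):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
        records.append(
            KcatRecord(
                record_id=f"rec{i}",
                sequence=seq,
                reaction="CCO>>CC=O" if i % 2 else "CC(=O)O.OCC>>CC(=O)OCC.O",
                kcat=float(10 ** rng.normal(0, 1)),
            )
        )
    return KcatDataset(records=records)


@pytest.fixture(scope="session")
def esterification():
    """Toy esterification reaction SMILES used across fingerprint tests."""
    return "CC(=O)O.OCC>>CC(=O)OCC.O"
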