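import numpy as np
import pandas as pd
import pytest

from scatdiet.synthetic import GeneratorConfig, generate_dataset, generate_reference_db
from scatdiet.tables import MOTUTable, ReferenceDB


def make_table(rows: dict[str, tuple[str, dict[str, int]]], pcr_ids: list[str]) -> MOTUTable:
    """Build a MOTUTable from {motu_id: (sequence, {pcr_id: count})}."""
    ids = list(rows)
    counts = pd.DataFrame(0, index=ids, columns=pcr_ids, dtype=int)
    for motu_id, (_, cnts) in rows.items():
        for pcr, c in cnts.items():
            counts.at[motu_id, pcr] = c
    seqs = pd.Series({m: rows[m][0] for m in ids}, name="sequence")
    return MOTUTable(sequences=seqs, counts=counts)


def random_table(rng: np.random.Generator, n_motus: int, n_samples: int,
                 max_count: int = 200, seq_len_range=(50, 140)) -> MOTUTable:
    """Random MOTU table with skewed counts and varied sequence lengths."""
    pcr_ids = [f"S{i:03d}.R{r}" for i in range(n_samples) for r in (1, 2, 3)]
    alphabet = np.array(list("ACGTN"))
    seqs = []
    for _ in range(n_motus):
        length = int(rng.integers(*seq_len_range))
        probs = [0.24, 0.24, 0.24, 0.24, 0.04]
        seqs.append("".join(rng.choice(alphabet, size=length, p=probs)))
    # sparse, heavy-tailed counts
    counts = np.where(
        rng.uniform(size=(n_motus, len(pcr_ids))) < 0.1,
        rng.geometric(p=1.0 / 30.0, size=(n_motus, len(pcr_ids))),
        0,
    )
    ids = [f"M{i:05d}" for i in range(n_motus)]
    return MOTUTable(
        sequences=pd.Series(seqs, index=ids, name="sequence"),
        counts=pd.DataFrame(counts, index=ids, columns=pcr_ids),
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_sites=3, samples_per_site_season=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ref = generate_reference_db(small_config)
    table, metadata, truth = generate_dataset(small_config, ref)
    return ref, table, metadata, truth


@pytest.fixture(scope="session")
def reference_db(small_dataset) -> ReferenceDB:
    return small_dataset[0]
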