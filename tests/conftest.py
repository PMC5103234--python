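"""Shared fixtures: tiny hand-built alignments and a small generated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from pathsel.io_formats import HaplotypeAlignment, PopulationPartition
from pathsel.synthetic_data import SimConfig, generate_dataset


def make_alignment(seqs, ids=None, gene_id="gene", frame_offset=0):
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    return HaplotypeAlignment(gene_id=gene_id, sample_ids=ids,
                              sequences=list(seqs), frame_offset=frame_offset)


def random_alignment(rng, n, length, missing_rate=0.0, gene_id="rand"):
    """Random alignment over ACGT with optional missing data (N/-)."""
    mat = rng.integers(0, 4, size=(n, length))
    chars = np.array(list("ACGT"), dtype="U1")
    rows = []
    for i in range(n):
        row = chars[mat[i]].copy()
        if missing_rate > 0:
            mask = rng.random(length) < missing_rate
            gap = rng.random(length) < 0.5
            row[mask & gap] = "-"
            row[mask & ~gap] = "N"
        rows.append("".join(row))
    return make_alignment(rows, gene_id=gene_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20160611)


@pytest.fixture
def two_group_partition():
    assignment = {f"L{i}": "landrace" for i in range(1, 5)}
    assignment.update({f"W{i}": "wild" for i in range(1, 5)})
    return PopulationPartition(assignment)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small generated dataset shared by IO/pipeline tests."""
    out = tmp_path_factory.mktemp("dataset") / "ds"
    config = SimConfig(
        genes_per_pathway={"SSP1": 6, "SSP2": 5, "SSP3": 5},
        length_range=(300, 1200),
        regime_counts={"purifying": 3, "balancing": 3},
        seed=11,
    )
    manifest = generate_dataset(config, out)
    return {"dir": out, "config": config, "manifest": manifest}
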