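import numpy as np
import pandas as pd
import pytest

from dualbcr import (SimConfig, classify_pairing, filter_functional_contigs,
                     group_cells, simulate_expression, simulate_repertoire)
from dualbcr.bcr_core import CellChainSet
from dualbcr.io_formats import CONTIG_COLUMNS


def make_contig_csv(path, rows):
    """Write a minimal 10x-dialect contig CSV from row dicts."""
    defaults = {
        "barcode": "AAAC-1", "is_cell": "True", "contig_id": "",
        "high_confidence": "True", "chain": "IGH", "v_gene": "IGHV1-1",
        "d_gene": "", "j_gene": "IGHJ1", "c_gene": "IGHM",
        "cdr3": "CARW", "cdr3_nt": "TGTGCTAGATGG", "productive": "True",
        "reads": "100", "umis": "5",
    }
    frames = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.update(row)
        if not r["contig_id"]:
            r["contig_id"] = f"contig_{i}"
        frames.append(r)
    pd.DataFrame(frames).to_csv(path, index=False)
    return path


def make_cell(barcode, chains, sample_id="s", cdr3s=None):
    """Build a CellChainSet from a list of chain tokens (and optional CDR3s)."""
    n = len(chains)
    cdr3s = cdr3s or [f"TGTGC{i}AGATGG" for i in range(n)]
    df = pd.DataFrame({
        "barcode": [barcode] * n,
        "contig_id": [f"{barcode}_{i}" for i in range(n)],
        "is_cell": pd.array([True] * n, dtype="boolean"),
        "high_confidence": pd.array([True] * n, dtype="boolean"),
        "chain": chains,
        "v_gene": ["IGHV1-1"] * n,
        "d_gene": [""] * n,
        "j_gene": ["IGHJ1"] * n,
        "c_gene": ["IGHM" if c == "IGH" else "IGKC" for c in chains],
        "cdr3_aa": [s[:4] for s in cdr3s],
        "cdr3_nt": cdr3s,
        "productive": pd.array([True] * n, dtype="boolean"),
        "umis": [5] * n,
        "reads": [100] * n,
        "sample_id": [sample_id] * n,
    })
    return CellChainSet(barcode=barcode, sample_id=sample_id, chains=df)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated sample shared across tests (n=400, fixed seed)."""
    cfg = SimConfig(n_cells=400, seed=5, sample_id="sim", group="control")
    table, truth = simulate_repertoire(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_sim_cells(small_sim):
    cfg, table, truth = small_sim
    filtered, log = filter_functional_contigs(table)
    cells, n_dropped = group_cells(filtered)
    calls = [classify_pairing(c) for c in cells]
    return cells, calls, log, n_dropped


@pytest.fixture(scope="session")
def small_expression(small_sim):
    cfg, table, truth = small_sim
    return simulate_expression(truth, cfg)
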