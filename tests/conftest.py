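"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from endegrid.grid_metrics import PresenceMatrix
from endegrid.occurrences import FLAG_COLUMNS, RECORD_COLUMNS


def make_records(rows, **default_flags) -> pd.DataFrame:
    """Build a canonical record frame from (species, lon, lat[, country]) tuples."""
    out = []
    for row in rows:
        species, lon, lat = row[:3]
        country = row[3] if len(row) > 3 else ""
        flags = row[4] if len(row) > 4 else {}
        rec = {
            "species": species,
            "genus": species.split()[0],
            "longitude": lon,
            "latitude": lat,
            "country": country,
        }
        for f in FLAG_COLUMNS:
            rec[f] = bool(flags.get(f, default_flags.get(f, False)))
        out.append(rec)
    return pd.DataFrame(out, columns=list(RECORD_COLUMNS))


def random_presence_matrix(rng: np.random.Generator, n_cells: int, n_species: int) -> PresenceMatrix:
    """Random binary matrix with no empty rows or columns."""
    while True:
        incidence = (rng.random((n_cells, n_species)) < rng.uniform(0.15, 0.5)).astype(np.uint8)
        if incidence.sum(axis=1).min() > 0 and incidence.sum(axis=0).min() > 0:
            break
    cells = np.column_stack([np.arange(n_cells), np.zeros(n_cells, dtype=int)])
    species = np.array([f"sp{j:03d}" for j in range(n_species)], dtype=object)
    return PresenceMatrix(cells, species, incidence)


def brute_force_scores(incidence: np.ndarray):
    """Triple-loop SR/WE/CWE oracle, independent of the vectorized code path."""
    n_cells, n_species = incidence.shape
    ranges = [sum(incidence[c][s] for c in range(n_cells)) for s in range(n_species)]
    sr, we, cwe = [], [], []
    for c in range(n_cells):
        richness = 0
        endemism = 0.0
        for s in range(n_species):
            if incidence[c][s]:
                richness += 1
                endemism += 1.0 / ranges[s]
        sr.append(richness)
        we.append(endemism)
        cwe.append(endemism / richness)
    return np.array(sr), np.array(we), np.array(cwe)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
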