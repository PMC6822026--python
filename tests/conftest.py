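import numpy as np
import pandas as pd
import pytest

import srpkit


def tau_oracle(x, y):
    """Independent tau-b oracle: explicit classification of every pair."""
    import math

    n = len(x)
    n0 = n * (n - 1) // 2
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx == 0:
                tx += 1
            if dy == 0:
                ty += 1
            if dx * dy == 1:
                c += 1
            elif dx * dy == -1:
                d += 1
    if tx == n0 or ty == n0:
        return float("nan")
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


@pytest.fixture(scope="session")
def make_assemblage():
    def _make(scenario="neutral", n_species=100, seed=0, **kw):
        cfg = srpkit.ScenarioConfig(n_species=n_species, scenario=scenario, seed=seed, **kw)
        return srpkit.generate_assemblage(cfg)

    return _make


@pytest.fixture(scope="session")
def recon_inputs():
    """Records -> (in-grid profiles, species cell indices, overall richness, surface)."""

    def _make(records):
        prof = srpkit.species_profiles(records)
        surf = srpkit.richness_surface(records, srpkit.GridSpec.covering(records))
        _cells, overall, species_cells = surf.species_cell_indices()
        in_grid = prof[prof["species_id"].isin(species_cells)].reset_index(drop=True)
        return in_grid, species_cells, overall, surf

    return _make


def surface_with_richness(richness_values, cell_size=20.0):
    """A richness surface whose occupied cells carry the given counts.

    Cell i (one per value, spaced along a row) holds `richness_values[i]`
    distinct species placed at its center.
    """
    rows = []
    loc = 0
    for i, r in enumerate(richness_values):
        x = cell_size * (i + 0.5)
        for s in range(int(r)):
            rows.append((f"sp{i}_{s}", f"L{loc}", x, cell_size / 2, 1.0, True))
            loc += 1
    records = pd.DataFrame(
        rows,
        columns=["species_id", "locality_id", "x_km", "y_km", "accuracy_km", "in_study_area"],
    )
    grid = srpkit.GridSpec(0.0, 0.0, cell_size, len(richness_values), 1)
    return srpkit.richness_surface(records, grid)
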