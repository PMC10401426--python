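import numpy as np
import pandas as pd
import pytest

from tmespatial.cell_io import CoreCellTable


def make_core(cells, area_um2=1.0e6, core_id="c0", patient_id="p0", geometry=None):
    """Build a CoreCellTable from (x, y, flags-dict) triples."""
    rows = []
    for i, (x, y, flags) in enumerate(cells):
        row = {"cell_id": f"cell{i:04d}", "x": float(x), "y": float(y)}
        row.update(flags)
        rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["cell_id", "x", "y"])
    return CoreCellTable(
        core_id=core_id,
        patient_id=patient_id,
        cells=df,
        area_um2=area_um2,
        geometry=geometry,
    )


def random_core(rng, n_cells, extent=500.0, phenotype_probs=None, core_id="c0", patient_id="p0"):
    """Uniform random core with independent Bernoulli phenotype flags."""
    probs = phenotype_probs or {"cd3": 0.4, "cd8": 0.2, "nkp46": 0.15, "cd56": 0.1}
    cells = []
    for _ in range(n_cells):
        flags = {flag: bool(rng.random() < p) for flag, p in probs.items()}
        if flags.get("cd8"):
            flags["cd3"] = True
        flags["mhc1"] = bool(rng.random() < 0.5)
        cells.append((rng.random() * extent, rng.random() * extent, flags))
    return make_core(cells, area_um2=extent**2, core_id=core_id, patient_id=patient_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
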