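import numpy as np
import pandas as pd
import pytest

from saltscan.config import PipelineConfig
from saltscan.simulate import SimulationSpec, simulate_panel


def make_records(rows):
    """Build a phenotype frame from (accession, treatment, rep, sown, counts, meas) tuples."""
    out = []
    for accession, treatment, rep, sown, counts, meas in rows:
        row = {
            "accession": accession,
            "treatment": treatment,
            "replicate": rep,
            "seeds_sown": sown,
        }
        for i in range(10):
            row[f"n_day{i + 1}"] = counts[i] if i < len(counts) else 0
        row.update(
            dict(
                zip(
                    ["shoot_length_cm", "root_length_cm", "fresh_weight_mg", "dry_weight_mg"],
                    meas,
                )
            )
        )
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def tiny_spec():
    return SimulationSpec(n_accessions=40, n_markers=120, seed=7, qtl=None)


@pytest.fixture(scope="session")
def tiny_panel(tiny_spec):
    return simulate_panel(tiny_spec)


@pytest.fixture(scope="session")
def desk_panel():
    """Full desk-scale panel: 192 accessions x 2000 markers."""
    return simulate_panel(SimulationSpec(seed=11))


@pytest.fixture()
def config():
    return PipelineConfig(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
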