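import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dosetrace import ColumnSchema, DoseDesign, RunConfig

settings.register_profile(
    "det", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def design() -> DoseDesign:
    return DoseDesign()


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def cols() -> ColumnSchema:
    return ColumnSchema()


def write_site_table(path, rows, design=None, cols=None, drop_columns=()):
    """Write a minimal site table; ``rows`` are dicts of field overrides."""
    design = design or DoseDesign()
    cols = cols or ColumnSchema()
    records = []
    for i, row in enumerate(rows):
        rec = {
            cols.protein: row.get("protein", f"P{i:05d}"),
            cols.gene: row.get("gene", f"G{i}"),
            cols.position: row.get("position", 10 + i),
            cols.amino_acid: row.get("residue", "S"),
            cols.localization: row.get("prob", 0.99),
            cols.replicate: row.get("replicate", 1),
            cols.temperature: row.get("temperature", 37),
        }
        intensities = row.get("intensities", [1000.0 + 10 * k for k in range(design.n)])
        for ch, v in zip(design.dose_channels, intensities):
            rec[cols.intensity(ch)] = v
        records.append(rec)
    df = pd.DataFrame(records)
    for c in drop_columns:
        df = df.drop(columns=[c])
    df.to_csv(path, sep="\t", index=False)
    return path


def write_protein_table(path, rows, design=None, cols=None):
    design = design or DoseDesign()
    cols = cols or ColumnSchema()
    records = []
    for i, row in enumerate(rows):
        rec = {
            cols.protein: row.get("protein", f"Q{i:05d}"),
            cols.gene: row.get("gene", f"G{i}"),
            cols.replicate: row.get("replicate", 1),
            cols.temperature: row.get("temperature", 37),
        }
        intensities = row.get("intensities", [1000.0] * design.n)
        for ch, v in zip(design.dose_channels, intensities):
            rec[cols.intensity(ch)] = v
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    return path
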