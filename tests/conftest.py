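import numpy as np
import pandas as pd
import pytest

from flowscreen.experiments import null_calibration, planted_recovery
from flowscreen.io import PlateMap


@pytest.fixture
def tiny_plate_map() -> PlateMap:
    """Two plates x one culture each: 3 targets + 2 controls per plate."""
    rows = []
    for culture, age in (("c1", "pup"), ("c2", "adult")):
        plate = f"{culture}-P01"
        for i, gene in enumerate(["GeneA", "GeneB", "GeneC"]):
            rows.append(
                dict(plate_id=plate, well_id=f"A{i + 1}", role="target",
                     target_gene=gene, culture_id=culture, culture_age=age)
            )
        rows.append(
            dict(plate_id=plate, well_id="H10", role="nontargeted_control",
                 target_gene="", culture_id=culture, culture_age=age)
        )
        rows.append(
            dict(plate_id=plate, well_id="H11", role="nontargeted_control",
                 target_gene="", culture_id=culture, culture_age=age)
        )
    return PlateMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def null_run() -> dict:
    """One all-null 1440-target, 3-replicate screen shared by the null
    calibration checks (expensive: simulated once per session)."""
    return null_calibration(seed=7)


@pytest.fixture(scope="session")
def null_run_6rep() -> dict:
    """All-null screen with 3 pup + 3 adult replicates, for checks of the
    pup-versus-adult comparison under the null."""
    return null_calibration(seed=13, n_replicates=6)


@pytest.fixture(scope="session")
def planted_run() -> dict:
    """One planted-effect screen (20 targets at bright_weight_factor 0.4,
    6 replicates) shared by the recovery checks."""
    return planted_recovery(seed=7)
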