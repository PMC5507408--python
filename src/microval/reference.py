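"""Published force measurements of the reference porcine vertebra cohort.

Four porcine thoracic vertebral bodies (S#1-S#4) compressed in situ to
5% nominal strain: the experimentally measured axial force increment and
the axial forces the voxel microFE models predicted at tissue moduli of
12.0 GPa and 4.6 GPa.  These printed values are the inputs for the
force-statistics and modulus back-calculation reproductions; the image
data behind them are not shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

E_REFERENCE_GPA = 12.0
E_BACKCALC_GPA = 4.6


def load_reference_cohort() -> pd.DataFrame:
    """Cohort table: specimen id, free height, BV/TV, measured and predicted forces."""
    with resources.files("microval.data").joinpath("reference_cohort.csv").open() as f:
        return pd.read_csv(f)
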