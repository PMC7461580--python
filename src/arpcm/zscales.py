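"""Bundled five-component z-scale amino-acid descriptor table.

Z-scales summarise each amino acid by five scores obtained from a principal
component analysis of a panel of measured and computed physico-chemical
properties: z1 tracks lipophilicity, z2 steric bulk/polarizability, z3
polarity, and z4/z5 electronic character.  The table ships as a versioned
JSON data file so the featurizer has no runtime descriptor dependency.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

N_COMPONENTS = 5

ZScaleTable = dict[str, tuple[float, ...]]


@lru_cache(maxsize=1)
def load_zscale_table() -> ZScaleTable:
    """Load and validate the bundled z-scale table."""
    raw = json.loads(
        resources.files("arpcm.data").joinpath("zscales.json").read_text()
    )
    table = {aa: tuple(map(float, vals)) for aa, vals in raw["scales"].items()}
    if len(table) != 20:
        raise ValueError(f"z-scale table must have 20 residues, got {len(table)}")
    for aa, vals in table.items():
        if len(vals) != N_COMPONENTS:
            raise ValueError(f"z-scale entry for {aa} has {len(vals)} components")
    return table


def zscale_version() -> str:
    raw = json.loads(
        resources.files("arpcm.data").joinpath("zscales.json").read_text()
    )
    return str(raw["version"])
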