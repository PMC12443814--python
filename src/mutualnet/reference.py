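"""Published reference values for the karst frugivory network.

The source study printed its species-level table (degree, strength, d' per
bird and plant), a per-season network summary (richness, links, events,
z-scores), robustness values and coverage percentages; it did not print the
interaction matrix itself.  These tables ship with the package as plain CSV so
consistency checks and the worked analysis can run without the archived field
dataset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("mutualnet") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def species_table() -> pd.DataFrame:
    """Printed species-level metrics (18 birds + 14 plants), keyed by code."""
    return _read("reference_species.csv").set_index("code")


def network_table() -> pd.DataFrame:
    """Printed per-scope network summary: richness, links, events, z-scores."""
    return _read("reference_network.csv").set_index("parameter")


def robustness_table() -> pd.DataFrame:
    """Printed robustness R per removal side and scenario."""
    return _read("reference_robustness.csv")


def coverage_table() -> pd.DataFrame:
    """Printed sample-coverage percentages per scope and target."""
    return _read("reference_coverage.csv")
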