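"""Published reference values used as validation inputs.

These are the carcinogenic-risk tables of a published PM2.5 source
apportionment and health-risk study of a medium-sized industrial city in
Korea (median daily elemental concentrations, adult inhalation exposure).
They serve two purposes: worked-example inputs, and fixed points against
which the package's margin/share and reduction arithmetic is validated.
They are data, not code defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENT_ILCR_MEDIAN",
    "ELEMENT_ILCR_P95",
    "IUR",
    "SOURCE_ELEMENT_ILCR",
    "source_element_ilcr_table",
]

#: Inhalation unit risks (m³/µg) used by the reference study (IRIS/OEHHA).
IUR = {"As": 4.3e-3, "Cr6+": 1.2e-2, "Ni": 2.4e-4, "Pb": 1.2e-5}

#: Element-level ILCR at median daily concentrations.
ELEMENT_ILCR_MEDIAN = {"As": 4.47e-6, "Cr6+": 2.04e-6, "Ni": 7.07e-8, "Pb": 6.92e-8}

#: Element-level ILCR at 95th-percentile daily concentrations.
ELEMENT_ILCR_P95 = {"As": 1.17e-5, "Cr6+": 4.17e-6, "Ni": 1.30e-7, "Pb": 1.72e-7}

#: Source × element ILCR cells (median concentrations); absent pairs were
#: not reported (dash in the published table).
SOURCE_ELEMENT_ILCR = {
    "Secondary nitrate":       {"As": 2.90e-7, "Pb": 2.86e-9},
    "Secondary sulfate":       {"Ni": 1.14e-8},
    "Mobile":                  {"As": 8.34e-7, "Cr6+": 2.30e-7, "Pb": 7.07e-9},
    "Combustion for heating":  {"Cr6+": 1.32e-7, "Ni": 4.51e-9, "Pb": 7.17e-9},
    "Biomass burning":         {"As": 1.52e-7, "Cr6+": 2.12e-8, "Ni": 2.19e-9},
    "Coal combustion":         {"As": 3.24e-6, "Pb": 4.02e-8},
    "Industry (oil)":          {"Cr6+": 1.32e-6, "Ni": 4.93e-8},
    "Industry (smelting)":     {"Cr6+": 3.02e-7, "Pb": 6.26e-9},
    "Sea salts":               {"Cr6+": 5.11e-8, "Ni": 3.53e-9, "Pb": 4.61e-10},
    "Soil":                    {"Ni": 2.60e-10, "Pb": 6.13e-9},
}

#: Published margins for cross-checking.
PUBLISHED_GRAND_TOTAL = 6.71e-6
PUBLISHED_SOURCE_SHARES_PCT = {
    "Secondary nitrate": 4.4, "Secondary sulfate": 0.2, "Mobile": 16.0,
    "Combustion for heating": 2.1, "Biomass burning": 2.6,
    "Coal combustion": 48.9, "Industry (oil)": 20.4,
    "Industry (smelting)": 4.6, "Sea salts": 0.8, "Soil": 0.1,
}
PUBLISHED_ELEMENT_SUMS = {"As": 4.52e-6, "Cr6+": 2.06e-6, "Ni": 7.12e-8, "Pb": 7.02e-8}
PUBLISHED_ELEMENT_SHARES_PCT = {"As": 67.2, "Cr6+": 30.7, "Ni": 1.1, "Pb": 1.0}


def source_element_ilcr_table() -> pd.DataFrame:
    """The published source × element ILCR cells as a sources × elements
    DataFrame (NaN for unreported pairs)."""
    table = pd.DataFrame.from_dict(SOURCE_ELEMENT_ILCR, orient="index")
    return table[["As", "Cr6+", "Ni", "Pb"]].astype(float)
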