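"""Packaged defaults: medium component table, per-round bounds and levels.

Concentrations are expressed throughout as multiples of the reference
medium ("xRef" units). The component table encodes, for each of the 17
stock components (the two phosphate salts count as one because of their
pH-dependent equilibrium), whether it is varied independently, held
fixed, merged into a cluster variable, or tied to another component's
stock solution.
"""

from __future__ import annotations

# Variation decisions: "vary" (independent input variable), "fix" (held at a
# constant level), "cluster" (merged with others into the variable named by
# "with"), "tie" (co-varied with the varied component named by "with" because
# both ship in one stock solution).
COMPONENT_TABLE: list[dict] = [
    {"name": "MES", "decision": "vary"},
    {"name": "phosphate", "decision": "vary"},  # K2HPO4 + KH2PO4, one compound
    {"name": "NaNO3", "decision": "vary"},
    {"name": "MgSO4", "decision": "vary"},
    {"name": "NaCl", "decision": "vary"},
    {"name": "CaCl2", "decision": "vary"},
    {"name": "ZnSO4", "decision": "cluster", "with": "trace"},
    {"name": "MnCl2", "decision": "cluster", "with": "trace"},
    {"name": "Na2MoO4", "decision": "cluster", "with": "trace"},
    {"name": "CuSO4", "decision": "cluster", "with": "trace"},
    {"name": "CoSO4", "decision": "cluster", "with": "trace"},
    {"name": "H3BO3", "decision": "cluster", "with": "trace"},
    {"name": "FeSO4", "decision": "vary"},
    {"name": "H2SO4", "decision": "tie", "with": "FeSO4"},
    {"name": "Na2EDTA", "decision": "vary"},
    {"name": "KOH", "decision": "tie", "with": "Na2EDTA"},
    {"name": "penicillin_G", "decision": "fix", "level": 1.0},
]

# Reference concentrations of the free variables (mg/L of the representative
# component; informational metadata only -- the pipeline works in xRef units).
REFERENCE_CONCENTRATIONS = {
    "MES": 9760.0,
    "phosphate": 2000.0,
    "NaNO3": 1500.0,
    "MgSO4": 187.5,
    "NaCl": 6.25,
    "CaCl2": 125.0,
    "trace": 50.0,
    "FeSO4": 9.96,
    "Na2EDTA": 100.0,
}

# Screening-phase (rounds 1 and 2) bounds in xRef units. The trace-element
# cluster is allowed a wider upper bound than the single salts.
ROUND12_BOUNDS: dict[str, tuple[float, float]] = {
    "MES": (0.5, 1.7),
    "phosphate": (0.5, 1.7),
    "NaNO3": (0.5, 1.7),
    "MgSO4": (0.5, 1.7),
    "NaCl": (0.5, 1.7),
    "CaCl2": (0.5, 1.7),
    "trace": (0.5, 2.5),
    "FeSO4": (0.5, 1.7),
    "Na2EDTA": (0.5, 1.7),
}

# Factors retained after round-1 screening (preset mirrors the published
# campaign trajectory; data-driven screening results are logged alongside).
ROUND2_FACTORS = ("NaNO3", "MgSO4", "CaCl2", "NaCl", "trace")

# Factors carried into the refinement rounds.
ROUND34_FACTORS = ("MgSO4", "CaCl2", "trace", "NaNO3")

# Refinement-phase bound updates: nitrate upper bound lowered to the
# reference level, trace upper bound raised by 50%, calcium unchanged
# (precipitation above), magnesium range extended upward.
ROUND34_BOUNDS: dict[str, tuple[float, float]] = {
    "MgSO4": (0.5, 3.75),
    "CaCl2": (0.5, 1.7),
    "trace": (0.5, 3.75),
    "NaNO3": (0.1, 1.0),
}

# Three magnesium levels of the nested round-3 design (xRef).
ROUND3_MG_LEVELS = (0.5, 2.125, 3.75)

PLATE_CAPACITY = 48
SIGNIFICANCE_LEVEL = 0.1
N_REF_ROUND12 = 5
N_REF_ROUND34 = 4
N_EI_PROPOSALS = 12
N_UNIFORM_ROUND4 = 23
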