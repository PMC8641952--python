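"""Pharmacology emulation: channel blockers as conductance scaling.

Each supported drug scales exactly one maximal conductance by
``(1 - block_fraction)``, mirroring bath application of a selective
blocker at a given efficacy:

* ``ah_ttx_49``  — 4,9-anhydrotetrodotoxin, Nav1.6 blocker → g_NaP
* ``nifedipine`` — L-type Ca channel blocker → g_CaL
* ``zd7288``     — HCN channel blocker → g_H
* ``ivabradine`` — HCN channel blocker → g_H
"""

from __future__ import annotations

from ..errors import InvalidArgumentError
from .params import ModelParams

DRUG_TARGETS = {
    "ah_ttx_49": "g_NaP",
    "nifedipine": "g_CaL",
    "zd7288": "g_H",
    "ivabradine": "g_H",
}


def apply_drug(params: ModelParams, drug: str,
               block_fraction: float = 1.0) -> ModelParams:
    """Return a copy of ``params`` with the drug's target conductance scaled
    by ``(1 - block_fraction)``; all other fields are unchanged."""
    if drug not in DRUG_TARGETS:
        raise InvalidArgumentError(
            f"unknown drug {drug!r}; expected one of {sorted(DRUG_TARGETS)}")
    if not 0.0 <= block_fraction <= 1.0:
        raise InvalidArgumentError("block_fraction must lie in [0, 1]")
    target = DRUG_TARGETS[drug]
    return params.replace(**{target: getattr(params, target)
                             * (1.0 - block_fraction)})
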