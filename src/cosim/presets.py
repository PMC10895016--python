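"""Versioned regime presets.

Three parameter sets put the spiking microcircuits into the three canonical
dynamical regimes:

* ``A``  -- asynchronous: weak spike-triggered adaptation, extra Poisson
  drive, reduced noise and coupling; the population rate is flat.
* ``IS`` -- irregular synchronous: a fluctuation-driven network with strong
  slow spike-triggered adaptation (b ~ 60 pA, tau_w ~ 500 ms) alternating
  irregularly between high- and low-rate episodes, giving a broad ~3 Hz
  peak in the rate spectrum.
* ``RB`` -- regular bursting: raised voltage reset and leak reversal with
  stronger, faster adaptation produce regular population bursts (~6 Hz)
  whose intra-burst inter-spike interval sets a second high-frequency peak
  (~160 Hz).

Each preset is a full co-simulation parameter file (JSON, one object per
module section) shipped with the package.  The microcircuits are scaled to
2,000 neurons per region with quantal conductances rescaled inversely to
network size, preserving the mean synaptic drive of the 10,000-neuron
configuration.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import ParameterError

REGIMES = ("A", "IS", "RB")

__all__ = ["REGIMES", "preset", "preset_path"]


def preset(regime: str) -> dict:
    """The parameter tree for one regime (deep copy, safe to mutate)."""
    if regime not in REGIMES:
        raise ParameterError(f"unknown regime {regime!r}; choose from {REGIMES}")
    text = resources.files("cosim").joinpath(f"presets/{regime}.json").read_text()
    return json.loads(text)


def preset_path(regime: str):
    if regime not in REGIMES:
        raise ParameterError(f"unknown regime {regime!r}; choose from {REGIMES}")
    return resources.files("cosim").joinpath(f"presets/{regime}.json")
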