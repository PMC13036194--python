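"""Shared stimulus, group, and day labels used across the pipeline."""

from __future__ import annotations

WATER = "water"
CS_LABEL = "NaCl"
AVERSIVE_LABEL = "QHCl_high"
FORCED_CS_LABEL = "NaCl-Force"
CONDITIONING_LABEL = "conditioning"

#: The four basic-taste stimuli, in the fixed order used for tie breaking
#: and for best-stimulus unit labels.
BASIC_TASTES = ("sucrose", "NaCl", "citric_acid", "QHCl_high")

#: Best-stimulus unit label per basic taste.
UNIT_LABELS = {
    "sucrose": "S-Unit",
    "NaCl": "N-Unit",
    "citric_acid": "C-Unit",
    "QHCl_high": "Q-Unit",
}

GROUP_CONTROL = "CON"
GROUP_CTA = "CTA"

DAY_KINDS = ("pretest", "conditioning", "posttest", "extinction")
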