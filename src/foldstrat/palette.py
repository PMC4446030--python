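"""Colour anchors used when rendering virtual stained sections.

Masson's trichrome renders collagen green (anomalously reddish in aged
cranial-fold superficial zones); resorcin-fuchsin renders elastic fibres a
dark violet.  The anchors below are fixed RGB values; at render time every
channel receives independent multiplicative jitter of +/-10%, so any colour
rule must accept the whole jittered neighbourhood of its anchor and reject
the neighbourhoods of all other anchors.
"""

from __future__ import annotations

import numpy as np

# 8-bit RGB anchors (pre-jitter).
BACKGROUND = (235, 228, 232)       # pale ground substance
EPITHELIUM = (214, 168, 186)       # eosinophilic pink band
COLLAGEN_GREEN = (60, 130, 90)     # regular trichrome collagen
COLLAGEN_REDDISH = (185, 75, 90)   # anomalous trichrome reaction
ELASTIC_VIOLET = (80, 40, 100)     # resorcin-fuchsin elastic fibres
NUCLEI = (165, 158, 172)           # desaturated fibroblast nuclei texture

#: Fractional half-width of the per-channel multiplicative jitter.
CHANNEL_JITTER = 0.10


def jitter_colour(anchor: tuple[int, int, int], rng: np.random.Generator,
                  n: int) -> np.ndarray:
    """Sample ``n`` jittered 8-bit RGB variants of ``anchor``."""
    base = np.asarray(anchor, dtype=float)
    factors = rng.uniform(1.0 - CHANNEL_JITTER, 1.0 + CHANNEL_JITTER, (n, 3))
    return np.clip(base * factors, 0, 255).astype(np.uint8)
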