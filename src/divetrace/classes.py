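"""Class codes shared across the pipeline.

The segmentation problem has five mutually exclusive pixel classes. Codes
are stable across masks, probability maps and event tables; palette PNGs
use the same order.
"""

from __future__ import annotations

BACKGROUND = 0
SEAFLOOR = 1
KRILL_SWARM = 2
WHALE = 3
BUBBLE_TRAIL = 4

N_CLASSES = 5

CLASS_NAMES = ("background", "seafloor", "krill_swarm", "whale", "bubble_trail")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}

#: Classes that correspond to air-breathing predator signals.
PREDATOR_CLASSES = (WHALE, BUBBLE_TRAIL)

#: Precedence when planted objects overlap: stronger scatterers win.
#: whale > bubble_trail > krill_swarm > seafloor > background.
CLASS_PRECEDENCE = (BACKGROUND, SEAFLOOR, KRILL_SWARM, BUBBLE_TRAIL, WHALE)

#: Default per-class loss weights: whales up-weighted 10:1 against the rest
#: to counter their extreme rarity in annotated echograms.
DEFAULT_CLASS_WEIGHTS = (1.0, 1.0, 1.0, 10.0, 1.0)

#: Palette (RGB, 0-255) for mask PNGs and control plots.
CLASS_PALETTE = (
    (0, 0, 0),        # background
    (140, 90, 40),    # seafloor
    (60, 170, 60),    # krill swarm
    (220, 60, 60),    # whale
    (70, 120, 230),   # bubble trail
)

# Grid constants of the standard echogram product.
TIME_STEP_S = 1.0
DEPTH_STEP_M = 0.5
WINDOW_COLS = 600     # 10 min at 1 s per column
WINDOW_ROWS = 1000    # 500 m at 0.5 m per row
SV_FLOOR_DB = -90.0
SV_CEIL_DB = -20.0
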