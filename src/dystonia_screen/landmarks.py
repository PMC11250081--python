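"""Canonical hand-landmark index table.

The 21-point hand model follows the MediaPipe Hands convention: index 0 is the
wrist, then four points per digit running proximal to distal.  Every module in
the package indexes landmarks through this table, so the order is asserted in
one place only.
"""

from __future__ import annotations

N_LANDMARKS = 21
N_COORDS = 3  # x, y in normalized image units, z relative depth

WRIST = 0

#: landmark ids per finger, proximal -> distal (CMC/MCP, PIP-like, DIP-like, tip)
FINGER_CHAINS: dict[str, tuple[int, int, int, int]] = {
    "thumb": (1, 2, 3, 4),
    "index": (5, 6, 7, 8),
    "middle": (9, 10, 11, 12),
    "ring": (13, 14, 15, 16),
    "little": (17, 18, 19, 20),
}

FINGERS = ("thumb", "index", "middle", "ring", "little")

FINGERTIPS: dict[str, int] = {name: chain[-1] for name, chain in FINGER_CHAINS.items()}

LANDMARK_NAMES: tuple[str, ...] = ("wrist",) + tuple(
    f"{finger}_{part}"
    for finger in FINGERS
    for part in ("mcp", "pip", "dip", "tip")
)

assert len(LANDMARK_NAMES) == N_LANDMARKS
assert sorted(i for chain in FINGER_CHAINS.values() for i in chain) == list(range(1, 21))
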