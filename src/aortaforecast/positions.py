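"""The nine thoracic-aorta measurement positions.

Diameters are measured perpendicular to the aortic wall at nine anatomical
landmarks from the aortic root to the distal descending aorta.  Every vector
and matrix in the package that carries a position axis uses this order.
"""

from __future__ import annotations

POSITIONS: tuple[str, ...] = (
    "aortic_sinus",
    "sinotubular_junction",
    "mid_ascending",
    "distal_ascending",
    "proximal_arch",
    "mid_arch",
    "distal_transverse_arch",
    "proximal_descending",
    "distal_descending",
)

N_POSITIONS = len(POSITIONS)

#: Human-readable labels, same order as :data:`POSITIONS`.
POSITION_LABELS: tuple[str, ...] = (
    "Aortic sinus",
    "Sinotubular junction",
    "Mid-ascending aorta",
    "Distal ascending aorta",
    "Proximal aortic arch",
    "Mid aortic arch",
    "Distal transverse aortic arch",
    "Proximal descending",
    "Distal descending aorta",
)

_INDEX = {name: i for i, name in enumerate(POSITIONS)}


def position_index(name: str) -> int:
    """Index of a position label in the canonical order."""
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown aortic position {name!r}; expected one of {POSITIONS}"
        ) from None
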