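"""Wave-tagged node naming.

Analysis nodes are item identifiers tagged with the wave they were measured
at, ``item@W1`` / ``item@W2``.  Static covariates (measured once, e.g. twin
status) carry no tag.  All modules share this convention so that arcs can be
classified as within-item (persistence) or cross-item (cross-lag) and so the
temporal constraint set can be constructed from node names alone.
"""

from __future__ import annotations

W1 = "W1"
W2 = "W2"
STATIC = "static"
WAVES = (W1, W2)
_SEP = "@"


def tag(item: str, wave: str) -> str:
    """Return the wave-tagged node name for *item* (static items untouched)."""
    if wave == STATIC:
        return item
    if wave not in WAVES:
        raise ValueError(f"unknown wave {wave!r}; expected one of {WAVES + (STATIC,)}")
    return f"{item}{_SEP}{wave}"


def split_node(name: str) -> tuple[str, str]:
    """Split a node name into ``(base_item, wave)``; untagged names are static."""
    if _SEP in name:
        base, wave = name.rsplit(_SEP, 1)
        if wave not in WAVES:
            raise ValueError(f"node {name!r} has unknown wave tag {wave!r}")
        return base, wave
    return name, STATIC


def wave_of(name: str) -> str:
    return split_node(name)[1]


def base_of(name: str) -> str:
    return split_node(name)[0]
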