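"""Default node labels: abbreviated region names of the AAL 90-region atlas.

The AAL parcellation (78 cortical + 12 subcortical regions) interleaves
hemispheres: odd atlas indices are left-hemisphere regions, even indices the
right-hemisphere homologue.  Labels carry a ``.L`` / ``.R`` suffix.
"""

from __future__ import annotations

# Base abbreviations in canonical AAL order (each expands to .L then .R).
_AAL_BASE = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtri",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

AAL90_LABELS: list[str] = [
    f"{name}.{hemi}" for name in _AAL_BASE for hemi in ("L", "R")
]


def default_labels(node_count: int) -> list[str]:
    """Labels for ``node_count`` nodes.

    90-node networks get the AAL90 abbreviations; any other size gets
    synthetic ``N001``-style names.
    """
    if node_count == len(AAL90_LABELS):
        return list(AAL90_LABELS)
    return [f"N{i + 1:03d}" for i in range(node_count)]
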