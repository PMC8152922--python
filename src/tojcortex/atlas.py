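"""Desikan-Killiany gyral parcellation labels.

The cortical analyses operate on the standard 68-region gyral-based
parcellation (34 regions per hemisphere). Labels are ``lh_``/``rh_``
prefixed FreeSurfer region names.
"""

from __future__ import annotations

# 34 gyral-based region names per hemisphere (FreeSurfer aparc naming).
DK_BASE_NAMES: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

DK_REGIONS: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("lh", "rh") for name in DK_BASE_NAMES
)

N_REGIONS = len(DK_REGIONS)


def hemisphere_of(region: str) -> str:
    """Return 'L' or 'R' for a DK region label."""
    if region.startswith("lh_"):
        return "L"
    if region.startswith("rh_"):
        return "R"
    raise ValueError(f"not a hemisphere-prefixed region label: {region!r}")
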