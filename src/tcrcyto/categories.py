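"""Functional classification of the 48-plex cytokine panel.

The panel (Bio-Plex Pro Human Cytokine 48-plex) is grouped into five
functional categories — chemokines, growth factors, pro-inflammatory,
anti-inflammatory and "other" cytokines — the grouping used throughout the
network and association analyses.  Vendor labels are inconsistent across
exports ("IL-12 (p70)" vs "IL-12", "FGF basic" vs "FGF2"); a canonical
alias map normalises them to one identifier per analyte.
"""

from __future__ import annotations

CHEMOKINE = "chemokine"
GROWTH_FACTOR = "growth factor"
PRO_INFLAMMATORY = "pro-inflammatory"
ANTI_INFLAMMATORY = "anti-inflammatory"
OTHER = "other"

CATEGORIES = (CHEMOKINE, GROWTH_FACTOR, PRO_INFLAMMATORY, ANTI_INFLAMMATORY, OTHER)

#: canonical analyte -> functional category, 48 analytes.
ANALYTE_CATEGORIES: dict[str, str] = {
    # chemokines (12)
    "CTACK": CHEMOKINE,
    "eotaxin": CHEMOKINE,
    "GRO-a": CHEMOKINE,
    "IL-8": CHEMOKINE,
    "IP-10": CHEMOKINE,
    "MCP-1": CHEMOKINE,
    "MCP-3": CHEMOKINE,
    "MIG": CHEMOKINE,
    "MIP-1a": CHEMOKINE,
    "MIP-1b": CHEMOKINE,
    "RANTES": CHEMOKINE,
    "SDF-1a": CHEMOKINE,
    # growth factors (9)
    "FGF2": GROWTH_FACTOR,
    "G-CSF": GROWTH_FACTOR,
    "GM-CSF": GROWTH_FACTOR,
    "HGF": GROWTH_FACTOR,
    "SCF": GROWTH_FACTOR,
    "SCGF-b": GROWTH_FACTOR,
    "VEGF": GROWTH_FACTOR,
    "b-NGF": GROWTH_FACTOR,
    "PDGF-BB": GROWTH_FACTOR,
    # pro-inflammatory (10)
    "IFN-g": PRO_INFLAMMATORY,
    "IL-1a": PRO_INFLAMMATORY,
    "IL-1b": PRO_INFLAMMATORY,
    "IL-6": PRO_INFLAMMATORY,
    "IL-12": PRO_INFLAMMATORY,       # p70 heterodimer
    "IL-12-1": PRO_INFLAMMATORY,     # p40 subunit
    "IL-17": PRO_INFLAMMATORY,
    "IL-18": PRO_INFLAMMATORY,
    "TNF-a": PRO_INFLAMMATORY,
    "TNF-b": PRO_INFLAMMATORY,
    # anti-inflammatory (4)
    "IL-1RA": ANTI_INFLAMMATORY,
    "IL-4": ANTI_INFLAMMATORY,
    "IL-10": ANTI_INFLAMMATORY,
    "IL-13": ANTI_INFLAMMATORY,
    # other (13)
    "IFN-a2": OTHER,
    "IL-2": OTHER,
    "IL-2Ra": OTHER,
    "IL-3": OTHER,
    "IL-5": OTHER,
    "IL-7": OTHER,
    "IL-9": OTHER,
    "IL-15": OTHER,
    "IL-16": OTHER,
    "LIF": OTHER,
    "M-CSF": OTHER,
    "MIF": OTHER,
    "TRAIL": OTHER,
}

#: vendor / manuscript spellings -> canonical identifier.
CANONICAL_ALIASES: dict[str, str] = {
    "IL-12 (p70)": "IL-12",
    "IL-12p70": "IL-12",
    "IL-12 (p40)": "IL-12-1",
    "IL-12p40": "IL-12-1",
    "IL-17A": "IL-17",
    "FGF basic": "FGF2",
    "basic FGF": "FGF2",
    "GRO-α": "GRO-a",
    "MIP-1α": "MIP-1a",
    "MIP-1β": "MIP-1b",
    "SDF-1α": "SDF-1a",
    "SCGF-β": "SCGF-b",
    "β-NGF": "b-NGF",
    "IFN-γ": "IFN-g",
    "IFN-α2": "IFN-a2",
    "IL-1α": "IL-1a",
    "IL-1β": "IL-1b",
    "IL-2Rα": "IL-2Ra",
    "TNF-α": "TNF-a",
    "TNF-β": "TNF-b",
    "Eotaxin": "eotaxin",
}


def canonical_analyte(name: str) -> str:
    """Map a raw analyte label to its canonical identifier."""
    name = name.strip()
    return CANONICAL_ALIASES.get(name, name)


def category_of(analyte: str, category_map: dict[str, str] | None = None) -> str:
    """Functional category of an analyte (KeyError if unmapped)."""
    cmap = ANALYTE_CATEGORIES if category_map is None else category_map
    return cmap[canonical_analyte(analyte)]


assert len(ANALYTE_CATEGORIES) == 48
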