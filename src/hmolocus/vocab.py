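"""Controlled vocabulary of gene-family tokens.

Gene landscapes are encoded as strings of tokens naming the protein
families found around a GH112 anchor: glycoside hydrolase (CAZyme)
families, the ABC-transporter components, the flanking regulatory genes,
and two catch-alls (HP for annotated hypothetical proteins, OTHER for
anything that maps to no family and no keyword).
"""

from __future__ import annotations

# CAZyme and accessory families recognised by homology search.
FAMILY_TOKENS: tuple[str, ...] = (
    "GH112",
    "GH136_I",
    "GH136_II",
    "GH10",
    "GH29",
    "GH95",
    "GH42",
    "GH36",
    "GH98",
    "SBP",
    "PP",
    "TransR",
    "HisK",
    "HP",
)

#: The two subunits of the GH136 lacto-N-biosidase; "GH136" as an aggregate
#: family means a genome carrying at least one of them.
GH136_SUBUNITS: frozenset[str] = frozenset({"GH136_I", "GH136_II"})

#: Anchor family: the GNB/LNB phosphorylase every locus is centred on.
ANCHOR_FAMILY = "GH112"

#: Fallback token for genes with no family hit and no keyword match.
OTHER_TOKEN = "OTHER"

ALL_TOKENS: tuple[str, ...] = FAMILY_TOKENS + (OTHER_TOKEN,)

#: Ordered keyword → token table used to tokenize un-hit genes from their
#: product annotation. First (most specific) match wins; matching is
#: case-insensitive substring search.
DEFAULT_KEYWORD_TABLE: tuple[tuple[str, str], ...] = (
    ("solute binding", "SBP"),
    ("solute-binding", "SBP"),
    ("permease", "PP"),
    ("transcriptional regulator", "TransR"),
    ("regulator", "TransR"),
    ("histidine kinase", "HisK"),
    ("hypothetical", "HP"),
)


def is_gh136(token: str) -> bool:
    return token in GH136_SUBUNITS
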