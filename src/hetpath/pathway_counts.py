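"""The 11 KEGG top-level metabolism categories used as the label vocabulary,
with the published per-category membership counts of the curated
2329-chemical / 1124-enzyme dataset. Because many molecules participate in
more than one pathway type, the per-category counts sum to more than the
number of distinct nodes -- the bookkeeping that makes the task multilabel.
"""

from __future__ import annotations

PATHWAY_TYPES: tuple[str, ...] = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of other amino acids",
    "Glycan biosynthesis and metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation and metabolism",
)

#: chemicals per pathway type, same order as PATHWAY_TYPES
CHEMICAL_COUNTS: tuple[int, ...] = (399, 153, 405, 135, 427, 132, 22, 303, 195, 326, 422)

#: enzymes per pathway type, same order as PATHWAY_TYPES
ENZYME_COUNTS: tuple[int, ...] = (274, 102, 337, 113, 215, 106, 156, 175, 46, 54, 141)

#: distinct chemicals / enzymes in the curated dataset
N_CHEMICALS = 2329
N_ENZYMES = 1124


def total_memberships(kind: str) -> int:
    """Sum of per-category counts ('chemical' or 'enzyme'); exceeds the
    distinct-node count because of multilabel membership."""
    if kind == "chemical":
        return sum(CHEMICAL_COUNTS)
    if kind == "enzyme":
        return sum(ENZYME_COUNTS)
    raise ValueError(f"unknown kind {kind!r}")
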