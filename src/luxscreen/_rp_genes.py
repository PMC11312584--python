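"""Curated list of S. cerevisiae cytoplasmic ribosomal-protein genes.

The budding-yeast ribosome is built from 78 distinct ribosomal proteins
encoded by 137 genes: 19 proteins from single-copy genes and 59 from
duplicated (A/B paralog) gene pairs.  This module packages that gene list so
manifests for the full heterozygous-deletion strain library can be built
without any external lookup.

Protein labels follow a simple eL/eS convention derived from the gene name
(RPL40A -> "eL40", RPS8B -> "eS8", P-stalk RPP1A -> "P1"); they are display
labels, not a strict mapping onto the unified ribosomal-protein
nomenclature.
"""

# 19 ribosomal proteins encoded by a single gene.
SINGLE_COPY_GENES: tuple[str, ...] = (
    "RPL3",
    "RPL5",
    "RPL10",
    "RPL25",
    "RPL28",
    "RPL29",
    "RPL30",
    "RPL32",
    "RPL38",
    "RPL39",
    "RPS2",
    "RPS3",
    "RPS5",
    "RPS12",
    "RPS13",
    "RPS15",
    "RPS20",
    "RPS31",
    "RPP0",
)

# 59 ribosomal proteins encoded by duplicated A/B paralog pairs; the gene
# names are the base name plus an "A" or "B" suffix.
DUPLICATED_GENE_BASES: tuple[str, ...] = (
    "RPL1",
    "RPL2",
    "RPL4",
    "RPL6",
    "RPL7",
    "RPL8",
    "RPL9",
    "RPL11",
    "RPL12",
    "RPL13",
    "RPL14",
    "RPL15",
    "RPL16",
    "RPL17",
    "RPL18",
    "RPL19",
    "RPL20",
    "RPL21",
    "RPL22",
    "RPL23",
    "RPL24",
    "RPL26",
    "RPL27",
    "RPL31",
    "RPL33",
    "RPL34",
    "RPL35",
    "RPL36",
    "RPL37",
    "RPL40",
    "RPL41",
    "RPL42",
    "RPL43",
    "RPS0",
    "RPS1",
    "RPS4",
    "RPS6",
    "RPS7",
    "RPS8",
    "RPS9",
    "RPS10",
    "RPS11",
    "RPS14",
    "RPS16",
    "RPS17",
    "RPS18",
    "RPS19",
    "RPS21",
    "RPS22",
    "RPS23",
    "RPS24",
    "RPS25",
    "RPS26",
    "RPS27",
    "RPS28",
    "RPS29",
    "RPS30",
    "RPP1",
    "RPP2",
)

# The 9 library strains that do not grow under the screen's culture
# conditions and are therefore excluded from analysis.
NONVIABLE_GENES: tuple[str, ...] = (
    "RPL4B",
    "RPL5",
    "RPS8B",
    "RPL9B",
    "RPL11A",
    "RPL14B",
    "RPS26A",
    "RPL31B",
    "RPL36B",
)


def protein_label(gene_id: str) -> str:
    """Display label for the ribosomal protein encoded by ``gene_id``."""
    # gene names are RP[LSP]<number>[A|B]; strip a trailing paralog suffix
    core = gene_id
    if core[-1] in ("A", "B") and core[:-1][-1].isdigit():
        core = core[:-1]
    if core.startswith("RPL"):
        return "eL" + core[3:]
    if core.startswith("RPS"):
        return "eS" + core[3:]
    if core.startswith("RPP"):
        return "P" + core[3:]
    return core
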