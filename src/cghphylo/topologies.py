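"""Reference MLSA cladograms for the *Neurospora* study system.

The study compares CGH-derived trees against the multilocus
sequence-analysis (MLSA) phylogeny of nine Sordariomycete fungi: seven
*Neurospora* species/strains plus *Sordaria macrospora* and *Podospora
anserina*.  Three nested taxon sets of increasing evolutionary breadth
are used:

* ``CON`` — the six most closely related conidiating, outbreeding
  *Neurospora* (including the reference strain *N. crassa* A);
* ``NEU`` — CON plus the homothallic *N. terricola*;
* ``ALL`` — NEU plus the outgroups *S. macrospora* and *P. anserina*.

The newick strings below transcribe the established MLSA topology for
these taxa (cladograms only; branch lengths carry no meaning here).
Each set is available with and without the reference taxon, formed by
pruning, so the nesting CON ⊂ NEU ⊂ ALL is exact by construction.
"""

from __future__ import annotations

from .io import Tree, read_newick
from .treemetrics import restrict_tree

REFERENCE_TAXON = "N_crassa_A"

CON_TAXA = (
    "N_crassa_A",
    "N_crassa_C",
    "N_intermedia",
    "N_sitophila",
    "N_tetrasperma",
    "N_discreta",
)
NEU_TAXA = CON_TAXA + ("N_terricola",)
ALL_TAXA = NEU_TAXA + ("S_macrospora", "P_anserina")

TAXON_SETS = {"CON": CON_TAXA, "NEU": NEU_TAXA, "ALL": ALL_TAXA}

#: MLSA cladogram on all nine taxa.  The two N. crassa strains are
#: sisters, N. intermedia joins them, N. sitophila + N. tetrasperma form
#: the sister pair to that clade, N. discreta is the most divergent
#: conidiating taxon, N. terricola branches below the conidiating clade,
#: and Sordaria + Podospora are the outgroup pair.
ALL_NEWICK = (
    "((((((N_crassa_A,N_crassa_C),N_intermedia),"
    "(N_sitophila,N_tetrasperma)),N_discreta),N_terricola),"
    "(S_macrospora,P_anserina));"
)


def reference_topology(taxon_set: str = "ALL", include_reference: bool = True) -> Tree:
    """The MLSA topology for one taxon set, optionally without the reference.

    Parameters
    ----------
    taxon_set:
        ``"CON"``, ``"NEU"`` or ``"ALL"``.
    include_reference:
        When False, the reference taxon (*N. crassa* A) is pruned.
    """
    if taxon_set not in TAXON_SETS:
        raise ValueError(f"unknown taxon set {taxon_set!r}; expected CON/NEU/ALL")
    keep = set(TAXON_SETS[taxon_set])
    if not include_reference:
        keep.discard(REFERENCE_TAXON)
    full = read_newick(ALL_NEWICK).without_lengths()
    if keep == full.leaves:
        return full
    return restrict_tree(full, keep)
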