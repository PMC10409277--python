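"""Published sugar beet reference values used as worked-example inputs.

These small tables are the published observations for the sugar beet
(*Beta vulgaris*) system this package was built around: the homology
category totals of the TK-81mm-O mitochondrial reference (368,801 bp)
against the EL10 nuclear and plastid assemblies, the allele matrix of the
intra-individually polymorphic sites in a 309-bp category-2 window
(reference positions 35,507-35,815) observed in lines NK-195BRmm-O and
NK-291BRmm-O, and the allele matrix at eleven polymorphic sites around
position 286,732-286,944 together with the residues of the matching
DH1440 numt (scaffold4651).  They serve as inputs to the summary and
table-construction operations, not as test expectations wired into the
implementation.
"""

from __future__ import annotations

#: Length of the TK-81mm-O mitochondrial reference (bp).
MT_REFERENCE_LENGTH = 368_801

#: Per-category bp totals of the eight-way homology partition of the
#: TK-81mm-O mtDNA reference (nuclear/plastid homology vs line EL10).
CATEGORY_TOTALS = {
    1: 14_657,
    2: 97_099,
    3: 61_941,
    4: 186_351,
    5: 0,
    6: 248,
    7: 151,
    8: 8_354,
}

#: 1-based mtDNA positions of the polymorphic sites reported in the 309-bp
#: window (35,507-35,815) and just downstream of it.
WINDOW_309_POSITIONS = (
    35_559, 35_578, 35_581, 35_595, 35_610, 35_611, 35_613,
    35_615, 35_633, 35_634, 35_653, 35_670, 35_738, 35_776,
)

#: Observed alleles per line at those positions ("X/Y" = intra-individually
#: polymorphic, reference allele first).
WINDOW_309_ALLELES = {
    "mt_Ref": ("A", "G", "C", "G", "C", "C", "C",
               "G", "A", "C", "A", "G", "G", "G"),
    "NK-195": ("A/G", "G/T", "C", "G/A", "C/G", "C/T", "C/T",
               "G", "A/G", "C", "A/T", "G/A", "G/T", "G/T"),
    "NK-291": ("A/G", "G", "C/T", "G/A", "C/G", "C", "C/T",
               "G/A", "A/G", "C/T", "A", "G/A", "G/T", "G/T"),
}

#: The 309-bp window itself (1-based inclusive mtDNA coordinates).
WINDOW_309 = (35_507, 35_815)

#: The twelve closely linked polymorphic sites lie within this sub-interval.
WINDOW_309_CORE = (35_559, 35_670)

#: Position whose variant allele abolishes the Cla I site (ATCGAT -> TTCGAT).
CLAI_POLYMORPHIC_POSITION = 35_653

#: Cla I recognition motif.
CLAI_MOTIF = "ATCGAT"

#: F2 genotype counts from the RFLP segregation assay
#: (numt-bearing-line homozygotes, heterozygotes, other homozygotes).
F2_GENOTYPE_COUNTS = (1, 10, 5)

#: Published p-value quoted for those counts against 1:2:1 ("Fisher's exact
#: test", construction unspecified).  Recorded for comparison only.
F2_PUBLISHED_P = 0.49

#: Eleven intra-individually polymorphic positions in NK-195BRmm-O whose
#: variant alleles match the DH1440 scaffold4651 numt residue-for-residue.
NUMT_MATCH_POSITIONS = (
    286_732, 286_777, 286_781, 286_783, 286_790, 286_796,
    286_816, 286_821, 286_828, 286_903, 286_944,
)

NUMT_MATCH_ALLELES = {
    "mt_Ref": ("G", "G", "G", "A", "C", "G", "G", "G", "T", "G", "T"),
    "NK-195": ("G/T", "G/A", "G/C", "A/T", "C/A", "G/T",
               "G/A", "G/A", "T/A", "G/T", "T/A"),
    "NK-291": ("G", "G", "G", "A", "C", "G", "G", "G", "T", "G", "T"),
    "DH1440": ("T", "A", "C", "T", "A", "T", "A", "A", "A", "T", "A"),
}


def polymorphic_positions(line: str) -> list[int]:
    """Positions where ``line`` shows more than one allele in the 309-bp table."""
    return [
        p
        for p, cell in zip(WINDOW_309_POSITIONS, WINDOW_309_ALLELES[line])
        if "/" in cell
    ]


def variant_allele(line: str, pos: int) -> str:
    """The variant (non-reference) allele of ``line`` at ``pos``."""
    for table_pos, table in (
        (WINDOW_309_POSITIONS, WINDOW_309_ALLELES),
        (NUMT_MATCH_POSITIONS, NUMT_MATCH_ALLELES),
    ):
        if pos in table_pos:
            cell = table[line][table_pos.index(pos)]
            if "/" not in cell:
                raise ValueError(f"{line} is monomorphic at {pos}")
            return cell.split("/")[1]
    raise KeyError(f"position {pos} not in the published tables")
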