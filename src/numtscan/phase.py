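"""Coupling/repulsion phasing of linked variant alleles and numt matching.

When several intra-individual polymorphic sites cluster within a window
smaller than a read (or a cloned PCR product), each source spanning two or
more sites reveals which alleles travel together.  If essentially every
informative source is either all-reference or all-variant, the variant
alleles are in *coupling phase* -- the signature expected when a second
molecule class (a diverged numt, or a genuinely heteroplasmic mtDNA
molecule) underlies the polymorphism.  Matching the variant haplotype
against candidate numt sequences from other assemblies then decides
between the two explanations: a perfect residue-by-residue match labels
the sites numt-consistent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

from numtscan._sequtil import validate_nucleotides
from numtscan.pileup import Alignment

GAP = "-"


@dataclass
class HaplotypeWindow:
    """Per-source allele strings over an ordered set of variant positions."""

    window: tuple[int, int]  # 1-based inclusive on the reference
    positions: tuple[int, ...]
    ref_alleles: str
    alleles: dict[str, str]  # source id -> allele string (GAP where uncovered)

    def informative(self) -> dict[str, str]:
        """Sources covering at least two variant positions."""
        return {
            k: v
            for k, v in self.alleles.items()
            if sum(c != GAP for c in v) >= 2
        }


class NoInformativeSourcesError(ValueError):
    """No source spans two or more variant positions."""


def _positions_from_alignment(aln: Alignment) -> dict[int, str]:
    """Map 1-based reference position -> base (or '*' for deletion)."""
    out: dict[int, str] = {}
    rpos = aln.pos
    qpos = 0
    for op, n in aln.cigar:
        if op == "M":
            for i in range(n):
                out[rpos + i] = aln.seq[qpos + i]
            rpos += n
            qpos += n
        elif op in ("I", "S"):
            qpos += n
        elif op == "D":
            for i in range(n):
                out[rpos + i] = "*"
            rpos += n
    return out


def _positions_from_sequence(seq: str, reference: str,
                             window: tuple[int, int]) -> dict[int, str]:
    """Align a clone/numt sequence to the reference window, read off bases."""
    ref_win = reference[window[0] - 1 : window[1]]
    res = edlib.align(seq.upper(), ref_win, mode="NW", task="path")
    out: dict[int, str] = {}
    rpos = window[0]
    qpos = 0
    n = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            n = n * 10 + int(ch)
            continue
        if ch in "=XM":
            for i in range(n):
                out[rpos + i] = seq[qpos + i].upper()
            rpos += n
            qpos += n
        elif ch == "I":  # extra bases in the source
            qpos += n
        elif ch == "D":  # source lacks these reference positions
            for i in range(n):
                out[rpos + i] = "*"
            rpos += n
        n = 0
    return out


def extract_window_haplotypes(
    sources: Sequence[Alignment] | Mapping[str, str],
    positions: Sequence[int],
    reference: str,
    window: tuple[int, int] | None = None,
) -> HaplotypeWindow:
    """Build per-source allele strings at the given variant positions.

    ``sources`` are either read alignments or named sequences (cloned PCR
    products and numts are simply long error-free sources; both modes share
    this code path).  A source contributes a gap token at positions it does
    not cover; a single-token ``*`` marks a deleted position so that string
    length always equals the number of positions.
    """
    if len(positions) < 2:
        raise ValueError("need at least two variant positions to phase")
    positions = tuple(sorted(positions))
    if window is None:
        window = (positions[0], positions[-1])
    if positions[0] < window[0] or positions[-1] > window[1]:
        raise ValueError("variant positions fall outside the window")
    validate_nucleotides(reference, "reference")
    ref_alleles = "".join(reference[p - 1].upper() for p in positions)

    alleles: dict[str, str] = {}
    if isinstance(sources, Mapping):
        for name, seq in sources.items():
            cover = _positions_from_sequence(seq, reference, window)
            alleles[name] = "".join(cover.get(p, GAP) for p in positions)
    else:
        for aln in sources:
            if not aln.mapped:
                continue
            cover = _positions_from_alignment(aln)
            s = "".join(cover.get(p, GAP) for p in positions)
            if s.strip(GAP):
                alleles[aln.read_id] = s
    return HaplotypeWindow(window=window, positions=positions,
                           ref_alleles=ref_alleles, alleles=alleles)


@dataclass
class PhaseResult:
    classes: dict[str, int]  # allele string -> count (informative sources)
    verdict: str  # coupling | repulsion | mixed
    n_informative: int
    homogeneous_fraction: float


def phase_verdict(window: HaplotypeWindow, threshold: float = 0.95) -> PhaseResult:
    """Decide coupling vs repulsion from informative sources.

    A source is *homogeneous* when every covered position is reference, or
    every covered position is variant.  The verdict is ``coupling`` when at
    least ``threshold`` of informative sources are homogeneous and the
    variant class is the all-variant string; ``repulsion`` when at least
    ``threshold`` carry a mix of reference and variant alleles; ``mixed``
    otherwise.
    """
    informative = window.informative()
    if not informative:
        raise NoInformativeSourcesError(
            "no source spans two or more variant positions"
        )
    classes = Counter(informative.values())
    n = len(informative)
    homog = 0
    for string, count in classes.items():
        states = {
            c == r
            for c, r in zip(string, window.ref_alleles)
            if c != GAP
        }
        if len(states) == 1:
            homog += count
    frac = homog / n
    if frac >= threshold:
        verdict = "coupling"
    elif 1.0 - frac >= threshold:
        verdict = "repulsion"
    else:
        verdict = "mixed"
    return PhaseResult(
        classes=dict(classes),
        verdict=verdict,
        n_informative=n,
        homogeneous_fraction=frac,
    )


def build_allele_table(
    samples: Mapping[str, Mapping[int, Sequence[str]]],
    positions: Sequence[int],
    reference_alleles: Mapping[int, str],
    reference_row: str = "mt_Ref",
):
    """Per-sample allele matrix over ordered positions.

    ``samples`` maps sample name -> {position -> observed alleles}.  A cell
    is the single observed character when the sample is monomorphic there
    and ``"R/V"`` (reference allele first) when polymorphic; samples without
    an entry show the reference allele.  Construction is deterministic and
    order-invariant in samples.
    """
    import pandas as pd

    positions = list(positions)
    if positions != sorted(positions):
        raise ValueError("positions must be sorted ascending")
    rows: dict[str, list[str]] = {
        reference_row: [reference_alleles[p] for p in positions]
    }
    for name in samples:
        cells = []
        for p in positions:
            ref = reference_alleles[p]
            obs = list(dict.fromkeys(samples[name].get(p, [ref])))
            if len(obs) == 1:
                cells.append(obs[0])
            else:
                variants = sorted(a for a in obs if a != ref)
                cells.append("/".join([ref] + variants) if ref in obs
                             else "/".join(sorted(obs)))
        rows[name] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=positions)


@dataclass
class NumtMatchResult:
    """Residue-by-residue comparison of a variant haplotype against a numt."""

    matched: int
    total: int
    gap_positions: tuple[int, ...]  # variant positions falling in alignment gaps
    private_edits: int  # numt differences from the reference outside the sites

    @property
    def perfect(self) -> bool:
        return self.matched == self.total

    @property
    def label(self) -> str:
        return "numt-consistent" if self.perfect else "heteroplasmy-consistent"


def match_haplotype_to_numt(
    variant_alleles: Mapping[int, str],
    numt_seq: str,
    reference: str,
    window: tuple[int, int],
) -> NumtMatchResult:
    """Compare called variant alleles with the residues of a candidate numt.

    The numt is aligned to the cognate reference window; at every variant
    position the numt residue is compared with the variant allele.  A
    position falling into an alignment gap counts as unmatched and is
    flagged.  Differences between numt and reference *outside* the variant
    positions (numt-private substitutions or indel events) are also counted:
    a perfectly matching numt with no private edits is indistinguishable
    from the variant molecule class.
    """
    validate_nucleotides(numt_seq, "numt sequence")
    cover = _positions_from_sequence(numt_seq, reference, window)
    for p in variant_alleles:
        if not window[0] <= p <= window[1]:
            raise ValueError(f"variant position {p} outside window {window}")
    matched = 0
    gaps: list[int] = []
    for p, allele in variant_alleles.items():
        residue = cover.get(p, GAP)
        if residue in (GAP, "*"):
            gaps.append(p)
        elif residue == allele.upper():
            matched += 1
    private = 0
    in_del = False
    for p in range(window[0], window[1] + 1):
        if p in variant_alleles:
            in_del = False
            continue
        residue = cover.get(p, GAP)
        if residue == "*":
            if not in_del:  # one deletion event, however long
                private += 1
            in_del = True
        else:
            in_del = False
            if residue != GAP and residue != reference[p - 1].upper():
                private += 1
    # insertion events private to the numt
    res = edlib.align(numt_seq.upper(),
                      reference[window[0] - 1 : window[1]].upper(),
                      mode="NW", task="path")
    num = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            if ch == "I":
                private += 1
            num = 0
    return NumtMatchResult(
        matched=matched,
        total=len(variant_alleles),
        gap_positions=tuple(sorted(gaps)),
        private_edits=private,
    )
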