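"""Read mapping, per-site base composition and intra-individual site calling.

An intra-individual polymorphic site is a reference position where reads
from a *single* individual show a non-reference allele at or above a
fraction threshold (default 1% of total coverage) with a minimum read
support (default 10 reads, interpreting the "fewer than ~10 reads are
artifacts" floor).  At organelle sequencing depths these thresholds sit
exactly where cross-mapped reads from a single-copy numt land (about
``1/(r+1)`` of coverage at an mtDNA:nuDNA copy ratio of r:1), so called
sites are candidates for *either* heteroplasmy or numt contamination and
must be interpreted against a homology partition of the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from numtscan._sequtil import encode_bases, revcomp, validate_nucleotides
from numtscan.homology import CategoryPartition
from numtscan.simulate import ReadSet

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class Alignment:
    """A placed read: 1-based leftmost reference position plus CIGAR.

    CIGAR operations are SAM-style: ``M`` consumes read and reference
    (matches and mismatches), ``I``/``S`` consume read only, ``D`` consumes
    reference only.  Soft clips (``S``) mark read ends trimmed by the
    local-alignment refinement; clipped bases never enter the pileup.
    """

    read_id: str
    pos: int
    strand: str
    cigar: tuple[tuple[str, int], ...]
    seq: str
    edit_distance: int
    mapped: bool = True

    @classmethod
    def unmapped(cls, read_id: str, seq: str) -> "Alignment":
        return cls(read_id=read_id, pos=0, strand=".", cigar=(),
                   seq=seq, edit_distance=-1, mapped=False)


def _parse_edlib_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops: list[tuple[str, int]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            op = "M" if ch in "=XM" else ch
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))
            n = 0
    return tuple(ops)


_COL_SCORE = {"=": 1, "X": -4, "I": -6, "D": -6}


def _softclip(cigar: str, pos0: int, min_anchor: int = 25
              ) -> tuple[int, tuple[tuple[str, int], ...], int] | None:
    """Trim low-quality alignment ends, local-aligner style.

    Takes the extended-cigar string of a full-query alignment, finds the
    maximal-scoring contiguous stretch of columns (match +1, mismatch -4,
    gap -6) and soft-clips everything outside it, so a read crossing a
    homology boundary contributes only its homologous part to the pileup.
    Returns (new 0-based ref pos, cigar with S ops, matched columns) or
    None when fewer than ``min_anchor`` columns survive.
    """
    cols: list[str] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            cols.extend(ch * n)
            n = 0
    # maximal-scoring subarray (Kadane) over column scores
    best = cur = 0
    best_lo = best_hi = cur_lo = 0
    for i, c in enumerate(cols):
        s = _COL_SCORE[c]
        if cur <= 0:
            cur = s
            cur_lo = i
        else:
            cur += s
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    kept = cols[best_lo:best_hi]
    matched = sum(c in "=X" for c in kept)
    if matched < min_anchor:
        return None
    pre_q = sum(c in "=XI" for c in cols[:best_lo])
    pre_r = sum(c in "=XD" for c in cols[:best_lo])
    post_q = sum(c in "=XI" for c in cols[best_hi:])
    ops: list[tuple[str, int]] = []
    if pre_q:
        ops.append(("S", pre_q))
    for c in kept:
        op = "M" if c in "=X" else c
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if post_q:
        ops.append(("S", post_q))
    return pos0 + pre_r, tuple(ops), matched


def map_reads_lightweight(
    reads: ReadSet | Iterable[tuple[str, str]],
    reference: str,
    k: int = 21,
    max_edits: int = 12,
    max_candidates: int = 4,
    seed: int = 0,
) -> list[Alignment]:
    """Place each read at its best k-mer-seeded, edit-bounded location.

    Seeds are exact ``k``-mers taken at ``k``-spaced offsets along the read
    (both strands); each candidate placement is verified by a bounded
    edit-distance alignment against a padded reference window and the
    lowest-distance placement wins.  Ties break deterministically toward
    the smaller reference position, then the forward strand (``seed`` is
    accepted for interface stability; tie-breaking does not consume
    randomness).  Alignment ends are then soft-clipped to the maximal-
    scoring stretch, so reads crossing a homology boundary contribute only
    their homologous part.  Reads without a qualifying placement are
    flagged unmapped.
    """
    validate_nucleotides(reference, "reference")
    reference = reference.upper()
    del seed  # deterministic tie-break; kept for interface stability
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)

    if isinstance(reads, ReadSet):
        read_iter: Iterable[tuple[str, str]] = reads.iter_reads()
    else:
        read_iter = reads

    pad = 8
    out: list[Alignment] = []
    for read_id, seq in read_iter:
        L = len(seq)
        if L > len(reference):
            raise ValueError("read longer than reference")
        best: tuple[int, int, int, str, str] | None = None  # dist,pos,_,strand,cigar
        for strand in "+-":
            s = seq.upper() if strand == "+" else revcomp(seq.upper())
            votes: dict[int, int] = {}
            offsets = set(range(0, L - k + 1, k))
            offsets.add(L - k)
            for off in offsets:
                for p in index.get(s[off : off + k], ()):
                    cand = p - off
                    votes[cand] = votes.get(cand, 0) + 1
            for cand in sorted(votes, key=lambda c: (-votes[c], c))[:max_candidates]:
                w0 = max(0, cand - pad)
                w1 = min(len(reference), cand + L + pad)
                res = edlib.align(s, reference[w0:w1], mode="HW",
                                  task="path", k=max_edits)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                key = (res["editDistance"], w0 + loc[0], 0 if strand == "+" else 1)
                if best is None or key < (best[0], best[1], 0 if best[3] == "+" else 1):
                    best = (res["editDistance"], w0 + loc[0], 0, strand,
                            res["cigar"])
                if res["editDistance"] == 0:
                    break
            if best is not None and best[0] == 0:
                break
        if best is None:
            out.append(Alignment.unmapped(read_id, seq))
            continue
        dist, pos0, _, strand, cigar = best
        clipped = _softclip(cigar, pos0)
        if clipped is None:
            out.append(Alignment.unmapped(read_id, seq))
            continue
        new_pos0, ops, _ = clipped
        s = seq.upper() if strand == "+" else revcomp(seq.upper())
        out.append(
            Alignment(
                read_id=read_id,
                pos=new_pos0 + 1,
                strand=strand,
                cigar=ops,
                seq=s,
                edit_distance=dist,
            )
        )
    return out


@dataclass(frozen=True)
class SiteComposition:
    """Per-position base and indel evidence counts."""

    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int]  # A/C/G/T
    insertions: int  # events anchored at the position left of the insertion
    deletions: int  # reads deleting this position
    depth: int  # base counts + deletion evidence


@dataclass
class PileupTable:
    """Dense per-position composition over the whole reference."""

    reference: str
    base_counts: np.ndarray  # (L, 4) A,C,G,T
    insertions: np.ndarray  # (L,)
    deletions: np.ndarray  # (L,)
    n_used: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.deletions

    def site(self, pos: int) -> SiteComposition:
        i = pos - 1
        return SiteComposition(
            pos=pos,
            ref_base=self.reference[i],
            counts={b: int(self.base_counts[i, j]) for j, b in enumerate(_BASES)},
            insertions=int(self.insertions[i]),
            deletions=int(self.deletions[i]),
            depth=int(self.depth[i]),
        )

    def sites(self) -> list[SiteComposition]:
        return [self.site(p) for p in range(1, len(self.reference) + 1)]


def _alignments_from_sam(path: str | Path, reference: str,
                         ref_name: str | None = None,
                         deduplicate: bool = False) -> list[Alignment]:
    import pysam

    out: list[Alignment] = []
    seen: set[tuple[str, int]] = set()
    op_map = {0: "M", 7: "M", 8: "M", 1: "I", 2: "D"}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for sq in fh.header.get("SQ", []):
            if sq.get("LN") and int(sq["LN"]) != len(reference) and (
                ref_name is None or sq.get("SN") == ref_name
            ):
                raise ValueError(
                    f"alignment header reference {sq.get('SN')!r} has length "
                    f"{sq['LN']}, expected {len(reference)}"
                )
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            if ref_name is not None and rec.reference_name != ref_name:
                continue
            if deduplicate:
                key = (rec.reference_name or "", rec.reference_start)
                if key in seen:
                    continue
                seen.add(key)
            cigar: list[tuple[str, int]] = []
            seq = rec.query_sequence
            qpos = 0
            for op, n in rec.cigartuples or ():
                if op == 4:  # soft clip: trim from counted sequence
                    if not cigar:
                        seq = seq[n:]
                    else:
                        seq = seq[: len(seq) - n]
                    qpos += 0
                elif op in op_map:
                    cigar.append((op_map[op], n))
            out.append(
                Alignment(
                    read_id=rec.query_name or "",
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    cigar=tuple(cigar),
                    seq=seq,
                    edit_distance=rec.get_tag("NM") if rec.has_tag("NM") else 0,
                )
            )
    return out


def base_composition(
    alignments: Sequence[Alignment] | str | Path,
    reference: str,
    ref_name: str | None = None,
    deduplicate: bool = False,
) -> PileupTable:
    """Per-position A/C/G/T counts plus indel evidence over all reads.

    ``alignments`` may be internal :class:`Alignment` records or a path to a
    SAM/BAM file produced by an external mapper (the header's reference
    length must match, otherwise the file is rejected).  Insertions are
    counted at the anchor position left of the event; deletions are counted
    at every deleted position.
    """
    validate_nucleotides(reference, "reference")
    reference = reference.upper()
    if isinstance(alignments, (str, Path)):
        alignments = _alignments_from_sam(alignments, reference, ref_name,
                                          deduplicate)
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    ins = np.zeros(L, dtype=np.int64)
    dele = np.zeros(L, dtype=np.int64)
    flat: list[np.ndarray] = []
    n_used = 0
    for aln in alignments:
        if not aln.mapped:
            continue
        n_used += 1
        rpos = aln.pos - 1
        qpos = 0
        codes = encode_bases(aln.seq)
        for op, n in aln.cigar:
            if op == "M":
                c = codes[qpos : qpos + n]
                idx = np.arange(rpos, rpos + n)
                ok = c < 4
                if ok.any():
                    flat.append(idx[ok] * 4 + c[ok])
                rpos += n
                qpos += n
            elif op in ("I", "S"):
                if op == "I" and rpos > 0:
                    ins[rpos - 1] += 1
                qpos += n
            elif op == "D":
                dele[rpos : rpos + n] += 1
                rpos += n
        if len(flat) > 4096:
            counts += np.bincount(np.concatenate(flat),
                                  minlength=L * 4).reshape(L, 4)
            flat = []
    if flat:
        counts += np.bincount(np.concatenate(flat),
                              minlength=L * 4).reshape(L, 4)
    return PileupTable(reference=reference, base_counts=counts,
                       insertions=ins, deletions=dele, n_used=n_used)


@dataclass(frozen=True)
class VariantAllele:
    allele: str  # base, "INS" or "DEL"
    count: int
    fraction: float
    kind: str  # SNP | indel


@dataclass(frozen=True)
class PolymorphicSite:
    pos: int
    ref: str
    alleles: tuple[VariantAllele, ...]

    @property
    def kind(self) -> str:
        return "SNP" if any(a.kind == "SNP" for a in self.alleles) else "indel"

    @property
    def max_fraction(self) -> float:
        return max(a.fraction for a in self.alleles)


def call_intraindividual_sites(
    pileup: PileupTable,
    min_fraction: float = 0.01,
    min_reads: int = 10,
) -> list[PolymorphicSite]:
    """Extract sites with a non-reference allele above both thresholds.

    A site is emitted iff some non-reference allele reaches
    ``fraction >= min_fraction`` of the total coverage *and*
    ``count >= min_reads``; the fraction denominator is total depth
    including deletion evidence.  Every qualifying allele is listed
    (per-allele thresholding); SNP and indel alleles are flagged
    separately.  Zero-depth positions are skipped (count logged).
    """
    L = len(pileup.reference)
    depth = pileup.depth
    zero = int((depth == 0).sum())
    if zero:
        logger.info("skipping %d zero-depth positions", zero)

    ref_codes = encode_bases(pileup.reference)
    nonref = pileup.base_counts.copy()
    valid = ref_codes < 4
    nonref[np.arange(L)[valid], ref_codes[valid]] = 0
    evidence = np.maximum(nonref.max(axis=1),
                          np.maximum(pileup.insertions, pileup.deletions))
    cand = np.flatnonzero((evidence >= min_reads) & (depth > 0))

    out: list[PolymorphicSite] = []
    for i in cand:
        d = int(depth[i])
        alleles: list[VariantAllele] = []
        for j, b in enumerate(_BASES):
            c = int(nonref[i, j])
            frac = c / d
            if c >= min_reads and frac >= min_fraction:
                alleles.append(VariantAllele(b, c, frac, "SNP"))
        for label, c in (("INS", int(pileup.insertions[i])),
                         ("DEL", int(pileup.deletions[i]))):
            frac = c / d
            if c >= min_reads and frac >= min_fraction:
                alleles.append(VariantAllele(label, c, frac, "indel"))
        if alleles:
            out.append(PolymorphicSite(pos=int(i) + 1,
                                       ref=pileup.reference[i],
                                       alleles=tuple(alleles)))
    return out


def restrict_to_category(
    sites: Sequence[PolymorphicSite],
    partition: CategoryPartition,
    categories: Iterable[int] = (2,),
) -> list[PolymorphicSite]:
    """Keep only sites whose position falls in the given partition categories.

    Restricting to category 2 (unique, single-copy, no nuclear or plastid
    homology) is the standard guard against cross-mapping artifacts -- but
    it is only as good as the nuclear reference behind the partition.
    """
    cats = set(categories)
    for s in sites:
        if not 1 <= s.pos <= len(partition):
            raise ValueError(f"site position {s.pos} outside partition")
    return [s for s in sites if partition.category_of(s.pos) in cats]


def shared_sites(
    sites_a: Sequence[PolymorphicSite],
    sites_b: Sequence[PolymorphicSite],
    by_allele: bool = False,
) -> list[int]:
    """Positions polymorphic in both samples (optionally same variant allele)."""
    if not by_allele:
        shared = {s.pos for s in sites_a} & {s.pos for s in sites_b}
    else:
        a = {(s.pos, v.allele) for s in sites_a for v in s.alleles}
        b = {(s.pos, v.allele) for s in sites_b for v in s.alleles}
        shared = {pos for pos, _ in a & b}
    return sorted(shared)


def sites_to_frame(sites: Sequence[PolymorphicSite],
                   partition: CategoryPartition | None = None):
    """Tabular (VCF-like) export of called sites."""
    import pandas as pd

    rows = []
    for s in sites:
        for v in s.alleles:
            rows.append(
                {
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": v.allele,
                    "alt_count": v.count,
                    "fraction": round(v.fraction, 5),
                    "class": v.kind,
                    "category": partition.category_of(s.pos) if partition else "",
                }
            )
    return pd.DataFrame(rows)
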