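"""Local homology search and the eight-category partition of an mtDNA reference.

A plant mtDNA reference can be dissected by three booleans per position --
homologous to another region of the same mtDNA (a repeat), homologous to
nuclear DNA, homologous to plastid DNA -- giving eight categories:

====  ======  ======  ======
cat   repeat  nuDNA   ptDNA
====  ======  ======  ======
1     yes     no      no
2     no      no      no
3     yes     yes     no
4     no      yes     no
5     yes     no      yes
6     no      no      yes
7     yes     yes     yes
8     no      yes     yes
====  ======  ======  ======

Category 2 ("unique and single-copy") is the only compartment where an
intra-individual polymorphic site cannot be explained by cross-mapping from
a *known* homolog -- which is why polymorphism scans are restricted to it,
and why numts missing from the chosen nuclear reference are so misleading.

The homology engine is a k-mer seed / chain / X-drop-extend search with
edit-distance refinement; alignments shorter than ``min_len`` (default
100 bp) or below ``min_identity`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from numtscan._sequtil import revcomp, validate_nucleotides

#: category id indexed by (repeat<<2 | nu<<1 | pt)
_CATEGORY_LUT = np.array([2, 6, 4, 8, 1, 5, 3, 7], dtype=np.int8)

REPEATED_CATEGORIES = (1, 3, 5, 7)
SINGLE_COPY_CATEGORIES = (2, 4, 6, 8)
NU_HOMOLOGOUS_CATEGORIES = (3, 4, 7, 8)
PT_HOMOLOGOUS_CATEGORIES = (5, 6, 7, 8)
UNIQUE_CATEGORIES = (1, 2)


@dataclass(frozen=True)
class HomologyInterval:
    """A located local alignment between the query and a subject sequence.

    Coordinates are 1-based inclusive; subject coordinates always refer to
    the forward strand of the subject, with ``strand`` recording the
    orientation of the alignment.
    """

    qstart: int
    qend: int
    subject: str
    sstart: int
    send: int
    strand: str
    identity: float
    aligned_length: int


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _xdrop_extend(q: str, s: str, q0: int, q1: int, s0: int, s1: int,
                  match: int = 1, mismatch: int = -3, xdrop: int = 12
                  ) -> tuple[int, int, int, int]:
    """Extend an ungapped anchor [q0,q1) x [s0,s1) in both directions."""
    # right
    score = best = 0
    bi = 0
    i = 0
    while q1 + i < len(q) and s1 + i < len(s):
        score += match if q[q1 + i] == s[s1 + i] else mismatch
        if score > best:
            best, bi = score, i + 1
        elif score < best - xdrop:
            break
        i += 1
    q1 += bi
    s1 += bi
    # left
    score = best = 0
    bi = 0
    i = 1
    while q0 - i >= 0 and s0 - i >= 0:
        score += match if q[q0 - i] == s[s0 - i] else mismatch
        if score > best:
            best, bi = score, i
        elif score < best - xdrop:
            break
        i += 1
    return q0 - bi, q1, s0 - bi, s1


def find_local_homologies(
    query: str,
    subject: str,
    min_len: int = 100,
    min_identity: float = 0.80,
    subject_name: str = "subject",
    k: int = 15,
    diag_band: int = 20,
    max_chain_gap: int = 60,
) -> list[HomologyInterval]:
    """Locate maximal local homologies between ``query`` and ``subject``.

    Both strands are searched.  When the two sequences are identical
    (self-comparison) the trivial full-length identity diagonal is excluded,
    so only genuine internal repeats are reported.

    Exact ``k``-mer seed matches are chained when they lie on nearby
    diagonals (within ``diag_band``) and within ``max_chain_gap`` on the
    query; each chain is extended without gaps under an X-drop rule and its
    identity refined by a banded edit-distance alignment.
    """
    validate_nucleotides(query, "query")
    validate_nucleotides(subject, "subject")
    if min_len < k:
        raise ValueError(f"min_len must be >= k-mer size ({k})")
    query = query.upper()
    subject = subject.upper()
    self_mode = query == subject

    qindex = _kmer_index(query, k)
    out: list[HomologyInterval] = []

    for strand in "+-":
        s_seq = subject if strand == "+" else revcomp(subject)
        # seed pairs (qpos, spos), 0-based
        seeds: list[tuple[int, int]] = []
        for j in range(len(s_seq) - k + 1):
            for i in qindex.get(s_seq[j : j + k], ()):
                if self_mode and strand == "+" and i == j:
                    continue
                seeds.append((i, j))
        if not seeds:
            continue
        # chain seeds sorted by (diagonal, query position)
        seeds.sort(key=lambda t: (t[1] - t[0], t[0]))
        chains: list[list[tuple[int, int]]] = []
        cur: list[tuple[int, int]] = [seeds[0]]
        for q, s in seeds[1:]:
            pd = cur[-1][1] - cur[-1][0]
            if abs((s - q) - pd) <= diag_band and 0 <= q - cur[-1][0] <= max_chain_gap + k:
                cur.append((q, s))
            else:
                chains.append(cur)
                cur = [(q, s)]
        chains.append(cur)

        for chain in chains:
            q0 = min(q for q, _ in chain)
            q1 = max(q for q, _ in chain) + k
            s0 = min(s for _, s in chain)
            s1 = max(s for _, s in chain) + k
            q0, q1, s0, s1 = _xdrop_extend(query, s_seq, q0, q1, s0, s1)
            qlen = q1 - q0
            slen = s1 - s0
            if max(qlen, slen) < min_len:
                continue
            res = edlib.align(query[q0:q1], s_seq[s0:s1], mode="NW", task="distance")
            identity = 1.0 - res["editDistance"] / max(qlen, slen)
            if identity < min_identity:
                continue
            if strand == "+":
                sstart, send = s0 + 1, s1
            else:
                sstart, send = len(subject) - s1 + 1, len(subject) - s0
            out.append(
                HomologyInterval(
                    qstart=q0 + 1,
                    qend=q1,
                    subject=subject_name,
                    sstart=sstart,
                    send=send,
                    strand=strand,
                    identity=round(identity, 4),
                    aligned_length=qlen,
                )
            )
    return _suppress_contained(out)


def _suppress_contained(hits: list[HomologyInterval]) -> list[HomologyInterval]:
    """Drop hits whose query and subject spans lie inside another hit."""
    hits = sorted(hits, key=lambda h: (h.qend - h.qstart), reverse=True)
    kept: list[HomologyInterval] = []
    for h in hits:
        contained = any(
            h.strand == o.strand
            and o.qstart <= h.qstart and h.qend <= o.qend
            and o.sstart <= h.sstart and h.send <= o.send
            for o in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.qstart, h.qend, h.sstart))
    return kept


@dataclass
class CategoryPartition:
    """Per-position 1..8 category labels over the mtDNA reference."""

    labels: np.ndarray  # int8, length = reference length

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    def category_of(self, pos: int) -> int:
        """Category at a 1-based reference position."""
        return int(self.labels[pos - 1])

    def totals(self) -> dict[int, int]:
        counts = np.bincount(self.labels, minlength=9)
        return {c: int(counts[c]) for c in range(1, 9)}

    def intervals(self) -> list[tuple[int, int, int]]:
        """Maximal runs of equal category as (start, end, category), 1-based."""
        lab = self.labels
        if len(lab) == 0:
            return []
        breaks = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(lab)]))
        return [(int(s) + 1, int(e), int(lab[s])) for s, e in zip(starts, ends)]

    def to_bed(self, path, chrom: str = "mt") -> None:
        """BED export (0-based half-open, name = category)."""
        with open(path, "w") as fh:
            for start, end, cat in self.intervals():
                fh.write(f"{chrom}\t{start - 1}\t{end}\tcategory{cat}\n")


def _coverage_mask(length: int, hits: Iterable[HomologyInterval]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for h in hits:
        if not (1 <= h.qstart <= h.qend <= length):
            raise ValueError(
                f"hit interval {h.qstart}-{h.qend} outside reference of "
                f"length {length}"
            )
        mask[h.qstart - 1 : h.qend] = True
    return mask


def classify_categories(
    mt_length: int,
    self_hits: Sequence[HomologyInterval],
    nu_hits: Sequence[HomologyInterval],
    pt_hits: Sequence[HomologyInterval],
) -> CategoryPartition:
    """Label every mtDNA position with its homology category (1..8).

    Overlapping hits within one evidence class are unioned first; only the
    per-position boolean matters for the partition.
    """
    rep = _coverage_mask(mt_length, self_hits)
    nu = _coverage_mask(mt_length, nu_hits)
    pt = _coverage_mask(mt_length, pt_hits)
    idx = (rep.astype(np.int8) << 2) | (nu.astype(np.int8) << 1) | pt.astype(np.int8)
    return CategoryPartition(labels=_CATEGORY_LUT[idx])


@dataclass
class PartitionSummary:
    """Aggregates over the eight homology categories.

    All derived sums come from the same per-category totals: repeated bp is
    the sum of categories 1,3,5,7; single-copy of 2,4,6,8; nuclear-
    homologous of 3,4,7,8; plastid-homologous of 5,6,7,8; unique (no
    homology to nuclear or plastid DNA) of 1,2.  Percentages are reported to
    the nearest 1%.
    """

    per_category: dict[int, int]
    total_bp: int = field(init=False)
    repeated_bp: int = field(init=False)
    single_copy_bp: int = field(init=False)
    nu_homologous_bp: int = field(init=False)
    pt_homologous_bp: int = field(init=False)
    unique_bp: int = field(init=False)
    pct_nu_homologous: int = field(init=False)
    pct_pt_homologous: int = field(init=False)
    pct_pt_with_nu: int | None = field(init=False)

    def __post_init__(self):
        c = {cat: int(self.per_category.get(cat, 0)) for cat in range(1, 9)}
        self.per_category = c
        self.total_bp = sum(c.values())
        self.repeated_bp = sum(c[i] for i in REPEATED_CATEGORIES)
        self.single_copy_bp = sum(c[i] for i in SINGLE_COPY_CATEGORIES)
        self.nu_homologous_bp = sum(c[i] for i in NU_HOMOLOGOUS_CATEGORIES)
        self.pt_homologous_bp = sum(c[i] for i in PT_HOMOLOGOUS_CATEGORIES)
        self.unique_bp = sum(c[i] for i in UNIQUE_CATEGORIES)
        self.pct_nu_homologous = (
            int(round(100 * self.nu_homologous_bp / self.total_bp))
            if self.total_bp else 0
        )
        self.pct_pt_homologous = (
            int(round(100 * self.pt_homologous_bp / self.total_bp))
            if self.total_bp else 0
        )
        self.pct_pt_with_nu = (
            int(round(100 * (c[7] + c[8]) / self.pt_homologous_bp))
            if self.pt_homologous_bp else None
        )

    def as_frame(self):
        import pandas as pd

        rows = [
            {"category": cat, "bp": bp} for cat, bp in self.per_category.items()
        ]
        rows.append({"category": "total", "bp": self.total_bp})
        return pd.DataFrame(rows)


def summarize_partition(
    partition: CategoryPartition | dict[int, int],
) -> PartitionSummary:
    """Summarize a partition (or raw per-category bp totals)."""
    if isinstance(partition, CategoryPartition):
        totals = partition.totals()
    else:
        totals = dict(partition)
    return PartitionSummary(per_category=totals)


def depth_flag_pt_homology(
    depth_track: Sequence[int] | np.ndarray, threshold: int = 10_000
) -> list[tuple[int, int]]:
    """Flag plastid-homologous regions from mapped read depth.

    Plastid DNA is present in large per-cell excess, so mtDNA positions with
    read depth *strictly greater than* ``threshold`` (default 10,000) are
    flagged.  Returns maximal runs as 1-based inclusive intervals.
    """
    depth = np.asarray(depth_track)
    if (depth < 0).any():
        raise ValueError("negative depth in track")
    above = depth > threshold
    if not above.any():
        return []
    diff = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return [(int(s) + 1, int(e)) for s, e in zip(starts, ends)]
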