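"""Tiling presence/absence scan of an mtDNA reference against nuclear assemblies.

The mtDNA reference is cut into consecutive 50-bp tiles and each tile is
searched in every nuclear assembly; a tile is *positive* for an assembly
when some local alignment covers the full tile at or above an identity
threshold.  Comparing the positive/negative columns across assemblies
exposes the reference dependency of numt detection: a numt present in one
line and absent from another shows up as a discordant column, and a
heteroplasmy study that consulted only the numt-lacking assembly would
misread the cross-mapped reads as heteroplasmy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import multimode
from typing import Mapping, Sequence

import edlib
import numpy as np

from numtscan._sequtil import revcomp, validate_nucleotides


@dataclass(frozen=True)
class Tile:
    index: int
    start: int  # 1-based inclusive on the mtDNA reference
    end: int
    sequence: str


@dataclass(frozen=True)
class TileHit:
    """Best alignment of a tile in one subject (forward-strand coordinates)."""

    sstart: int
    send: int
    strand: str
    identity: float


@dataclass
class PresenceAbsenceMatrix:
    tiles: list[Tile]
    references: list[str]
    positive: np.ndarray  # bool, (n_tiles, n_refs)
    best_hits: list[list[TileHit | None]]  # [tile][ref]
    min_identity: float
    min_cov: float

    def to_frame(self):
        import pandas as pd

        data = {
            "tile": [t.index for t in self.tiles],
            "mt_start": [t.start for t in self.tiles],
            "mt_end": [t.end for t in self.tiles],
        }
        for j, ref in enumerate(self.references):
            data[ref] = self.positive[:, j].astype(int)
            data[f"{ref}_identity"] = [
                h.identity if h else np.nan
                for h in (row[j] for row in self.best_hits)
            ]
        return pd.DataFrame(data)


@dataclass
class NumtInterval:
    """A merged run of positive tiles for one nuclear reference."""

    reference: str
    mt_start: int
    mt_end: int
    tile_indices: tuple[int, ...]
    subject_start: int
    subject_end: int
    cluster_id: int | None = None
    solitary: bool | None = None

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start + 1


def tile_reference(
    mt_seq: str, tile_len: int = 50, step: int = 50, min_remainder: int = 20
) -> list[Tile]:
    """Cut the reference into consecutive tiles.

    A terminal remainder shorter than ``min_remainder`` is merged into the
    previous tile (tiny queries produce spurious matches); a remainder of at
    least ``min_remainder`` bp is kept as its own shorter tile.
    """
    validate_nucleotides(mt_seq, "mt reference")
    if tile_len < 20:
        raise ValueError("tile_len must be >= 20")
    if step < 1:
        raise ValueError("step must be >= 1")
    L = len(mt_seq)
    tiles: list[Tile] = []
    starts = list(range(0, L, step))
    for i, s in enumerate(starts):
        e = min(s + tile_len, L)
        if e - s < min_remainder and tiles and step >= tile_len:
            prev = tiles.pop()
            tiles.append(Tile(prev.index, prev.start, L,
                              mt_seq[prev.start - 1 : L]))
            break
        if s >= L:
            break
        tiles.append(Tile(len(tiles), s + 1, e, mt_seq[s:e]))
        if e == L:
            break
    return tiles


def scan_tiles(
    tiles: Sequence[Tile],
    nuclear_refs: Mapping[str, str],
    min_identity: float = 0.90,
    min_cov: float = 0.90,
) -> PresenceAbsenceMatrix:
    """Search every tile in every nuclear reference, both strands.

    A cell is positive iff an alignment covering the full tile (coverage 1,
    which satisfies any ``min_cov`` <= 1) reaches ``identity >= min_identity``
    where identity = 1 - edit distance / tile length.  The hit criterion is
    therefore monotone: raising ``min_identity`` can only turn positives
    negative.  The matrix does not depend on reference processing order.
    """
    if not nuclear_refs:
        raise ValueError("no nuclear references given")
    if not 0 < min_cov <= 1:
        raise ValueError("min_cov must be in (0, 1]")
    refs = sorted(nuclear_refs)
    positive = np.zeros((len(tiles), len(refs)), dtype=bool)
    best_hits: list[list[TileHit | None]] = [
        [None] * len(refs) for _ in tiles
    ]
    for j, name in enumerate(refs):
        subject = nuclear_refs[name].upper()
        validate_nucleotides(subject, name)
        for i, tile in enumerate(tiles):
            n = len(tile.sequence)
            k_allow = int(np.floor((1.0 - min_identity) * n))
            best: TileHit | None = None
            for strand in "+-":
                q = tile.sequence if strand == "+" else revcomp(tile.sequence)
                res = edlib.align(q, subject, mode="HW", task="locations",
                                  k=k_allow)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                identity = 1.0 - res["editDistance"] / n
                if best is None or identity > best.identity:
                    best = TileHit(
                        sstart=loc[0] + 1,
                        send=loc[1] + 1,
                        strand=strand,
                        identity=round(identity, 4),
                    )
            if best is not None:
                positive[i, j] = True
                best_hits[i][j] = best
    return PresenceAbsenceMatrix(
        tiles=list(tiles),
        references=refs,
        positive=positive,
        best_hits=best_hits,
        min_identity=min_identity,
        min_cov=min_cov,
    )


def merge_positive_tiles(
    matrix: PresenceAbsenceMatrix, max_gap_tiles: int = 1
) -> dict[str, list[NumtInterval]]:
    """Merge consecutive positive tiles into maximal numt-homologous intervals.

    Runs of positive tiles separated by at most ``max_gap_tiles`` negative
    tiles are merged (short drop-outs from divergence within one numt).
    """
    out: dict[str, list[NumtInterval]] = {}
    for j, ref in enumerate(matrix.references):
        pos_idx = np.flatnonzero(matrix.positive[:, j])
        intervals: list[NumtInterval] = []
        run: list[int] = []
        for idx in pos_idx:
            if run and idx - run[-1] - 1 > max_gap_tiles:
                intervals.append(_make_interval(matrix, ref, j, run))
                run = []
            run.append(int(idx))
        if run:
            intervals.append(_make_interval(matrix, ref, j, run))
        out[ref] = intervals
    return out


def _make_interval(matrix: PresenceAbsenceMatrix, ref: str, j: int,
                   run: list[int]) -> NumtInterval:
    tiles = matrix.tiles
    hits = [matrix.best_hits[i][j] for i in run if matrix.best_hits[i][j]]
    return NumtInterval(
        reference=ref,
        mt_start=tiles[run[0]].start,
        mt_end=tiles[run[-1]].end,
        tile_indices=tuple(run),
        subject_start=min(h.sstart for h in hits),
        subject_end=max(h.send for h in hits),
    )


@dataclass(frozen=True)
class SizeStats:
    mean: int
    mode: int
    median: float


def numt_size_stats(
    lengths: Sequence[int], median_rule: str = "lower"
) -> SizeStats:
    """Mean / mode / median of numt lengths in bp.

    Mean is rounded to the nearest bp; ties in the mode resolve to the
    smallest length.  ``median_rule`` picks the convention for even counts:
    ``"lower"`` (default) takes the lower of the two middle values,
    ``"interpolate"`` averages them.
    """
    if not lengths:
        raise ValueError("no numt intervals: size statistics undefined")
    arr = sorted(int(x) for x in lengths)
    mean = int(np.floor(np.mean(arr) + 0.5))
    mode = min(multimode(arr))
    n = len(arr)
    if median_rule == "lower":
        median: float = arr[(n - 1) // 2]
    elif median_rule == "interpolate":
        median = float(np.median(arr))
    else:
        raise ValueError("median_rule must be 'lower' or 'interpolate'")
    return SizeStats(mean=mean, mode=mode, median=median)


def classify_solitary_clustered(
    intervals: Sequence[NumtInterval], cluster_gap: int = 5_000
) -> list[NumtInterval]:
    """Single-linkage clustering of numt intervals along the subject.

    Intervals whose nearest neighbour on the subject lies within
    ``cluster_gap`` bp share a cluster; singleton clusters are flagged
    solitary.  Returns new intervals annotated with ``cluster_id`` and
    ``solitary``; input order is preserved.
    """
    order = sorted(range(len(intervals)),
                   key=lambda i: intervals[i].subject_start)
    cluster_of: dict[int, int] = {}
    cluster_members: dict[int, int] = {}
    cid = -1
    prev_end: int | None = None
    for i in order:
        iv = intervals[i]
        if prev_end is None or iv.subject_start - prev_end - 1 > cluster_gap:
            cid += 1
            prev_end = iv.subject_end
        else:
            prev_end = max(prev_end, iv.subject_end)
        cluster_of[i] = cid
        cluster_members[cid] = cluster_members.get(cid, 0) + 1
    out = []
    for i, iv in enumerate(intervals):
        cid = cluster_of[i]
        out.append(
            NumtInterval(
                reference=iv.reference,
                mt_start=iv.mt_start,
                mt_end=iv.mt_end,
                tile_indices=iv.tile_indices,
                subject_start=iv.subject_start,
                subject_end=iv.subject_end,
                cluster_id=cid,
                solitary=cluster_members[cid] == 1,
            )
        )
    return out
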