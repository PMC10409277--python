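"""In-silico PCR-RFLP assay and exact multinomial segregation test.

A presence/absence numt can be proven nuclear by Mendelian genetics: a
primer pair anchored in the flanking nuclear sequence amplifies the locus,
a restriction site difference between the two parental alleles produces
distinct fragment patterns (RFLP), and in an F2 population a nuclear locus
must segregate 1 homozygote : 2 heterozygotes : 1 homozygote.  An organelle
locus would not.  The goodness-of-fit test here is an exact multinomial
test: the p-value is the total probability, under the hypothesized ratio,
of all genotype-count outcomes no more probable than the observed one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from numtscan._sequtil import iupac_regex, revcomp, validate_nucleotides


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a template (1-based inclusive interval)."""

    start: int
    end: int
    strand: str  # strand the forward primer annealed to
    sequence: str  # in amplification orientation (starts with the fwd primer)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _match_positions(template: np.ndarray, primer: str,
                     max_mismatches: int) -> list[int]:
    """0-based start positions where ``primer`` binds with <= mismatches."""
    p = np.frombuffer(primer.encode("ascii"), dtype=np.uint8)
    L, n = len(template), len(p)
    if n > L:
        return []
    mism = np.zeros(L - n + 1, dtype=np.int32)
    for i in range(n):
        mism += template[i : L - n + i + 1] != p[i]
    return [int(i) for i in np.flatnonzero(mism <= max_mismatches)]


def extract_amplicon(
    template: str,
    fwd: str,
    rev: str,
    max_mismatches: int = 0,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    For each forward-primer binding site the *shortest* product ending at a
    reverse-complemented reverse-primer site is reported; both template
    strands are searched.  An empty list means "no amplification" -- the
    expected outcome when a line lacks the numt allele, not an error.
    """
    validate_nucleotides(template, "template")
    for name, p in (("forward primer", fwd), ("reverse primer", rev)):
        validate_nucleotides(p, name)
        if len(p) < 15:
            raise ValueError(f"{name} shorter than 15 nt")
    template = template.upper()
    products: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for strand in "+-":
        t = template if strand == "+" else revcomp(template)
        arr = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
        f_sites = _match_positions(arr, fwd.upper(), max_mismatches)
        r_sites = _match_positions(arr, revcomp(rev.upper()), max_mismatches)
        for f in f_sites:
            downstream = [r for r in r_sites if r >= f + len(fwd)]
            if not downstream:
                continue
            r = min(downstream)
            a0, a1 = f, r + len(rev) - 1  # 0-based on strand t
            if strand == "+":
                start, end = a0 + 1, a1 + 1
            else:
                start, end = len(template) - a1, len(template) - a0
            if (start, end) in seen:
                continue
            seen.add((start, end))
            products.append(
                Amplicon(start=start, end=end, strand=strand,
                         sequence=t[a0 : a1 + 1])
            )
    products.sort(key=lambda a: (a.start, a.end))
    return products


def digest(seq: str, motif: str, cut_offset: int | None = None) -> list[int]:
    """Fragment lengths after complete digestion at an IUPAC recognition motif.

    ``n`` recognition sites produce ``n + 1`` fragments, ordered along the
    sequence; fragment lengths always sum to the input length.  By default
    cuts are placed at the start of each motif occurrence -- at gel
    resolution the within-site cut offset is irrelevant -- but an explicit
    ``cut_offset`` (0-based within the motif) is honoured.
    """
    validate_nucleotides(seq, "sequence")
    seq = seq.upper()
    pattern = re.compile(f"(?=({iupac_regex(motif)}))")
    offset = 0 if cut_offset is None else int(cut_offset)
    if not 0 <= offset < len(motif):
        raise ValueError("cut_offset must lie within the motif")
    cuts = sorted(
        {
            m.start() + offset
            for m in pattern.finditer(seq)
            if 0 < m.start() + offset < len(seq)
        }
    )
    bounds = [0] + cuts + [len(seq)]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def _collapse_bands(lengths: Sequence[int], tol: float) -> list[int]:
    """Distinct gel bands: lengths within ``tol`` relative difference merge."""
    bands: list[int] = []
    for x in sorted(set(int(v) for v in lengths)):
        if bands and abs(x - bands[-1]) <= tol * max(x, bands[-1]):
            continue
        bands.append(x)
    return bands


def _patterns_equal(a: Sequence[int], b: Sequence[int], tol: float) -> bool:
    ba, bb = _collapse_bands(a, tol), _collapse_bands(b, tol)
    if len(ba) != len(bb):
        return False
    return all(abs(x - y) <= tol * max(x, y) for x, y in zip(ba, bb))


def genotype_individual(
    observed_fragments: Sequence[int],
    allele_patterns: Mapping[str, Sequence[int]],
    tolerance: float = 0.05,
) -> str:
    """Score one individual's fragment pattern against two parental alleles.

    Bands within ``tolerance`` relative length are treated as co-migrating
    (agarose-gel resolution).  The call is heterozygous when the observed
    pattern equals the union of both parental patterns, homozygous when it
    equals exactly one, and ``"unscorable"`` otherwise.
    """
    if len(allele_patterns) != 2:
        raise ValueError("exactly two parental allele patterns required")
    (name_a, pat_a), (name_b, pat_b) = allele_patterns.items()
    if _patterns_equal(pat_a, pat_b, tolerance):
        raise ValueError("parental fragment patterns are not distinct")
    union = list(pat_a) + list(pat_b)
    if _patterns_equal(observed_fragments, union, tolerance):
        return f"{name_a}/{name_b}"
    if _patterns_equal(observed_fragments, pat_a, tolerance):
        return f"{name_a}/{name_a}"
    if _patterns_equal(observed_fragments, pat_b, tolerance):
        return f"{name_b}/{name_b}"
    return "unscorable"


@lru_cache(maxsize=32)
def _outcome_weights(n: int, ratio: tuple[int, ...]) -> dict[tuple[int, ...], int]:
    """Integer weights W(x) = multinom(n;x) * prod r_i^x_i for all outcomes.

    P(x) = W(x) / R^n with R = sum(ratio), so comparing weights compares
    probabilities exactly, with no floating-point ties.
    """
    r1, r2, r3 = ratio
    out: dict[tuple[int, ...], int] = {}
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            w = (math.factorial(n) // (math.factorial(a) * math.factorial(b)
                                       * math.factorial(c)))
            out[(a, b, c)] = w * r1**a * r2**b * r3**c
    return out


def exact_multinomial_pvalue(
    counts: Sequence[int], ratio: Sequence[int] = (1, 2, 1)
) -> float:
    """Exact multinomial goodness-of-fit p-value.

    Sums, over every outcome ``(a, b, c)`` with ``a+b+c = n``, the
    probability under the hypothesized ratio of all outcomes whose
    probability is less than or equal to that of the observed outcome.
    Computed in exact integer arithmetic.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError("counts must be three non-negative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("total count must be >= 1")
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != 3 or any(r <= 0 for r in ratio):
        raise ValueError("ratio must be three positive integers")
    weights = _outcome_weights(n, ratio)
    w_obs = weights[counts]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(ratio) ** n))


@dataclass(frozen=True)
class SegregationResult:
    counts: tuple[int, int, int]
    ratio: tuple[int, int, int]
    p_exact: float
    p_chisq: float
    alpha: float
    reject: bool


def segregation_test(
    counts: Sequence[int],
    ratio: Sequence[int] = (1, 2, 1),
    alpha: float = 0.05,
) -> SegregationResult:
    """Test genotype counts against a Mendelian ratio (default 1:2:1).

    Reports the exact multinomial p-value (decision at ``alpha`` uses this)
    alongside a chi-square (df=2) comparison value, since published
    segregation analyses often quote one or the other without detail.
    """
    from scipy.stats import chisquare

    p_exact = exact_multinomial_pvalue(counts, ratio)
    n = sum(counts)
    expected = [n * r / sum(ratio) for r in ratio]
    p_chisq = float(chisquare(list(counts), f_exp=expected).pvalue)
    return SegregationResult(
        counts=tuple(int(c) for c in counts),
        ratio=tuple(int(r) for r in ratio),
        p_exact=p_exact,
        p_chisq=p_chisq,
        alpha=alpha,
        reject=p_exact < alpha,
    )
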