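"""Synthetic genome systems and copy-ratio-weighted paired-end reads.

The simulator emulates the situation faced when hunting for heteroplasmy in
total-cellular-DNA sequencing of a plant: a mitochondrial genome carrying
internal repeats and plastid-homologous blocks, one or more nuclear genomes
("lines") that may or may not carry numts slightly diverged from their
cognate mtDNA interval, and paired-end reads drawn from all three
compartments in proportion to per-cell copy number.  In green leaf tissue
the mtDNA:nuDNA copy ratio is around 40-60:1, so reads from a single-copy
numt amount to roughly ``1/(r+1)`` (about 2% at r=50) of the reads covering
the cognate mtDNA window -- the same order as a low-frequency heteroplasmic
allele, which is exactly why the two are confusable.

Every read records its true origin, so downstream stages can be scored
against ground truth.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from numtscan._sequtil import random_sequence, revcomp, validate_nucleotides

FEATURE_KINDS = ("mt_repeat", "pt_homolog_in_mt", "numt", "true_heteroplasmy_site")

#: constant placeholder base quality (Q37); quality filtering is upstream
#: preprocessing and deliberately not modelled here.
PLACEHOLDER_QUALITY = "F"


@dataclass(frozen=True)
class Edit:
    """One divergence edit inside a planted feature.

    ``offset`` is 1-based relative to the start of the feature's cognate
    interval.  ``op`` is ``sub`` (replace ``ref`` by ``alt``), ``ins``
    (insert ``alt`` after ``offset``) or ``del`` (delete ``ref`` starting at
    ``offset``).
    """

    offset: int
    op: str = "sub"
    ref: str = ""
    alt: str = ""

    def __post_init__(self):
        if self.op not in ("sub", "ins", "del"):
            raise ValueError(f"unknown edit op {self.op!r}")
        if self.offset < 1:
            raise ValueError("edit offset must be >= 1 (1-based)")


@dataclass
class PlantedFeature:
    """A feature planted into a synthetic genome system.

    ``host`` names the sequence the feature lives on: ``"mt"``, ``"pt"`` or
    ``"<line>:<chrom>"`` for nuclear hosts.  ``interval`` coordinates are
    1-based inclusive on the host; for kinds derived from mtDNA
    (``mt_repeat``, ``pt_homolog_in_mt``, ``numt``) ``cognate_interval``
    gives the source interval on the mtDNA reference and ``end`` may be left
    at 0 to be computed from the edited sequence length.
    """

    kind: str
    host: str
    start: int
    end: int = 0
    cognate_start: int = 0
    cognate_end: int = 0
    edits: tuple[Edit, ...] = ()
    alt_allele: str = ""
    het_frequency: float = 0.0
    molecule_class: str = ""
    name: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.het_frequency and self.kind != "true_heteroplasmy_site":
            raise ValueError("het_frequency > 0 only valid for true_heteroplasmy_site")
        if self.kind == "true_heteroplasmy_site":
            if not 0.0 < self.het_frequency < 1.0:
                raise ValueError(
                    "heteroplasmy frequency must lie strictly in (0, 1); "
                    "remove the site instead of using frequency 0"
                )
            if self.end == 0:
                self.end = self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def cognate_interval(self) -> tuple[int, int]:
        return (self.cognate_start, self.cognate_end)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the read simulator.

    Defaults follow the study conditions the package targets: 150-bp
    paired-end reads with ~350-bp inserts, a per-cell mtDNA:nuDNA copy
    ratio of 50:1 (middle of the 40-60:1 leaf estimate) and plastid DNA in
    roughly ten-fold excess over mtDNA (500:1 vs nuclear), which puts pt
    coverage past the >10,000x depth flag when mtDNA is sequenced around
    1,000x.
    """

    seed: int = 0
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.002
    copy_ratio_mt_nu: float = 50.0
    copy_ratio_pt_nu: float = 500.0
    mt_depth: float = 500.0
    circular_mt: bool = False

    def __post_init__(self):
        if self.copy_ratio_mt_nu <= 0 or self.copy_ratio_pt_nu <= 0:
            raise ValueError("copy ratios must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.read_len < 20:
            raise ValueError("read_len too short")
        if self.mt_depth < 0:
            raise ValueError("mt_depth must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class GenomeSystem:
    """Synthetic mt/pt/nuclear sequences plus planted-feature ground truth.

    ``nuclear`` maps line name -> {chromosome name -> sequence}.  Lines share
    chromosome backbones and differ only in numt presence/absence and numt
    allele edits, mirroring numt presence/absence polymorphism between
    closely related lines.
    """

    mt_seq: str
    pt_seq: str
    nuclear: dict[str, dict[str, str]]
    features: list[PlantedFeature] = field(default_factory=list)
    circular_mt: bool = False

    @property
    def lines(self) -> list[str]:
        return list(self.nuclear)

    def host_sequence(self, host: str, line: str | None = None) -> str:
        if host == "mt":
            return self.mt_seq
        if host == "pt":
            return self.pt_seq
        if ":" in host:
            ln, chrom = host.split(":", 1)
            return self.nuclear[ln][chrom]
        if line is not None:
            return self.nuclear[line][host]
        raise KeyError(f"cannot resolve host {host!r} without a line")

    def heteroplasmy_classes(self) -> dict[str, tuple[float, list[PlantedFeature]]]:
        """Group heteroplasmic sites by molecule class (coupling groups)."""
        classes: dict[str, tuple[float, list[PlantedFeature]]] = {}
        for f in self.features:
            if f.kind != "true_heteroplasmy_site":
                continue
            key = f.molecule_class or f"site{f.start}"
            if key in classes:
                freq, members = classes[key]
                if abs(freq - f.het_frequency) > 1e-12:
                    raise ValueError(
                        f"molecule class {key!r} mixes frequencies "
                        f"{freq} and {f.het_frequency}"
                    )
                members.append(f)
            else:
                classes[key] = (f.het_frequency, [f])
        return classes

    def numt_intervals(self, line: str) -> list[tuple[str, int, int]]:
        """(chrom, start, end) of planted numts on one line's nuclear genome."""
        out = []
        for f in self.features:
            if f.kind != "numt":
                continue
            ln, chrom = f.host.split(":", 1)
            if ln == line:
                out.append((chrom, f.start, f.end))
        return out

    def write_fasta(self, path: str | Path, line: str | None = None) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.mt_seq), id="mt", description=""),
            SeqRecord(Seq(self.pt_seq), id="pt", description=""),
        ]
        lines = [line] if line is not None else self.lines
        for ln in lines:
            for chrom, seq in self.nuclear[ln].items():
                records.append(
                    SeqRecord(Seq(seq), id=f"{ln}:{chrom}", description="")
                )
        SeqIO.write(records, str(path), "fasta")

    def write_truth(self, path: str | Path) -> None:
        """Serialize planted-feature ground truth as TSV."""
        import pandas as pd

        rows = []
        for f in self.features:
            rows.append(
                {
                    "name": f.name,
                    "kind": f.kind,
                    "host": f.host,
                    "start": f.start,
                    "end": f.end,
                    "cognate_start": f.cognate_start,
                    "cognate_end": f.cognate_end,
                    "edits": json.dumps([dataclasses.asdict(e) for e in f.edits]),
                    "alt_allele": f.alt_allele,
                    "het_frequency": f.het_frequency,
                    "molecule_class": f.molecule_class,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    # truth: host name, 1-based start of each mate on the host, mate strands
    origin_host: str
    start1: int
    start2: int
    strand1: str
    strand2: str
    truth_kind: str  # mt | pt | nuclear | numt-cognate


@dataclass
class ReadSet:
    """Paired reads with per-read truth of origin."""

    pairs: list[ReadPair]
    line: str
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.pairs)

    def iter_reads(self) -> Iterable[tuple[str, str]]:
        for p in self.pairs:
            yield p.id + "/1", p.seq1
            yield p.id + "/2", p.seq2

    def write_fastq(self, prefix: str | Path, gz: bool = True) -> tuple[Path, Path]:
        """Write mate files ``<prefix>_1.fastq[.gz]`` / ``<prefix>_2.fastq[.gz]``."""
        prefix = Path(prefix)
        suffix = ".fastq.gz" if gz else ".fastq"
        paths = (
            prefix.parent / (prefix.name + "_1" + suffix),
            prefix.parent / (prefix.name + "_2" + suffix),
        )
        for mate, path in enumerate(paths, start=1):
            opener = gzip.open if gz else open
            with opener(path, "wt") as fh:
                for p in self.pairs:
                    seq = p.seq1 if mate == 1 else p.seq2
                    fh.write(
                        f"@{p.id}/{mate}\n{seq}\n+\n"
                        f"{PLACEHOLDER_QUALITY * len(seq)}\n"
                    )
        return paths

    def write_truth(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(p) for p in self.pairs]).to_csv(
            path, sep="\t", index=False
        )


def apply_edits(seq: str, edits: Sequence[Edit]) -> str:
    """Apply divergence edits (1-based offsets into ``seq``) right-to-left."""
    chars = list(seq)
    for e in sorted(edits, key=lambda e: e.offset, reverse=True):
        i = e.offset - 1
        if e.op == "sub":
            if i >= len(chars):
                raise ValueError(f"edit offset {e.offset} outside feature")
            if e.ref and chars[i] != e.ref:
                raise ValueError(
                    f"edit at offset {e.offset}: expected ref {e.ref!r}, "
                    f"found {chars[i]!r}"
                )
            chars[i] = e.alt
        elif e.op == "ins":
            if i >= len(chars):
                raise ValueError(f"edit offset {e.offset} outside feature")
            chars[i] = chars[i] + e.alt
        else:  # del
            n = max(1, len(e.ref))
            if i + n > len(chars):
                raise ValueError(f"deletion at offset {e.offset} exceeds feature")
            del chars[i : i + n]
    return "".join(chars)


@dataclass
class GenomePlan:
    """Lengths of the backbone sequences plus the features to plant."""

    mt_len: int
    pt_len: int = 3000
    nuclear_lens: dict[str, int] = field(default_factory=lambda: {"chr1": 30000})
    lines: tuple[str, ...] = ("lineA", "lineB")
    features: list[PlantedFeature] = field(default_factory=list)


def _check_overlap(planted: dict[str, list[PlantedFeature]], f: PlantedFeature) -> None:
    for other in planted.get(f.host, []):
        if f.start <= other.end and other.start <= f.end:
            raise ValueError(
                f"features {f.name or f.kind!r} and {other.name or other.kind!r} "
                f"overlap on host {f.host}"
            )


def build_genome_system(config: SimulationConfig, plan: GenomePlan) -> GenomeSystem:
    """Generate backbone sequences and plant every feature of the plan.

    Backbones are uniform random sequences from ``config.seed``; nuclear
    chromosome backbones are generated once and shared across lines, so two
    lines differ only through the numts planted on them.  Features are
    placed by replacing the host interval with the derived sequence; for a
    numt this is the cognate mtDNA substring with the divergence edits
    applied (so indel edits change the planted length).
    """
    rng = np.random.default_rng(config.seed)
    mt = random_sequence(rng, plan.mt_len)
    pt = random_sequence(rng, plan.pt_len)
    backbones = {c: random_sequence(rng, n) for c, n in plan.nuclear_lens.items()}
    nuclear = {ln: dict(backbones) for ln in plan.lines}

    planted: dict[str, list[PlantedFeature]] = {}
    features: list[PlantedFeature] = []

    def _place(host_seq: str, f: PlantedFeature, derived: str) -> str:
        f.end = f.start + len(derived) - 1
        if f.start < 1 or f.end > len(host_seq):
            raise ValueError(
                f"feature {f.name or f.kind!r} interval {f.start}-{f.end} "
                f"outside host {f.host} (length {len(host_seq)})"
            )
        _check_overlap(planted, f)
        return host_seq[: f.start - 1] + derived + host_seq[f.end :]

    for f in plan.features:
        f = dataclasses.replace(f)
        if f.kind == "true_heteroplasmy_site":
            if not 1 <= f.start <= len(mt):
                raise ValueError(f"heteroplasmy site {f.start} outside mt sequence")
            f.host = "mt"
            f.end = f.start
        else:
            if not (1 <= f.cognate_start <= f.cognate_end <= len(mt)):
                raise ValueError(
                    f"feature {f.name or f.kind!r}: cognate interval "
                    f"{f.cognate_start}-{f.cognate_end} outside mt sequence"
                )
            source = mt[f.cognate_start - 1 : f.cognate_end]
            derived = apply_edits(source, f.edits)
            if f.kind == "mt_repeat":
                f.host = "mt"
                mt = _place(mt, f, derived)
            elif f.kind == "pt_homolog_in_mt":
                f.host = "pt"
                pt = _place(pt, f, derived)
            else:  # numt
                line, chrom = f.host.split(":", 1)
                if line not in nuclear or chrom not in nuclear[line]:
                    raise ValueError(f"numt host {f.host!r} not in plan")
                nuclear[line][chrom] = _place(nuclear[line][chrom], f, derived)
        planted.setdefault(f.host, []).append(f)
        features.append(f)

    system = GenomeSystem(
        mt_seq=mt,
        pt_seq=pt,
        nuclear=nuclear,
        features=features,
        circular_mt=config.circular_mt,
    )
    # truth invariant: planted numt equals its derived sequence at coordinates
    for f in features:
        if f.kind == "numt":
            src = apply_edits(mt[f.cognate_start - 1 : f.cognate_end], f.edits)
            assert system.host_sequence(f.host) [f.start - 1 : f.end] == src
    return system


def inject_heteroplasmy(
    system: GenomeSystem,
    sites: Sequence[tuple[int, str, float]],
    molecule_class: str = "",
) -> GenomeSystem:
    """Return a copy of the system with true heteroplasmy planted.

    ``sites`` are ``(mt position, alt allele, frequency)`` with frequency
    strictly in (0, 1).  Sites given a common ``molecule_class`` are in
    coupling phase: during read simulation a single per-fragment draw
    decides whether the fragment comes from the variant molecule class, so
    reads spanning several sites carry either all reference or all variant
    alleles.  Without a class each site segregates independently.
    """
    new = GenomeSystem(
        mt_seq=system.mt_seq,
        pt_seq=system.pt_seq,
        nuclear={ln: dict(ch) for ln, ch in system.nuclear.items()},
        features=list(system.features),
        circular_mt=system.circular_mt,
    )
    for pos, alt, freq in sites:
        if not 1 <= pos <= len(system.mt_seq):
            raise ValueError(f"heteroplasmy position {pos} outside mt sequence")
        validate_nucleotides(alt, "alt allele")
        f = PlantedFeature(
            kind="true_heteroplasmy_site",
            host="mt",
            start=pos,
            end=pos,
            alt_allele=alt,
            het_frequency=freq,
            molecule_class=molecule_class,
            name=f"het{pos}",
        )
        new.features.append(f)
    new.heteroplasmy_classes()  # validates class frequency consistency
    return new


def simulate_reads(
    system: GenomeSystem, line: str, config: SimulationConfig
) -> ReadSet:
    """Draw paired-end reads for one line with copy-weighted host sampling.

    Each fragment picks its host with probability proportional to
    ``copies x length`` (mt: ``copy_ratio_mt_nu``, pt: ``copy_ratio_pt_nu``,
    nuclear chromosomes: 1), a start uniform on the host and an insert size
    from a clipped normal.  Substitution errors are i.i.d. per base at
    ``config.error_rate``; indel sequencing errors are not modelled.
    """
    if line not in system.nuclear:
        raise KeyError(f"line {line!r} not in genome system")
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    hosts = [("mt", system.mt_seq, cfg.copy_ratio_mt_nu),
             ("pt", system.pt_seq, cfg.copy_ratio_pt_nu)]
    for chrom, seq in system.nuclear[line].items():
        hosts.append((chrom, seq, 1.0))
    # effective length = number of admissible fragment start positions; using
    # it (rather than raw length) keeps interior per-bp coverage proportional
    # to copy number even when a host is not much longer than the insert
    eff = max(1.0, cfg.insert_mean - 1.0)
    weights = np.array(
        [copies * max(1.0, len(seq) - eff) for _, seq, copies in hosts], float
    )
    probs = weights / weights.sum()
    p_mt = probs[0]

    n_mt_pairs = cfg.mt_depth * len(system.mt_seq) / (2 * cfg.read_len)
    n_pairs = int(round(n_mt_pairs / p_mt)) if n_mt_pairs > 0 else 0
    if n_pairs == 0:
        return ReadSet(pairs=[], line=line, config=cfg)

    het_classes = list(system.heteroplasmy_classes().items())
    numts = system.numt_intervals(line)
    numt_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in numts:
        numt_by_chrom.setdefault(chrom, []).append((s, e))

    host_idx = rng.choice(len(hosts), size=n_pairs, p=probs)
    inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
    inserts = np.maximum(np.round(inserts).astype(int), cfg.read_len)
    u_start = rng.random(n_pairs)

    pairs: list[ReadPair] = []
    base_arr = np.array(list("ACGT"))
    for i in range(n_pairs):
        name, seq, _ = hosts[host_idx[i]]
        L = len(seq)
        ins = min(inserts[i], L)
        start = int(u_start[i] * (L - ins + 1))  # 0-based
        frag = seq[start : start + ins]

        kind = "nuclear"
        if name == "mt":
            kind = "mt"
        elif name == "pt":
            kind = "pt"
        elif any(start + 1 <= e and s <= start + ins
                 for s, e in numt_by_chrom.get(name, ())):
            kind = "numt-cognate"

        if name == "mt" and het_classes:
            frag_chars = None
            for _, (freq, members) in het_classes:
                if rng.random() < freq:
                    for f in members:
                        off = f.start - 1 - start
                        if 0 <= off < ins:
                            if frag_chars is None:
                                frag_chars = list(frag)
                            frag_chars[off] = f.alt_allele
            if frag_chars is not None:
                frag = "".join(frag_chars)

        r1 = frag[: cfg.read_len]
        r2 = revcomp(frag[-cfg.read_len :])
        if cfg.error_rate > 0:
            r1 = _mutate(rng, r1, cfg.error_rate, base_arr)
            r2 = _mutate(rng, r2, cfg.error_rate, base_arr)

        pairs.append(
            ReadPair(
                id=f"{line}.{i}",
                seq1=r1,
                seq2=r2,
                origin_host=name,
                start1=start + 1,
                start2=start + ins - cfg.read_len + 1,
                strand1="+",
                strand2="-",
                truth_kind=kind,
            )
        )
    return ReadSet(pairs=pairs, line=line, config=cfg)


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            base_arr: np.ndarray) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)
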