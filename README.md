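# numtscan

Tools for deciding whether low-frequency "heteroplasmic" variants found by
mapping whole-genome reads onto a plant mitochondrial reference are real —
or artifacts of nuclear insertions of mitochondrial DNA (numts).

## The problem

When total-cellular DNA from a single plant is sequenced and mapped onto an
mtDNA reference, some positions show a second allele in a small fraction of
reads. That is the expected signature of heteroplasmy (several mtDNA
sequence classes coexisting in a cell) — but it is also exactly what a numt
produces: a nuclear copy of an mtDNA segment, slightly diverged from its
cognate region, whose reads cross-map onto the mitochondrial reference. In
green leaf tissue the mtDNA:nuDNA per-cell copy ratio *r* is roughly
40–60:1, so a single-copy numt contributes about

```
1 / (r + 1)  ≈  2%  of the reads over its cognate window,
```

squarely in the range a heteroplasmy scan works in. Worse, numts are
presence/absence-polymorphic between lines of one species: masking with a
single nuclear reference removes only the numts *that reference happens to
carry*.

`numtscan` implements the full decision pipeline at desk scale:

- **`numtscan.simulate`** — synthetic mt/pt/nuclear genome systems with
  planted repeats, plastid-homologous blocks, per-line numts and true
  heteroplasmy; copy-ratio-weighted paired-end read simulation with full
  per-read ground truth.
- **`numtscan.homology`** — k-mer seed/chain/extend local homology search,
  and the eight-category partition of an mtDNA reference by the three
  booleans (self-repeat, nuclear-homologous, plastid-homologous). Category
  2 — single-copy, no known homology — is where heteroplasmy scans look.
- **`numtscan.tiling`** — 50-bp tiling presence/absence scan of the mtDNA
  reference against multiple nuclear assemblies; merged numt intervals,
  size statistics, solitary/clustered classification.
- **`numtscan.pileup`** — lightweight read mapping, per-site base
  composition, and extraction of intra-individual polymorphic sites (allele
  fraction ≥ 1% of coverage and ≥ ~10 supporting reads).
- **`numtscan.phase`** — coupling/repulsion phasing from reads or cloned
  PCR products spanning several variant sites, allele tables, and
  residue-by-residue matching of a variant haplotype against candidate
  numts.
- **`numtscan.marker`** — in-silico PCR, restriction digestion, RFLP
  genotyping and an exact multinomial test of F2 genotype counts against
  the 1:2:1 ratio a nuclear locus must obey.

## Worked example

Plant a 1-kb numt (six divergent substitutions, cognate mtDNA interval
4,001–5,000) on line A's chromosome 1, leave line B without it, simulate
~1,200× mtDNA-depth reads for line A at r = 50, and call sites:

```python
from numtscan import simulate, homology, pileup

cfg = simulate.SimulationConfig(seed=7, mt_depth=1200, error_rate=0.002,
                                copy_ratio_mt_nu=50, copy_ratio_pt_nu=50)
# ... build plan with the numt planted on lineA:chr1 (see docs/methods.md)
reads = simulate.simulate_reads(system, "lineA", cfg)
alns = pileup.map_reads_lightweight(reads, system.mt_seq)
table = pileup.base_composition(alns, system.mt_seq)
sites = pileup.call_intraindividual_sites(table)
print(pileup.sites_to_frame(sites).to_string(index=False))
```

```
 pos ref alt  alt_count  fraction class category
4350   C   A         27   0.02160   SNP
4401   T   G         27   0.02160   SNP
4460   C   A         31   0.02441   SNP
4509   C   A         30   0.02387   SNP
4561   T   G         30   0.02396   SNP
4615   C   A         26   0.02112   SNP
```

Six "heteroplasmy-like" sites at ~2% — precisely 1/(50+1) of coverage.
Now restrict the calls to category-2 regions, using each line's nuclear
genome in turn to build the partition:

```
partition vs lineA: 6 called -> 0 survive category-2 restriction
partition vs lineB: 6 called -> 6 survive category-2 restriction
```

Against the numt-bearing reference (line A) every site is recognized as
numt homology and removed; against the numt-lacking reference (line B) all
six survive and would be misread as heteroplasmy. This reference dependency
is the pipeline's central, testable property. True heteroplasmy behaves
differently: injected 5% coupling-phase sites survive restriction under
*both* references, phase as `coupling`, and match no candidate numt.

A command-line interface mirrors the main steps
(`numtscan partition | scan-numt | call-sites | assay | segregate`):

```
$ numtscan segregate --counts 1,10,5
{"counts": [1, 10, 5], "ratio": [1, 2, 1],
 "p_exact": 0.2209, "p_chisq": 0.2231, "reject_at_alpha": false}
```

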