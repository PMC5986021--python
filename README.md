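# protatether

In-silico design and simulation of **reiterative-primer linker libraries** for
protein fusions.

When two proteins are joined into a fusion, the peptide linker between them —
its length and its rigidity — often decides whether the fusion works. Rather
than cloning one linker at a time, a focused *library* of linker lengths can be
inserted in a single restriction-free cloning step using **reiterative
primers**: primers whose 3′ tail is a tandem array of a linker codon unit
(e.g. `GGCGGCAGC` → Gly-Gly-Ser). Because the repeat tails of the forward and
reverse primers are mutually complementary in several ungapped **annealing
registers**, one primer pair seeds a whole family of products, each with a
different number of linker units. The products share 17-bp homology arms with
the vector, so they assemble into circular clones without restriction enzymes,
and colonies are screened by sequencing across the junction.

This package models that entire workflow as deterministic sequence algebra:

| Step | Module | What it does |
|---|---|---|
| 1 | `primer_design` | Vector primers flanking the variable linker region (VLR) and reiterative library primers; Tm estimation; primer-set validation |
| 2 | `library_sim` | Enumerates annealing registers, iterates thermal cycles (products become templates), models single-unit repeat slippage, predicts the reachable linker library and its gel bands |
| 3 | `assembly` | Amplifies the vector in silico and joins amplicons through their homology arms; reading-frame validation |
| 4 | `screen` | Classifies sequencing reads into per-colony linker calls and screen summaries |
| — | `structure_flag` | Chou–Fasman helix-propensity flagging (flexible vs rigid linkers) |
| — | `fixtures` | Seeded synthetic vectors and reads so everything runs offline |

The model, its assumptions and its limitations are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Generate a toy fusion vector, design primers, simulate the GGS 2X/4X library,
and inspect the prediction — every command is seeded and reproducible:

```console
$ protatether fixtures --out vec.gb --seed 7
INFO:protatether:wrote vec.gb (462 bp, seed=7)

$ protatether design-vector --vector vec.gb --out vprimers.fasta --tsv vprimers.tsv
$ cat vprimers.tsv
# primer order sheet; length_nt in nt, tm_C in deg C
name	sequence	length_nt	gc_percent	tm_C	description
vector_fwd	ATGGCTAGCAAAGGAGA	17	47.06	39.49	vector primer F; homology with downstream gene start
vector_rev	AAACTCAGTAAACTCCT	17	35.29	34.67	vector primer R; homology with upstream gene end

$ protatether simulate --motif GGS --out pred.tsv --bands bands.tsv
INFO:protatether:simulate: GGS2X_fwd/GGS4X_rev -> 4 products
$ cat pred.tsv
# library prediction; repeat_count in motif units, linker_aa in amino acids, amplicon_nt in nt, weight is a normalised relative abundance
repeat_count	linker_nt	linker_aa	linker_peptide	amplicon_nt	first_reachable_cycle	weight
1.0	9	3.0	GGS	43	1	0.0035087719298245615
2.0	18	6.0	GGSGGS	52	1	0.48771929824561405
3.0	27	9.0	GGSGGSGGS	61	1	0.3333333333333333
4.0	36	12.0	GGSGGSGGSGGS	70	1	0.17543859649122806
```

A single GGS pair (two units on the forward tail, four on the reverse) yields
linkers of 1–4 units — 3 to 12 amino acids — from one PCR. The same pipeline
continues through assembly and colony screening, from Python:

```python
import protatether as pt

vec = pt.read_records("vec.gb")[0]
primers = pt.design_vector_primers(vec, vec.feature("downstream_gene").start)
va = pt.amplify_vector(vec, primers)

fwd, rev = pt.design_library_primers(pt.MOTIFS["GGS"], 2, 4)
pred = pt.simulate_cycles(fwd, rev)
for amp in pred.amplicons():
    construct = pt.fast_clone(va, amp)
    report = pt.validate_orf(construct)
    print(f"{amp.repeat_count}X  plasmid {len(construct.plasmid)} bp  "
          f"linker {report.linker_peptide!r}  orf_ok={report.ok}")
```

```text
1X  plasmid 471 bp  linker 'GGS'           orf_ok=True
2X  plasmid 480 bp  linker 'GGSGGS'        orf_ok=True
3X  plasmid 489 bp  linker 'GGSGGSGGS'     orf_ok=True
4X  plasmid 498 bp  linker 'GGSGGSGGSGGS'  orf_ok=True
```

Screening reads classify back to the exact repeat count:

```python
construct = pt.fast_clone(va, pred.amplicons()[1])            # the 2X clone
for read in pt.make_reads(construct, 3, pt.FixtureSpec(seed=1)):
    print(pt.classify_read(read, pt.UPSTREAM_JUNCTION_ARM,
                           pt.VECTOR_FWD_PRIMER, list(pt.MOTIFS.values())))
```

```text
LinkerCall(read_id='read_001', status='insert', motif='GGS', repeat_count=2, linker_aa=6, frame_ok=True)
LinkerCall(read_id='read_002', status='insert', motif='GGS', repeat_count=2, linker_aa=6, frame_ok=True)
LinkerCall(read_id='read_003', status='insert', motif='GGS', repeat_count=2, linker_aa=6, frame_ok=True)
```

Rigidity flagging of candidate linkers:

```console
$ protatether propensity
 name      peptide  mean_p_alpha  mean_p_beta classification
  G12 GGGGGGGGGGGG        0.5700        0.750  coil_flexible
  K12 KKKKKKKKKKKK        1.1600        0.740    helix_prone
  L10   LLLLLLLLLL        1.2100        1.300    helix_prone
  KR6 KRKRKRKRKRKR        1.0700        0.835    helix_prone
GGS4X GGSGGSGGSGGS        0.6367        0.750  coil_flexible
```

## Scope

This is a sequence-level model: polymerase kinetics, annealing thermodynamics
beyond an empirical Tm threshold, transformation efficiency and expression are
out of scope (see `docs/methods.md` for the full list of assumptions). The
package predicts *which* linker variants a reiterative primer pair can
generate, in what relative abundance under a simple stability weighting, and
verifies that every variant assembles in frame.
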