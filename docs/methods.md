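# Methods note: the register-enumeration model

This note records the model implemented by `protatether`, the assumptions
behind it, and its parameters and limitations. Everything stated here is a
property of the implemented algorithms; no empirical claim is made beyond what
the package itself computes.

## 1. Reiterative primers and annealing registers

A library primer is a 17-nt homology **arm** (5′) followed by a tandem-repeat
**tail** (3′): `arm + unit × k`, where `unit` is the codon block encoding one
linker unit (e.g. `GGCGGCAGC` → GGS). The reverse primer's tail carries
reverse-complemented units, so the two tails are mutually complementary — not
in one alignment, but in a family of ungapped **registers**.

### Geometry

Write the template's repeat block 5′→3′ as it appears on the template strand
and let `B = revcomp(block)` be its sense-strand equivalent of length `nB`.
Align the forward tail `T` (length `nT`) at sense offset `s`
(`−(nT−1) ≤ s ≤ nB−nT`):

* the register is a **duplex** when every aligned position matches
  (no mismatches tolerated inside the paired region);
* it is **extensible** when the tail's 3′-terminal base is paired, i.e.
  `s + nT ≤ nB`;
* extension copies the remainder of the template, so the product linker is
  `T + B[s+nT:]`.

Larger overlaps give shorter products. Registers with `s < 0` leave a 3′
overhang of the tail unpaired on the template side and yield products *longer*
than the template block — this **template overrun** is how a primer pair can
generate more repeat units than either primer encodes. The enumerator returns
registers in a fixed total order (decreasing overlap, then decreasing offset,
then lexicographic paired sequence), so all downstream output is reproducible.

The enumerator is verified in the test suite against a brute-force oracle that
walks every antiparallel diagonal `i + j = const` with an explicit complement
table and shares no code with the implementation.

### Minimum-overlap rule

A register is admitted when its paired region is predicted stable at the
annealing temperature. Three interchangeable rules are provided:

* `tm:<°C>` (default `tm:55`) — the paired region's salt-adjusted Tm must
  reach the annealing temperature; overlaps under 8 nt are always rejected
  (outside the formula's validity range, and unstable at any realistic
  annealing temperature);
* `nt:<n>` — at least `n` paired nucleotides;
* `units:<n>` — at least `n` whole motif units paired.

Under the default `tm:55`, a single-unit 9-nt GGS overlap (Tm ≈ 21.3 °C) is
rejected and a two-unit 18-nt overlap (Tm ≈ 58.8 °C) is accepted, which is the
behaviour the default configuration is built around. Very repeat-rich,
low-complexity duplexes are the worst case for any empirical Tm formula, so
the rule is exposed in configuration rather than hard-coded.

## 2. Melting temperature

The default estimator is the empirical salt-adjusted long-oligo formula

```
Tm = 81.5 + 16.6·log10([Na+]) + 0.41·%GC − 675/N
```

with `[Na+] = 50 mM` and `N` the duplex length; it requires `N ≥ 8`. A
Wallace-rule variant (`2(A+T) + 4(G+C)`) is available through
`TmParams(formula_id="wallace")` for very short overlaps — under the Wallace
rule the 9-nt GGS unit scores exactly 34 °C, a figure often quoted for short
repeat overlaps. Only the *ordering* of Tm values across overlap lengths is
treated as meaningful; absolute values from either formula are rough for
repeat-rich sequences.

## 3. Thermal-cycle iteration

Cycle 1 enumerates forward-primer-on-reverse-primer registers. From cycle 2
on, accumulated products serve as templates: the forward primer is enumerated
against `revcomp(linker)` of each product (the product's bottom strand
presents exactly that block between the arms). Two modelling choices:

* **Primers in excess.** Product-product annealing is ignored; only
  primer-on-primer and primer-on-product events are enumerated. This is the
  standard excess-primer approximation for PCR.
* **Forward-primer templating only.** The reverse primer's arm-anchored flush
  register on a product only reproduces existing lengths, and admitting its
  overhung registers as well would double-count the same overrun mechanism
  each cycle and let the library grow without bound under the default
  threshold. Template overrun is therefore attributed to the forward primer's
  promiscuous overlap with full-length products. This is the single most
  consequential simplification in the model.

Products whose linker is out of frame (length not a codon multiple) or
contains a stop codon are discarded: they cannot yield a viable fusion clone,
and the package predicts the *clonable* library.

Iteration stops at the configured cycle count (default 35) or earlier when a
cycle generates nothing new.

## 4. Repeat slippage

Tandem arrays are copied with occasional gain or loss of whole units —
the only frame-preserving copy error available to such an array. The default
mode is **contraction only** with at most one event per product lineage,
which is the minimal mechanism that produces single-unit products from pairs
whose smallest direct register is two units. `both` (expansion and
contraction) and `off` are available. Slippage applies only to linkers that
are a perfect whole-unit array of the motif. Slipped products are
down-weighted by `slip_weight` (default 0.1) relative to their parent.

## 5. Abundance weights

Each generation event is weighted `2^(overlap / unit_nt)` — one doubling per
additional paired unit — and a product's weight accumulates over all events
that generate it; weights are normalised at the end. This is a deliberately
coarse stability proxy, not a thermodynamic model: it encodes only "more
paired units anneal more often", and the reported weights should be read as
an ordering, not as molar fractions.

Stochastic mode (`stochastic=True`) resamples the normalised weights as a
single seeded multinomial draw of `n_draws` molecules (default 10 000),
emulating the sampling noise of a finite colony screen. The deterministic
mode is the default and is byte-reproducible.

## 6. Assembly and screening

Vector amplification and homology joining are modelled as exact string
operations: arms must match the vector exactly and occur exactly once
(mispriming and recombination tolerance are not modelled; template removal
and purification are assumed perfect). Joining requires full-length 17-nt
terminal homology at both ends in a unique register; either insert
orientation is accepted since the two distinct arms force a unique productive
arrangement. An arms-only insert regenerates the parent plasmid exactly,
which models vector re-circularisation — the dominant background in homology
cloning — and is why screens report a separate `no_linker` category.

Read classification locates both arms on either strand, extracts the
intervening insert and matches it against the motif panel by smallest-period
analysis; every failure mode is a status (`no_call`, `no_linker`,
`aberrant`), never an exception. A Hamming mismatch budget is available for
noisy reads (default 0).

Motif units must pass a **frame-ambiguity check**: a unit whose infinite
tandem array is invariant under a 1- or 2-nt shift (e.g. `AAA`) is rejected,
because repeat counts in its products would be unrecoverable by sequencing
across the junction. This is why lysine repeats use `AAG`, not `AAA`.
Single-residue motifs are named by codon count, multi-residue motifs by unit
count.

## 7. Rigidity flagging

Linker peptides are flagged `helix_prone` or `coil_flexible` from the mean
classical Chou–Fasman α-helix propensity (Pα) of their residues, with
threshold 1.03; β-strand propensity is reported but not classified on, since
the operative contrast for linkers is helix (rigid) vs coil (flexible). With
the default threshold the stock comparison panel splits into
{K12, L10, KR6} helix-prone and {G12, GGS4X} coil. Mean single-residue
propensity ignores neighbour effects and length dependence; it is a flag, not
a structure prediction.

## 8. Fixtures

All test inputs are generated programmatically and seeded. The toy vector is
a small circular plasmid whose fusion ORF embeds the two canonical 17-bp
junction arms exactly once, with the junction on a codon boundary; a
full-scale variant with a 4962-bp plasmid and a 607-residue fusion ORF
(1053-nt upstream segment) provides realistic dimensions. Both are synthetic
sequences — random codons around fixed junctions — not any real plasmid.
Read generation emits seeded, strand-randomised windows (±40 nt) around the
linker junction with optional per-base substitution errors; indels and
quality values are not modelled.

## 9. Parameter summary (defaults)

| Parameter | Default | Where |
|---|---|---|
| Homology arm length | 17 nt | `primer_design.DEFAULT_ARM_LEN` |
| Tm formula | salt-adjusted, `[Na+]` = 50 mM | `TmParams` |
| Minimum overlap | `tm:55` | `MinOverlap` |
| Thermal cycles | 35 | `SimConfig.cycles` |
| Slippage | contraction only, ≤ 1 event | `SimConfig` |
| Slippage weight factor | 0.1 | `SimConfig.slip_weight` |
| Register weight | `2^(overlap/unit)` | `SimConfig.weight_model` |
| Stochastic draws | 10 000 | `SimConfig.n_draws` |
| Helix threshold | mean Pα ≥ 1.03 | `structure_flag.DEFAULT_THRESHOLD` |
| Read mismatch budget | 0 | `classify_read(max_mismatch=...)` |

## 10. Known limitations

* No mismatch tolerance inside annealing registers; no gapped or partial-arm
  annealing.
* The Tm threshold is an empirical gate, not a nearest-neighbour
  thermodynamic model; absolute Tm values for repeat-rich duplexes are rough.
* Reverse-primer-on-product registers are not enumerated (see §3); the
  overrun spectrum is therefore a lower bound on mechanistic possibilities.
* Abundance weights are an ordering heuristic; no amplification efficiency,
  plateau or polymerase-drop-off model.
* Assembly assumes perfect purification and exact, unique arms; chimeras and
  multimer inserts are not modelled.
* Reads carry substitutions only — no indels, no quality model.
* Rigidity flagging is mean per-residue propensity only.
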