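"""Synthetic test inputs: toy fusion vectors and screening reads.

The generators build circular plasmids that embed the exact 17-bp junction
arms the stock primers are built from, so the whole design → simulate →
assemble → classify pipeline runs end-to-end on them without any external
data.  The upstream gene stub ends with the codons …ACT GAG TTT (…-T-E-F),
keeping the printed 17-mer junction arm frame-consistent; the downstream stub
begins with the GFP-start arm.  All randomness is seeded and outputs are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .assembly import AssembledConstruct
from .core_seq import DnaRecord, Feature, ProtatetherError, revcomp
from .primer_design import (
    DOWNSTREAM_JUNCTION_ARM,
    UPSTREAM_JUNCTION_ARM,
    VECTOR_FWD_PRIMER,
)
from .core_seq import MOTIFS, LinkerMotif

__all__ = ["FixtureSpec", "make_toy_vector", "make_reads", "make_fullscale_vector"]

# Upstream gene tail: six codons (K E F T E F) whose last 17 nt are the
# upstream junction arm, placed so the junction falls on a codon boundary.
_UPSTREAM_TAIL = "AAGGAGTTTACTGAGTTT"
assert _UPSTREAM_TAIL.endswith(UPSTREAM_JUNCTION_ARM)
# Downstream gene head: the GFP-start arm plus one base completing its sixth codon.
_DOWNSTREAM_HEAD = VECTOR_FWD_PRIMER + "C"  # ATG GCT AGC AAA GGA GAC

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic toy vector and its screening reads."""

    upstream_stub_codons: int = 20
    downstream_stub_codons: int = 20
    backbone_nt: int = 300
    linker: tuple[str, int] | None = None
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upstream_stub_codons < 3 or self.downstream_stub_codons < 3:
            raise ValueError("stub codon counts must be >= 3")
        if not (0.0 <= self.read_error_rate <= 1.0):
            raise ValueError("read_error_rate must be in [0, 1]")
        if self.backbone_nt < 0:
            raise ValueError("backbone_nt must be non-negative")


def _random_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_CODONS) for _ in range(n))


def _resolve_linker(linker: tuple[str, int] | None) -> str:
    if linker is None:
        return ""
    motif_name, n = linker
    motif = MOTIFS.get(motif_name)
    if motif is None:
        raise KeyError(f"unknown motif {motif_name!r}; known: {sorted(MOTIFS)}")
    if n < 1:
        raise ValueError("linker repeat count must be >= 1")
    return motif.repeat(n)


def _unique_arms(record: DnaRecord) -> bool:
    arms = (
        UPSTREAM_JUNCTION_ARM,
        VECTOR_FWD_PRIMER,
        revcomp(DOWNSTREAM_JUNCTION_ARM),
    )
    return all(len(record.find_all(a)) == 1 for a in arms)


def make_toy_vector(spec: FixtureSpec | None = None) -> DnaRecord:
    """A circular toy fusion vector with the canonical junction arms.

    Layout (ORF first, backbone after; the VLR never spans the origin)::

        ATG [random upstream codons] AAG GAG TTT ACT GAG TTT
        [optional linker]
        ATG GCT AGC AAA GGA GAC [random downstream codons] TAA
        [random backbone]

    Features annotated: ``upstream_gene``, optional ``VLR``, ``downstream_gene``
    (including the stop codon) and ``ORF``.  Both junction arms occur exactly
    once, so the stock primer set validates cleanly against every fixture.
    """
    spec = spec or FixtureSpec()
    linker = _resolve_linker(spec.linker)
    for attempt in range(64):
        rng = random.Random(spec.seed * 997 + attempt)
        upstream = "ATG" + _random_codons(rng, spec.upstream_stub_codons) + _UPSTREAM_TAIL
        downstream = _DOWNSTREAM_HEAD + _random_codons(rng, spec.downstream_stub_codons) + "TAA"
        backbone = "".join(rng.choice("ACGT") for _ in range(spec.backbone_nt))
        ue = len(upstream)
        ds = ue + len(linker)
        de = ds + len(downstream)
        features = [
            Feature("upstream_gene", 0, ue),
            Feature("downstream_gene", ds, de),
            Feature("ORF", 0, de),
        ]
        if linker:
            features.insert(1, Feature("VLR", ue, ds))
        record = DnaRecord(
            "toy_fusion_vector", upstream + linker + downstream + backbone,
            "circular", features,
        )
        if _unique_arms(record):
            return record
    raise ProtatetherError("could not build a fixture with unique junction arms")


def make_fullscale_vector(seed: int = 0) -> DnaRecord:
    """Synthetic full-scale stand-in for the real kinase-GFP expression vector.

    This is *not* the proprietary plasmid sequence — it is a synthetic
    construction with the same dimensions: a 4962-bp circular plasmid whose
    fusion ORF encodes 607 amino acids, with a 1053-nt upstream (kinase)
    segment ending at the canonical junction arm and a 771-nt downstream
    (GFP) segment (stop included) beginning with the GFP-start arm.
    """
    for attempt in range(64):
        rng = random.Random(seed * 104729 + attempt + 31)
        upstream = "ATG" + _random_codons(rng, 344) + _UPSTREAM_TAIL
        assert len(upstream) == 1053
        downstream = _DOWNSTREAM_HEAD + _random_codons(rng, 250) + "TAA"
        assert len(downstream) == 771
        backbone = "".join(rng.choice("ACGT") for _ in range(4962 - 1824))
        record = DnaRecord(
            "synthetic_fullscale_fusion_vector",
            upstream + downstream + backbone,
            "circular",
            [
                Feature("upstream_gene", 0, 1053),
                Feature("downstream_gene", 1053, 1824),
                Feature("ORF", 0, 1824),
            ],
        )
        if _unique_arms(record):
            return record
    raise ProtatetherError("could not build a full-scale fixture with unique arms")


def make_reads(
    construct: AssembledConstruct, n_reads: int, spec: FixtureSpec | None = None
) -> list[DnaRecord]:
    """Sanger-style reads spanning the linker junction of an assembled clone.

    Each read covers 40 nt on either side of the variable linker region, is
    emitted on a random strand, and carries seeded per-base substitution
    errors at ``spec.read_error_rate``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed * 7919 + 1)
    plasmid = construct.plasmid
    up = plasmid.feature("upstream_gene")
    rotated = plasmid.rotate(up.start) if plasmid.is_circular else plasmid
    up = rotated.feature("upstream_gene")
    down = rotated.feature("downstream_gene")
    flank = 40
    start = max(0, up.end - flank)
    end = min(len(rotated), down.start + flank)
    window = rotated.seq[start:end]
    reads = []
    for i in range(n_reads):
        bases = list(window)
        for j, b in enumerate(bases):
            if spec.read_error_rate and rng.random() < spec.read_error_rate:
                bases[j] = rng.choice([x for x in "ACGT" if x != b])
        seq = "".join(bases)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(DnaRecord(f"read_{i + 1:03d}", seq))
    return reads
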