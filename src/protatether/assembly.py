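"""In-silico restriction-free cloning: vector amplification and homology joining.

The cloning step of the workflow is purely sequence-defined: the vector is
amplified with primers flanking the variable linker region (VLR), template
removal and gel purification are modelled as perfect (the amplicon is the sole
carried-forward species), and a library amplicon whose 17-nt termini match the
vector amplicon's termini is joined into a circular plasmid.  Junctions must
be exact, full-length arm matches — the primers define them, and modelling
recombination tolerance would add nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_seq import DnaRecord, Feature, ProtatetherError, revcomp, translate
from .library_sim import Amplicon
from .primer_design import PrimerSpec

__all__ = [
    "AssemblyError",
    "ArmSiteError",
    "AssembledConstruct",
    "OrfReport",
    "amplify_vector",
    "fast_clone",
    "validate_orf",
]


class AssemblyError(ProtatetherError):
    pass


class ArmSiteError(AssemblyError):
    """An arm is absent from, or occurs more than once in, the target."""


@dataclass
class JunctionReport:
    arm: str
    match_len: int
    exact: bool


@dataclass
class AssembledConstruct:
    plasmid: DnaRecord
    linker_peptide: str
    orf_ok: bool
    junction_report: list[JunctionReport] = field(default_factory=list)


@dataclass
class OrfReport:
    orf_codons: int
    internal_stops: int
    linker_peptide: str
    ok: bool


def amplify_vector(vector: DnaRecord, primers: tuple[PrimerSpec, PrimerSpec]) -> DnaRecord:
    """Linear amplicon of the whole plasmid minus the VLR.

    The forward primer anneals at the downstream gene start and the reverse
    primer at the upstream gene end; the product runs from the forward arm
    around the circle to the reverse-arm complement, so its 5' terminus is
    the forward arm and its 3' terminus the upstream junction arm.  A vector
    with a zero-width VLR yields an amplicon of the full plasmid length,
    linearised at the junction.

    Both arms must occur exactly once.  Linear inputs whose arms flank the
    origin must be rotated to circular form first.
    """
    fwd, rev = primers
    fwd_sites = vector.find_all(fwd.sequence)
    rev_arm_sense = revcomp(rev.sequence)
    rev_sites = vector.find_all(rev_arm_sense)
    for name, sites in (("forward", fwd_sites), ("reverse", rev_sites)):
        if not sites:
            raise ArmSiteError(f"{name} primer arm not found in vector {vector.id!r}")
        if len(sites) > 1:
            raise ArmSiteError(
                f"{name} primer arm occurs {len(sites)} times in vector {vector.id!r}"
            )
    start = fwd_sites[0]
    rev_end = rev_sites[0] + len(rev_arm_sense)
    n = len(vector)
    if not vector.is_circular:
        if rev_end < start:
            raise AssemblyError(
                "arms flank the origin of a linear record; rotate to circular first"
            )
        return DnaRecord(
            f"{vector.id}_amplicon",
            vector.seq[start:rev_end],
            "linear",
            [
                Feature(f.name, f.start - start, f.end - start, f.strand)
                for f in vector.features
                if f.start >= start and f.end <= rev_end
            ],
        )
    rotated = vector.rotate(start)
    span = (rev_end - start) % n or n
    amp = DnaRecord(
        f"{vector.id}_amplicon",
        rotated.seq[:span],
        "linear",
        [f for f in rotated.features if f.end <= span],
    )
    return amp


def _insert_sequence(insert: "Amplicon | DnaRecord | str") -> str:
    if isinstance(insert, Amplicon):
        return insert.seq
    if isinstance(insert, DnaRecord):
        return insert.seq
    return str(insert).upper()


def fast_clone(
    vector_amplicon: DnaRecord,
    insert: "Amplicon | DnaRecord | str",
    arm_len: int = 17,
) -> AssembledConstruct:
    """Join a vector amplicon and a library amplicon via their shared arms.

    The insert's 5' terminus must equal the vector amplicon's 3' terminus and
    vice versa (either orientation of the insert is accepted; the two distinct
    arms force a unique productive orientation).  The resulting plasmid is
    circular, with the insert's linker sitting between the upstream gene's
    last codon and the downstream gene's start, annotated as a ``VLR``
    feature.  A 2·arm_len insert (arms only, zero-length linker) regenerates
    the parent no-linker construct exactly.
    """
    ins = _insert_sequence(insert)
    va = vector_amplicon.seq
    if len(ins) < 2 * arm_len:
        raise AssemblyError(
            f"insert of {len(ins)} nt cannot carry two {arm_len}-nt arms"
        )

    def termini_match(s: str) -> tuple[bool, bool]:
        return (s[:arm_len] == va[-arm_len:], s[-arm_len:] == va[:arm_len])

    left, right = termini_match(ins)
    if not (left and right):
        rc = revcomp(ins)
        rleft, rright = termini_match(rc)
        if rleft and rright:
            ins = rc
            left, right = rleft, rright
    if not (left or right):
        raise AssemblyError("no terminal homology between insert and vector amplicon")
    if not (left and right):
        raise AssemblyError("terminal homology at one end only")
    # ambiguity: each vector terminus must have a unique register on the insert
    if ins.count(va[-arm_len:]) > 1 or ins.count(va[:arm_len]) > 1:
        raise AssemblyError("ambiguous multi-register homology between insert and vector")

    linker = ins[arm_len:-arm_len]
    seq = va + linker
    features = [Feature(f.name, f.start, f.end, f.strand) for f in vector_amplicon.features]
    if linker:
        features.append(Feature("VLR", len(va), len(va) + len(linker)))
    plasmid = DnaRecord(f"{vector_amplicon.id}_clone", seq, "circular", features)

    frame_ok = len(linker) % 3 == 0
    peptide = ""
    stop_free = True
    if linker and frame_ok:
        peptide = translate(linker)
        stop_free = "*" not in peptide
    junctions = [
        JunctionReport(va[-arm_len:], arm_len, True),
        JunctionReport(va[:arm_len], arm_len, True),
    ]
    return AssembledConstruct(
        plasmid=plasmid,
        linker_peptide=peptide if stop_free else peptide,
        orf_ok=frame_ok and stop_free,
        junction_report=junctions,
    )


def validate_orf(
    construct: AssembledConstruct,
    start_feature: str = "upstream_gene",
    end_feature: str = "downstream_gene",
) -> OrfReport:
    """Check the fusion reading frame across upstream gene, linker, downstream gene.

    Rotates the circular plasmid so the upstream gene starts at position 0,
    requires upstream gene → (linker) → downstream gene to be contiguous,
    translates the whole fusion, and reports its length in codons, any
    internal stops, and the linker peptide between the two genes.
    """
    plasmid = construct.plasmid
    try:
        up = plasmid.feature(start_feature)
    except KeyError as exc:
        raise AssemblyError(f"feature {start_feature!r} missing") from exc
    rotated = plasmid.rotate(up.start) if plasmid.is_circular else plasmid
    up = rotated.feature(start_feature)
    try:
        down = rotated.feature(end_feature)
    except KeyError as exc:
        raise AssemblyError(f"feature {end_feature!r} missing") from exc
    if up.start != 0 or down.start < up.end:
        raise AssemblyError("gene features are not in upstream->downstream order")

    linker_nt = down.start - up.end
    linker_region = rotated.seq[up.end : down.start]
    linker_peptide = translate(linker_region) if linker_nt >= 3 else ""

    orf_region = rotated.seq[up.start : down.end]
    aa = translate(orf_region) if len(orf_region) >= 3 else ""
    stopped = aa.endswith("*")
    # codons up to (excluding) a terminal stop; internal stop = premature halt
    orf_codons = len(aa) - (1 if stopped else 0)
    full_codons = len(orf_region) // 3
    internal_stops = 1 if (stopped and len(aa) < full_codons) else 0
    ok = (
        linker_nt % 3 == 0
        and "*" not in linker_peptide
        and internal_stops == 0
    )
    return OrfReport(
        orf_codons=orf_codons,
        internal_stops=internal_stops,
        linker_peptide=linker_peptide,
        ok=ok,
    )
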