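"""Vector and reiterative linker-library primer construction.

A library primer is a 17-nt homology arm (5') followed by a tandem array of
linker codon units (3').  Forward primers carry sense units; reverse primers
carry reverse-complemented units.  Because the repeat tails of a forward and a
reverse primer are mutually complementary in several registers, a single
primer pair seeds a whole family of products — that enumeration lives in
:mod:`protatether.library_sim`; this module only builds and scores the
primers themselves.

Melting temperatures are estimated with a salt-adjusted empirical formula
(see :func:`tm_salt_adjusted`); a Wallace-rule variant is available through
``TmParams.formula_id`` for very short overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_seq import (
    DnaRecord,
    LinkerMotif,
    ProtatetherError,
    _normalize,
    frame_ambiguity_check,
    revcomp,
)

__all__ = [
    "DEFAULT_ARM_LEN",
    "UPSTREAM_JUNCTION_ARM",
    "DOWNSTREAM_JUNCTION_ARM",
    "VECTOR_FWD_PRIMER",
    "VECTOR_REV_PRIMER",
    "PrimerSpec",
    "TmParams",
    "PrimerDesignError",
    "tm_salt_adjusted",
    "gc_percent",
    "design_vector_primers",
    "design_library_primers",
    "library_primer_from_tail",
    "infer_repeat_units",
    "validate_primer_set",
    "order_sheet",
]

#: Homology arms all use 17 bp of overlap with the vector junction by default.
DEFAULT_ARM_LEN = 17

#: Sense sequence of the last 17 nt of the upstream (kinase) gene at the
#: fusion junction — the arm of every forward library primer.
UPSTREAM_JUNCTION_ARM = "AGGAGTTTACTGAGTTT"

#: Arm of every reverse library primer: reverse complement of the first 17 nt
#: of the downstream (GFP) gene.
DOWNSTREAM_JUNCTION_ARM = "TCTCCTTTGCTAGCCAT"

#: Vector-amplification primers flanking the variable linker region: the
#: forward primer anneals at the downstream gene start, the reverse primer at
#: the upstream gene end.
VECTOR_FWD_PRIMER = "ATGGCTAGCAAAGGAGA"
VECTOR_REV_PRIMER = "AAACTCAGTAAACTCCT"


class PrimerDesignError(ProtatetherError):
    pass


@dataclass(frozen=True)
class PrimerSpec:
    """A primer: homology ``arm`` (5') plus repeat ``tail`` (3').

    ``repeat_units`` is the whole-unit count of the tail when it is a whole
    number of motif units; irregular tails (e.g. a unit-and-a-half) leave it
    ``None``.
    """

    name: str
    arm: str
    tail: str = ""
    orientation: str = "forward"
    motif: LinkerMotif | None = None
    repeat_units: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", _normalize(self.arm, what=f"arm of {self.name}"))
        object.__setattr__(self, "tail", _normalize(self.tail, what=f"tail of {self.name}") if self.tail else "")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if not self.arm:
            raise ValueError(f"primer {self.name!r} has an empty arm")

    @property
    def sequence(self) -> str:
        """Full 5'→3' sequence: arm then tail."""
        return self.arm + self.tail

    @property
    def is_irregular(self) -> bool:
        return bool(self.tail) and self.repeat_units is None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TmParams:
    """Conditions for melting-temperature estimation.

    monovalent_cation_M
        Total monovalent cation concentration in mol/L (default 50 mM).
    formula_id
        ``"salt_adjusted"`` — Tm = 81.5 + 16.6·log10([Na+]) + 0.41·%GC − 675/N,
        the long-oligo salt-adjusted formula; or ``"wallace"`` — the
        2(A+T) + 4(G+C) rule (the cation term is then unused).
    """

    monovalent_cation_M: float = 0.05
    formula_id: str = "salt_adjusted"

    def __post_init__(self) -> None:
        if self.monovalent_cation_M <= 0:
            raise ValueError("cation concentration must be positive")
        if self.formula_id not in ("salt_adjusted", "wallace"):
            raise ValueError(f"unknown Tm formula {self.formula_id!r}")


def gc_percent(seq: str) -> float:
    s = _normalize(seq)
    if not s:
        raise ValueError("GC content of an empty sequence is undefined")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def tm_salt_adjusted(seq: str, params: TmParams | None = None) -> float:
    """Melting temperature (°C) of ``seq`` under ``params``.

    Deterministic; requires at least 8 nt (shorter duplexes are outside the
    formula's range and are treated as unstable by callers).
    """
    params = params or TmParams()
    s = _normalize(seq)
    n = len(s)
    if n < 8:
        raise ValueError(f"Tm estimation needs >= 8 nt, got {n}")
    if params.formula_id == "wallace":
        return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (s.count("G") + s.count("C"))
    return (
        81.5
        + 16.6 * math.log10(params.monovalent_cation_M)
        + 0.41 * gc_percent(s)
        - 675.0 / n
    )


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def design_vector_primers(
    vector: DnaRecord, vlr_point: int, arm_len: int = DEFAULT_ARM_LEN
) -> tuple[PrimerSpec, PrimerSpec]:
    """Primers that amplify everything except the variable linker region.

    The forward primer is the sense window of ``arm_len`` nt starting at
    ``vlr_point`` (the downstream gene's first bases); the reverse primer is
    the reverse complement of the window ending at ``vlr_point`` (the
    upstream gene's last bases).  Both have empty tails.
    """
    if arm_len < 10:
        raise PrimerDesignError("arm length must be at least 10 nt")
    n = len(vector)
    if not (0 <= vlr_point <= n):
        raise PrimerDesignError(f"VLR point {vlr_point} outside record of length {n}")
    if vector.is_circular:
        doubled = vector.seq * 2
        fwd_window = doubled[vlr_point : vlr_point + arm_len]
        rev_window = doubled[vlr_point + n - arm_len : vlr_point + n]
    else:
        if vlr_point + arm_len > n or vlr_point - arm_len < 0:
            raise PrimerDesignError(
                f"arm window of {arm_len} nt around position {vlr_point} runs "
                "off the end of a linear record"
            )
        fwd_window = vector.seq[vlr_point : vlr_point + arm_len]
        rev_window = vector.seq[vlr_point - arm_len : vlr_point]
    fwd = PrimerSpec(
        "vector_fwd", fwd_window, "", "forward",
        description="vector primer F; homology with downstream gene start",
    )
    rev = PrimerSpec(
        "vector_rev", revcomp(rev_window), "", "reverse",
        description="vector primer R; homology with upstream gene end",
    )
    return fwd, rev


def design_library_primers(
    motif: LinkerMotif,
    fwd_units: int,
    rev_units: int,
    fwd_arm: str = UPSTREAM_JUNCTION_ARM,
    rev_arm: str = DOWNSTREAM_JUNCTION_ARM,
) -> tuple[PrimerSpec, PrimerSpec]:
    """Whole-unit reiterative primer pair for ``motif``.

    forward = ``fwd_arm`` + unit × ``fwd_units``;
    reverse = ``rev_arm`` + revcomp(unit) × ``rev_units``.

    The arms normally come from :func:`design_vector_primers` applied to the
    target vector: the forward-library arm is the reverse complement of the
    vector reverse primer, and vice versa.
    """
    if fwd_units < 1 or rev_units < 1:
        raise PrimerDesignError("repeat-unit counts must be >= 1")
    if not frame_ambiguity_check(motif.codon_unit):
        raise PrimerDesignError(f"motif {motif.name} fails the frame-ambiguity check")
    fwd = PrimerSpec(
        f"{motif.name}{fwd_units}X_fwd",
        _normalize(fwd_arm), motif.repeat(fwd_units), "forward", motif, fwd_units,
        description=f"variable insert F primer; {motif.name} x {fwd_units}",
    )
    rev = PrimerSpec(
        f"{motif.name}{rev_units}X_rev",
        _normalize(rev_arm), revcomp(motif.codon_unit) * rev_units, "reverse", motif, rev_units,
        description=f"variable insert R primer; {motif.name} x {rev_units}",
    )
    return fwd, rev


def library_primer_from_tail(
    name: str,
    arm: str,
    tail: str,
    orientation: str,
    motif: LinkerMotif | None = None,
    description: str = "",
) -> PrimerSpec:
    """Literal-tail constructor for irregular primers.

    Some useful primers carry a tail that is not a whole number of motif units
    (for instance a unit-and-a-half).  This bypasses whole-unit accounting but
    still requires the tail to be a whole number of codons, so insertion
    cannot shift the downstream reading frame.
    """
    tail = _normalize(tail, what=f"tail of {name}")
    if len(tail) % 3 != 0:
        raise PrimerDesignError(
            f"literal tail of {name!r} is {len(tail)} nt, not a codon multiple"
        )
    units: int | None = None
    if motif is not None:
        u = motif.unit_nt
        if len(tail) % u == 0:
            k = len(tail) // u
            if tail == motif.codon_unit * k or tail == revcomp(motif.codon_unit) * k:
                units = k
    return PrimerSpec(name, arm, tail, orientation, motif, units, description)


def infer_repeat_units(primer: PrimerSpec) -> int:
    """Recover the whole-unit repeat count of a library primer's tail."""
    if primer.motif is None:
        raise PrimerDesignError(f"primer {primer.name!r} has no motif")
    unit = primer.motif.codon_unit
    if primer.orientation == "reverse":
        unit = revcomp(unit)
    u = len(unit)
    if len(primer.tail) % u == 0 and primer.tail == unit * (len(primer.tail) // u):
        return len(primer.tail) // u
    raise PrimerDesignError(
        f"tail of {primer.name!r} is not a whole number of {primer.motif.name} units"
    )


# ---------------------------------------------------------------------------
# Validation / reporting
# ---------------------------------------------------------------------------


@dataclass
class PrimerIssue:
    primer: str
    code: str
    message: str


@dataclass
class PrimerSetReport:
    issues: list[PrimerIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def codes(self, primer: str | None = None) -> set[str]:
        return {i.code for i in self.issues if primer is None or i.primer == primer}


def _arm_occurrences(vector: DnaRecord, primer: PrimerSpec) -> list[int]:
    # forward primers match the sense strand directly; reverse primers match
    # as the reverse complement of their arm
    arm = primer.arm if primer.orientation == "forward" else revcomp(primer.arm)
    return vector.find_all(arm)


def validate_primer_set(
    primers: Sequence[PrimerSpec], vector: DnaRecord
) -> PrimerSetReport:
    """Check a primer set against its target vector.

    Flags raised per primer: ``arm-not-found``, ``arm-multi-site`` (mispriming
    risk), ``frame-ambiguous`` (tail repeat unit fails the frameshift check),
    ``tail-frame`` (tail not a codon multiple), and ``junction-out-of-frame``
    (the insertion point is not on a codon boundary of the annotated ORF —
    checked against the ORF feature, not the arm boundary, because the 17-nt
    arm deliberately starts mid-codon).
    """
    report = PrimerSetReport()
    orf = None
    try:
        orf = vector.feature("ORF")
    except KeyError:
        pass
    for p in primers:
        hits = _arm_occurrences(vector, p)
        if not hits:
            report.issues.append(PrimerIssue(p.name, "arm-not-found", f"arm of {p.name} absent from vector"))
            continue
        if len(hits) > 1:
            report.issues.append(PrimerIssue(p.name, "arm-multi-site", f"arm of {p.name} occurs {len(hits)} times"))
        if p.tail:
            if len(p.tail) % 3 != 0:
                report.issues.append(PrimerIssue(p.name, "tail-frame", "tail is not a codon multiple"))
            unit_len = p.motif.unit_nt if p.motif else min(len(p.tail), 3)
            unit = p.tail[:unit_len]
            if len(unit) % 3 == 0 and unit and not frame_ambiguity_check(unit):
                report.issues.append(PrimerIssue(p.name, "frame-ambiguous", f"repeat unit {unit} is frame-ambiguous"))
            if orf is not None:
                pos = hits[0]
                junction = pos + len(p.arm) if p.orientation == "forward" else pos
                if (junction - orf.start) % 3 != 0:
                    report.issues.append(
                        PrimerIssue(p.name, "junction-out-of-frame",
                                    f"junction at {junction} is off the ORF codon grid")
                    )
    return report


def order_sheet(
    primers: Iterable[PrimerSpec], tm_params: TmParams | None = None
) -> pd.DataFrame:
    """TSV-ready order sheet: name, sequence, length, %GC, Tm, description."""
    rows = []
    for p in primers:
        seq = p.sequence
        rows.append(
            {
                "name": p.name,
                "sequence": seq,
                "length_nt": len(seq),
                "gc_percent": round(gc_percent(seq), 2),
                "tm_C": round(tm_salt_adjusted(seq, tm_params), 2),
                "description": p.description,
            }
        )
    return pd.DataFrame(rows)
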