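"""Register-shifted annealing simulation of linker-library PCR.

The generative trick of reiterative primers is that the 3' repeat tail of the
forward primer can pair with the repeat block of the reverse primer (or of an
already-made product) in several ungapped registers.  Each register that
leaves the forward primer's 3' end paired is extensible and yields a product
with a different linker length.  This module enumerates those registers,
extends them into amplicons, models single-unit repeat slippage (the simplest
frame-preserving mechanism for the observed truncated products), and iterates
the process over thermal cycles, letting products serve as templates for the
forward primer from cycle 2 on.  Reverse-primer-on-product registers are not
enumerated: the template-overrun products seen experimentally are attributed
to promiscuous overlap of the *forward* primer with full-length amplicons,
and the arm-anchored flush register of the reverse primer only reproduces
existing lengths.

Geometry
--------
Write the template's repeat block 5'→3' (as given on the template strand) and
let ``B = revcomp(block)`` be its sense-strand equivalent.  Aligning the
forward tail ``T`` at sense offset ``s`` (``s < 0`` leaves a 5' overhang of
the tail unpaired) is a valid register when every aligned position matches and
``s + len(T) <= len(B)`` (the tail's 3'-terminal base is paired).  Extension
copies the rest of the template, so the product linker is
``T + B[s + len(T):]`` — larger overlaps give shorter products, and 3'
overhang registers (``s < 0``) give products longer than the template block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_seq import DnaRecord, LinkerMotif, ProtatetherError, _normalize, revcomp, translate
from .primer_design import PrimerSpec, TmParams, tm_salt_adjusted

__all__ = [
    "AnnealingRegister",
    "Amplicon",
    "MinOverlap",
    "SimConfig",
    "LibraryPrediction",
    "IncompatiblePrimersError",
    "enumerate_registers",
    "extend_register",
    "apply_slippage",
    "simulate_cycles",
    "band_table",
]


class IncompatiblePrimersError(ProtatetherError):
    pass


@dataclass(frozen=True)
class MinOverlap:
    """Minimum-overlap rule for accepting an annealing register.

    mode ``"tm"``: the paired region must reach ``anneal_temp_C`` under the
    salt-adjusted formula (overlaps under 8 nt are always rejected — they are
    outside the formula's range and unstable at any realistic annealing
    temperature).  mode ``"nt"``: at least ``min_nt`` paired nucleotides.
    mode ``"units"``: at least ``min_units`` whole motif units paired.
    """

    mode: str = "tm"
    anneal_temp_C: float = 55.0
    min_nt: int = 1
    min_units: int = 1
    tm_params: TmParams = field(default_factory=TmParams)

    def __post_init__(self) -> None:
        if self.mode not in ("tm", "nt", "units"):
            raise ValueError(f"unknown min-overlap mode {self.mode!r}")
        if self.min_nt < 1 or self.min_units < 1:
            raise ValueError("overlap thresholds must be positive")

    @classmethod
    def parse(cls, text: str) -> "MinOverlap":
        """Parse ``"tm:55"``, ``"nt:6"`` or ``"units:2"``."""
        mode, _, value = text.partition(":")
        if mode == "tm":
            return cls(mode="tm", anneal_temp_C=float(value or 55))
        if mode == "nt":
            return cls(mode="nt", min_nt=int(value or 1))
        if mode == "units":
            return cls(mode="units", min_units=int(value or 1))
        raise ValueError(f"cannot parse min-overlap rule {text!r}")

    def accepts(self, paired_seq: str, unit_nt: int | None) -> bool:
        n = len(paired_seq)
        if self.mode == "nt":
            return n >= self.min_nt
        if self.mode == "units":
            if unit_nt is None:
                raise ValueError("units mode needs a motif unit length")
            return n >= self.min_units * unit_nt
        if n < 8:
            return False
        return tm_salt_adjusted(paired_seq, self.tm_params) >= self.anneal_temp_C


@dataclass(frozen=True)
class AnnealingRegister:
    """One ungapped annealing configuration of a forward tail on a template.

    ``offset_nt`` is the distance from the template block's 3' end to the
    3'-proximal edge of the paired region; ``shift`` is the internal sense
    offset ``s`` described in the module docstring (negative for 3'-overhang
    registers).  Only extensible registers (forward 3' end paired) are ever
    constructed.
    """

    overlap_nt: int
    offset_nt: int
    shift: int
    paired_seq: str
    fwd_3prime_paired: bool = True
    overlap_tm: float | None = None

    def sort_key(self) -> tuple:
        return (-self.overlap_nt, -self.offset_nt, self.paired_seq)


@dataclass(frozen=True)
class Amplicon:
    """A double-stranded product: forward arm + linker + downstream arm (sense)."""

    seq: str
    linker: str
    fwd_arm: str
    rev_arm_sense: str
    motif: LinkerMotif | None
    born_cycle: int
    provenance: tuple[str, ...] = ()
    weight: float | None = None
    slip_events: int = 0

    @property
    def linker_nt(self) -> int:
        return len(self.linker)

    @property
    def repeat_count(self) -> Fraction | None:
        if self.motif is None:
            return None
        return Fraction(self.linker_nt, self.motif.unit_nt)

    @property
    def linker_aa(self) -> Fraction:
        return Fraction(self.linker_nt, 3)

    @property
    def linker_peptide(self) -> str:
        return translate(self.linker) if self.linker_nt >= 3 else ""

    @property
    def in_frame(self) -> bool:
        if self.linker_nt % 3 != 0:
            return False
        return self.linker_nt == 0 or "*" not in self.linker_peptide


def enumerate_registers(
    fwd_tail: str,
    template_repeat_block: str,
    min_overlap: MinOverlap | None = None,
    unit_nt: int | None = None,
) -> list[AnnealingRegister]:
    """All extensible annealing registers of ``fwd_tail`` on a template block.

    ``template_repeat_block`` is given 5'→3' as written on the template
    strand (e.g. a reverse primer's tail of reverse-complemented units).
    Registers are ordered by decreasing overlap, then decreasing offset, then
    lexicographically by paired sequence — a fixed total order so downstream
    output is reproducible.
    """
    tail = _normalize(fwd_tail, what="forward tail")
    block = _normalize(template_repeat_block, what="template block")
    if not tail or not block:
        raise ValueError("tail and template block must be non-empty")
    rule = min_overlap or MinOverlap()
    B = revcomp(block)
    nT, nB = len(tail), len(B)
    registers = []
    for s in range(-(nT - 1), nB - nT + 1):
        i0 = max(0, -s)
        if tail[i0:] != B[s + i0 : s + nT]:
            continue
        paired = tail[i0:]
        if not rule.accepts(paired, unit_nt):
            continue
        tm = None
        if len(paired) >= 8:
            tm = tm_salt_adjusted(paired, rule.tm_params)
        registers.append(
            AnnealingRegister(
                overlap_nt=len(paired),
                offset_nt=max(0, s),
                shift=s,
                paired_seq=paired,
                overlap_tm=tm,
            )
        )
    return sorted(registers, key=AnnealingRegister.sort_key)


def _product_linker(fwd_tail: str, template_block: str, register: AnnealingRegister) -> str:
    B = revcomp(template_block)
    return fwd_tail + B[register.shift + len(fwd_tail):]


def extend_register(
    fwd: PrimerSpec, rev: PrimerSpec, register: AnnealingRegister, born_cycle: int = 1
) -> Amplicon:
    """Extension product of one primer-on-primer register.

    The amplicon carries both homology arms: forward arm, linker, then the
    sense equivalent of the reverse primer's arm.
    """
    if not register.fwd_3prime_paired:
        raise ProtatetherError("register is not extensible (forward 3' end unpaired)")
    linker = _product_linker(fwd.tail, rev.tail, register)
    rev_arm_sense = revcomp(rev.arm)
    return Amplicon(
        seq=fwd.arm + linker + rev_arm_sense,
        linker=linker,
        fwd_arm=fwd.arm,
        rev_arm_sense=rev_arm_sense,
        motif=fwd.motif or rev.motif,
        born_cycle=born_cycle,
        provenance=(f"register(overlap={register.overlap_nt},offset={register.offset_nt})",),
    )


def apply_slippage(
    amplicon: Amplicon, motif: LinkerMotif, mode: str, max_events: int = 1
) -> list[Amplicon]:
    """Single-unit repeat slippage variants of a whole-unit amplicon.

    ``contraction_only`` emits the (n-1)-unit variant (never below one unit);
    ``both`` additionally emits n+1.  Slippage applies only to linkers that
    are a whole tandem array of ``motif`` — gain or loss of a whole unit is
    the only frame-preserving copy error in such an array.
    """
    if mode == "off":
        return []
    if mode not in ("contraction_only", "both"):
        raise ValueError(f"unknown slippage mode {mode!r}")
    if amplicon.slip_events >= max_events:
        return []
    u = motif.unit_nt
    n, rem = divmod(amplicon.linker_nt, u)
    if rem != 0 or amplicon.linker != motif.codon_unit * n:
        return []
    out = []
    counts = []
    if n >= 2:
        counts.append(n - 1)
    if mode == "both":
        counts.append(n + 1)
    for m in counts:
        linker = motif.codon_unit * m
        out.append(
            replace(
                amplicon,
                seq=amplicon.fwd_arm + linker + amplicon.rev_arm_sense,
                linker=linker,
                provenance=amplicon.provenance + (f"slippage({n}->{m})",),
                slip_events=amplicon.slip_events + 1,
            )
        )
    return out


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a library-generation PCR run.

    Defaults mirror the reference protocol: 35 thermal cycles, a Tm-based
    overlap-stability floor of 55 °C (which rejects single-unit 9-nt GGS
    overlaps and accepts 2-unit 18-nt overlaps), and contraction-only
    slippage with at most one event per lineage.
    """

    cycles: int = 35
    min_overlap: MinOverlap = field(default_factory=MinOverlap)
    slippage: str = "contraction_only"
    max_slippage_events: int = 1
    stochastic: bool = False
    n_draws: int = 10000
    seed: int = 0
    weight_model: str = "overlap_exp2"
    slip_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.slippage not in ("off", "contraction_only", "both"):
            raise ValueError(f"unknown slippage mode {self.slippage!r}")
        if self.weight_model != "overlap_exp2":
            raise ValueError(f"unknown weight model {self.weight_model!r}")


@dataclass(frozen=True)
class PredictionEntry:
    repeat_count: Fraction | None
    linker: str
    linker_nt: int
    linker_aa: Fraction
    linker_peptide: str
    amplicon_nt: int
    first_reachable_cycle: int
    weight: float
    provenance: tuple[str, ...] = ()


@dataclass
class LibraryPrediction:
    """The reachable linker library of a primer pair under one configuration."""

    fwd: PrimerSpec
    rev: PrimerSpec
    config: SimConfig
    entries: list[PredictionEntry]

    @property
    def motif(self) -> LinkerMotif | None:
        return self.fwd.motif or self.rev.motif

    def reachable_counts(self) -> list[Fraction]:
        return sorted(e.repeat_count for e in self.entries if e.repeat_count is not None)

    def reachable_int_counts(self) -> set[int]:
        """Whole-unit repeat counts in the reachable set."""
        return {
            int(e.repeat_count)
            for e in self.entries
            if e.repeat_count is not None and e.repeat_count.denominator == 1
        }

    @property
    def min_linker_aa(self) -> int:
        return int(min(e.linker_aa for e in self.entries))

    @property
    def max_linker_aa(self) -> int:
        return int(max(e.linker_aa for e in self.entries))

    def amplicons(self) -> list[Amplicon]:
        rev_arm_sense = revcomp(self.rev.arm)
        return [
            Amplicon(
                seq=self.fwd.arm + e.linker + rev_arm_sense,
                linker=e.linker,
                fwd_arm=self.fwd.arm,
                rev_arm_sense=rev_arm_sense,
                motif=self.motif,
                born_cycle=e.first_reachable_cycle,
                provenance=e.provenance,
                weight=e.weight,
            )
            for e in self.entries
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rc = e.repeat_count
            rows.append(
                {
                    "repeat_count": float(rc) if rc is not None else None,
                    "linker_nt": e.linker_nt,
                    "linker_aa": float(e.linker_aa),
                    "linker_peptide": e.linker_peptide,
                    "amplicon_nt": e.amplicon_nt,
                    "first_reachable_cycle": e.first_reachable_cycle,
                    "weight": e.weight,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Full provenance graph of the prediction as JSON."""
        payload = {
            "fwd": {"name": self.fwd.name, "sequence": self.fwd.sequence},
            "rev": {"name": self.rev.name, "sequence": self.rev.sequence},
            "config": {
                "cycles": self.config.cycles,
                "min_overlap_mode": self.config.min_overlap.mode,
                "anneal_temp_C": self.config.min_overlap.anneal_temp_C,
                "min_nt": self.config.min_overlap.min_nt,
                "min_units": self.config.min_overlap.min_units,
                "slippage": self.config.slippage,
                "max_slippage_events": self.config.max_slippage_events,
                "stochastic": self.config.stochastic,
                "seed": self.config.seed,
                "weight_model": self.config.weight_model,
            },
            "entries": [
                {
                    "repeat_count": str(e.repeat_count) if e.repeat_count is not None else None,
                    "linker_nt": e.linker_nt,
                    "linker_peptide": e.linker_peptide,
                    "amplicon_nt": e.amplicon_nt,
                    "first_reachable_cycle": e.first_reachable_cycle,
                    "weight": e.weight,
                    "provenance": list(e.provenance),
                }
                for e in self.entries
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulate_cycles(fwd: PrimerSpec, rev: PrimerSpec, config: SimConfig | None = None) -> LibraryPrediction:
    """Enumerate the linker library reachable from one primer pair.

    Cycle 1 enumerates forward-primer-on-reverse-primer registers; every later
    cycle additionally enumerates forward-primer-on-product registers, with
    existing products serving as templates (primers are in vast molar excess,
    so product-product annealing is ignored).  Out-of-frame or stop-containing
    linkers are discarded — they cannot yield a viable fusion clone.

    Deterministic mode reports the reachable set with analytic stability
    weights (each generation event weighted by 2^(overlap in motif units),
    slippage events down-weighted by ``slip_weight``, normalised at the end).
    Stochastic mode resamples those weights as a seeded multinomial draw of
    ``n_draws`` molecules, emulating the sampling noise of a finite screen.
    """
    config = config or SimConfig()
    motif = fwd.motif or rev.motif
    if fwd.motif is not None and rev.motif is not None and fwd.motif.name != rev.motif.name:
        raise IncompatiblePrimersError(
            f"primers carry different motifs: {fwd.motif.name} vs {rev.motif.name}"
        )
    if not fwd.tail or not rev.tail:
        raise IncompatiblePrimersError("both primers need a repeat tail to seed a library")
    if not enumerate_registers(fwd.tail, rev.tail, MinOverlap(mode="nt", min_nt=1)):
        raise IncompatiblePrimersError(
            "no complementary tail window between the primer pair at any overlap"
        )
    unit_nt = motif.unit_nt if motif else None

    # state: linker sequence -> bookkeeping
    state: dict[str, dict] = {}

    def admit(linker: str, cycle: int, weight: float, slip: int, prov: tuple[str, ...]) -> bool:
        nt = len(linker)
        if nt % 3 != 0 or (nt >= 3 and "*" in translate(linker)):
            return False
        rec = state.get(linker)
        if rec is None:
            state[linker] = {"cycle": cycle, "weight": weight, "slip": slip, "prov": prov}
            return True
        rec["weight"] += weight
        rec["slip"] = min(rec["slip"], slip)
        return False

    def register_weight(reg: AnnealingRegister) -> float:
        u = unit_nt or 3
        return float(2.0 ** (reg.overlap_nt / u))

    def slip_variants(linker: str, cycle: int, parent_w: float, parent_slip: int, prov: tuple[str, ...]) -> None:
        if config.slippage == "off" or motif is None or parent_slip >= config.max_slippage_events:
            return
        u = motif.unit_nt
        n, rem = divmod(len(linker), u)
        if rem != 0 or linker != motif.codon_unit * n:
            return
        targets = []
        if n >= 2:
            targets.append(n - 1)
        if config.slippage == "both":
            targets.append(n + 1)
        for m in targets:
            admit(
                motif.codon_unit * m,
                cycle,
                parent_w * config.slip_weight,
                parent_slip + 1,
                prov + (f"slippage({n}->{m})",),
            )

    # cycle 1: primer-on-primer
    for reg in enumerate_registers(fwd.tail, rev.tail, config.min_overlap, unit_nt):
        linker = _product_linker(fwd.tail, rev.tail, reg)
        w = register_weight(reg)
        prov = (f"cycle1:primer-on-primer(overlap={reg.overlap_nt},offset={reg.offset_nt})",)
        admit(linker, 1, w, 0, prov)
        slip_variants(linker, 1, w, 0, prov)

    # cycles 2..C: forward primer on products
    processed_templates: set[str] = set()
    for cycle in range(2, config.cycles + 1):
        templates = [l for l in state if l not in processed_templates]
        if not templates:
            break
        new_any = False
        for template_linker in sorted(templates):
            processed_templates.add(template_linker)
            parent = state[template_linker]
            # the product's bottom strand presents revcomp(linker) as template
            for reg in enumerate_registers(
                fwd.tail, revcomp(template_linker), config.min_overlap, unit_nt
            ):
                linker = _product_linker(fwd.tail, revcomp(template_linker), reg)
                w = parent["weight"] * register_weight(reg)
                prov = (
                    f"cycle{cycle}:primer-on-product(len={len(template_linker)},"
                    f"overlap={reg.overlap_nt},offset={reg.offset_nt})",
                )
                created = admit(linker, cycle, w, parent["slip"], prov)
                if created:
                    new_any = True
                    slip_variants(linker, cycle, w, parent["slip"], prov)
        if not new_any and all(l in processed_templates for l in state):
            break

    # weights
    arm_nt = len(fwd.arm) + len(rev.arm)
    linkers = sorted(state)
    raw = np.array([state[l]["weight"] for l in linkers], dtype=float)
    if len(raw):
        probs = raw / raw.sum()
        if config.stochastic:
            rng = np.random.default_rng(config.seed)
            counts = rng.multinomial(config.n_draws, probs)
            probs = counts / counts.sum()
        weights = {l: float(p) for l, p in zip(linkers, probs)}
    else:
        weights = {}

    entries = []
    for linker in linkers:
        rec = state[linker]
        nt = len(linker)
        entries.append(
            PredictionEntry(
                repeat_count=Fraction(nt, motif.unit_nt) if motif else None,
                linker=linker,
                linker_nt=nt,
                linker_aa=Fraction(nt, 3),
                linker_peptide=translate(linker) if nt >= 3 else "",
                amplicon_nt=arm_nt + nt,
                first_reachable_cycle=rec["cycle"],
                weight=weights[linker],
                provenance=rec["prov"],
            )
        )
    entries.sort(key=lambda e: e.linker_nt)
    return LibraryPrediction(fwd=fwd, rev=rev, config=config, entries=entries)


def band_table(prediction: LibraryPrediction) -> pd.DataFrame:
    """Predicted gel bands, longest first (gel order), with the modal band flagged.

    Ties in weight are broken toward the longer band (the first row in gel
    order), matching the documented tie-break.
    """
    if not prediction.entries:
        raise ValueError("cannot tabulate bands of an empty prediction")
    df = prediction.to_frame().sort_values(
        "amplicon_nt", ascending=False, kind="mergesort"
    )[["repeat_count", "amplicon_nt", "weight"]].reset_index(drop=True)
    modal = df["weight"].to_numpy().argmax()  # first max -> longest on ties
    df["modal"] = [i == modal for i in range(len(df))]
    return df
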