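"""Classification of colony-screening reads into linker calls.

After transformation, colonies are characterised by Sanger sequencing across
the linker junction.  Each read is classified by locating both homology arms
(on either strand), extracting the intervening sequence and matching it
against a panel of linker motifs by smallest-period analysis.  Every failure
mode is a status, never an exception: reads missing an arm are ``no_call``,
arms directly adjacent are ``no_linker`` (vector re-circularisation), and
off-frame or unrecognised inserts are ``aberrant``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_seq import DnaRecord, LinkerMotif, revcomp, smallest_period, translate

__all__ = ["LinkerCall", "classify_read", "summarize_screen"]


@dataclass(frozen=True)
class LinkerCall:
    """Classification of one screening read."""

    read_id: str
    status: str  # insert | no_linker | aberrant | no_call
    motif: str | None = None
    repeat_count: int | None = None
    linker_aa: int | None = None
    frame_ok: bool = False


def _find_with_mismatches(hay: str, needle: str, max_mismatch: int) -> int:
    """Leftmost start of ``needle`` in ``hay`` allowing Hamming mismatches; -1 if none."""
    if max_mismatch == 0:
        return hay.find(needle)
    n, m = len(hay), len(needle)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(hay[i : i + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return -1


def _locate_arms(seq: str, fwd_arm: str, rev_arm_sense: str, max_mismatch: int) -> tuple[int, int] | None:
    i = _find_with_mismatches(seq, fwd_arm, max_mismatch)
    if i < 0:
        return None
    j = _find_with_mismatches(seq[i + len(fwd_arm):], rev_arm_sense, max_mismatch)
    if j < 0:
        return None
    return i + len(fwd_arm), i + len(fwd_arm) + j


def classify_read(
    read: DnaRecord | str,
    fwd_arm: str,
    rev_arm_sense: str,
    motif_panel: Sequence[LinkerMotif],
    max_mismatch: int = 0,
) -> LinkerCall:
    """Classify a Sanger-style read spanning the linker junction.

    ``fwd_arm`` is the sense sequence of the upstream junction arm and
    ``rev_arm_sense`` the sense sequence of the downstream gene's start; the
    read is tried on both strands.  Motif matching prefers the panel motif
    whose unit length equals the smallest period of the insert; ties are
    broken by panel order.
    """
    if min(len(fwd_arm), len(rev_arm_sense)) < 10:
        raise ValueError("arms must be at least 10 nt for confident classification")
    if isinstance(read, DnaRecord):
        read_id, seq = read.id, read.seq
    else:
        read_id, seq = "read", str(read).upper()

    oriented = seq
    located = _locate_arms(oriented, fwd_arm, rev_arm_sense, max_mismatch)
    if located is None:
        oriented = revcomp(seq)
        located = _locate_arms(oriented, fwd_arm, rev_arm_sense, max_mismatch)
    if located is None:
        return LinkerCall(read_id, "no_call")

    start, end = located
    insert = oriented[start:end]
    if not insert:
        return LinkerCall(read_id, "no_linker", repeat_count=0, linker_aa=0, frame_ok=True)
    if len(insert) % 3 != 0:
        return LinkerCall(read_id, "aberrant", frame_ok=False)

    period = smallest_period(insert)
    candidates = [
        m
        for m in motif_panel
        if len(insert) % m.unit_nt == 0 and insert == m.codon_unit * (len(insert) // m.unit_nt)
    ]
    if not candidates:
        return LinkerCall(read_id, "aberrant", frame_ok=True)
    # prefer the motif whose unit is the smallest period; stable on ties
    candidates.sort(key=lambda m: (m.unit_nt != period,))
    motif = candidates[0]
    n = len(insert) // motif.unit_nt
    frame_ok = "*" not in translate(insert)
    if not frame_ok:
        return LinkerCall(read_id, "aberrant", frame_ok=False)
    return LinkerCall(
        read_id,
        "insert",
        motif=motif.name,
        repeat_count=n,
        linker_aa=len(insert) // 3,
        frame_ok=True,
    )


def summarize_screen(calls: Iterable[LinkerCall], pair: str = "") -> pd.DataFrame:
    """One screen-summary row per primer pair label.

    Columns mirror a colony-screen results table: colonies sequenced,
    colonies with inserts, a formatted per-repeat-count frequency string like
    ``"1X(1), 2X(2), 3X(2), 4X(4)"``, and separate no-linker / aberrant /
    no-call tallies (the categories are kept apart rather than collapsed).
    """
    calls = list(calls)
    if not calls:
        return pd.DataFrame(
            columns=[
                "primer_pair", "colonies_sequenced", "colonies_with_inserts",
                "result", "no_linker", "aberrant", "no_call",
            ]
        )
    inserts = [c for c in calls if c.status == "insert"]
    freq: dict[int, int] = {}
    for c in inserts:
        freq[c.repeat_count] = freq.get(c.repeat_count, 0) + 1
    result = ", ".join(f"{n}X({freq[n]})" for n in sorted(freq))
    row = {
        "primer_pair": pair,
        "colonies_sequenced": len(calls),
        "colonies_with_inserts": len(inserts),
        "result": result or "No inserts",
        "no_linker": sum(c.status == "no_linker" for c in calls),
        "aberrant": sum(c.status == "aberrant" for c in calls),
        "no_call": sum(c.status == "no_call" for c in calls),
    }
    return pd.DataFrame([row])
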