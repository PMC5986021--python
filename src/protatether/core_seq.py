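"""Nucleotide and peptide primitives shared by every other module.

This module holds the small algebra the whole package is built on:

* :class:`DnaRecord` — a named DNA sequence with linear/circular topology and
  lightweight interval features (the substrate of primer design, simulation
  and assembly);
* :class:`LinkerMotif` — a tandem-repeat linker unit (amino-acid unit plus the
  codon unit that encodes it), with a registry of the stock motifs the package
  ships (GGS, GGSD, polyG, polyK, polyL, polyKR);
* repeat-unit string algebra: :func:`revcomp`, :func:`translate`,
  :func:`smallest_period`, :func:`frame_ambiguity_check`;
* FASTA/GenBank I/O (:func:`read_records` / :func:`write_records`), delegated
  to Biopython's ``SeqIO``.

Conventions
-----------
All coordinates are 0-based, half-open.  Sequences are normalised to uppercase
DNA over ``{A, C, G, T}``; ``U`` and IUPAC ambiguity codes are rejected, since
primer design requires exact sequence.  Circular records are handled by
rotating them so that regions of interest never span the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "ProtatetherError",
    "InvalidAlphabetError",
    "Feature",
    "DnaRecord",
    "LinkerMotif",
    "MOTIFS",
    "revcomp",
    "translate",
    "smallest_period",
    "frame_ambiguity_check",
    "read_records",
    "write_records",
]


class ProtatetherError(Exception):
    """Base class for all errors raised by this package."""


class InvalidAlphabetError(ProtatetherError, ValueError):
    """A sequence contains characters outside ``{A, C, G, T}``."""


_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it is plain DNA."""
    s = str(seq).upper()
    bad = set(s) - _DNA
    if bad:
        raise InvalidAlphabetError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string.

    An involution: ``revcomp(revcomp(s)) == s`` for every valid input.  The
    empty string maps to itself.
    """
    return _normalize(seq)[::-1].translate(_COMPLEMENT)


def translate(seq: str, frame: int = 0) -> str:
    """Translate complete codons of ``seq`` starting at ``frame``.

    Translation uses the standard genetic code and halts at the first stop
    codon, which is reported as a trailing ``*``.  Trailing bases that do not
    fill a codon are ignored.

    Raises
    ------
    ValueError
        If ``frame`` is not 0, 1 or 2, or if fewer than one complete codon is
        available from ``frame``.
    """
    s = _normalize(seq)
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    coding = s[frame:]
    if len(coding) < 3:
        raise ValueError(
            f"need at least one complete codon after frame {frame}; "
            f"sequence has {len(coding)} nt"
        )
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[: stop + 1]


def smallest_period(seq: str) -> int:
    """Smallest ``p`` such that ``seq`` is a prefix of ``(seq[:p]) * inf``.

    Equivalently the smallest ``p`` with ``seq[i] == seq[i - p]`` for all
    ``i >= p``.  ``p`` need not divide ``len(seq)``.
    """
    if not seq:
        raise ValueError("smallest_period of the empty string is undefined")
    n = len(seq)
    for p in range(1, n + 1):
        if all(seq[i] == seq[i - p] for i in range(p, n)):
            return p
    return n  # pragma: no cover - loop always returns


def frame_ambiguity_check(codon_unit: str) -> bool:
    """Accept a codon unit whose tandem array cannot hide a frameshift.

    A unit is rejected when the infinite tandem array of the unit is invariant
    under a shift of 1 or 2 nucleotides: losing or gaining one or two bases in
    such an array is invisible at the sequence level, so repeat counts (and
    hence reading frame) become ambiguous.  ``AAA`` (poly-Lys via the Lys
    codon AAA) is the canonical reject; ``AAG`` encodes the same residue and
    is accepted, which is why the stock poly-Lys motif uses it.

    Returns ``True`` for accept, ``False`` for reject.
    """
    unit = _normalize(codon_unit, what="codon unit")
    if len(unit) % 3 != 0 or not unit:
        raise ValueError(
            f"codon unit length must be a positive multiple of 3, got {len(unit)}"
        )
    arr = unit * 3
    window = 2 * len(unit)
    for shift in (1, 2):
        if arr[:window] == arr[shift : shift + window]:
            return False
    return True


# ---------------------------------------------------------------------------
# Records and features
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """A named, stranded interval on a :class:`DnaRecord` (0-based, half-open)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DnaRecord:
    """A named DNA sequence with topology and annotated features."""

    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = _normalize(self.seq, what=f"record {self.id!r}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.name!r} extends past the end of record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def feature(self, name: str) -> Feature:
        """Return the unique feature called ``name``."""
        hits = [f for f in self.features if f.name == name]
        if len(hits) != 1:
            raise KeyError(
                f"record {self.id!r}: expected exactly one feature {name!r}, "
                f"found {len(hits)}"
            )
        return hits[0]

    def find_all(self, sub: str) -> list[int]:
        """Start positions of exact sense-strand occurrences of ``sub``.

        On circular records occurrences spanning the origin are found by
        searching the doubled sequence; positions are reported mod length.
        """
        sub = _normalize(sub, what="query")
        if not sub:
            raise ValueError("cannot search for an empty sequence")
        hay = self.seq + (self.seq[: len(sub) - 1] if self.is_circular else "")
        positions, start = [], 0
        while True:
            i = hay.find(sub, start)
            if i < 0 or i >= len(self.seq):
                break
            positions.append(i)
            start = i + 1
        return positions

    def rotate(self, offset: int) -> "DnaRecord":
        """Rotate a circular record so position ``offset`` becomes position 0.

        Features are shifted accordingly; a feature that would span the new
        origin is dropped (callers choose rotations that avoid this).
        """
        if not self.is_circular:
            raise ValueError("only circular records can be rotated")
        n = len(self.seq)
        offset %= n
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % n
            e = s + f.length
            if e <= n:
                feats.append(Feature(f.name, s, e, f.strand))
        return DnaRecord(self.id, seq, "circular", feats)


# ---------------------------------------------------------------------------
# Linker motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkerMotif:
    """A tandem-repeat linker unit.

    ``naming_convention`` records how repeat counts are labelled for this
    motif: single-amino-acid motifs are conventionally counted in codons
    (a "12X" poly-Gly linker is 12 Gly codons), while multi-amino-acid motifs
    are counted in whole units (a "4X" GGS linker is four GGS units).
    """

    name: str
    aa_unit: str
    codon_unit: str
    naming_convention: str = "unit-count"

    def __post_init__(self) -> None:
        object.__setattr__(self, "codon_unit", _normalize(self.codon_unit, what="codon unit"))
        if self.naming_convention not in ("unit-count", "codon-count"):
            raise ValueError(f"unknown naming convention {self.naming_convention!r}")
        if len(self.codon_unit) != 3 * len(self.aa_unit):
            raise ValueError(
                f"motif {self.name!r}: codon unit length {len(self.codon_unit)} "
                f"does not encode {len(self.aa_unit)} residues"
            )
        if translate(self.codon_unit) != self.aa_unit:
            raise ValueError(
                f"motif {self.name!r}: codon unit {self.codon_unit} does not "
                f"translate to {self.aa_unit}"
            )
        if not frame_ambiguity_check(self.codon_unit):
            raise ValueError(
                f"motif {self.name!r}: codon unit {self.codon_unit} is "
                "frame-ambiguous (tandem array invariant under a 1- or 2-nt shift)"
            )

    @property
    def unit_nt(self) -> int:
        return len(self.codon_unit)

    def repeat(self, n: int) -> str:
        """The nucleotide sequence of ``n`` tandem units."""
        if n < 0:
            raise ValueError("repeat count must be non-negative")
        return self.codon_unit * n


#: Stock motif registry.  Codon units are the package defaults for each linker
#: chemistry; the poly-Lys unit is AAG (not AAA) and poly-Leu is CTT so that
#: every unit passes the frame-ambiguity check.
MOTIFS: dict[str, LinkerMotif] = {
    m.name: m
    for m in (
        LinkerMotif("GGS", "GGS", "GGCGGCAGC", "unit-count"),
        LinkerMotif("GGSD", "GGSD", "GGCGGCAGCGAC", "unit-count"),
        LinkerMotif("polyG", "G", "GGC", "codon-count"),
        LinkerMotif("polyK", "K", "AAG", "codon-count"),
        LinkerMotif("polyL", "L", "CTT", "codon-count"),
        LinkerMotif("polyKR", "KR", "AAACGC", "unit-count"),
    )
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMAT_ALIASES = {
    "fasta": "fasta",
    "fa": "fasta",
    "fna": "fasta",
    "genbank": "genbank",
    "gb": "genbank",
    "gbk": "genbank",
}


def _guess_format(path: Path) -> str:
    fmt = _FORMAT_ALIASES.get(path.suffix.lstrip(".").lower())
    if fmt is None:
        raise ValueError(f"cannot guess format from extension of {path}")
    return fmt


def _to_bio(record: DnaRecord) -> _BioRecord:
    bio = _BioRecord(Seq(record.seq), id=record.id, name=record.id[:16], description="")
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = record.topology
    for f in record.features:
        loc = SimpleLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        bio.features.append(
            SeqFeature(loc, type="misc_feature", qualifiers={"label": [f.name]})
        )
    return bio


def _from_bio(bio: _BioRecord) -> DnaRecord:
    topology = bio.annotations.get("topology", "linear")
    feats = []
    for sf in bio.features:
        if sf.type == "source":
            continue
        label = sf.qualifiers.get("label") or sf.qualifiers.get("gene") or [sf.type]
        start, end = int(sf.location.start), int(sf.location.end)
        if start >= end:
            continue
        strand = "-" if sf.location.strand == -1 else "+"
        feats.append(Feature(str(label[0]), start, end, strand))
    return DnaRecord(bio.id, str(bio.seq), topology, feats)


def read_records(path: str | Path, format: str | None = None) -> list[DnaRecord]:
    """Read FASTA or GenBank records from ``path``.

    The GenBank LOCUS circular flag is honoured; FASTA records come back
    linear with no features (the format cannot carry either).
    """
    path = Path(path)
    fmt = _FORMAT_ALIASES[format.lower()] if format else _guess_format(path)
    try:
        records = [_from_bio(b) for b in SeqIO.parse(str(path), fmt)]
    except (ValueError, KeyError) as exc:
        raise ProtatetherError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not records:
        # Biopython returns an empty iterator for unparseable content
        raise ProtatetherError(f"no {fmt} records found in {path}")
    return records


def write_records(
    records: Iterable[DnaRecord] | DnaRecord,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write records to FASTA (wrapped at 60 columns) or GenBank."""
    if isinstance(records, DnaRecord):
        records = [records]
    path = Path(path)
    fmt = _FORMAT_ALIASES[format.lower()] if format else _guess_format(path)
    SeqIO.write([_to_bio(r) for r in records], str(path), fmt)
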