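"""Chou-Fasman helix-propensity flagging of linker peptides.

Rigid (helix-forming) linkers behave very differently from flexible (coil)
linkers in a fusion, so the package flags each linker peptide as
``helix_prone`` or ``coil_flexible`` from the mean Chou-Fasman alpha-helix
propensity (Pα) of its residues.  The embedded table is the classical
per-residue propensity set; a mean Pα at or above the threshold (default
1.03) marks a peptide as helix-prone.  With that threshold the stock
comparison panel — G12, K12, L10, KR6 and GGS4X — splits into three
helix-prone peptides (K12, L10, KR6) and two flexible coils (G12, GGS4X).
Beta-strand propensity (Pβ) is reported for reference but plays no part in
the classification: the operative contrast for linkers is helix vs coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "P_ALPHA",
    "P_BETA",
    "DEFAULT_THRESHOLD",
    "DEFAULT_PANEL",
    "PropensityProfile",
    "helix_propensity",
    "classify_linker_panel",
]

#: Chou-Fasman alpha-helix propensities (Pα) per residue.
P_ALPHA: dict[str, float] = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

#: Chou-Fasman beta-strand propensities (Pβ), reported but not classified on.
P_BETA: dict[str, float] = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

DEFAULT_THRESHOLD = 1.03

#: The stock comparison panel of linker peptides.
DEFAULT_PANEL: list[tuple[str, str]] = [
    ("G12", "G" * 12),
    ("K12", "K" * 12),
    ("L10", "L" * 10),
    ("KR6", "KR" * 6),
    ("GGS4X", "GGS" * 4),
]


@dataclass(frozen=True)
class PropensityProfile:
    peptide: str
    per_residue_p_alpha: tuple[float, ...]
    mean_p_alpha: float
    classification: str
    per_residue_p_beta: tuple[float, ...]
    mean_p_beta: float


def helix_propensity(peptide: str, threshold: float = DEFAULT_THRESHOLD) -> PropensityProfile:
    """Per-residue and mean Pα of ``peptide``, with a helix/coil call.

    ``classification`` is ``helix_prone`` iff mean Pα >= ``threshold``, else
    ``coil_flexible``.  The peptide must be at least 3 residues of the 20
    standard amino acids.
    """
    pep = str(peptide).upper()
    if len(pep) < 3:
        raise ValueError("peptide must be at least 3 residues")
    bad = set(pep) - set(P_ALPHA)
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)!r}")
    pa = tuple(P_ALPHA[r] for r in pep)
    pb = tuple(P_BETA[r] for r in pep)
    mean_pa = sum(pa) / len(pa)
    return PropensityProfile(
        peptide=pep,
        per_residue_p_alpha=pa,
        mean_p_alpha=mean_pa,
        classification="helix_prone" if mean_pa >= threshold else "coil_flexible",
        per_residue_p_beta=pb,
        mean_p_beta=sum(pb) / len(pb),
    )


def classify_linker_panel(
    linkers: Sequence[tuple[str, str]] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Classify a panel of (name, peptide) linkers; defaults to the stock panel."""
    if linkers is None:
        linkers = DEFAULT_PANEL
    rows = []
    for name, pep in linkers:
        prof = helix_propensity(pep, threshold)
        rows.append(
            {
                "name": name,
                "peptide": pep,
                "mean_p_alpha": round(prof.mean_p_alpha, 4),
                "mean_p_beta": round(prof.mean_p_beta, 4),
                "classification": prof.classification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "peptide", "mean_p_alpha", "mean_p_beta", "classification"],
    )
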