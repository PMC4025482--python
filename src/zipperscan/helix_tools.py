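"""Helical-wheel projection and sequence-logo statistics.

The wheel projects a peptide down an ideal α-helix axis at 100° per residue
(3.6 residues/turn), placing the first projected residue at 12 o'clock and
advancing clockwise when viewed from the N-terminus.  Amphipathicity is then
summarized per heptad face: hydrophobicity of the a/d core, polarity of the
outward b/c/f face, and presence of charge at the specificity positions
e/g.

Logos are summarized numerically: per-position residue frequencies and
information content in bits, ``info = log2(20) − H`` with ``H`` the Shannon
entropy of the position, optionally with the standard small-sample
correction ``e(n) = (20−1)/(2·ln2·n)``.  The background is uniform over the
20 residues and no pseudocounts are added, so the closed forms (log2 20 at
zero entropy, 0 at the uniform limit) hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import (
    ACIDIC,
    BASIC,
    DEFAULT_CLASSES,
    HYDROPHOBIC,
    POLAR,
    Peptide,
    ResidueClassTable,
    classify_residue,
)
from .heptad_zipper import HEPTAD_LETTERS

#: Ideal α-helix rotation per residue, degrees.
ROTATION_DEG = 100.0

#: Fixed alphabet order used for logo frequency matrices.
AA_ORDER = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

MAX_INFO_BITS = math.log2(20)


@dataclass(frozen=True)
class WheelResidue:
    index: int          # 1-based position in the peptide
    residue: str
    angle_degrees: float
    heptad_letter: str | None
    residue_class: str


@dataclass(frozen=True)
class WheelProjection:
    """Helical-wheel projection of a peptide."""

    peptide_id: str
    register_start: int
    rotation: float
    residues: tuple[WheelResidue, ...]

    def at_letter(self, letter: str) -> list[WheelResidue]:
        """All residues assigned a given heptad letter."""
        return [r for r in self.residues if r.heptad_letter == letter]


def project_wheel(
    peptide: Peptide,
    register_start: int = 1,
    table: ResidueClassTable | None = None,
    rotation: float = ROTATION_DEG,
) -> WheelProjection:
    """Project a peptide onto a helical wheel.

    Residue ``i`` sits at ``((i − 1) × rotation) mod 360`` degrees, residue 1
    at 0°.  Heptad letters a–g are assigned cyclically starting at
    ``register_start`` (the *a* of the first heptad) and cover only complete
    heptads; residues before the register start or in a trailing partial
    heptad carry no letter.
    """
    if len(peptide) < 7:
        raise ValueError(f"peptide {peptide.id!r} shorter than one heptad")
    if not 1 <= register_start <= len(peptide):
        raise ValueError(
            f"register_start {register_start} outside 1..{len(peptide)}"
        )
    table = table if table is not None else DEFAULT_CLASSES
    n_complete = (len(peptide) - register_start + 1) // 7
    lettered_end = register_start + 7 * n_complete - 1

    residues = []
    for i, aa in enumerate(peptide.sequence, start=1):
        letter = None
        if register_start <= i <= lettered_end:
            letter = HEPTAD_LETTERS[(i - register_start) % 7]
        residues.append(
            WheelResidue(
                index=i,
                residue=aa,
                angle_degrees=((i - 1) * rotation) % 360.0,
                heptad_letter=letter,
                residue_class=classify_residue(aa, table),
            )
        )
    return WheelProjection(
        peptide_id=peptide.id,
        register_start=register_start,
        rotation=rotation,
        residues=tuple(residues),
    )


def face_summary(
    projection: WheelProjection, table: ResidueClassTable | None = None
) -> dict:
    """Summarize amphipathicity of the lettered heptad faces.

    Reports the hydrophobic fraction of the a/d core, the polar fraction of
    the outward b/c/f face, and any charged residues at the specificity
    positions e and g (with their 1-based indices).
    """
    if table is not None:
        classes = {
            r.index: classify_residue(r.residue, table) for r in projection.residues
        }
    else:
        classes = {r.index: r.residue_class for r in projection.residues}

    ad = [r for letter in "ad" for r in projection.at_letter(letter)]
    bcf = [r for letter in "bcf" for r in projection.at_letter(letter)]
    eg = [r for letter in "eg" for r in projection.at_letter(letter)]
    charged = [
        r for r in eg if classes[r.index] in (BASIC, ACIDIC)
    ]
    ad_hydro = sum(classes[r.index] == HYDROPHOBIC for r in ad)
    bcf_polar = sum(classes[r.index] == POLAR for r in bcf)
    return {
        "ad_total": len(ad),
        "ad_hydrophobic": ad_hydro,
        "ad_hydrophobic_fraction": ad_hydro / len(ad) if ad else float("nan"),
        "bcf_total": len(bcf),
        "bcf_polar": bcf_polar,
        "bcf_polar_fraction": bcf_polar / len(bcf) if bcf else float("nan"),
        "charged_eg": [
            {"index": r.index, "residue": r.residue, "letter": r.heptad_letter}
            for r in charged
        ],
        "has_charged_eg": bool(charged),
    }


@dataclass(frozen=True)
class LogoMatrix:
    """Numerical sequence-logo summary of an ungapped alignment.

    ``freq`` is an (n_positions × 20) array of relative frequencies over
    :data:`AA_ORDER`; ``info_bits`` the per-position information content;
    ``letter_heights`` their product (the stack heights a logo would draw).
    ``consensus`` is the per-position modal residue, ties broken
    alphabetically and reported in ``ties``.
    """

    n_sequences: int
    n_positions: int
    freq: np.ndarray
    info_bits: np.ndarray
    letter_heights: np.ndarray
    consensus: str
    ties: tuple[tuple[str, ...], ...]

    def frequency(self, position: int, aa: str) -> float:
        """Relative frequency of a residue at a 1-based position."""
        return float(self.freq[position - 1, _AA_INDEX[aa.upper()]])


def build_logo(
    heptads: Sequence[str], correction: str = "off"
) -> LogoMatrix:
    """Per-position frequencies and information content of aligned windows.

    All input windows must have equal length (7 for heptad alignments) and
    contain only canonical residues; gaps are disallowed.  With
    ``correction="small_sample"`` the approximate small-sample error
    ``(20−1)/(2·ln2·n)`` is subtracted from each position's information,
    floored at 0.
    """
    if correction not in ("off", "small_sample"):
        raise ValueError(f"unknown correction {correction!r}")
    if not heptads:
        raise ValueError("at least one sequence is required")
    length = len(heptads[0])
    if length == 0:
        raise ValueError("sequences must be non-empty")
    counts = np.zeros((length, 20), dtype=float)
    for seq in heptads:
        s = seq.upper()
        if len(s) != length:
            raise ValueError(
                f"mixed window lengths: {len(s)} != {length} (gaps are not allowed)"
            )
        for pos, aa in enumerate(s):
            if aa not in _AA_INDEX:
                raise ValueError(f"non-canonical residue {aa!r} in {seq!r}")
            counts[pos, _AA_INDEX[aa]] += 1

    n = len(heptads)
    freq = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    info = MAX_INFO_BITS - entropy
    if correction == "small_sample":
        info = np.maximum(info - (20 - 1) / (2 * math.log(2) * n), 0.0)
    heights = freq * info[:, None]

    consensus_chars = []
    ties: list[tuple[str, ...]] = []
    for pos in range(length):
        best = freq[pos].max()
        winners = tuple(
            aa for aa, i in _AA_INDEX.items() if freq[pos, i] == best
        )
        consensus_chars.append(winners[0])
        ties.append(winners)
    return LogoMatrix(
        n_sequences=n,
        n_positions=length,
        freq=freq,
        info_bits=info,
        letter_heights=heights,
        consensus="".join(consensus_chars),
        ties=tuple(ties),
    )
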