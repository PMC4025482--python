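"""Seeded generators for every input class the pipeline consumes.

Each generator plants a known ground truth — heptad starts, homologous
structure windows, an interaction effect — and returns it alongside the
artifact, so every analysis stage can be validated end-to-end without any
external download.  All generators are deterministic given a seed, and each
truth block records the parameters needed to regenerate the fixture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import GenotypePhenotype, Peptide
from .ss_homology import (
    StructureWindow,
    SubstitutionMatrix,
    blosum62,
    search,
)

#: Residues eligible for planted a/d core positions: hydrophobic minus proline.
HYDROPHOBIC_AD = tuple("GAVLIMFW")
#: Background residues for non-core positions: the polar class.
POLAR_BACKGROUND = tuple("STNQYC")

_SS_LABELS = tuple("HECT")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Peptides with planted heptads
# ---------------------------------------------------------------------------


def gen_zipper_peptide(
    length: int = 19,
    n_heptads: int = 2,
    register: int = 2,
    seed: int | np.random.Generator = 0,
    peptide_id: str | None = None,
) -> tuple[Peptide, dict]:
    """Generate a peptide with ``n_heptads`` consecutive planted heptads.

    Planted heptads start at 1-based position ``register`` and abut at
    spacing 7; their *a* and *d* residues are drawn from the hydrophobic
    class minus proline, every other position from the polar class.  With a
    polar background, no window outside the planted run can place both its
    *a* and *d* on hydrophobic residues, so a heptad scan recovers exactly
    the planted starts.

    Returns the peptide and a truth block with the planted starts and
    generation parameters.
    """
    rng = _rng(seed)
    if n_heptads < 0 or register < 1:
        raise ValueError("n_heptads must be >= 0 and register >= 1")
    if n_heptads > 0 and register + 7 * n_heptads - 1 > length:
        raise ValueError(
            f"cannot fit {n_heptads} heptads from position {register} "
            f"in length {length}"
        )
    seq = [str(rng.choice(POLAR_BACKGROUND)) for _ in range(length)]
    starts = [register + 7 * k for k in range(n_heptads)]
    for start in starts:
        seq[start - 1] = str(rng.choice(HYDROPHOBIC_AD))      # position a
        seq[start + 2] = str(rng.choice(HYDROPHOBIC_AD))      # position d
    peptide = Peptide(
        id=peptide_id or f"synth_zipper_n{n_heptads}",
        sequence="".join(seq),
        description=f"synthetic peptide with {n_heptads} planted heptad(s)",
    )
    truth = {
        "length": length,
        "n_heptads": n_heptads,
        "register": register,
        "planted_starts": starts,
    }
    return peptide, truth


# ---------------------------------------------------------------------------
# Structure databases with planted homologous windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedWindow:
    """Specification of one window to plant relative to a query substring."""

    query_start: int          # 1-based start of the source substring
    length: int
    n_substitutions: int = 0  # 0-2, each with strictly positive score
    ss: str = "H"             # one label, or a full per-residue string
    family_id: str = "fam_planted"
    source_id: str | None = None


def _positive_partners(matrix: SubstitutionMatrix) -> dict[str, list[str]]:
    residues = sorted({x for x, _ in matrix.scores})
    return {
        x: [y for y in residues if y != x and matrix.score(x, y) > 0]
        for x in residues
    }


def gen_structure_db(
    query: Peptide,
    planted: Sequence[PlantedWindow] = (),
    n_decoys: int = 20,
    seed: int | np.random.Generator = 0,
    decoy_length: int | None = None,
    max_tries: int = 500,
) -> tuple[list[StructureWindow], dict]:
    """Generate a structure-window database with planted homologs and decoys.

    Planted windows copy a query substring either verbatim or with 1–2
    substitutions whose per-residue scores are strictly positive, so the
    matcher must accept them.  Decoys are composition-preserving shuffles of
    query substrings, rejection-sampled until they admit no accepted
    alignment against the query; their secondary structure is random.

    Returns the windows plus a truth block naming the planted source ids.
    """
    rng = _rng(seed)
    matrix = blosum62()
    partners = _positive_partners(matrix)
    windows: list[StructureWindow] = []
    planted_ids: list[str] = []

    for k, spec in enumerate(planted):
        sub = query.sequence[spec.query_start - 1 : spec.query_start - 1 + spec.length]
        if len(sub) != spec.length:
            raise ValueError(
                f"planted window {k}: query span "
                f"{spec.query_start}..{spec.query_start + spec.length - 1} "
                f"outside query of length {len(query)}"
            )
        if not 0 <= spec.n_substitutions <= 2:
            raise ValueError("planted n_substitutions must be 0, 1 or 2")
        seq = list(sub)
        eligible = [i for i, aa in enumerate(seq) if partners[aa]]
        if len(eligible) < spec.n_substitutions:
            raise ValueError(
                f"planted window {k}: not enough positions admit a "
                f"positive-score substitution"
            )
        pos = rng.choice(len(eligible), size=spec.n_substitutions, replace=False)
        for p in np.atleast_1d(pos):
            i = eligible[int(p)]
            seq[i] = str(rng.choice(partners[seq[i]]))
        ss = spec.ss if len(spec.ss) == spec.length else spec.ss * spec.length
        windows.append(
            StructureWindow(
                source_id=spec.source_id or f"planted_{k}",
                family_id=spec.family_id,
                sequence="".join(seq),
                ss=ss,
            )
        )
        planted_ids.append(windows[-1].source_id)

    decoy_length = decoy_length or min(len(query), 12)
    decoy_ids: list[str] = []
    for k in range(n_decoys):
        start = int(rng.integers(0, len(query) - decoy_length + 1))
        base = list(query.sequence[start : start + decoy_length])
        for attempt in range(max_tries):
            rng.shuffle(base)
            candidate = StructureWindow(
                source_id=f"decoy_{k}",
                family_id=f"fam_decoy_{k}",
                sequence="".join(base),
                ss="".join(rng.choice(_SS_LABELS, size=decoy_length)),
            )
            hits = search(query, [candidate], matrix)
            if not any(m.accepted for m in hits):
                break
        else:
            raise RuntimeError(
                f"decoy {k}: no acceptable shuffle found in {max_tries} tries"
            )
        windows.append(candidate)
        decoy_ids.append(candidate.source_id)

    truth = {
        "query_id": query.id,
        "planted_ids": planted_ids,
        "planted_specs": [dataclasses.asdict(s) for s in planted],
        "decoy_ids": decoy_ids,
        "n_decoys": n_decoys,
        "decoy_length": decoy_length,
    }
    return windows, truth


# ---------------------------------------------------------------------------
# Per-fly phenotype counts
# ---------------------------------------------------------------------------


def gen_phenotype_counts(
    mu_a: float = 6.2,
    mu_b: float = 2.5,
    delta: float = -1.7,
    sigma: float = 0.7,
    n_flies: int = 50,
    tissue: str = "sex_comb",
    seed: int | np.random.Generator = 0,
    labels: tuple[str, str, str] = ("A/Df", "B/Df", "A/B"),
    noise: str = "normal",
) -> tuple[pd.DataFrame, dict[str, GenotypePhenotype], dict]:
    """Simulate per-fly counts for two hemizygotes and their trans-heterozygote.

    The hemizygotes have true means ``mu_a`` and ``mu_b``; the
    trans-heterozygote mean is ``mu_a + mu_b + delta``, so ``delta < 0``
    plants an inhibitory interaction against the additive null.  Counts are
    ``round(max(0, Normal(mu, sigma)))`` per fly (``noise="poisson"`` swaps
    in Poisson counts); summaries (mean, SEM = sd/√n) are computed from the
    simulated sample, not copied from the truth.

    The default magnitudes mirror sex-comb bristle counts: hemizygote means
    of 6.2 and 2.5 with SEM ≈ 0.1 at n = 50.
    """
    if n_flies < 2:
        raise ValueError("n_flies must be >= 2")
    if noise not in ("normal", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = _rng(seed)
    true_means = {
        labels[0]: mu_a,
        labels[1]: mu_b,
        labels[2]: mu_a + mu_b + delta,
    }
    rows = []
    summaries: dict[str, GenotypePhenotype] = {}
    for label, mu in true_means.items():
        if noise == "poisson":
            counts = rng.poisson(max(mu, 0.0), size=n_flies).astype(int)
        else:
            counts = np.round(
                np.clip(rng.normal(mu, sigma, size=n_flies), 0.0, None)
            ).astype(int)
        for fly, c in enumerate(counts, start=1):
            rows.append(
                {"genotype": label, "tissue": tissue, "fly": fly, "count": int(c)}
            )
        sem = float(np.std(counts, ddof=1) / np.sqrt(n_flies))
        summaries[label] = GenotypePhenotype(
            genotype=label,
            tissue=tissue,
            mean=float(np.mean(counts)),
            sem=sem,
            n=n_flies,
        )
    truth = {
        "mu_a": mu_a,
        "mu_b": mu_b,
        "delta": delta,
        "sigma": sigma,
        "n_flies": n_flies,
        "tissue": tissue,
        "labels": list(labels),
        "noise": noise,
        "true_means": true_means,
    }
    return pd.DataFrame(rows), summaries, truth


# ---------------------------------------------------------------------------
# Heptad alignments around a consensus
# ---------------------------------------------------------------------------


def gen_heptad_alignment(
    consensus: str = "LEALRQE",
    n: int = 130,
    noise_rate: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Sample an ungapped heptad alignment around a consensus.

    Each position of each sequence equals the consensus residue with
    probability ``1 − noise_rate`` and otherwise is replaced by a uniformly
    chosen different residue.  The defaults emulate an alignment of 130
    leucine-zipper heptads whose modal sequence is the consensus.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    rng = _rng(seed)
    alphabet = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
    cons = consensus.upper()
    out = []
    for _ in range(n):
        chars = []
        for aa in cons:
            if rng.random() < noise_rate:
                others = alphabet[alphabet != aa]
                chars.append(str(rng.choice(others)))
            else:
                chars.append(aa)
        out.append("".join(chars))
    return out
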