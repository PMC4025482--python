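"""Sequence and table I/O plus the shared residue-class table.

Everything downstream (heptad scanning, wheel projection, logo building,
structure-window matching) consumes the :class:`Peptide`,
:class:`GenotypePhenotype` and :class:`ResidueClassTable` types defined here.

Conventions: sequence indices are 1-based inclusive in all reports; lowercase
input is uppercased silently; ambiguity codes (B, Z, X, J, U, O) are rejected.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("zipperscan")

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Tissues for which phenotype counts are scored.
VALID_TISSUES = frozenset({"sex_comb", "pseudotrachea", "salivary_gland"})

HYDROPHOBIC = "hydrophobic"
BASIC = "basic"
ACIDIC = "acidic"
POLAR = "polar"

_RESIDUE_CLASS_NAMES = frozenset({HYDROPHOBIC, BASIC, ACIDIC, POLAR})


class FastaError(ValueError):
    """Malformed FASTA input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class Peptide:
    """A short amino-acid sequence record.

    The sequence is uppercased on construction and must consist solely of the
    20 canonical one-letter codes; ambiguity codes are rejected so that every
    residue has a well-defined biochemical class and substitution score.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        bad = sorted(set(seq) - CANONICAL_AA)
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: non-canonical residue(s) {''.join(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, index: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= index <= len(self.sequence):
            raise IndexError(f"position {index} outside 1..{len(self.sequence)}")
        return self.sequence[index - 1]


@dataclass(frozen=True)
class ResidueClassTable:
    """Total, disjoint assignment of the 20 residues to biochemical classes.

    The default grouping is the four-way scheme used for coloring leucine
    zipper logos: basic {K,R,H}, acidic {D,E}, hydrophobic
    {G,A,V,L,I,M,P,F,W} (note glycine and proline counted hydrophobic), and
    polar {S,T,N,Q,Y,C}.  Alternative schemes (e.g. Kyte–Doolittle-style
    splits) can be supplied as a plain mapping.
    """

    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        covered = set(self.classes)
        if covered != CANONICAL_AA:
            missing = sorted(CANONICAL_AA - covered)
            extra = sorted(covered - CANONICAL_AA)
            raise ValueError(
                f"class table must cover exactly the 20 canonical residues "
                f"(missing {missing}, extra {extra})"
            )
        bad = {c for c in self.classes.values() if c not in _RESIDUE_CLASS_NAMES}
        if bad:
            raise ValueError(f"unknown residue class name(s): {sorted(bad)}")
        object.__setattr__(self, "classes", dict(self.classes))

    def __getitem__(self, aa: str) -> str:
        return classify_residue(aa, self)

    def members(self, cls: str) -> frozenset[str]:
        return frozenset(aa for aa, c in self.classes.items() if c == cls)


def _default_classes() -> ResidueClassTable:
    table: dict[str, str] = {}
    for aa in "KRH":
        table[aa] = BASIC
    for aa in "DE":
        table[aa] = ACIDIC
    for aa in "GAVLIMPFW":
        table[aa] = HYDROPHOBIC
    for aa in "STNQYC":
        table[aa] = POLAR
    return ResidueClassTable(table)


#: Default four-class grouping (see :class:`ResidueClassTable`).
DEFAULT_CLASSES = _default_classes()


def classify_residue(aa: str, table: ResidueClassTable | None = None) -> str:
    """Return the biochemical class of a canonical residue.

    Parameters
    ----------
    aa:
        One-letter residue code (case-insensitive).
    table:
        Class table; defaults to :data:`DEFAULT_CLASSES`.
    """
    table = table if table is not None else DEFAULT_CLASSES
    key = aa.upper()
    if key not in CANONICAL_AA:
        raise ValueError(f"non-canonical residue {aa!r}")
    return table.classes[key]


@dataclass(frozen=True)
class GenotypePhenotype:
    """Summary phenotype record: mean count and SEM for one genotype/tissue."""

    genotype: str
    tissue: str
    mean: float
    sem: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.genotype:
            raise ValueError("genotype label must be non-empty")
        if self.tissue not in VALID_TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; expected one of {sorted(VALID_TISSUES)}"
            )
        for name, value in (("mean", self.mean), ("sem", self.sem)):
            if not math.isfinite(value):
                raise ValueError(f"{self.genotype}/{self.tissue}: {name} not finite")
            if value < 0:
                raise ValueError(f"{self.genotype}/{self.tissue}: {name} < 0")
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.genotype}/{self.tissue}: n must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------
# Parsed by hand rather than through Bio.SeqIO because the contract requires
# errors that name the offending line (illegal residue, duplicate id, record
# with no sequence), which generic parsers do not report.


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read a multi-record FASTA file into a list of :class:`Peptide`.

    Record order is preserved; sequences are uppercased.  Raises
    :class:`FastaError` naming the offending line for malformed headers,
    illegal residues, empty sequences, or duplicate ids.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    seen: set[str] = set()

    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        name, _, desc = header.partition(" ")
        seq = "".join(chunks)
        try:
            pep = Peptide(name, seq, desc.strip())
        except ValueError as exc:
            raise FastaError(str(exc), header_line) from exc
        if pep.id in seen:
            raise FastaError(f"duplicate record id {pep.id!r}", header_line)
        seen.add(pep.id)
        peptides.append(pep)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaError("header with no identifier", lineno)
            else:
                if header is None:
                    raise FastaError("sequence data before first '>' header", lineno)
                bad = sorted(set(line.upper()) - CANONICAL_AA)
                if bad:
                    raise FastaError(
                        f"illegal residue(s) {''.join(bad)} in record {header!r}",
                        lineno,
                    )
                chunks.append(line)
    flush()
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path, width: int = 60) -> None:
    """Write peptides as multi-record FASTA, wrapping sequence lines."""
    path = Path(path)
    with path.open("w") as fh:
        for pep in peptides:
            desc = f" {pep.description}" if pep.description else ""
            fh.write(f">{pep.id}{desc}\n")
            for i in range(0, len(pep.sequence), width):
                fh.write(pep.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

_PHENO_REQUIRED = ("genotype", "tissue", "mean", "sem")


def read_phenotype_table(path: str | Path) -> list[GenotypePhenotype]:
    """Read a TSV of genotype/tissue phenotype summaries.

    Expected header columns: genotype, tissue, mean, sem, and optionally n.
    An empty file yields an empty list with a logged warning; invalid rows
    (unknown tissue, negative mean or SEM) raise ``ValueError``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"phenotype table {path} is empty", stacklevel=2)
        logger.warning("phenotype table %s is empty", path)
        return []
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[GenotypePhenotype] = []
    for row in df.itertuples(index=False):
        n = getattr(row, "n", None)
        if n is not None and pd.isna(n):
            n = None
        records.append(
            GenotypePhenotype(
                genotype=str(row.genotype),
                tissue=str(row.tissue),
                mean=float(row.mean),
                sem=float(row.sem),
                n=int(n) if n is not None else None,
            )
        )
    return records


def write_phenotype_table(
    records: Sequence[GenotypePhenotype], path: str | Path
) -> None:
    """Write phenotype summaries as a TSV with header."""
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "tissue": [r.tissue for r in records],
            "mean": [r.mean for r in records],
            "sem": [r.sem for r in records],
            "n": [r.n for r in records],
        }
    )
    if df["n"].isna().all():
        df = df.drop(columns="n")
    df.to_csv(path, sep="\t", index=False)
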