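"""Packaged fixture data: the SCR N-terminal queries and phenotype tables.

The two 19-residue queries are the wild-type SCR N-terminus and its
Ser10→Leu variant (the Scr14 allele product).  The phenotype tables hold the
published mean ± SEM counts per genotype and tissue for the 2013 and 2009
scoring campaigns; raw per-fly counts were not published, so these summary
rows are the complete quantitative record.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .seqio import GenotypePhenotype, Peptide, read_fasta, read_phenotype_table

SCR_WT_SEQUENCE = "FAMSSYQFVNSLACYPQMN"
SCR14_SEQUENCE = "FAMSLYQFVNSLACYPQMN"


def _data_path(name: str) -> Path:
    return Path(resources.files("zipperscan") / "data" / name)


def scr_queries() -> tuple[Peptide, Peptide]:
    """The packaged (wild-type, Ser10→Leu) SCR N-terminus query pair."""
    wt, mut = read_fasta(_data_path("scr_queries.fasta"))
    return wt, mut


def scr_phenotypes(year: int = 2013) -> list[GenotypePhenotype]:
    """Published phenotype summaries (mean ± SEM) for the given campaign year."""
    if year not in (2009, 2013):
        raise ValueError("phenotype tables are available for 2009 and 2013")
    return read_phenotype_table(_data_path(f"scr_phenotypes_{year}.tsv"))


def phenotype(
    records: list[GenotypePhenotype], genotype: str, tissue: str
) -> GenotypePhenotype:
    """Look up one (genotype, tissue) record, erroring if absent."""
    for rec in records:
        if rec.genotype == genotype and rec.tissue == tissue:
            return rec
    raise KeyError(f"no record for genotype {genotype!r}, tissue {tissue!r}")
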