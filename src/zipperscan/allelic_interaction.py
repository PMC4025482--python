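"""Allelic-interaction statistics from summary phenotype data.

If two alleles of a gene do not interact, the phenotype of the
trans-heterozygote should equal the sum of the activities each allele shows
alone over a deficiency (the additive null).  A trans-heterozygote mean
significantly below that sum indicates the alleles inhibit one another —
the signature of antimorphy; significantly above, synergy.  Because raw
per-individual counts are typically not published, all statistics here
operate on printed means and SEMs: the additive expectation combines SEMs
in quadrature, departures are scored as a z statistic, and two-group
comparisons use the summary-statistic t

    t = (mean1 − mean2) / sqrt(sem1² + sem2²),

with a Welch–Satterthwaite df and two-sided p-value when group sizes are
known.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd
from scipy import stats

from .seqio import GenotypePhenotype

CALL_INHIBITORY = "inhibitory"
CALL_ADDITIVE = "additive"
CALL_SYNERGISTIC = "synergistic"

FLAG_REDUCED = "reduced"
FLAG_UNCHANGED = "unchanged"
FLAG_INCREASED = "increased"


class Expectation(NamedTuple):
    """Additive-null expectation for a trans-heterozygote phenotype."""

    mean: float
    sem: float
    allele_a: str = ""
    allele_b: str = ""
    tissue: str = ""


def additive_expectation(
    a: GenotypePhenotype, b: GenotypePhenotype
) -> Expectation:
    """Sum of two hemizygote activities, SEMs combined in quadrature.

    Both records must describe the same tissue.  A null allele is modelled
    by passing a zero-activity record (mean 0, SEM 0), which acts as the
    identity.
    """
    if a.tissue != b.tissue:
        raise ValueError(
            f"tissue mismatch: {a.genotype}={a.tissue!r} vs {b.genotype}={b.tissue!r}"
        )
    return Expectation(
        mean=a.mean + b.mean,
        sem=math.hypot(a.sem, b.sem),
        allele_a=a.genotype,
        allele_b=b.genotype,
        tissue=a.tissue,
    )


@dataclass(frozen=True)
class InteractionResult:
    """Observed trans-heterozygote phenotype scored against the additive null."""

    allele_a: str
    allele_b: str
    tissue: str
    expected_mean: float
    expected_sem: float
    observed_mean: float
    observed_sem: float
    delta: float
    z: float
    call: str


def classify_interaction(
    expected: Expectation | tuple[float, float],
    observed: GenotypePhenotype,
    z_crit: float = 1.96,
) -> InteractionResult:
    """Score an observed trans-heterozygote against the additive null.

    ``delta = observed − expected`` and ``z = delta / sqrt(sem_e² + sem_o²)``.
    The call is ``inhibitory`` when z < −z_crit, ``synergistic`` when
    z > +z_crit, otherwise ``additive`` (default z_crit 1.96, the two-sided
    5% convention).
    """
    if isinstance(expected, Expectation):
        exp = expected
    else:
        exp = Expectation(float(expected[0]), float(expected[1]))
    for name, value in (
        ("expected mean", exp.mean),
        ("expected sem", exp.sem),
        ("observed mean", observed.mean),
        ("observed sem", observed.sem),
    ):
        if not math.isfinite(value):
            raise ValueError(f"{name} is not finite")

    delta = observed.mean - exp.mean
    denom = math.hypot(exp.sem, observed.sem)
    if denom == 0.0:
        z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
    else:
        z = delta / denom
    if z < -z_crit:
        call = CALL_INHIBITORY
    elif z > z_crit:
        call = CALL_SYNERGISTIC
    else:
        call = CALL_ADDITIVE
    return InteractionResult(
        allele_a=exp.allele_a,
        allele_b=exp.allele_b,
        tissue=exp.tissue or observed.tissue,
        expected_mean=exp.mean,
        expected_sem=exp.sem,
        observed_mean=observed.mean,
        observed_sem=observed.sem,
        delta=delta,
        z=z,
        call=call,
    )


@dataclass(frozen=True)
class SummaryTTest:
    """Two-group t computed from printed means and SEMs.

    ``df`` and ``p`` (two-sided) are available only when both group sizes
    are supplied; the df is Welch–Satterthwaite.  With equal n and equal
    SEMs the statistic coincides with the pooled-variance Student t.
    """

    mean1: float
    sem1: float
    mean2: float
    sem2: float
    n1: int | None
    n2: int | None
    t: float
    df: float | None
    p: float | None


def summary_t(
    mean1: float,
    sem1: float,
    mean2: float,
    sem2: float,
    n1: int | None = None,
    n2: int | None = None,
) -> SummaryTTest:
    """t = (mean1 − mean2) / sqrt(sem1² + sem2²) from summary statistics."""
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError(
            "summary_t requires both SEMs > 0; for SEM = 0 compare the exact "
            "counts directly"
        )
    t = (mean1 - mean2) / math.hypot(sem1, sem2)
    df = p = None
    if n1 is not None and n2 is not None:
        if n1 < 2 or n2 < 2:
            raise ValueError("group sizes must be >= 2 for df computation")
        v1, v2 = sem1**2, sem2**2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return SummaryTTest(mean1, sem1, mean2, sem2, n1, n2, t, df, p)


def hypomorphy_report(
    records: Sequence[GenotypePhenotype],
    genotype: str,
    reference: str,
    z_crit: float = 1.96,
) -> pd.DataFrame:
    """Per-tissue comparison of one genotype against a reference hemizygote.

    For each tissue where both genotypes have records, reports
    delta = mean − ref_mean, the z statistic against quadrature-combined
    SEMs, and a flag (``reduced``/``unchanged``/``increased``).  Tissues
    missing either genotype are skipped with a warning.  Repeated calls with
    different genotypes against the same reference support rank-ordering an
    allelic series.
    """
    by_tissue: dict[str, dict[str, GenotypePhenotype]] = {}
    for rec in records:
        if rec.genotype in (genotype, reference):
            by_tissue.setdefault(rec.tissue, {})[rec.genotype] = rec

    rows = []
    for tissue in sorted(by_tissue):
        pair = by_tissue[tissue]
        if genotype not in pair or reference not in pair:
            warnings.warn(
                f"tissue {tissue!r}: missing record for "
                f"{genotype if genotype not in pair else reference!r}; skipped",
                stacklevel=2,
            )
            continue
        rec, ref = pair[genotype], pair[reference]
        delta = rec.mean - ref.mean
        denom = math.hypot(rec.sem, ref.sem)
        if denom == 0.0:
            z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        else:
            z = delta / denom
        if z < -z_crit:
            flag = FLAG_REDUCED
        elif z > z_crit:
            flag = FLAG_INCREASED
        else:
            flag = FLAG_UNCHANGED
        rows.append(
            {
                "tissue": tissue,
                "genotype": genotype,
                "mean": rec.mean,
                "sem": rec.sem,
                "reference": reference,
                "ref_mean": ref.mean,
                "ref_sem": ref.sem,
                "delta": delta,
                "z": z,
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "genotype",
            "mean",
            "sem",
            "reference",
            "ref_mean",
            "ref_sem",
            "delta",
            "z",
            "flag",
        ],
    )
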