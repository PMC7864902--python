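"""Gene-set enrichment of poly-proline-tract carriers via a 2x2 table.

The association between gene-set membership (e.g. microcephaly-associated
genes) and carrying at least one PPT is tested with an uncorrected Pearson
chi-square on the 2x2 contingency table, and effect size is reported as
the cross-product odds ratio with a Wald (Woolf) 95% confidence interval
computed on the log scale. No continuity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

from scipy import special

from protract.ppt_scan import GeneSet, PPTProfile

#: two-sided 95% normal quantile
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = in/out of gene set, columns = >=1 PPT / 0 PPTs.

    ``a`` set carriers, ``b`` set non-carriers, ``c`` background carriers,
    ``d`` background non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def require_margins(self) -> None:
        margins = {
            "gene-set row (a+b)": self.a + self.b,
            "background row (c+d)": self.c + self.d,
            "carrier column (a+c)": self.a + self.c,
            "non-carrier column (b+d)": self.b + self.d,
        }
        for name, value in margins.items():
            if value == 0:
                raise ValueError(f"degenerate table: {name} is zero")

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-square association plus odds-ratio effect size for one table."""

    table: ContingencyTable
    chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    fraction_set: float
    fraction_background: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = asdict(self.table)
        return d


def build_table(
    profiles: Sequence[PPTProfile], gene_set: GeneSet
) -> ContingencyTable:
    """Cross-classify profiled genes by set membership and >=1-PPT status.

    The background is the complement of the gene set among profiled genes,
    so the four cells partition the profile list. Profiles must all have
    been computed at the same ``min_tract_len``.
    """
    a = b = c = d = 0
    for p in profiles:
        carrier = p.n_tracts >= 1
        if p.protein_id in gene_set.members:
            if carrier:
                a += 1
            else:
                b += 1
        else:
            if carrier:
                c += 1
            else:
                d += 1
    table = ContingencyTable(a, b, c, d)
    table.require_margins()
    return table


def chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (df=1) and its upper-tail p-value.

    The p-value uses the closed form ``erfc(sqrt(chi2 / 2))`` for the
    chi-square distribution with one degree of freedom.
    """
    table.require_margins()
    n = table.n
    a, b, c, d = table.a, table.b, table.c, table.d
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(special.erfc(math.sqrt(chi2 / 2.0)))
    return float(chi2), p


def odds_ratio_ci(
    table: ContingencyTable, z: float = Z_95
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Wald log-scale confidence interval.

    OR = ad/bc; CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    All four cells must be positive — the Wald standard error is undefined
    otherwise and no continuity adjustment is offered.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise ValueError(
            "Wald odds-ratio interval is undefined with a zero cell; "
            "all four cells must be positive"
        )
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(orr)
    return orr, math.exp(log_or - z * se), math.exp(log_or + z * se)


def enrich(table: ContingencyTable) -> EnrichmentResult:
    """Full enrichment summary for one 2x2 table."""
    chi2, p = chi_square(table)
    orr, lo, hi = odds_ratio_ci(table)
    return EnrichmentResult(
        table=table,
        chi2=chi2,
        p_value=p,
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        fraction_set=table.a / (table.a + table.b),
        fraction_background=table.c / (table.c + table.d),
    )


def enrich_profiles(
    profiles: Sequence[PPTProfile], gene_set: GeneSet
) -> EnrichmentResult:
    """Build the table from profiles and run the full enrichment analysis."""
    return enrich(build_table(profiles, gene_set))
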