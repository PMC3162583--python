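"""Carrier-frequency association statistics for a hemizygous (X-linked) variant.

Case and control groups are summarised as carrier / non-carrier counts; the
effect measure is the odds ratio of a 2x2 table with a Woolf (logit) 95%
confidence interval, the field-standard large-sample interval

    CI = exp( ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ).

Control groups may be pooled by summing counts.  Genotype distributions in
females can be checked against Hardy-Weinberg proportions; males are
hemizygous, so by default they contribute only to allele-frequency pooling,
never to the genotype chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "CarrierFrequency",
    "XLinkedGenotypeCounts",
    "HweResult",
    "pool_controls",
    "odds_ratio_woolf",
    "carrier_frequency",
    "hwe_xlinked",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts for one case group against one (possibly pooled) control group."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int
    case_label: str = "cases"
    control_label: str = "controls"

    def __post_init__(self) -> None:
        cells = (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError("contingency cells must be non-negative integers")
        if self.case_carriers + self.case_noncarriers == 0:
            raise ValueError("case margin is zero")
        if self.control_carriers + self.control_noncarriers == 0:
            raise ValueError("control margin is zero")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )

    @property
    def n(self) -> int:
        return sum(self.cells)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool
    table: ContingencyTable2x2

    def formatted(self) -> str:
        return (
            f"{round_half_up(self.odds_ratio):.2f} "
            f"({round_half_up(self.ci_low):.2f}-{round_half_up(self.ci_high):.2f})"
        )


@dataclass(frozen=True)
class CarrierFrequency:
    carriers: int
    total: int
    percent: float
    ci_low_percent: float
    ci_high_percent: float

    def formatted(self) -> str:
        return f"{self.carriers}/{self.total} ({round_half_up(self.percent):.2f}%)"


@dataclass(frozen=True)
class XLinkedGenotypeCounts:
    """Genotype counts at an X-linked biallelic site; 'a' is the variant allele."""

    female_AA: int
    female_Aa: int
    female_aa: int
    male_A: int = 0
    male_a: int = 0

    def __post_init__(self) -> None:
        if min(self.female_AA, self.female_Aa, self.female_aa, self.male_A, self.male_a) < 0:
            raise ValueError("genotype counts must be non-negative")


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p_value: float
    allele_freq: float
    expected: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))


def pool_controls(groups: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Sum (carriers, total) pairs over control groups.

    >>> pool_controls([(7, 757), (5, 764), (2, 375)])
    (14, 1896)
    """
    if len(groups) == 0:
        raise ValueError("no control groups to pool")
    carriers = 0
    total = 0
    for k, n in groups:
        if k > n:
            raise ValueError(f"carriers {k} exceed total {n}")
        if k < 0 or n <= 0:
            raise ValueError("counts must be non-negative with positive totals")
        carriers += int(k)
        total += int(n)
    return carriers, total


def odds_ratio_woolf(table: ContingencyTable2x2, alpha: float = 0.05) -> AssociationResult:
    """Odds ratio with the Woolf logit confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 on every
    cell) for the OR and its interval; the flag on the result records it.
    The p-value is a Pearson chi-square on the uncorrected counts
    (1 df, no continuity correction).
    """
    a, b, c, d = (float(x) for x in table.cells)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    obs = np.array(table.cells, dtype=float).reshape(2, 2)
    # Pearson chi-square by hand: expected from margins, 1 df.
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=p,
        correction_applied=corrected,
        table=table,
    )


def carrier_frequency(carriers: int, total: int, alpha: float = 0.05) -> CarrierFrequency:
    """Carrier percentage with an exact (Clopper-Pearson) confidence interval."""
    if total <= 0:
        raise ValueError("total must be positive")
    if carriers < 0 or carriers > total:
        raise ValueError("carriers must lie in [0, total]")
    k, n = carriers, total
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return CarrierFrequency(
        carriers=k,
        total=n,
        percent=100.0 * k / n,
        ci_low_percent=100.0 * lo,
        ci_high_percent=100.0 * hi,
    )


def hwe_xlinked(counts: XLinkedGenotypeCounts, pool_males: bool = False) -> HweResult:
    """Chi-square test of female genotypes against Hardy-Weinberg proportions.

    The variant-allele frequency q is estimated from female genotypes
    (optionally pooling hemizygous male alleles); expected female counts are
    n * ((1-q)^2, 2q(1-q), q^2) and the statistic has one degree of freedom.
    """
    n_f = counts.female_AA + counts.female_Aa + counts.female_aa
    if n_f == 0:
        raise ValueError("no female genotypes supplied")
    var_alleles = counts.female_Aa + 2 * counts.female_aa
    tot_alleles = 2 * n_f
    if pool_males:
        var_alleles += counts.male_a
        tot_alleles += counts.male_A + counts.male_a
    q = var_alleles / tot_alleles
    p = 1.0 - q
    expected = (n_f * p * p, n_f * 2.0 * p * q, n_f * q * q)
    observed = (counts.female_AA, counts.female_Aa, counts.female_aa)
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            chi2 += (o - e) ** 2 / e
    return HweResult(
        chi2=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        allele_freq=float(q),
        expected=tuple(float(e) for e in expected),
    )
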