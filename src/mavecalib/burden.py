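"""Case-control carrier burden association.

For a score stratum, carriers of any qualifying variant are compared between
cases and controls as a 2×2 table (carrier / non-carrier × case / control).
The association is summarised as an odds ratio with a Woolf (log-scale
normal) confidence interval and a two-sided Fisher exact p-value. This
carrier-vs-noncarrier construction reproduces published burden tables for
rare-variant strata without covariate adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact, norm

from .core import ValidationError

__all__ = [
    "CarrierCounts",
    "OrEstimate",
    "burden_or",
    "fisher_exact_p",
    "stratify_burden",
    "read_carrier_table",
    "BRIDGES_CARRIER_COUNTS",
]


@dataclass(frozen=True)
class CarrierCounts:
    """Carrier tallies for one score stratum of a case-control cohort."""

    stratum: str
    n_variants: int
    carriers_cases: int
    carriers_controls: int
    total_cases: int
    total_controls: int

    def __post_init__(self) -> None:
        for name in (
            "n_variants",
            "carriers_cases",
            "carriers_controls",
            "total_cases",
            "total_controls",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.stratum}: {name} must be >= 0")
        if self.carriers_cases > self.total_cases:
            raise ValidationError(f"{self.stratum}: case carriers exceed case total")
        if self.carriers_controls > self.total_controls:
            raise ValidationError(
                f"{self.stratum}: control carriers exceed control total"
            )


@dataclass
class OrEstimate:
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    method: str
    corrected: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.odds_ratio <= hi:
            raise ValidationError("CI must bracket the odds ratio")

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 1.0 or hi < 1.0


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables (at fixed margins)
    no more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("cells must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("empty table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def burden_or(counts: CarrierCounts, level: float = 0.95) -> OrEstimate:
    """Carrier-vs-noncarrier odds ratio with Woolf CI and Fisher exact p."""
    a = counts.carriers_cases
    b = counts.total_cases - a
    c = counts.carriers_controls
    d = counts.total_controls - c
    if a == 0 and c == 0:
        raise ValidationError(f"{counts.stratum}: no carriers in either arm")
    if b <= 0 or d <= 0:
        raise ValidationError(f"{counts.stratum}: noncarriers must be positive")
    p_value = fisher_exact_p(a, b, c, d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (odds_ratio * math.exp(-half), odds_ratio * math.exp(half))
    return OrEstimate(
        odds_ratio=odds_ratio,
        ci95=ci,
        p=p_value,
        method="woolf+fisher",
        corrected=corrected,
    )


def stratify_burden(counts: list[CarrierCounts], level: float = 0.95) -> pd.DataFrame:
    """One odds-ratio row per stratum, flagged significant when the CI excludes 1."""
    rows = []
    for cc in counts:
        est = burden_or(cc, level)
        rows.append(
            {
                "stratum": cc.stratum,
                "n_variants": cc.n_variants,
                "carriers_cases": cc.carriers_cases,
                "carriers_controls": cc.carriers_controls,
                "total_cases": cc.total_cases,
                "total_controls": cc.total_controls,
                "odds_ratio": est.odds_ratio,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "p": est.p,
                "significant": est.significant,
                "corrected": est.corrected,
            }
        )
    columns = [
        "stratum",
        "n_variants",
        "carriers_cases",
        "carriers_controls",
        "total_cases",
        "total_controls",
        "odds_ratio",
        "ci_low",
        "ci_high",
        "p",
        "significant",
        "corrected",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_carrier_table(path: str | Path) -> list[CarrierCounts]:
    """Read a TSV with columns stratum, n_variants, carriers_cases,
    carriers_controls, total_cases, total_controls."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t")
    required = [
        "stratum",
        "n_variants",
        "carriers_cases",
        "carriers_controls",
        "total_cases",
        "total_controls",
    ]
    for col in required:
        if col not in frame.columns:
            raise ValidationError(f"mandatory column {col!r} not found in {path.name}")
    return [
        CarrierCounts(
            stratum=str(row.stratum),
            n_variants=int(row.n_variants),
            carriers_cases=int(row.carriers_cases),
            carriers_controls=int(row.carriers_controls),
            total_cases=int(row.total_cases),
            total_controls=int(row.total_controls),
        )
        for row in frame.itertuples()
    ]


# Published per-stratum carrier counts for BRCA1 missense variants in the
# BRIDGES breast cancer case-control study (53,572 cases / 48,048 controls),
# stratified by AlphaMissense (AM), FoldX ΔΔG on AlphaFold2 or PDB templates
# (DDG_AF / DDG_PDB, kcal/mol) and BayesDel (BD) score zones. These are real
# published tallies, usable directly as inputs to `stratify_burden`.
_N_CASES, _N_CONTROLS = 53_572, 48_048

BRIDGES_CARRIER_COUNTS: list[CarrierCounts] = [
    CarrierCounts("AM>=0.75", 33, 94, 18, _N_CASES, _N_CONTROLS),
    CarrierCounts("0.65<AM<0.75", 7, 22, 16, _N_CASES, _N_CONTROLS),
    CarrierCounts("AM<=0.65", 82, 146, 101, _N_CASES, _N_CONTROLS),
    CarrierCounts("DDG_AF>=+2.5", 32, 97, 20, _N_CASES, _N_CONTROLS),
    CarrierCounts("+1.5<DDG_AF<+2.5", 23, 43, 24, _N_CASES, _N_CONTROLS),
    CarrierCounts("DDG_AF<=+1.5", 67, 122, 91, _N_CASES, _N_CONTROLS),
    CarrierCounts("DDG_PDB>=+2.5", 35, 121, 30, _N_CASES, _N_CONTROLS),
    CarrierCounts("+1.5<DDG_PDB<+2.5", 19, 16, 15, _N_CASES, _N_CONTROLS),
    CarrierCounts("DDG_PDB<=+1.5", 68, 125, 90, _N_CASES, _N_CONTROLS),
    CarrierCounts("BD>=0.28", 33, 120, 30, _N_CASES, _N_CONTROLS),
    CarrierCounts("0.15<BD<0.28", 19, 54, 30, _N_CASES, _N_CONTROLS),
    CarrierCounts("BD<=0.15", 70, 88, 75, _N_CASES, _N_CONTROLS),
]
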