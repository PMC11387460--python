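"""Disproportionality statistics on 2x2 contingency tables.

For a target drug and a target event (MedDRA PT, or SOC after within-report
de-duplication), reports are cross-classified as

    =============  ==============  ==============
    .              event           other events
    =============  ==============  ==============
    target drug    a               b
    other drugs    c               d
    =============  ==============  ==============

and four classical pharmacovigilance statistics are computed:

* ROR, the reporting odds ratio a*d/(b*c) with a Wald 95% CI on the log scale;
* PRR, the proportional reporting ratio [a/(a+b)] / [c/(c+d)], paired with the
  Pearson chi-square statistic of the table;
* IC, the information component of the Bayesian Confidence Propagation Neural
  Network (BCPNN): a shrunken log2 observed-to-expected ratio whose posterior
  moments have a closed form (Bate et al., 1998), with a 95% lower credible
  bound.

A (drug, event) pair is flagged as a *signal* when all of the following hold:
a >= 3, the ROR CI lower bound exceeds 1, PRR > 2 with chi-square > 4, and the
IC lower bound exceeds 0 (all inequalities strict).  No multiple-testing
adjustment is applied: flagged pairs are hypotheses for review, not confirmed
risks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import Cohort
from .report_model_io import MedDRADict

logger = logging.getLogger("faerspv")

Z95 = 1.96


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts a/b/c/d for one (drug, event) pair against a background."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""
    level: str = "PT"  # PT | SOC
    soc: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(slots=True)
class SignalStats:
    """All four statistics for one table plus the combined signal verdict.

    Missing statistics (degenerate tables) are ``None`` with ``reason`` set;
    a missing component always yields ``is_signal == False``.
    """

    table: ContingencyTable
    ror: float | None = None
    ror_lo: float | None = None
    ror_hi: float | None = None
    prr: float | None = None
    chi2: float | None = None
    ic: float | None = None
    ic_lo: float | None = None
    is_signal: bool = False
    zero_cell_corrected: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def build_tables(cohort: Cohort, level: str = "PT", meddra: MedDRADict | None = None) -> list[ContingencyTable]:
    """Build one 2x2 table per event label occurring in the exposed reports.

    At PT level the events are the reaction preferred terms; at SOC level each
    report's PTs are mapped through ``meddra`` and de-duplicated, so a report
    with two PTs of the same SOC contributes 1 (not 2) to that SOC's table.
    For every table a+b equals the exposed count and c+d the background count.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if level == "SOC" and meddra is None:
        raise ValueError("SOC-level tables require a MedDRA dictionary")
    if not cohort.exposed:
        logger.warning("cohort %s has no exposed reports; no tables built", cohort.target_drug)
        return []

    def events_of(report) -> set[str]:
        if level == "PT":
            return report.reactions
        return {meddra.soc_of(pt) for pt in report.reactions}

    exposed_counts: dict[str, int] = {}
    for r in cohort.exposed:
        for ev in events_of(r):
            exposed_counts[ev] = exposed_counts.get(ev, 0) + 1
    background_counts: dict[str, int] = {}
    for r in cohort.background:
        for ev in events_of(r):
            if ev in exposed_counts:
                background_counts[ev] = background_counts.get(ev, 0) + 1

    n_exp, n_bg = len(cohort.exposed), len(cohort.background)
    pt_soc = (lambda ev: meddra.soc_of(ev)) if (level == "PT" and meddra is not None) else (lambda ev: ev)
    tables = [
        ContingencyTable(
            a=a,
            b=n_exp - a,
            c=background_counts.get(ev, 0),
            d=n_bg - background_counts.get(ev, 0),
            drug=cohort.target_drug,
            event=ev,
            level=level,
            soc=pt_soc(ev),
        )
        for ev, a in exposed_counts.items()
    ]
    tables.sort(key=lambda t: (-t.a, t.event))
    return tables


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _frequentist_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool] | None:
    """Cells for the frequentist statistics after the zero-cell policy.

    Returns ``None`` when a raw row or column margin is zero (the statistic is
    then undefined rather than merely unstable).  When any single cell is zero
    the Haldane-Anscombe correction adds 0.5 to all four cells.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return None
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def ror_ci(t: ContingencyTable) -> tuple[float, float, float] | None:
    """Reporting odds ratio with its Wald 95% CI, or None if undefined."""
    cells = _frequentist_cells(t)
    if cells is None:
        return None
    a, b, c, d, _ = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se)


def prr_chi2(t: ContingencyTable, continuity: bool = False) -> tuple[float, float] | None:
    """Proportional reporting ratio and the Pearson chi-square of the table.

    ``continuity=True`` applies the Yates correction to the chi-square (off by
    default, matching the classical PRR companion statistic).
    """
    cells = _frequentist_cells(t)
    if cells is None:
        return None
    a, b, c, d, _ = cells
    prr = (a / (a + b)) / (c / (c + d))
    n = a + b + c + d
    det = abs(a * d - b * c)
    if continuity:
        det = max(det - n / 2, 0.0)
    chi2 = n * det * det / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def bcpnn_ic(t: ContingencyTable, interval: str = "ci95") -> tuple[float, float]:
    """BCPNN information component: posterior mean and lower 95% bound (bits).

    Closed-form posterior moments with priors alpha1 = beta1 = 1,
    alpha = beta = 2, gamma11 = 1 and gamma chosen so the prior IC expectation
    is 0.  Defined for a = 0; no zero-cell correction is applied (the priors
    regularise the estimate).  ``interval="2sd"`` selects the IC - 2SD bound
    used by some reporting-database studies instead of the 1.96-SD bound.
    """
    if interval not in ("ci95", "2sd"):
        raise ValueError(f"unknown interval rule {interval!r}")
    n11 = float(t.a)
    n1_ = float(t.a + t.b)
    n_1 = float(t.a + t.c)
    n = float(t.n)
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((n1_ + a1) * (n_1 + b1))
    e_ic = math.log2((n11 + g11) * (n + al) * (n + be) / ((n + g) * (n1_ + a1) * (n_1 + b1)))
    v_ic = (1.0 / math.log(2)) ** 2 * (
        (n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
        + (n - n1_ + al - a1) / ((n1_ + a1) * (1 + n + al))
        + (n - n_1 + be - b1) / ((n_1 + b1) * (1 + n + be))
    )
    z = Z95 if interval == "ci95" else 2.0
    return e_ic, e_ic - z * math.sqrt(v_ic)


def compute_signal_stats(
    t: ContingencyTable,
    continuity: bool = False,
    ic_interval: str = "ci95",
) -> SignalStats:
    """Compute all four statistics for one table (signal verdict not yet set)."""
    stats = SignalStats(table=t)
    cells = _frequentist_cells(t)
    if cells is None:
        stats.reason = "zero_margin"
    else:
        stats.zero_cell_corrected = cells[4]
        stats.ror, stats.ror_lo, stats.ror_hi = ror_ci(t)
        stats.prr, stats.chi2 = prr_chi2(t, continuity=continuity)
    stats.ic, stats.ic_lo = bcpnn_ic(t, interval=ic_interval)
    return stats


def apply_signal_rule(stats: Iterable[SignalStats]) -> list[SignalStats]:
    """Set ``is_signal`` on each entry per the combined four-part criterion.

    True iff a >= 3, ror_lo > 1, prr > 2 and chi2 > 4, and ic_lo > 0; all
    inequalities strict, any missing component fails.
    """
    out = []
    for s in stats:
        s.is_signal = (
            s.table.a >= 3
            and s.ror_lo is not None
            and s.ror_lo > 1
            and s.prr is not None
            and s.prr > 2
            and s.chi2 is not None
            and s.chi2 > 4
            and s.ic_lo is not None
            and s.ic_lo > 0
        )
        out.append(s)
    return out


def analyze_tables(
    tables: Sequence[ContingencyTable],
    continuity: bool = False,
    ic_interval: str = "ci95",
) -> list[SignalStats]:
    """Statistics plus signal verdict for a list of tables."""
    return apply_signal_rule(compute_signal_stats(t, continuity, ic_interval) for t in tables)


def signals_frame(stats: Sequence[SignalStats]) -> pd.DataFrame:
    """Flatten SignalStats into the delimited signal table (one row per event)."""
    rows = [
        {
            "drug": s.table.drug,
            "level": s.table.level,
            "event": s.table.event,
            "soc": s.table.soc,
            "a": s.table.a,
            "b": s.table.b,
            "c": s.table.c,
            "d": s.table.d,
            "ror": s.ror,
            "ror_lo": s.ror_lo,
            "ror_hi": s.ror_hi,
            "prr": s.prr,
            "chi2": s.chi2,
            "ic": s.ic,
            "ic_lo": s.ic_lo,
            "is_signal": s.is_signal,
            "zero_cell_corrected": s.zero_cell_corrected,
        }
        for s in stats
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "level", "event", "soc", "a", "b", "c", "d",
            "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic_lo",
            "is_signal", "zero_cell_corrected",
        ],
    )
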