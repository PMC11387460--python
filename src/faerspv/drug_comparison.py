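"""Head-to-head comparison of event signals between two drugs.

For each adverse event the two drugs' 2x2 tables form strata of a stratified
table; the Breslow-Day test asks whether the odds ratios are homogeneous
across strata — i.e. whether the event is disproportionally reported to the
same degree for both drugs.  The common odds ratio under homogeneity is the
Mantel-Haenszel estimate; Tarone's correction (default on) removes the small
bias from plugging that estimate into the Breslow-Day statistic.

To keep strata independent, each drug's stratum is built against the shared
rest-of-database background with the *other* drug's exposed reports removed,
so no report appears in two strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .dpa_core import ContingencyTable, SignalStats, analyze_tables
from .preprocess import Cohort
from .report_model_io import FaersError, MedDRADict

logger = logging.getLogger("faerspv")


@dataclass
class StratifiedTables:
    """K aligned 2x2 tables (one per drug) sharing the same event."""

    strata: list[tuple[str, ContingencyTable]]
    event: str

    def __post_init__(self) -> None:
        if len(self.strata) < 2:
            raise ValueError("Breslow-Day comparison needs at least 2 strata")
        for label, t in self.strata:
            if t.event and t.event != self.event:
                raise ValueError(f"stratum {label!r} is for event {t.event!r}, not {self.event!r}")


@dataclass
class HomogeneityResult:
    """Mantel-Haenszel common OR and the Breslow-Day homogeneity test."""

    or_mh: float
    bd_stat: float
    df: int
    p_value: float
    tarone_corrected: bool


def _expected_a(psi: float, r1: float, r2: float, c1: float) -> float:
    """Expected a-cell of a 2x2 table with margins (r1, r2, c1) and odds ratio psi.

    Solves psi = a(r2 - c1 + a) / ((r1 - a)(c1 - a)) for the root inside the
    admissible interval (max(0, c1 - r2), min(r1, c1)).
    """
    lo, hi = max(0.0, c1 - r2), min(r1, c1)
    if abs(psi - 1.0) < 1e-12:
        return r1 * c1 / (r1 + r2)
    # (psi - 1) a^2 - [psi (r1 + c1) + (r2 - c1)] a + psi r1 c1 = 0
    A = psi - 1.0
    B = -(psi * (r1 + c1) + (r2 - c1))
    C = psi * r1 * c1
    disc = B * B - 4 * A * C
    if disc < 0:
        raise FaersError(f"no real root for expected cell (psi={psi}, margins={r1, r2, c1})")
    sq = math.sqrt(disc)
    for root in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
        if lo < root < hi:
            return root
    raise FaersError(
        f"no admissible root for expected cell in ({lo}, {hi}); psi={psi}, margins={r1, r2, c1}"
    )


def breslow_day(s: StratifiedTables, tarone: bool = True) -> HomogeneityResult:
    """Breslow-Day chi-square test of odds-ratio homogeneity across strata.

    The statistic sums (a_k - E[a_k | OR_MH])^2 / Var_k over strata; under
    homogeneity it is chi-square with K-1 degrees of freedom.  With
    ``tarone=True`` the Tarone correction term (sum of residuals)^2 / (sum of
    variances) is subtracted.
    """
    num = den = 0.0
    for label, t in s.strata:
        if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
            raise FaersError(f"stratum {label!r} has a zero margin: {t}")
        num += t.a * t.d / t.n
        den += t.b * t.c / t.n
    if den == 0:
        raise FaersError("Mantel-Haenszel denominator is zero (all b*c products vanish)")
    or_mh = num / den

    bd = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for label, t in s.strata:
        r1, r2, c1 = float(t.a + t.b), float(t.c + t.d), float(t.a + t.c)
        a_tilde = _expected_a(or_mh, r1, r2, c1)
        var = 1.0 / (1.0 / a_tilde + 1.0 / (r1 - a_tilde) + 1.0 / (c1 - a_tilde) + 1.0 / (r2 - c1 + a_tilde))
        resid = t.a - a_tilde
        bd += resid * resid / var
        resid_sum += resid
        var_sum += var
    if tarone:
        bd -= resid_sum * resid_sum / var_sum
        bd = max(bd, 0.0)
    df = len(s.strata) - 1
    p = float(_chi2_dist.sf(bd, df))
    return HomogeneityResult(or_mh=or_mh, bd_stat=bd, df=df, p_value=p, tarone_corrected=tarone)


# ---------------------------------------------------------------------------
# Two-drug comparison table
# ---------------------------------------------------------------------------


def disjoint_strata_counts(
    cohort_a: Cohort, cohort_b: Cohort, level: str, meddra: MedDRADict | None
) -> tuple[dict[str, tuple[int, int]], int, int, dict[str, int], int]:
    """Event counts for drug A's exposed, drug B's exposed, and the shared rest.

    Returns (per-event (count_a, count_b), n_exposed_a, n_exposed_b,
    per-event rest count, n_rest).  "Rest" is the set of reports exposed to
    neither drug, so the two strata built from it are disjoint.
    """
    ids_a = {r.primaryid for r in cohort_a.exposed}
    ids_b = {r.primaryid for r in cohort_b.exposed}

    def events_of(report) -> set[str]:
        if level == "PT":
            return report.reactions
        return {meddra.soc_of(pt) for pt in report.reactions}

    counts: dict[str, list[int]] = {}
    rest_counts: dict[str, int] = {}
    n_rest = 0
    seen_rest: set[str] = set()
    for which, cohort in ((0, cohort_a), (1, cohort_b)):
        for r in cohort.exposed:
            if r.primaryid in (ids_b if which == 0 else ids_a):
                continue  # exposed to both drugs: ambiguous, kept out of both strata
            for ev in events_of(r):
                counts.setdefault(ev, [0, 0])[which] += 1
    for r in cohort_a.background:
        if r.primaryid in ids_b or r.primaryid in seen_rest:
            continue
        seen_rest.add(r.primaryid)
        n_rest += 1
        for ev in events_of(r):
            rest_counts[ev] = rest_counts.get(ev, 0) + 1
    return (
        {ev: (c[0], c[1]) for ev, c in counts.items()},
        len(ids_a - ids_b),
        len(ids_b - ids_a),
        rest_counts,
        n_rest,
    )


def compare_drugs(
    cohort_a: Cohort,
    cohort_b: Cohort,
    level: str = "PT",
    meddra: MedDRADict | None = None,
    tarone: bool = True,
    top: int | None = None,
) -> pd.DataFrame:
    """Head-to-head signal comparison table for two drugs.

    One row per event signalled for either drug; per-drug report count and ROR
    with CI (from each drug's own cohort, exposed vs all other reports), and
    the Breslow-Day homogeneity p-value on the disjoint strata where both have
    positive margins.  Events present for only one drug carry NA on the other
    side.  Rows are ordered by SOC, then descending report count; ``top``
    keeps the top-N events per drug by report count before taking the union.
    """
    if cohort_a.n_total != cohort_b.n_total:
        raise FaersError(
            "cohorts come from different databases "
            f"({cohort_a.n_total} vs {cohort_b.n_total} deduplicated reports)"
        )
    from .dpa_core import build_tables

    stats_a = {s.table.event: s for s in analyze_tables(build_tables(cohort_a, level, meddra))}
    stats_b = {s.table.event: s for s in analyze_tables(build_tables(cohort_b, level, meddra))}
    sig_a = [ev for ev, s in stats_a.items() if s.is_signal]
    sig_b = [ev for ev, s in stats_b.items() if s.is_signal]
    if top is not None:
        sig_a = sorted(sig_a, key=lambda ev: -stats_a[ev].table.a)[:top]
        sig_b = sorted(sig_b, key=lambda ev: -stats_b[ev].table.a)[:top]
    events = set(sig_a) | set(sig_b)

    counts, n_a, n_b, rest_counts, n_rest = disjoint_strata_counts(cohort_a, cohort_b, level, meddra)

    rows = []
    for ev in events:
        sa, sb = stats_a.get(ev), stats_b.get(ev)
        ca, cb = counts.get(ev, (0, 0))
        c_rest = rest_counts.get(ev, 0)
        bd_stat = bd_p = None
        if ca > 0 and cb > 0 and 0 < c_rest < n_rest and ca < n_a and cb < n_b:
            strata = StratifiedTables(
                strata=[
                    (cohort_a.target_drug, ContingencyTable(ca, n_a - ca, c_rest, n_rest - c_rest, event=ev)),
                    (cohort_b.target_drug, ContingencyTable(cb, n_b - cb, c_rest, n_rest - c_rest, event=ev)),
                ],
                event=ev,
            )
            res = breslow_day(strata, tarone=tarone)
            bd_stat, bd_p = res.bd_stat, res.p_value
        soc = (sa or sb).table.soc if (sa or sb) else ""
        rows.append(
            {
                "event": ev,
                "soc": soc,
                "drug_a": cohort_a.target_drug,
                "n_a": sa.table.a if sa else None,
                "ror_a": sa.ror if sa else None,
                "ror_lo_a": sa.ror_lo if sa else None,
                "ror_hi_a": sa.ror_hi if sa else None,
                "signal_a": sa.is_signal if sa else False,
                "drug_b": cohort_b.target_drug,
                "n_b": sb.table.a if sb else None,
                "ror_b": sb.ror if sb else None,
                "ror_lo_b": sb.ror_lo if sb else None,
                "ror_hi_b": sb.ror_hi if sb else None,
                "signal_b": sb.is_signal if sb else False,
                "bd_stat": bd_stat,
                "bd_p": bd_p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["_n"] = df[["n_a", "n_b"]].max(axis=1)
        df = df.sort_values(["soc", "_n", "event"], ascending=[True, False, True]).drop(columns="_n")
        df = df.reset_index(drop=True)
    return df


def volcano_coords(stats: list[SignalStats]) -> pd.DataFrame:
    """Plot-ready coordinates: x = log2(ROR), y = sqrt(chi2), size = a.

    Events with missing statistics are omitted.  Point position encodes signal
    strength under both the ROR and the chi-square view; size encodes how many
    reports carry the event.
    """
    rows = [
        {
            "event": s.table.event,
            "soc": s.table.soc,
            "x": math.log2(s.ror),
            "y": math.sqrt(s.chi2),
            "size": s.table.a,
        }
        for s in stats
        if s.ror is not None and s.chi2 is not None and s.ror > 0
    ]
    return pd.DataFrame(rows, columns=["event", "soc", "x", "y", "size"])


def homogeneity_type1_study(
    n_events: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    n_exposed: tuple[int, int] = (2000, 3000),
    n_background: int = 20_000,
) -> float:
    """Empirical type-I error of the Breslow-Day test under homogeneous ORs.

    For each simulated event a shared odds ratio (lognormal around 1) and a
    background event probability (uniform 1-5%) generate two independent
    drug strata by binomial sampling; the rejection rate at ``alpha`` should
    sit near alpha.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.01, 0.05, n_events)
    shared_or = np.exp(rng.normal(0.0, 0.5, n_events))
    p1 = shared_or * p / (1 - p + shared_or * p)
    n1, n2 = n_exposed
    a1 = rng.binomial(n1, p1)
    a2 = rng.binomial(n2, p1)
    c1 = rng.binomial(n_background, p)
    c2 = rng.binomial(n_background, p)
    rejected = 0
    for i in range(n_events):
        strata = StratifiedTables(
            [
                ("A", ContingencyTable(int(a1[i]), n1 - int(a1[i]), int(c1[i]), n_background - int(c1[i]))),
                ("B", ContingencyTable(int(a2[i]), n2 - int(a2[i]), int(c2[i]), n_background - int(c2[i]))),
            ],
            event=f"event{i}",
        )
        rejected += int(breslow_day(strata).p_value < alpha)
    return rejected / n_events
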