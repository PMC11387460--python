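"""Case deduplication, drug-name standardisation and cohort construction.

Spontaneous-report databases accumulate multiple versions of the same case;
disproportionality analysis requires exactly one row per case, conventionally
the latest version by FDA receipt date.  Drug names arrive as free text (brand
names, strengths, misspellings) and are mapped to canonical active ingredients
through an alias dictionary.  A :class:`Cohort` then partitions the
deduplicated database into reports exposed to a target ingredient and the
background of all other reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .report_model_io import FaersError, SafetyReport, _sniff_delimiter

logger = logging.getLogger("faerspv")

DEFAULT_ROLES = frozenset({"PS", "SS"})  # suspect drugs


@dataclass
class DrugDictionary:
    """Alias → canonical-ingredient lookup used to standardise drug names.

    In ``substring`` mode an alias matches anywhere inside the verbatim name
    (or active-ingredient string), and the longest matching alias wins — so
    "CLARITIN-D" beats "CLARITIN" on the string "CLARITIN-D 12 HOUR".
    """

    alias_to_ingredient: dict[str, str]
    match_mode: str = "substring"  # substring | exact

    def __post_init__(self) -> None:
        if self.match_mode not in ("substring", "exact"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        self.alias_to_ingredient = {
            " ".join(alias.upper().split()): ing for alias, ing in self.alias_to_ingredient.items()
        }
        # longest aliases first so the first substring hit is the longest one
        self._ordered = sorted(self.alias_to_ingredient, key=len, reverse=True)

    @property
    def ingredients(self) -> set[str]:
        return set(self.alias_to_ingredient.values())

    def lookup(self, name: str | None) -> str | None:
        if not name:
            return None
        name_u = " ".join(name.upper().split())
        if self.match_mode == "exact":
            return self.alias_to_ingredient.get(name_u)
        hit = self.alias_to_ingredient.get(name_u)
        if hit is not None:
            return hit
        for alias in self._ordered:
            if alias in name_u:
                return self.alias_to_ingredient[alias]
        return None

    @classmethod
    def from_file(cls, path: str | Path, match_mode: str = "substring") -> "DrugDictionary":
        """Read a two-column delimited (alias, ingredient) file with a header."""
        path = Path(path)
        lines = path.read_text().splitlines()
        if not lines:
            raise FaersError(f"empty drug dictionary file: {path}")
        sep = _sniff_delimiter(lines[0])
        mapping: dict[str, str] = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise FaersError(f"malformed drug dictionary line in {path}: {line!r}")
            mapping[parts[0]] = parts[1].strip()
        return cls(mapping, match_mode)


@dataclass
class ExclusionCriteria:
    """Substring patterns that disqualify a report from the exposed cohort.

    A report is excluded when any of its drug strings (verbatim, active
    ingredient or standardised name) contains any pattern, case-insensitively.
    Used e.g. to keep levocetirizine reports out of a cetirizine cohort and
    combination products (pseudoephedrine co-formulations) out of both.
    """

    patterns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not p or not p.strip() for p in self.patterns):
            raise ValueError("exclusion patterns must be non-empty strings")
        self._patterns_u = [p.upper() for p in self.patterns]

    def matches_report(self, report: SafetyReport) -> bool:
        for d in report.drugs:
            for s in (d.verbatim_name, d.active_ingredient, d.standardized_name):
                if not s:
                    continue
                s_u = s.upper()
                if any(p in s_u for p in self._patterns_u):
                    return True
        return False

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionCriteria":
        """Read one pattern per line; blank lines and '#' comments ignored."""
        lines = Path(path).read_text().splitlines()
        patterns = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        return cls(patterns)


@dataclass
class Cohort:
    """Partition of a deduplicated report database for one target ingredient."""

    target_drug: str
    exposed: list[SafetyReport]
    background: list[SafetyReport]
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_exposed(self) -> int:
        return len(self.exposed)

    @property
    def n_total(self) -> int:
        return len(self.exposed) + len(self.background)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def deduplicate(reports: Sequence[SafetyReport]) -> list[SafetyReport]:
    """Keep exactly one report per case: the latest by receipt date.

    Ties on the date are broken by the numerically largest primaryid, then the
    largest case version.  Reports without a caseid cannot be merged and are
    kept as-is (flagged in the log).  Output preserves first-seen case order,
    so the operation is deterministic and idempotent.
    """
    best: dict[str, SafetyReport] = {}
    order: list[str] = []
    unmergeable: list[SafetyReport] = []
    for r in reports:
        if not r.caseid:
            unmergeable.append(r)
            continue
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            order.append(r.caseid)
        elif _dedup_key(r) > _dedup_key(cur):
            best[r.caseid] = r
    kept = [best[cid] for cid in order] + unmergeable
    removed = len(reports) - len(kept)
    if unmergeable:
        logger.warning("%d reports lack a caseid and were kept unmerged", len(unmergeable))
    logger.info("deduplicate: %d reports in, %d kept, %d removed", len(reports), len(kept), removed)
    return kept


def _dedup_key(r: SafetyReport) -> tuple:
    try:
        pid_num = int(r.primaryid)
    except ValueError:
        pid_num = -1
    return (r.receipt_date, pid_num, r.case_version)


def standardize_drugs(reports: Iterable[SafetyReport], dictionary: DrugDictionary) -> list[SafetyReport]:
    """Fill each DrugEntry's standardized_name from the alias dictionary.

    The verbatim name is tried first, then the active-ingredient string.
    Unmatched entries keep ``standardized_name`` missing (a valid state).
    Mutates the entries in place and returns the same reports for chaining.
    """
    reports = list(reports)
    n_hit = n_total = 0
    for r in reports:
        for d in r.drugs:
            n_total += 1
            ing = dictionary.lookup(d.verbatim_name) or dictionary.lookup(d.active_ingredient)
            d.standardized_name = ing
            if ing is not None:
                n_hit += 1
    logger.info("standardize_drugs: %d/%d entries matched", n_hit, n_total)
    return reports


def build_cohort(
    reports: Sequence[SafetyReport],
    target: str,
    exclusions: ExclusionCriteria | None = None,
    roles: frozenset[str] | set[str] = DEFAULT_ROLES,
    dictionary: DrugDictionary | None = None,
) -> Cohort:
    """Split a deduplicated, standardised database into exposed vs background.

    A report is *exposed* when at least one drug entry has
    ``standardized_name == target`` with a role in ``roles`` AND no drug
    string anywhere in the report matches an exclusion pattern.  Reports
    knocked out by an exclusion pattern stay in the background (exclusion is
    report-level: co-formulations confound attribution of the event to the
    target ingredient).

    Provenance records counts at each filter step: total, target-role match,
    after exclusion.
    """
    if dictionary is not None and target not in dictionary.ingredients:
        raise FaersError(f"target ingredient {target!r} is not a value of the drug dictionary")
    exclusions = exclusions or ExclusionCriteria([])
    exposed: list[SafetyReport] = []
    background: list[SafetyReport] = []
    n_target = 0
    for r in reports:
        has_target = any(d.standardized_name == target and d.role in roles for d in r.drugs)
        if has_target:
            n_target += 1
            if exclusions.matches_report(r):
                background.append(r)
            else:
                exposed.append(r)
        else:
            background.append(r)
    provenance = {
        "total": len(reports),
        "target_match": n_target,
        "after_exclusion": len(exposed),
    }
    logger.info("cohort %s: %s", target, provenance)
    return Cohort(target_drug=target, exposed=exposed, background=background, provenance=provenance)
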