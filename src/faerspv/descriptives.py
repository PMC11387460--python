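"""Descriptive summaries and the end-to-end pipeline orchestrator.

Covers the reporting-side outputs of a pharmacovigilance study: cohort
demographics (age/weight quartiles, sex, reporter occupation, outcomes,
countries, administration routes), yearly report-count trends, and top-K
indication / concomitant-medication tables — plus ``run_pipeline``, which
chains ingest → dedup → standardise → cohorts → signal statistics →
two-drug comparison → descriptives and writes every table with a provenance
report and a run manifest.

Percent conventions: within each categorical block the denominator is the sum
of the block's displayed counts.  For sex and reporter an explicit Unknown row
makes that sum equal the cohort size; outcomes count each outcome code once
per report (a report may carry several), and countries/routes exclude missing
values from the denominator.  Every emitted percent therefore recomputes
exactly from its own table.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dpa_core import analyze_tables, build_tables, signals_frame
from .drug_comparison import compare_drugs, volcano_coords
from .preprocess import (
    Cohort,
    DrugDictionary,
    ExclusionCriteria,
    build_cohort,
    deduplicate,
    standardize_drugs,
)
from .report_model_io import FaersError, MedDRADict, SafetyReport

logger = logging.getLogger("faerspv")

ROUTE_LABELS = {"ORAL": "Oral", "TRANSPLACENTAL": "Transplacental", "TOPICAL": "Topical", "OPHTHALMIC": "Ophthalmic"}
OUTCOME_LABELS = {
    "OT": "Other serious",
    "HO": "Hospitalization",
    "DS": "Disability",
    "LT": "Life threatening",
    "DE": "Death",
    "CA": "Congenital anomaly",
    "RI": "Permanent impairment/damage",
}
REPORTER_LABELS = {
    "consumer": "Consumer",
    "physician": "Physician",
    "pharmacist": "Pharmacist",
    "other_health_professional": "Other health-professional",
    "lawyer": "Lawyer",
    "registered_nurse": "Registered nurse",
    "unknown": "Unknown",
}
SEX_LABELS = {"F": "Female", "M": "Male", "UNK": "Unknown"}


def categorical_percents(counts: Mapping[str, int], denominator: int | None = None) -> list[tuple[str, int, float]]:
    """(label, count, percent) rows, descending count with alphabetical ties.

    The percent is count/denominator*100 rounded to 2 decimals; the
    denominator defaults to the sum of the counts, so the emitted percents
    always recompute from the emitted table.
    """
    den = denominator if denominator is not None else sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(label, c, round(100.0 * c / den, 2) if den else 0.0) for label, c in rows]


@dataclass
class DemographicSummary:
    """Cohort characteristics: continuous quartiles and categorical blocks."""

    n: int
    age_median: float | None
    age_q1: float | None
    age_q3: float | None
    weight_median: float | None
    weight_q1: float | None
    weight_q3: float | None
    blocks: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, entries in self.blocks.items():
            den = sum(c for _, c, _ in entries)
            for label, count, pct in entries:
                rows.append({"block": block, "label": label, "count": count, "percent": pct, "denominator": den})
        return pd.DataFrame(rows, columns=["block", "label", "count", "percent", "denominator"])


def _quartiles(values: list[float]) -> tuple[float | None, float | None, float | None]:
    if not values:
        return None, None, None
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize_demographics(cohort: Cohort, max_countries: int = 15) -> DemographicSummary:
    """Demographic and report-characteristic summary of the exposed cohort.

    Sex and reporter blocks include an Unknown row, so their denominators equal
    the cohort size; outcome percents are of all outcome occurrences (each
    code once per report); country and route percents are of reports with a
    known value, with countries beyond the ``max_countries`` most frequent
    bucketed as "Others".
    """
    reports = cohort.exposed
    n = len(reports)
    med_a, q1_a, q3_a = _quartiles([r.age_years for r in reports if r.age_years is not None])
    med_w, q1_w, q3_w = _quartiles([r.weight_kg for r in reports if r.weight_kg is not None])

    sex_counts = {label: 0 for label in SEX_LABELS.values()}
    reporter_counts = {label: 0 for label in REPORTER_LABELS.values()}
    outcome_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    route_counts: dict[str, int] = {}
    for r in reports:
        sex_counts[SEX_LABELS[r.sex]] += 1
        reporter_counts[REPORTER_LABELS.get(r.reporter, "Unknown")] += 1
        for oc in r.outcomes:
            label = OUTCOME_LABELS[oc]
            outcome_counts[label] = outcome_counts.get(label, 0) + 1
        if r.country:
            country_counts[r.country] = country_counts.get(r.country, 0) + 1
        if r.route:
            label = ROUTE_LABELS.get(r.route.upper(), "Others")
            route_counts[label] = route_counts.get(label, 0) + 1

    if len(country_counts) > max_countries:
        ranked = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = dict(ranked[:max_countries])
        kept["Others"] = sum(c for _, c in ranked[max_countries:])
        country_counts = kept

    return DemographicSummary(
        n=n,
        age_median=med_a, age_q1=q1_a, age_q3=q3_a,
        weight_median=med_w, weight_q1=q1_w, weight_q3=q3_w,
        blocks={
            "sex": categorical_percents(sex_counts),
            "reporter": categorical_percents(reporter_counts),
            "outcomes": categorical_percents(outcome_counts),
            "countries": categorical_percents(country_counts),
            "route": categorical_percents(route_counts),
        },
    )


def yearly_trend(cohorts: Mapping[str, Cohort], years: Iterable[int] | None = None) -> pd.DataFrame:
    """Report counts per receipt-date year per drug, zero-filled over the span."""
    all_years: set[int] = set(years or [])
    per_drug: dict[str, dict[int, int]] = {}
    for drug, cohort in cohorts.items():
        counts: dict[int, int] = {}
        for r in cohort.exposed:
            counts[r.receipt_date.year] = counts.get(r.receipt_date.year, 0) + 1
        per_drug[drug] = counts
        all_years.update(counts)
    if not all_years:
        return pd.DataFrame(columns=list(cohorts))
    span = range(min(all_years), max(all_years) + 1)
    return pd.DataFrame(
        {drug: [per_drug[drug].get(y, 0) for y in span] for drug in cohorts},
        index=pd.Index(span, name="year"),
    )


def top_k(cohort: Cohort, what: str = "indications", k: int = 5) -> pd.DataFrame:
    """Top-K indications or concomitant medications in the exposed cohort.

    Indications are the PTs attached to the target drug's entries, counted
    once per report; concomitants are the (standardised, else verbatim) names
    of role-C drugs.  The percent denominator is the number of exposed reports
    with at least one record of that kind, so the listed percents are shares
    among reports that carry the information at all.
    """
    if what not in ("indications", "concomitants"):
        raise ValueError(f"what must be 'indications' or 'concomitants', got {what!r}")
    counts: dict[str, int] = {}
    n_with = 0
    for r in cohort.exposed:
        if what == "indications":
            labels = {
                ind
                for d in r.drugs
                if d.standardized_name == cohort.target_drug
                for ind in d.indications
            }
        else:
            labels = {
                (d.standardized_name or d.verbatim_name)
                for d in r.drugs
                if d.role == "C" and (d.standardized_name or d.verbatim_name)
            }
        if labels:
            n_with += 1
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
    rows = categorical_percents(counts, denominator=n_with)[:k]
    return pd.DataFrame(rows, columns=["label", "n", "percent"])


# ---------------------------------------------------------------------------
# Reference characteristics (published large-scale extraction, for checks)
# ---------------------------------------------------------------------------


def load_reference_characteristics() -> pd.DataFrame:
    """Published report-characteristic counts for the two antihistamine cohorts.

    Columns: cohort, block, label, count, percent_printed.  The counts come
    from a published 2004Q1-2023Q4 FAERS extraction of cetirizine and
    loratadine reports; ``recompute_reference_percents`` reproduces the
    printed percents from the counts alone.
    """
    with resources.files("faerspv").joinpath("data/reference_characteristics.csv").open() as fh:
        return pd.read_csv(fh)


def recompute_reference_percents(ref: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each block percent from its counts under the block-sum rule."""
    ref = load_reference_characteristics() if ref is None else ref.copy()
    out = []
    for (cohort, block), grp in ref.groupby(["cohort", "block"], sort=False):
        rows = categorical_percents(dict(zip(grp["label"], grp["count"])))
        pct = {label: p for label, _, p in rows}
        g = grp.copy()
        g["percent_recomputed"] = [pct[l] for l in g["label"]]
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


class PipelineError(FaersError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis and write all artifact tables to ``outdir``.

    ``config`` either carries a ``simulate`` block (synthetic database) or an
    ``input`` block naming quarterly ASCII table files, plus ``targets`` (one
    or two ingredients), optional ``exclusions`` patterns, ``roles``,
    ``levels``, and dictionary paths.  Writes signal tables, comparison table,
    volcano coordinates, demographic summaries, trend series, top-K tables, a
    provenance report and a manifest (config hash + seed).  Reruns with the
    same config and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"outdir": outdir}
    provenance: list[str] = []

    # --- stage: ingest -------------------------------------------------------
    stage = "ingest"
    try:
        if "simulate" in config:
            from .synthetic_faers import SyntheticConfig, generate

            sim = dict(config["simulate"])
            planted = {
                (p["drug"], p["pt"]): float(p["lambda"]) for p in sim.pop("planted_signals", [])
            }
            if seed is not None:
                sim["seed"] = seed
            scfg = SyntheticConfig(planted_signals=planted, **sim)
            reports, truth = generate(scfg)
            meddra = scfg.meddra()
            drug_dict = scfg.drug_dictionary()
            artifacts["truth"] = truth
        else:
            from .report_model_io import assemble_reports, read_quarter

            inp = config["input"]
            meddra_path = Path(config["meddra"])
            if not meddra_path.exists():
                raise FaersError(f"MedDRA dictionary file not found: {meddra_path}")
            meddra = MedDRADict.from_file(meddra_path)
            drug_dict = DrugDictionary.from_file(Path(config["drug_dictionary"]))
            reports = []
            for quarter, paths in inp.items():
                raw = read_quarter(paths, quarter)
                reports.extend(assemble_reports(raw, meddra))
        provenance.append(f"total_reports\t{len(reports)}")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: dedup / standardise -----------------------------------------
    stage = "preprocess"
    try:
        deduped = deduplicate(reports)
        provenance.append(f"after_dedup\t{len(deduped)}")
        standardize_drugs(deduped, drug_dict)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: cohorts ------------------------------------------------------
    stage = "cohorts"
    try:
        targets = list(config["targets"])
        excl = ExclusionCriteria(list(config.get("exclusions", [])))
        roles = frozenset(config.get("roles", ("PS", "SS")))
        cohorts = {
            t: build_cohort(deduped, t, excl, roles, dictionary=drug_dict) for t in targets
        }
        for t, c in cohorts.items():
            provenance.append(f"cohort_{t}_target_match\t{c.provenance['target_match']}")
            provenance.append(f"cohort_{t}_exposed\t{c.provenance['after_exclusion']}")
        artifacts["cohorts"] = cohorts
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: signals ------------------------------------------------------
    stage = "signals"
    try:
        levels = list(config.get("levels", ["PT"]))
        all_stats: dict[tuple[str, str], list] = {}
        for t in targets:
            for level in levels:
                stats = analyze_tables(build_tables(cohorts[t], level, meddra))
                all_stats[(t, level)] = stats
                frame = signals_frame(stats)
                path = outdir / f"signals_{t}_{level}.csv"
                frame.to_csv(path, index=False)
                artifacts[f"signals_{t}_{level}"] = frame
                vpath = outdir / f"volcano_{t}_{level}.csv"
                volcano_coords(stats).to_csv(vpath, index=False)
                provenance.append(f"signals_{t}_{level}\t{int(frame['is_signal'].sum())}")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: comparison ---------------------------------------------------
    stage = "comparison"
    try:
        if len(targets) == 2:
            for level in levels:
                comp = compare_drugs(cohorts[targets[0]], cohorts[targets[1]], level, meddra)
                comp.to_csv(outdir / f"comparison_{level}.csv", index=False)
                artifacts[f"comparison_{level}"] = comp
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: descriptives -------------------------------------------------
    stage = "descriptives"
    try:
        for t in targets:
            summ = summarize_demographics(cohorts[t])
            summ.to_frame().to_csv(outdir / f"demographics_{t}.csv", index=False)
            artifacts[f"demographics_{t}"] = summ
            for what in ("indications", "concomitants"):
                top_k(cohorts[t], what).to_csv(outdir / f"top_{what}_{t}.csv", index=False)
        yearly_trend(cohorts).to_csv(outdir / "trend.csv")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "provenance.txt").write_text("\n".join(provenance) + "\n")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed if seed is not None else config.get("simulate", {}).get("seed"),
        "targets": targets,
        "levels": levels,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = manifest
    return artifacts
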