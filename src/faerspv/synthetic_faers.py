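"""Synthetic spontaneous-report generator with known ground truth.

Emulates the sampling structure that 2x2 disproportionality analysis assumes:
each report independently samples drugs (by prevalence) and reaction PTs,
where a planted association multiplies the baseline reporting probability of a
(drug, PT) pair by a rate ratio ``lambda`` (lambda = 1 means no association).
On top of the clean reports the generator injects the messiness the
preprocessing stage exists to handle: duplicate case versions with later
receipt dates, brand-name aliases replacing ingredient names, and per-field
missingness.

The generator makes no attempt to mimic real FAERS marginal frequencies, drug
market shares or secular reporting trends; it provides *controlled* data where
every downstream answer (cohort sizes, contingency counts, planted rate
ratios) can be checked against the truth it records.

Reaction sampling renormalises the tilted PT distribution per report and draws
without replacement via Gumbel top-k perturbation (equivalent to successive
weighted draws), so the number of reactions per report stays marginally
controlled across lambda values and the 2x2 margins remain stable.

All randomness derives from a single master seed through named
``numpy.random.SeedSequence`` child streams (demographics, drugs, reactions,
dates, duplicates, noise), so regenerating one aspect never perturbs the
others.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import DrugDictionary
from .report_model_io import (
    DELIMITER,
    DrugEntry,
    MedDRADict,
    SafetyReport,
    normalize_country,
)

_STREAMS = ("demographics", "drugs", "reactions", "dates", "duplicates", "noise")

_REPORTER_TO_CODE = {
    "consumer": "CN",
    "physician": "MD",
    "pharmacist": "PH",
    "other_health_professional": "HP",
    "lawyer": "LW",
    "registered_nurse": "RN",
    "unknown": "",
}

_DEFAULT_SOC_NAMES = (
    "NERVOUS SYSTEM DISORDERS",
    "PSYCHIATRIC DISORDERS",
    "GENERAL DISORDERS",
    "SKIN DISORDERS",
    "CARDIAC DISORDERS",
    "GASTROINTESTINAL DISORDERS",
    "RESPIRATORY DISORDERS",
    "EYE DISORDERS",
)

_INDICATION_VOCAB = (
    "ALLERGY",
    "HYPERSENSITIVITY",
    "ALLERGIC RHINITIS",
    "URTICARIA",
    "ASTHMA",
)

_COUNTRY_CODES = ("US", "GB", "FR", "DE", "CA", "JP", "AU", "IN")
_COUNTRY_PROBS = (0.80, 0.07, 0.03, 0.02, 0.02, 0.02, 0.02, 0.02)

_REPORTERS = ("consumer", "physician", "pharmacist", "other_health_professional", "unknown")
_REPORTER_PROBS = (0.78, 0.07, 0.05, 0.06, 0.04)

_OUTCOME_CODES_W = ("OT", "HO", "DS", "LT", "DE", "CA", "RI")
_OUTCOME_PROBS = (0.62, 0.22, 0.05, 0.04, 0.04, 0.02, 0.01)

_ROUTES = ("ORAL", "TOPICAL", "OPHTHALMIC")
_ROUTE_PROBS = (0.85, 0.10, 0.05)


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic report database.

    ``planted_signals`` maps (drug name, PT name) to the rate-ratio multiplier
    lambda applied to that PT's baseline reporting probability in reports that
    contain the drug (lambda = 1: no association).  Probability vectors must
    sum to 1 within 1e-9.
    """

    n_reports: int
    n_drugs: int = 20
    n_pts: int = 50
    seed: int = 0
    baseline_pt_probs: np.ndarray | None = None   # default: Zipf over PTs
    drug_prevalence: np.ndarray | None = None     # default: Zipf over drugs
    planted_signals: dict[tuple[str, str], float] = field(default_factory=dict)
    reactions_per_report_mu: float = 1.0          # k = 1 + Poisson(mu)
    drugs_per_report_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) drugs
    duplicate_rate: float = 0.0
    alias_noise_rate: float = 0.0
    missingness: dict[str, float] = field(
        default_factory=lambda: {"age": 0.2, "weight": 0.4, "sex": 0.1, "country": 0.05, "route": 0.3}
    )
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2004, 1, 1), _dt.date(2023, 12, 31))
    drug_names: tuple[str, ...] | None = None
    pt_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.drug_names is None:
            self.drug_names = tuple(f"ingredient{i:02d}" for i in range(self.n_drugs))
        if self.pt_names is None:
            self.pt_names = tuple(f"PT {j:03d}" for j in range(self.n_pts))
        if len(self.drug_names) != self.n_drugs or len(self.pt_names) != self.n_pts:
            raise ValueError("drug_names / pt_names lengths must match n_drugs / n_pts")
        if self.baseline_pt_probs is None:
            w = 1.0 / np.arange(1, self.n_pts + 1)
            self.baseline_pt_probs = w / w.sum()
        else:
            self.baseline_pt_probs = np.asarray(self.baseline_pt_probs, dtype=float)
        if self.drug_prevalence is None:
            w = 1.0 / np.arange(1, self.n_drugs + 1)
            self.drug_prevalence = w / w.sum()
        else:
            self.drug_prevalence = np.asarray(self.drug_prevalence, dtype=float)
        for name, vec, nexp in (
            ("baseline_pt_probs", self.baseline_pt_probs, self.n_pts),
            ("drug_prevalence", self.drug_prevalence, self.n_drugs),
        ):
            if len(vec) != nexp:
                raise ValueError(f"{name} must have length {nexp}")
            if abs(float(vec.sum()) - 1.0) > 1e-9 or (vec < 0).any():
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for key, rate in (("duplicate_rate", self.duplicate_rate), ("alias_noise_rate", self.alias_noise_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1]")
        for fld, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{fld!r}] must lie in [0, 1]")
        drug_set, pt_set = set(self.drug_names), set(self.pt_names)
        for (drug, pt), lam in self.planted_signals.items():
            if drug not in drug_set or pt not in pt_set:
                raise ValueError(f"planted signal ({drug!r}, {pt!r}) names an unknown drug or PT")
            if lam < 0:
                raise ValueError("planted lambda must be >= 0")

    # -- companion vocabularies ------------------------------------------------

    def meddra(self) -> MedDRADict:
        """Mock PT→SOC dictionary covering this config's PT vocabulary."""
        mapping = {
            pt: _DEFAULT_SOC_NAMES[j % len(_DEFAULT_SOC_NAMES)] for j, pt in enumerate(self.pt_names)
        }
        for ind in _INDICATION_VOCAB:
            mapping[ind] = "IMMUNE SYSTEM DISORDERS"
        return MedDRADict(mapping, version_label="synthetic")

    def drug_dictionary(self) -> DrugDictionary:
        """Alias dictionary: each ingredient plus one brand alias."""
        mapping: dict[str, str] = {}
        for i, ing in enumerate(self.drug_names):
            mapping[ing.upper()] = ing
            mapping[_brand_of(i)] = ing
        return DrugDictionary(mapping, match_mode="substring")


def _brand_of(drug_index: int) -> str:
    return f"BRAND{drug_index:02d}"


@dataclass
class GroundTruth:
    """What the generator actually planted, for checking pipeline output."""

    planted_signals: dict[tuple[str, str], float]
    case_versions: dict[str, list[str]]            # caseid -> primaryids (all versions)
    true_ingredients: dict[tuple[str, int], str]   # (primaryid, drug seq) -> ingredient


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: SyntheticConfig) -> tuple[list[SafetyReport], GroundTruth]:
    """Draw a report database and its ground truth from the config.

    Fully reproducible: the same config (including seed) yields an identical
    report list.
    """
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))
    }
    n = config.n_reports
    truth = GroundTruth(dict(config.planted_signals), {}, {})
    if n == 0:
        return [], truth

    # --- drugs per report (n x 3 index matrix, -1 padding) -------------------
    rng_drugs = rngs["drugs"]
    k_drugs = rng_drugs.choice(
        np.arange(1, len(config.drugs_per_report_probs) + 1), size=n, p=config.drugs_per_report_probs
    )
    max_k = int(k_drugs.max())
    drug_mat = rng_drugs.choice(config.n_drugs, size=(n, max_k), p=config.drug_prevalence)
    col = np.arange(max_k)[None, :]
    drug_mat = np.where(col < k_drugs[:, None], drug_mat, -1)
    # secondary-suspect flag for non-first drugs (else concomitant)
    ss_flags = rng_drugs.random(size=(n, max_k)) < 0.2
    indi_draws = rng_drugs.random(size=(n, max_k))
    indi_idx = rng_drugs.choice(len(_INDICATION_VOCAB), size=(n, max_k))

    # --- reaction sampling: Gumbel top-k on the tilted log-weights -----------
    rng_re = rngs["reactions"]
    log_lam = np.zeros((config.n_drugs + 1, config.n_pts))  # last row: padding (-1)
    drug_index = {name: i for i, name in enumerate(config.drug_names)}
    pt_index = {name: j for j, name in enumerate(config.pt_names)}
    for (drug, pt), lam in config.planted_signals.items():
        log_lam[drug_index[drug], pt_index[pt]] = np.log(lam) if lam > 0 else -np.inf
    with np.errstate(divide="ignore"):
        log_w = np.log(config.baseline_pt_probs)[None, :] + log_lam[drug_mat].sum(axis=1)
    k_react = np.minimum(1 + rng_re.poisson(config.reactions_per_report_mu, size=n), config.n_pts)
    gumbel = rng_re.gumbel(size=(n, config.n_pts))
    order = np.argsort(-(log_w + gumbel), axis=1)[:, : int(k_react.max())]

    # --- demographics ---------------------------------------------------------
    rng_demo = rngs["demographics"]
    ages = np.round(np.clip(rng_demo.lognormal(mean=np.log(40.0), sigma=0.45, size=n), 0.0, 120.0), 2)
    weights = np.round(np.clip(rng_demo.lognormal(mean=np.log(68.0), sigma=0.25, size=n), 2.0, 250.0), 2)
    sexes = rng_demo.choice(np.array(["F", "M", "UNK"]), size=n, p=(0.52, 0.30, 0.18))
    reporters = rng_demo.choice(np.array(_REPORTERS), size=n, p=_REPORTER_PROBS)
    countries = rng_demo.choice(np.array(_COUNTRY_CODES), size=n, p=_COUNTRY_PROBS)
    routes = rng_demo.choice(np.array(_ROUTES), size=n, p=_ROUTE_PROBS)
    n_outcomes = rng_demo.choice(np.array([0, 1, 2]), size=n, p=(0.55, 0.35, 0.10))
    outcome_mat = rng_demo.choice(len(_OUTCOME_CODES_W), size=(n, 2), p=_OUTCOME_PROBS)
    miss = {
        fld: rng_demo.random(size=n) < p for fld, p in config.missingness.items()
    }

    # --- dates ----------------------------------------------------------------
    rng_dates = rngs["dates"]
    start_ord, end_ord = config.date_range[0].toordinal(), config.date_range[1].toordinal()
    date_ords = rng_dates.integers(start_ord, end_ord + 1, size=n)

    # --- alias noise ----------------------------------------------------------
    noise = rngs["noise"].random(size=(n, max_k)) < config.alias_noise_rate

    # --- assemble report objects ---------------------------------------------
    # plain-list views of the sampled arrays: scalar indexing into numpy arrays
    # dominates runtime at n ~ 1e5 otherwise
    from_ordinal = _dt.date.fromordinal
    names = config.drug_names
    upper_names = tuple(nm.upper() for nm in names)
    brand_verbatim = tuple(f"{_brand_of(i)} 10MG TAB" for i in range(config.n_drugs))
    pts = config.pt_names
    countries_norm = {c: normalize_country(c) for c in _COUNTRY_CODES}
    k_drugs_l = k_drugs.tolist()
    drug_mat_l = drug_mat.tolist()
    ss_flags_l = ss_flags.tolist()
    indi_take_l = (indi_draws < 0.5).tolist()
    indi_idx_l = indi_idx.tolist()
    order_l = order.tolist()
    k_react_l = k_react.tolist()
    ages_l = ages.tolist()
    weights_l = weights.tolist()
    sexes_l = sexes.tolist()
    reporters_l = reporters.tolist()
    countries_l = countries.tolist()
    routes_l = routes.tolist()
    n_outcomes_l = n_outcomes.tolist()
    outcome_mat_l = outcome_mat.tolist()
    date_ords_l = date_ords.tolist()
    false_row = [False] * n
    miss_l = {fld: arr.tolist() for fld, arr in miss.items()}
    m_age = miss_l.get("age", false_row)
    m_wt = miss_l.get("weight", false_row)
    m_sex = miss_l.get("sex", false_row)
    m_ctry = miss_l.get("country", false_row)
    m_route = miss_l.get("route", false_row)
    noise_l = noise.tolist()

    reports: list[SafetyReport] = []
    true_ingredients = truth.true_ingredients
    case_versions = truth.case_versions
    for i in range(n):
        caseid = str(10_000_000 + i)
        pid = caseid + "1"
        entries: list[DrugEntry] = []
        row_drugs = drug_mat_l[i]
        row_noise = noise_l[i]
        for j in range(k_drugs_l[i]):
            di = row_drugs[j]
            if row_noise[j]:
                verbatim, active = brand_verbatim[di], None
            else:
                verbatim = active = upper_names[di]
            role = "PS" if j == 0 else ("SS" if ss_flags_l[i][j] else "C")
            inds = {_INDICATION_VOCAB[indi_idx_l[i][j]]} if indi_take_l[i][j] else set()
            entries.append(DrugEntry(j + 1, role, verbatim, active, None, inds))
            true_ingredients[(pid, j + 1)] = names[di]
        reactions = {pts[p] for p in order_l[i][: k_react_l[i]]}
        n_oc = n_outcomes_l[i]
        oc = {_OUTCOME_CODES_W[outcome_mat_l[i][m]] for m in range(n_oc)} if n_oc else set()
        reports.append(
            SafetyReport(
                pid,
                caseid,
                1,
                from_ordinal(date_ords_l[i]),
                None if m_age[i] else ages_l[i],
                "UNK" if m_sex[i] else sexes_l[i],
                None if m_wt[i] else weights_l[i],
                reporters_l[i],
                None if m_ctry[i] else countries_norm[countries_l[i]],
                None if m_route[i] else routes_l[i],
                oc,
                entries,
                reactions,
            )
        )
        case_versions[caseid] = [pid]

    # --- duplicate versions ---------------------------------------------------
    rng_dup = rngs["duplicates"]
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng_dup.choice(n, size=n_dup, replace=False)
        offsets = rng_dup.integers(1, 91, size=n_dup)
        for idx, off in zip(dup_idx, offsets):
            orig = reports[int(idx)]
            pid2 = orig.caseid + "2"
            dup = SafetyReport(
                primaryid=pid2,
                caseid=orig.caseid,
                case_version=2,
                receipt_date=orig.receipt_date + _dt.timedelta(days=int(off)),
                age_years=orig.age_years,
                sex=orig.sex,
                weight_kg=orig.weight_kg,
                reporter=orig.reporter,
                country=orig.country,
                route=orig.route,
                outcomes=set(orig.outcomes),
                drugs=[
                    DrugEntry(seq=d.seq, role=d.role, verbatim_name=d.verbatim_name,
                              active_ingredient=d.active_ingredient, indications=set(d.indications))
                    for d in orig.drugs
                ],
                reactions=set(orig.reactions),
            )
            for d in orig.drugs:
                truth.true_ingredients[(pid2, d.seq)] = truth.true_ingredients[(orig.primaryid, d.seq)]
            truth.case_versions[orig.caseid].append(pid2)
            reports.append(dup)

    return reports, truth


# ---------------------------------------------------------------------------
# Export to FAERS-style quarterly ASCII files
# ---------------------------------------------------------------------------


def _quarter_of(d: _dt.date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def _quarter_suffix(quarter: str) -> str:
    return quarter[2:4] + quarter[4:]  # "2019Q3" -> "19Q3"


def export_quarters(reports: Sequence[SafetyReport], outdir: str | Path) -> dict[str, dict[str, Path]]:
    """Write reports as '$'-delimited DEMO/DRUG/REAC/OUTC/INDI files per quarter.

    Files are named ``<TABLE><yy>Q<q>.txt``.  Returns {quarter: {table: path}}.
    Reading the files back through ``read_quarter`` + ``assemble_reports``
    reproduces the report model (the export is orphan-free by construction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_quarter: dict[str, list[SafetyReport]] = {}
    for r in reports:
        by_quarter.setdefault(_quarter_of(r.receipt_date), []).append(r)

    headers = {
        "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
                 "sex", "wt", "wt_cod", "occp_cod", "reporter_country"],
        "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"],
        "REAC": ["primaryid", "pt"],
        "OUTC": ["primaryid", "outc_cod"],
        "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
    }
    out: dict[str, dict[str, Path]] = {}
    for quarter in sorted(by_quarter):
        rows: dict[str, list[list[str]]] = {t: [] for t in headers}
        for r in by_quarter[quarter]:
            rows["DEMO"].append([
                r.primaryid, r.caseid, str(r.case_version), r.receipt_date.strftime("%Y%m%d"),
                "" if r.age_years is None else f"{r.age_years:g}",
                "" if r.age_years is None else "YR",
                "" if r.sex == "UNK" else r.sex,
                "" if r.weight_kg is None else f"{r.weight_kg:g}",
                "" if r.weight_kg is None else "KG",
                _REPORTER_TO_CODE.get(r.reporter, ""),
                r.country or "",
            ])
            for k, d in enumerate(r.drugs):
                rows["DRUG"].append([
                    r.primaryid, str(d.seq), d.role, d.verbatim_name, d.active_ingredient or "",
                    (r.route or "") if k == 0 else "",
                ])
                for ind in sorted(d.indications):
                    rows["INDI"].append([r.primaryid, str(d.seq), ind])
            for pt in sorted(r.reactions):
                rows["REAC"].append([r.primaryid, pt])
            for oc in sorted(r.outcomes):
                rows["OUTC"].append([r.primaryid, oc])
        out[quarter] = {}
        for table, header in headers.items():
            path = outdir / f"{table}{_quarter_suffix(quarter)}.txt"
            lines = [DELIMITER.join(header)] + [DELIMITER.join(row) for row in rows[table]]
            path.write_text("\n".join(lines) + "\n")
            out[quarter][table] = path
    return out


# ---------------------------------------------------------------------------
# Calibration studies (power / false-positive control of the signal criterion)
# ---------------------------------------------------------------------------


def _signal_stats_for(config: SyntheticConfig, target: str) -> dict:
    """Run generate → dedup → standardise → cohort → statistics for one drug."""
    from .dpa_core import analyze_tables, build_tables
    from .preprocess import build_cohort, deduplicate, standardize_drugs

    reports, _ = generate(config)
    deduped = deduplicate(reports)
    standardize_drugs(deduped, config.drug_dictionary())
    cohort = build_cohort(deduped, target, dictionary=config.drug_dictionary())
    return {s.table.event: s for s in analyze_tables(build_tables(cohort, "PT", config.meddra()))}


def recovery_config(n_reports: int, seed: int, lam: float = 10.0) -> SyntheticConfig:
    """Study conditions for planted-signal recovery: one lambda-tilted pair.

    A mid-prevalence drug and a mid-frequency PT give an expected exposed-with-
    event count well above the a >= 3 criterion floor at n = 100,000.
    """
    return SyntheticConfig(
        n_reports=n_reports, n_drugs=10, n_pts=30, seed=seed,
        planted_signals={("ingredient07", "PT 012"): lam},
        duplicate_rate=0.05, alias_noise_rate=0.05,
    )


def planted_signal_recovery(
    n_seeds: int = 100, n_reports: int = 100_000, lam: float = 10.0, base_seed: int = 0
) -> float:
    """Fraction of independent replicates in which the planted pair is flagged."""
    hits = 0
    for i in range(n_seeds):
        stats = _signal_stats_for(recovery_config(n_reports, base_seed + i, lam), "ingredient07")
        s = stats.get("PT 012")
        hits += bool(s is not None and s.is_signal)
    return hits / n_seeds


def null_flag_fraction(n_reports: int = 100_000, seed: int = 0) -> tuple[int, int]:
    """(flagged, eligible) over all 200 drug-PT pairs of a no-association database.

    All lambda = 1: any flagged pair with a >= 3 is a false positive of the
    combined criterion.
    """
    config = SyntheticConfig(n_reports=n_reports, n_drugs=20, n_pts=10, seed=seed,
                             duplicate_rate=0.05)
    from .dpa_core import analyze_tables, build_tables
    from .preprocess import build_cohort, deduplicate, standardize_drugs

    reports, _ = generate(config)
    deduped = deduplicate(reports)
    standardize_drugs(deduped, config.drug_dictionary())
    flagged = eligible = 0
    for drug in config.drug_names:
        cohort = build_cohort(deduped, drug, dictionary=config.drug_dictionary())
        for s in analyze_tables(build_tables(cohort, "PT", config.meddra())):
            if s.table.a >= 3:
                eligible += 1
                flagged += int(s.is_signal)
    return flagged, eligible
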