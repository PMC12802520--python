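"""End-to-end signal mining: reports file in, ranked signal tables out.

Stage order: read → deduplicate → primary-suspect filter → PT validation →
2×2 tables → four detectors → significance and intensity → invalid-signal
exclusion → SOC aggregation → ranking → novel-PT flagging → descriptive
summary.  Every stage's inflow and outflow is recorded in an accounting
dict, so nothing is lost silently.

One ordering subtlety: the primary-suspect filter defines the drug's report
subset (used for the descriptive summary and the drug-level accounting), but
the 2×2 background population is the *full* deduplicated set — the c and d
cells count reports where other drugs are the primary suspect.  The
``comparator`` option chooses whether reports losing all their PTs in
validation stay in that background (``all``) or are dropped (``cleaned``,
the default).

Signals are PT-level rows of a DataFrame carrying counts, statistics,
per-method significance and intensity, SOC, an exclusion category for
invalid signals (events reflecting the treated disease, its outcomes,
non-reference terms or unspecified events), and a novelty flag against the
drug's label PT list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import io as faers_io
from ._util import pct
from .contingency import build_all_tables, tables_to_frame
from .disproportionality import format_statistics_table, statistics_frame
from .model import NOT_SPECIFIED, OUTCOMES, ConfigurationError, MedDRAMap, SafetyReport

log = logging.getLogger(__name__)

EXCLUSION_CATEGORIES = ("primary_disease", "disease_outcome", "non_reference", "unspecified")

#: Default country → reporter-region assignment (ISO alpha-2 and common names).
DEFAULT_REGIONS: dict[str, str] = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "PR": "North America",
    "GB": "Europe", "FR": "Europe", "DE": "Europe", "IT": "Europe", "ES": "Europe",
    "NL": "Europe", "BE": "Europe", "CH": "Europe", "SE": "Europe", "DK": "Europe",
    "NO": "Europe", "FI": "Europe", "PL": "Europe", "AT": "Europe", "IE": "Europe",
    "PT": "Europe", "GR": "Europe", "CZ": "Europe", "RO": "Europe", "HU": "Europe",
    "RU": "Europe", "UA": "Europe", "TR": "Europe",
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "HK": "Asia", "SG": "Asia", "TH": "Asia", "MY": "Asia", "ID": "Asia",
    "PH": "Asia", "VN": "Asia", "IL": "Asia", "SA": "Asia", "AE": "Asia", "QA": "Asia",
    "BR": "South America", "AR": "South America", "CL": "South America",
    "CO": "South America", "PE": "South America", "VE": "South America",
    "AU": "Oceania", "NZ": "Oceania",
    "ZA": "Africa", "EG": "Africa", "NG": "Africa", "KE": "Africa", "MA": "Africa",
}

AGE_BANDS = ("< 18", "18-64", ">= 65", NOT_SPECIFIED)


def _norm(term: str) -> str:
    return " ".join(term.casefold().split())


@dataclass(frozen=True)
class ExclusionConfig:
    """PT lists defining the four invalid-signal categories.

    A statistically significant PT can still be uninformative about drug
    harm when it names the treated disease itself, an outcome of the
    disease, a non-reference term, or an unspecified event; such signals are
    tagged and removed from the positive set.
    """

    primary_disease: tuple[str, ...] = ()
    disease_outcome: tuple[str, ...] = ()
    non_reference: tuple[str, ...] = ()
    unspecified: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cat in EXCLUSION_CATEGORIES:
            for term in getattr(self, cat):
                key = _norm(term)
                if key in seen and seen[key] != cat:
                    raise ConfigurationError(
                        f"exclusion term {term!r} appears in both {seen[key]!r} and {cat!r}")
                seen[key] = cat

    def category_of(self, pt: str) -> str | None:
        key = _norm(pt)
        for cat in EXCLUSION_CATEGORIES:
            if key in {_norm(t) for t in getattr(self, cat)}:
                return cat
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionConfig":
        """Load category lists from YAML/JSON ({category: [terms...]})."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(EXCLUSION_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown exclusion categories: {sorted(unknown)}")
        return cls(**{cat: tuple(raw.get(cat, ())) for cat in EXCLUSION_CATEGORIES})


def default_exclusions() -> ExclusionConfig:
    """Starter lists for a breast-cancer indication; extend per study."""
    return ExclusionConfig(
        primary_disease=("Disease progression", "Neoplasm progression",
                         "Malignant neoplasm progression", "Breast cancer",
                         "Breast cancer metastatic", "Breast cancer female"),
        disease_outcome=("Death", "Disease recurrence"),
        non_reference=("Investigation",),
        unspecified=("Oncologic complication", "Adverse event"),
    )


@dataclass
class DescriptiveSummary:
    """Report-characteristics tables (counts and 2-decimal percentages).

    ``sections`` maps a partition name (sex, age_band, region, country,
    indication, year, outcome) to a DataFrame with ``level, count, pct``.
    All percentages use the full report total as denominator; outcome
    percentages need not sum to 100 because one report can carry several
    outcome classes.
    """

    total: int
    sections: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, frame in self.sections.items():
            part = frame.copy()
            part.insert(0, "section", name)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["section", "level", "count", "pct"])
        return pd.concat(parts, ignore_index=True)


def describe_reports(reports: Sequence[SafetyReport],
                     region_map: Mapping[str, str] | None = None,
                     top_indications: int = 10,
                     top_countries: int = 10) -> DescriptiveSummary:
    """Tabulate the clinical characteristics of a deduplicated report set.

    Countries absent from the region map fall into ``not_specified`` with a
    logged warning.  Age bands are <18, 18–64 (lower bounds inclusive) and
    ≥65, with missing ages as an explicit band.
    """
    regions = dict(DEFAULT_REGIONS if region_map is None else region_map)
    total = len(reports)

    def count_section(counter: dict[str, int], order: Iterable[str] | None = None,
                      top: int | None = None) -> pd.DataFrame:
        if order is None:
            items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        else:
            items = [(lvl, counter.get(lvl, 0)) for lvl in order]
        if top is not None:
            items = items[:top]
        return pd.DataFrame(
            [{"level": lvl, "count": n, "pct": pct(n, total)} for lvl, n in items],
            columns=["level", "count", "pct"],
        )

    sex: dict[str, int] = {}
    age: dict[str, int] = {b: 0 for b in AGE_BANDS}
    region: dict[str, int] = {}
    country: dict[str, int] = {}
    indication: dict[str, int] = {}
    year: dict[str, int] = {}
    outcome: dict[str, int] = {o: 0 for o in OUTCOMES}
    unmapped: set[str] = set()

    for r in reports:
        sex[r.sex] = sex.get(r.sex, 0) + 1
        if r.age_years is None:
            band = NOT_SPECIFIED
        elif r.age_years < 18:
            band = "< 18"
        elif r.age_years < 65:
            band = "18-64"
        else:
            band = ">= 65"
        age[band] += 1
        if r.country is None:
            reg = NOT_SPECIFIED
        else:
            reg = regions.get(r.country)
            if reg is None:
                unmapped.add(r.country)
                reg = NOT_SPECIFIED
            country[r.country] = country.get(r.country, 0) + 1
        region[reg] = region.get(reg, 0) + 1
        ind = r.indication if r.indication is not None else NOT_SPECIFIED
        indication[ind] = indication.get(ind, 0) + 1
        year[str(r.year)] = year.get(str(r.year), 0) + 1
        for o in r.outcomes:
            outcome[o] += 1

    if unmapped:
        log.warning("countries missing from region map, counted as not specified: %s",
                    ", ".join(sorted(unmapped)))

    region_order = ["North America", "Europe", "Asia", "South America",
                    "Oceania", "Africa", NOT_SPECIFIED]
    sections = {
        "sex": count_section(sex, order=("female", "male", NOT_SPECIFIED)),
        "age_band": count_section(age, order=AGE_BANDS),
        "region": count_section(region, order=region_order),
        "country": count_section(country, top=top_countries),
        "indication": count_section(indication, top=top_indications),
        "year": count_section(year, order=sorted(year, reverse=True)),
        "outcome": count_section(outcome, order=OUTCOMES),
    }
    return DescriptiveSummary(total=total, sections=sections)


# ---------------------------------------------------------------------------
# signal-table operations

def exclude_invalid(signals: pd.DataFrame, exclusions: ExclusionConfig
                    ) -> tuple[pd.DataFrame, dict]:
    """Tag significant signals matching an exclusion list; account for all.

    Accounting reports signal *records* (PT rows) and signal *reports* (the
    sum of n over rows, the flow-diagram unit) for detected, per-category
    excluded, and retained; retained = detected − excluded in both units.
    """
    out = signals.copy()
    categories = []
    for _, row in out.iterrows():
        if bool(row["sig_combined"]):
            categories.append(exclusions.category_of(str(row["pt"])))
        else:
            categories.append(None)
    out["excluded"] = pd.array(categories, dtype="string")

    detected = out[out["sig_combined"]]
    excluded = detected[detected["excluded"].notna()]
    retained = detected[detected["excluded"].isna()]
    acct = {
        "detected_records": int(len(detected)),
        "detected_reports": int(detected["n"].sum()),
        "excluded_records": {
            cat: int((excluded["excluded"] == cat).sum()) for cat in EXCLUSION_CATEGORIES
        },
        "excluded_reports": {
            cat: int(excluded.loc[excluded["excluded"] == cat, "n"].sum())
            for cat in EXCLUSION_CATEGORIES
        },
        "excluded_records_total": int(len(excluded)),
        "excluded_reports_total": int(excluded["n"].sum()),
        "retained_records": int(len(retained)),
        "retained_reports": int(retained["n"].sum()),
    }
    return out, acct


def positive_signals(signals: pd.DataFrame) -> pd.DataFrame:
    """Combined-positive rows not tagged by any exclusion category."""
    mask = signals["sig_combined"]
    if "excluded" in signals.columns:
        mask = mask & signals["excluded"].isna()
    return signals[mask]


def aggregate_soc(signals: pd.DataFrame, meddra: MedDRAMap | None = None
                  ) -> pd.DataFrame:
    """Per-SOC totals of positive signal reports, as shares of the positive total.

    Sums ``n`` over positive PT rows per SOC and expresses each SOC as a
    2-decimal percentage of the positive-signal total, sorted descending.
    """
    pos = positive_signals(signals).copy()
    if "soc" not in pos.columns or pos["soc"].isna().any():
        if meddra is None:
            missing = pos.loc[pos.get("soc", pd.Series(dtype=object)).isna(), "pt"]
            raise KeyError(f"PT(s) lack a SOC and no MedDRA map was given: "
                           f"{', '.join(map(str, missing))}")
        socs = [meddra.soc_of(pt) for pt in pos["pt"]]
        pos["soc"] = [s[0] for s in socs]
        pos["soc_code"] = [s[1] for s in socs]
    grouped = (pos.groupby(["soc", "soc_code"], as_index=False)["n"].sum()
               .sort_values(["n", "soc"], ascending=[False, True], ignore_index=True))
    total = int(grouped["n"].sum())
    grouped["pct"] = [pct(n, total) for n in grouped["n"]]
    return grouped


def rank_signals(signals: pd.DataFrame, by: str = "frequency",
                 top_k: int | None = None,
                 strength_metric: str = "ror") -> pd.DataFrame:
    """Order a signal table by report frequency or by signal strength.

    ``frequency``: n desc, ties by ROR desc then PT name.
    ``strength``: the strength metric (ROR by default, optionally ic025)
    desc, ties by n desc then PT name.
    """
    if by == "frequency":
        keys, ascending = ["n", "ror", "pt"], [False, False, True]
    elif by == "strength":
        keys, ascending = [strength_metric, "n", "pt"], [False, False, True]
    else:
        raise ValueError(f"unknown ranking: {by!r}")
    out = signals.sort_values(keys, ascending=ascending, kind="mergesort",
                              ignore_index=True)
    return out if top_k is None else out.head(top_k).reset_index(drop=True)


def flag_novel(signals: pd.DataFrame, label_pts: Iterable[str]) -> pd.DataFrame:
    """Mark PTs absent from the drug's label PT list as novel (case-insensitive)."""
    labels = {_norm(t) for t in label_pts}
    out = signals.copy()
    out["novel"] = [_norm(str(pt)) not in labels for pt in out["pt"]]
    return out


def load_label_pts(path: str | Path) -> list[str]:
    """Read a label PT list: one term per line, blank lines and # comments skipped."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class PipelineOptions:
    dialect: str = "wide"
    comparator: str = "cleaned"          # "cleaned" | "all"
    continuity_correction: bool = False
    bcpnn_additive_interval: bool = False
    top_k: int = 50
    rank_by: str = "frequency"
    strength_metric: str = "ror"
    synonyms: tuple[str, ...] = ()
    min_reports: int = 3


@dataclass
class PipelineResult:
    signals: pd.DataFrame
    accounting: dict
    summary: DescriptiveSummary
    soc_summary: pd.DataFrame
    ranked: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write signals/SOC/summary TSVs and the accounting JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.signals.to_csv(out / "signals.tsv", sep="\t", index=False,
                            float_format="%.10g")
        format_statistics_table(self.ranked).to_csv(
            out / "signals_ranked.tsv", sep="\t", index=False)
        self.soc_summary.to_csv(out / "soc_summary.tsv", sep="\t", index=False)
        self.summary.to_frame().to_csv(out / "report_summary.tsv", sep="\t", index=False)
        (out / "accounting.json").write_text(
            json.dumps(self.accounting, indent=2, sort_keys=True) + "\n")


def run_pipeline(reports: str | Path | Sequence[SafetyReport], drug: str,
                 meddra: MedDRAMap | str | Path,
                 exclusions: ExclusionConfig | None = None,
                 label_pts: Iterable[str] | None = None,
                 options: PipelineOptions | None = None,
                 region_map: Mapping[str, str] | None = None) -> PipelineResult:
    """Run the full mining flow for one drug of interest.

    ``reports`` may be a path to an interchange CSV or an in-memory report
    sequence.  Deterministic: identical inputs give identical outputs.  An
    empty post-filter set yields an empty signal table plus the summary, not
    an error.
    """
    opts = options or PipelineOptions()
    exclusions = exclusions if exclusions is not None else ExclusionConfig()
    if not isinstance(meddra, MedDRAMap):
        meddra = faers_io.load_meddra_map(meddra)

    acct: dict = {"drug": drug}
    if isinstance(reports, (str, Path)):
        read = faers_io.read_reports(reports, dialect=opts.dialect)
        report_list, rejects = read.reports, read.rejects
        acct["rows_rejected"] = int(len(rejects))
    else:
        report_list = list(reports)
        acct["rows_rejected"] = 0
    acct["reports_read"] = len(report_list)

    deduped, dedup_acct = faers_io.deduplicate(report_list)
    acct["duplicates_removed"] = dedup_acct.removed
    acct["unique_reports"] = dedup_acct.output_reports

    validated = faers_io.validate_pts(deduped, meddra,
                                      drop_empty=(opts.comparator == "cleaned"))
    acct["pts_rejected_terms"] = len(validated.rejected_terms)
    acct["pts_rejected_occurrences"] = int(sum(n for _, n in validated.rejected_terms))
    acct["reports_dropped_no_valid_pt"] = validated.dropped_reports
    population = validated.reports
    acct["background_reports"] = len(population)

    drug_reports = faers_io.filter_primary_suspect(population, drug, opts.synonyms)
    acct["primary_suspect_reports"] = len(drug_reports)
    summary = describe_reports(drug_reports, region_map=region_map)

    tables = build_all_tables(population, drug, synonyms=opts.synonyms)
    acct["pairs_evaluated"] = len(tables)
    if tables:
        signals = statistics_frame(
            tables_to_frame(tables.values()),
            continuity_correction=opts.continuity_correction,
            bcpnn_additive_interval=opts.bcpnn_additive_interval,
            min_reports=opts.min_reports,
        )
        socs = [meddra.soc_of(pt) for pt in signals["pt"]]
        signals["soc"] = [s[0] for s in socs]
        signals["soc_code"] = [s[1] for s in socs]
    else:
        signals = statistics_frame(pd.DataFrame(columns=["drug", "pt", "a", "b", "c", "d"]))
        signals["soc"] = pd.Series(dtype=object)
        signals["soc_code"] = pd.Series(dtype=object)
        signals["n"] = pd.Series(dtype=int)

    signals, excl_acct = exclude_invalid(signals, exclusions)
    acct["signals"] = excl_acct

    signals = flag_novel(signals, label_pts if label_pts is not None else [])
    positives = positive_signals(signals)
    soc_summary = (aggregate_soc(signals) if not positives.empty
                   else pd.DataFrame(columns=["soc", "soc_code", "n", "pct"]))
    ranked = rank_signals(positives, by=opts.rank_by, top_k=opts.top_k,
                          strength_metric=opts.strength_metric)
    return PipelineResult(signals=signals, accounting=acct, summary=summary,
                          soc_summary=soc_summary, ranked=ranked)
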