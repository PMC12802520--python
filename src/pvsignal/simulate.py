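"""Seeded generator of FAERS-like spontaneous report sets with planted signals.

Real spontaneous-report extracts cannot be redistributed, so every stage of
the mining pipeline is exercised against synthetic report sets whose
disproportionality is known by construction.  The generator emulates the
seven data classes of a spontaneous report — demographics, drug information,
indication, adverse-reaction terms, outcomes, therapy (dose) data and report
provenance (country, receipt date) — including superseded duplicate case
versions and a dominant-indication, female-skewed population.

Signal planting works on the odds scale.  Each planted PT is included in a
report by an independent Bernoulli draw: with probability ``p`` (its
configured background probability) when the report's primary suspect is any
other drug, and with the probability whose odds are ``lambda × p/(1-p)``
when the primary suspect is the planted drug.  The population reporting
odds ratio of the planted pair therefore equals lambda exactly, which makes
parameter-recovery targets analytic.  All remaining PTs fill each report
through a zero-truncated Poisson count and categorical draws, so every
report carries at least one event term.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import io as faers_io
from .model import (
    NOT_SPECIFIED,
    OUTCOMES,
    SEX_LEVELS,
    ConfigurationError,
    DrugEntry,
    MedDRAMap,
    SafetyReport,
)

_PROB_TOL = 1e-9


def _check_probs(name: str, probs: dict[str, float]) -> None:
    if not probs:
        raise ConfigurationError(f"{name}: empty probability vector")
    if any(p < 0 for p in probs.values()):
        raise ConfigurationError(f"{name}: negative probability")
    total = math.fsum(probs.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {total!r}, not 1")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic report population.

    Defaults mirror a scaled-down breast-cancer pharmacovigilance population:
    a strongly female-skewed sex distribution with a substantial
    not-specified share, roughly 40% missing age, a dominant indication plus
    an unknown-indication level, a US-dominant country mix, outcome-class
    rates in the range seen for serious oncology reports, and a ~15%
    duplicate-version rate.  ``events_per_report`` is the mean of the
    zero-truncated PT count per report.
    """

    n_cases: int
    drug_vocabulary: dict[str, float]
    pt_vocabulary: dict[str, float]
    pt_soc: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_signals: list[tuple[str, str, float]] = field(default_factory=list)
    events_per_report: float = 3.0
    concomitant_mean: float = 0.8
    sex_distribution: dict[str, float] = field(default_factory=lambda: {
        "female": 0.779, "male": 0.034, "not_specified": 0.187})
    age_mean: float = 56.0
    age_sd: float = 13.0
    age_missing_prob: float = 0.43
    country_distribution: dict[str, float] = field(default_factory=lambda: {
        "US": 0.46, "JP": 0.09, "FR": 0.07, "DE": 0.07, "GB": 0.05, "BR": 0.04,
        "CN": 0.03, "AU": 0.02, "ZA": 0.01, "not_specified": 0.16})
    indication_distribution: dict[str, float] = field(default_factory=lambda: {
        "Breast cancer": 0.50, "Breast cancer metastatic": 0.14,
        "Gastric cancer": 0.05, "Colorectal cancer": 0.04, "Lung cancer": 0.04,
        "unknown_indication": 0.23})
    outcome_distribution: dict[str, float] = field(default_factory=lambda: {
        "death": 0.138, "disability": 0.014, "hospitalisation": 0.288,
        "life_threatening": 0.031, "required_intervention": 0.001,
        "other": 0.367, "none": 0.161})
    dose_levels: dict[float, float] = field(default_factory=lambda: {
        1000.0: 0.15, 1250.0: 0.70, 1500.0: 0.15})
    dose_missing_prob: float = 0.3
    duplicate_fraction: float = 0.0
    year_range: tuple[int, int] = (2007, 2024)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        _check_probs("drug_vocabulary", self.drug_vocabulary)
        _check_probs("pt_vocabulary", self.pt_vocabulary)
        _check_probs("sex_distribution", self.sex_distribution)
        _check_probs("country_distribution", self.country_distribution)
        _check_probs("indication_distribution", self.indication_distribution)
        _check_probs("outcome_distribution", self.outcome_distribution)
        _check_probs("dose_levels", self.dose_levels)
        bad_sex = set(self.sex_distribution) - set(SEX_LEVELS)
        if bad_sex:
            raise ConfigurationError(f"unknown sex level(s): {sorted(bad_sex)}")
        bad_out = set(self.outcome_distribution) - set(OUTCOMES) - {"none"}
        if bad_out:
            raise ConfigurationError(f"unknown outcome class(es): {sorted(bad_out)}")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ConfigurationError("duplicate_fraction must lie in [0, 1]")
        if self.events_per_report <= 1.0:
            raise ConfigurationError("events_per_report must exceed 1 (zero-truncated mean)")
        for drug, pt, lam in self.planted_signals:
            if lam < 0:
                raise ConfigurationError(f"planted lambda must be >= 0, got {lam!r}")
            if drug not in self.drug_vocabulary:
                raise ConfigurationError(f"planted drug not in vocabulary: {drug!r}")
            if pt not in self.pt_vocabulary:
                raise ConfigurationError(f"planted PT not in vocabulary: {pt!r}")
        planted_pts = {pt for _, pt, _ in self.planted_signals}
        if len(planted_pts) >= len(self.pt_vocabulary):
            raise ConfigurationError(
                "at least one non-planted PT is required as background vocabulary")

    def meddra_map(self) -> MedDRAMap:
        """MedDRA map covering the generator's PT vocabulary."""
        soc = dict(self.pt_soc)
        for i, pt in enumerate(self.pt_vocabulary):
            soc.setdefault(pt, (f"SOC {i % 5}", f"{90000 + i % 5}"))
        return MedDRAMap({pt: soc[pt] for pt in self.pt_vocabulary})

    def to_json(self) -> str:
        enc = dataclasses.asdict(self)
        enc["year_range"] = list(self.year_range)
        enc["planted_signals"] = [list(t) for t in self.planted_signals]
        enc["pt_soc"] = {pt: list(v) for pt, v in self.pt_soc.items()}
        enc["dose_levels"] = {repr(k): v for k, v in self.dose_levels.items()}
        return json.dumps(enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        raw["year_range"] = tuple(raw["year_range"])
        raw["planted_signals"] = [tuple(t) for t in raw["planted_signals"]]
        raw["pt_soc"] = {pt: tuple(v) for pt, v in raw.get("pt_soc", {}).items()}
        raw["dose_levels"] = {float(k): v for k, v in raw["dose_levels"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was planted, and the counts that were actually realised."""

    planted: dict[tuple[str, str], float]
    realized_tables: dict[tuple[str, str], tuple[int, int, int, int]]

    def to_json(self) -> str:
        return json.dumps({
            "planted": [
                {"drug": d, "pt": p, "lambda": lam}
                for (d, p), lam in self.planted.items()
            ],
            "realized_tables": [
                {"drug": d, "pt": p, "a": t[0], "b": t[1], "c": t[2], "d": t[3]}
                for (d, p), t in self.realized_tables.items()
            ],
        }, indent=2)


def _ztp_mu(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    return optimize.brentq(lambda m: m / (1.0 - math.exp(-m)) - mean,
                           1e-9, mean + 10.0)


def _sample_ztp(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws via inverse-CDF restricted to k >= 1."""
    p0 = math.exp(-mu)
    u = p0 + rng.random(size) * (1.0 - p0)
    return stats.poisson.ppf(u, mu).astype(int)


def _recount(reports: Sequence[SafetyReport], drug: str, pt: str
             ) -> tuple[int, int, int, int]:
    """Brute-force report-level 2×2 recount (kept independent of contingency)."""
    a = b = c = d = 0
    for r in reports:
        has_drug = any(e.name == drug and e.role == "primary_suspect" for e in r.drugs)
        has_pt = pt in r.pts
        if has_drug and has_pt:
            a += 1
        elif has_drug:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return (a, b, c, d)


def simulate_reports(config: SimulationConfig
                     ) -> tuple[list[SafetyReport], GroundTruth]:
    """Generate ``config.n_cases`` unique cases (before duplicate injection).

    Identical configs (including seed) produce identical report sets.
    Duplicates are injected afterwards with :func:`inject_duplicates` when
    ``config.duplicate_fraction`` > 0; ground truth always refers to the
    pre-duplicate set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    drugs = list(config.drug_vocabulary)
    drug_p = np.array([config.drug_vocabulary[d] for d in drugs])
    drug_p = drug_p / drug_p.sum()

    planted_pts = sorted({pt for _, pt, _ in config.planted_signals})
    planted_by_pt: dict[str, list[tuple[str, float]]] = {pt: [] for pt in planted_pts}
    for drug, pt, lam in config.planted_signals:
        planted_by_pt[pt].append((drug, lam))

    background_pts = [pt for pt in config.pt_vocabulary if pt not in planted_by_pt]
    bg_p = np.array([config.pt_vocabulary[pt] for pt in background_pts])
    bg_p = bg_p / bg_p.sum()

    # ---- vectorised draws ------------------------------------------------
    primary_idx = rng.choice(len(drugs), size=n, p=drug_p)
    mu = _ztp_mu(config.events_per_report)
    pt_counts = _sample_ztp(rng, mu, n)
    flat_pts = rng.choice(len(background_pts), size=int(pt_counts.sum()), p=bg_p)
    splits = np.cumsum(pt_counts)[:-1]
    per_report_pts = np.split(flat_pts, splits)

    planted_draws: dict[str, np.ndarray] = {}
    for pt in planted_pts:
        p_bg = config.pt_vocabulary[pt]
        prob = np.full(n, p_bg)
        for drug, lam in planted_by_pt[pt]:
            mask = primary_idx == drugs.index(drug)
            odds = lam * p_bg / (1.0 - p_bg)
            prob[mask] = min(odds / (1.0 + odds), 1.0 - 1e-12)
        planted_draws[pt] = rng.random(n) < prob

    n_concom = rng.poisson(config.concomitant_mean, size=n)

    sex_levels = list(config.sex_distribution)
    sex = rng.choice(len(sex_levels), size=n,
                     p=np.array([config.sex_distribution[s] for s in sex_levels]))
    age_missing = rng.random(n) < config.age_missing_prob
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 0.0, 105.0)
    ages = np.round(ages, 1)

    countries = list(config.country_distribution)
    country_idx = rng.choice(len(countries), size=n,
                             p=np.array([config.country_distribution[c] for c in countries]))
    indications = list(config.indication_distribution)
    ind_idx = rng.choice(len(indications), size=n,
                         p=np.array([config.indication_distribution[i] for i in indications]))
    outcome_levels = list(config.outcome_distribution)
    out_idx = rng.choice(len(outcome_levels), size=n,
                         p=np.array([config.outcome_distribution[o] for o in outcome_levels]))
    dose_levels = list(config.dose_levels)
    dose_idx = rng.choice(len(dose_levels), size=n,
                          p=np.array([config.dose_levels[d] for d in dose_levels]))
    dose_missing = rng.random(n) < config.dose_missing_prob

    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)

    width = max(7, len(str(n)))
    reports: list[SafetyReport] = []
    for i in range(n):
        primary = drugs[int(primary_idx[i])]
        entries = [DrugEntry(primary, "primary_suspect")]
        k = min(int(n_concom[i]), len(drugs) - 1)
        if k > 0:
            others = [d for d in drugs if d != primary]
            picks = rng.choice(len(others), size=k, replace=False)
            entries.extend(DrugEntry(others[int(j)], "concomitant") for j in sorted(picks))
        pts = sorted({background_pts[int(j)] for j in per_report_pts[i]}
                     | {pt for pt in planted_pts if planted_draws[pt][i]})
        outcome = outcome_levels[int(out_idx[i])]
        country = countries[int(country_idx[i])]
        indication = indications[int(ind_idx[i])]
        reports.append(SafetyReport(
            report_id=f"R{i:0{width}d}",
            case_id=f"C{i:0{width}d}",
            receipt_date=date(int(years[i]), int(months[i]), int(days[i])),
            drugs=tuple(entries),
            pts=tuple(pts),
            sex=sex_levels[int(sex[i])],
            age_years=None if age_missing[i] else float(ages[i]),
            country=None if country == NOT_SPECIFIED else country,
            indication=None if indication == "unknown_indication" else indication,
            outcomes=() if outcome == "none" else (outcome,),
            dose_mg_per_day=None if dose_missing[i] else float(dose_levels[int(dose_idx[i])]),
        ))

    truth = GroundTruth(
        planted={(d, p): lam for d, p, lam in config.planted_signals},
        realized_tables={
            (d, p): _recount(reports, d, p) for d, p, _ in config.planted_signals
        },
    )
    if config.duplicate_fraction > 0:
        reports = inject_duplicates(reports, config.duplicate_fraction,
                                    seed=(config.seed + 1) % (2**31))
    return reports, truth


def inject_duplicates(reports: Sequence[SafetyReport], duplicate_fraction: float,
                      seed: int) -> list[SafetyReport]:
    """Emit an extra superseded version for a sampled subset of cases.

    The duplicate shares the case id but carries a distinct report id and an
    earlier receipt date, so deduplication provably recovers the original
    set.  ``duplicate_fraction`` is the per-case probability of emitting one
    extra version.
    """
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ConfigurationError("duplicate_fraction must lie in [0, 1]")
    reports = list(reports)
    if duplicate_fraction == 0.0:
        return reports
    rng = np.random.default_rng(seed)
    picks = rng.random(len(reports)) < duplicate_fraction
    lags = rng.integers(30, 400, size=len(reports))
    duplicates = []
    for r, pick, lag in zip(reports, picks, lags):
        if not pick:
            continue
        duplicates.append(dataclasses.replace(
            r,
            report_id=r.report_id + ".0",
            receipt_date=r.receipt_date - timedelta(days=int(lag)),
        ))
    return reports + duplicates


def write_fixture(reports: Sequence[SafetyReport], path: str | Path,
                  dialect: str = "wide",
                  ground_truth: GroundTruth | None = None) -> None:
    """Write a report set in the interchange dialect (plus ground-truth JSON)."""
    faers_io.write_reports(reports, path, dialect=dialect)
    if ground_truth is not None:
        Path(path).with_suffix(".truth.json").write_text(ground_truth.to_json())


# ---------------------------------------------------------------------------
# canonical study-shaped configurations

def default_config(n_cases: int = 5000, seed: int = 0,
                   planted: Sequence[tuple[str, str, float]] = (),
                   duplicate_fraction: float = 0.0) -> SimulationConfig:
    """A 20-drug × 50-PT population with realistic marginals.

    The drug of interest ``DRUG_00`` holds a 20% share of primary-suspect
    reports; PT background probabilities span 0.002–0.1 on a geometric
    gradient so both common and rare terms occur.
    """
    n_drugs, n_pts = 20, 50
    drug_w = np.array([4.0] + [1.0] * (n_drugs - 1))
    drug_vocab = {f"DRUG_{i:02d}": w for i, w in enumerate(drug_w / drug_w.sum())}
    pt_w = np.geomspace(0.1, 0.002, n_pts)
    pt_vocab = {f"PT_{j:02d}": float(w) for j, w in enumerate(pt_w / pt_w.sum())}
    socs = [("Gastrointestinal disorders", "10017947"),
            ("Skin and subcutaneous tissue disorders", "10040785"),
            ("General disorders and administration site conditions", "10018065"),
            ("Metabolism and nutrition disorders", "10027433"),
            ("Investigations", "10022891")]
    pt_soc = {f"PT_{j:02d}": socs[j % len(socs)] for j in range(n_pts)}
    return SimulationConfig(
        n_cases=n_cases,
        drug_vocabulary=drug_vocab,
        pt_vocabulary=pt_vocab,
        pt_soc=pt_soc,
        planted_signals=list(planted),
        duplicate_fraction=duplicate_fraction,
        seed=seed,
    )


def planted_pair_config(n_cases: int = 5000, seed: int = 0, lam: float = 10.0,
                        background_p: float = 0.01) -> SimulationConfig:
    """One planted (DRUG_00, PT_SIGNAL) pair of known odds multiplier.

    With the default 20% drug share and ``background_p``=0.01, lambda=10
    yields an expected ``a`` cell near 90 at ``n_cases``=5000.
    """
    cfg = default_config(n_cases=n_cases, seed=seed)
    rest = 1.0 - background_p
    cfg.pt_vocabulary = {pt: w * rest for pt, w in cfg.pt_vocabulary.items()}
    cfg.pt_vocabulary["PT_SIGNAL"] = background_p
    cfg.pt_soc["PT_SIGNAL"] = ("Skin and subcutaneous tissue disorders", "10040785")
    cfg.planted_signals = [("DRUG_00", "PT_SIGNAL", lam)]
    return cfg


# ---------------------------------------------------------------------------
# calibration experiments (generator invariants)

@dataclass(frozen=True)
class RecoveryResult:
    detected: int
    ci_covers_lambda: int
    n_replicates: int
    mean_realized_ror: float


def planted_recovery(n_replicates: int = 100, seed: int = 0, lam: float = 10.0,
                     n_cases: int = 5000, background_p: float = 0.01) -> RecoveryResult:
    """Replicate detection and CI coverage for one planted pair.

    For each replicate the realised 2×2 table of the planted pair is scored
    with all four detectors; ``detected`` counts combined-positive
    replicates, ``ci_covers_lambda`` counts replicates whose realised 95% ROR
    interval contains lambda.
    """
    from ._util import derive_seed
    from .contingency import ContingencyTable
    from .disproportionality import compute_statistics, evaluate_significance

    detected = covered = 0
    rors = []
    for k in range(n_replicates):
        cfg = planted_pair_config(n_cases=n_cases, seed=derive_seed(seed, k),
                                  lam=lam, background_p=background_p)
        _, truth = simulate_reports(cfg)
        a, b, c, d = truth.realized_tables[("DRUG_00", "PT_SIGNAL")]
        table = ContingencyTable(a, b, c, d, "DRUG_00", "PT_SIGNAL")
        s = compute_statistics(table)
        if evaluate_significance(s).combined:
            detected += 1
        if s.defined["ror"]:
            rors.append(s.ror)
            if s.ror_low <= lam <= s.ror_high:
                covered += 1
    return RecoveryResult(detected, covered, n_replicates,
                          float(np.mean(rors)) if rors else float("nan"))


def null_false_positive_rates(n_replicates: int = 100, seed: int = 0,
                              n_cases: int = 2000,
                              min_reports: int = 3) -> dict[str, float]:
    """Per-detector flag fraction on all-null drug×PT grids.

    Simulates replicates of the default 20-drug × 50-PT population with no
    planted signal, screens every (primary-suspect drug, PT) pair with
    ``a >= min_reports``, and returns the fraction each detector flags —
    its empirical false-positive behaviour under the null.

    The BCPNN rate is reported twice.  ``bcpnn`` uses the conventional
    additive IC interval, whose lower bound carries the sampling
    uncertainty and is the meaningful calibration gate.  ``bcpnn_printed``
    uses the package's default multiplicative bound, which is positive
    whenever IC is, so that gate degenerates to the sign of IC and flags
    roughly half of all null pairs by construction (see docs/methods.md).
    """
    from ._util import derive_seed
    from .contingency import pair_counts
    from .disproportionality import statistics_frame

    flags = {m: 0 for m in ("ror", "prr", "bcpnn", "bcpnn_printed", "mgps", "combined")}
    eligible = 0
    for k in range(n_replicates):
        cfg = default_config(n_cases=n_cases, seed=derive_seed(seed, 10_000 + k))
        reports, _ = simulate_reports(cfg)
        counts = pair_counts(reports)
        counts = counts[counts["a"] >= min_reports]
        if counts.empty:
            continue
        printed = statistics_frame(counts, min_reports=min_reports)
        additive = statistics_frame(counts, min_reports=min_reports,
                                    bcpnn_additive_interval=True)
        eligible += len(printed)
        for m in ("ror", "prr", "mgps", "combined"):
            flags[m] += int(printed[f"sig_{m}"].sum())
        flags["bcpnn"] += int(additive["sig_bcpnn"].sum())
        flags["bcpnn_printed"] += int(printed["sig_bcpnn"].sum())
    if eligible == 0:
        return {m: float("nan") for m in flags}
    return {m: flags[m] / eligible for m in flags}
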