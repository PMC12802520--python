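"""Shared fixtures: handcrafted report sets and the heavy calibration runs.

The two simulation studies (planted-signal recovery and the all-null grid)
are session-scoped so each runs once and serves both the generator
invariants and the end-to-end calibration checks.
"""

from __future__ import annotations

from datetime import date

import pytest

from pvsignal.model import DrugEntry, MedDRAMap, SafetyReport
from pvsignal.simulate import null_false_positive_rates, planted_recovery


def make_report(report_id, case_id="", drugs=(("X", "primary_suspect"),),
                pts=("Diarrhoea",), receipt="2020-01-01", **kw) -> SafetyReport:
    return SafetyReport(
        report_id=report_id,
        case_id=case_id or report_id.replace("R", "C"),
        receipt_date=date.fromisoformat(receipt),
        drugs=tuple(DrugEntry(n, r) for n, r in drugs),
        pts=tuple(pts),
        **kw,
    )


@pytest.fixture
def toy_reports() -> list[SafetyReport]:
    """Four single-drug reports giving (X, Diarrhoea) table (1, 1, 1, 1)."""
    return [
        make_report("R1", drugs=(("X", "primary_suspect"),), pts=("Diarrhoea",)),
        make_report("R2", drugs=(("X", "primary_suspect"),), pts=("Nausea",)),
        make_report("R3", drugs=(("Y", "primary_suspect"),), pts=("Diarrhoea",)),
        make_report("R4", drugs=(("Y", "primary_suspect"),), pts=("Rash",)),
    ]


@pytest.fixture
def meddra() -> MedDRAMap:
    return MedDRAMap({
        "Diarrhoea": ("Gastrointestinal disorders", "10017947"),
        "Nausea": ("Gastrointestinal disorders", "10017947"),
        "Rash": ("Skin and subcutaneous tissue disorders", "10040785"),
        "Paronychia": ("Skin and subcutaneous tissue disorders", "10040785"),
        "Fatigue": ("General disorders and administration site conditions", "10018065"),
    })


@pytest.fixture(scope="session")
def recovery_result():
    """100 replicates of the planted lambda=10 pair (expected a ≈ 90)."""
    return planted_recovery(n_replicates=100, seed=42, lam=10.0,
                            n_cases=5000, background_p=0.01)


@pytest.fixture(scope="session")
def null_rates():
    """100 all-null 20-drug × 50-PT grids, per-detector flag fractions."""
    return null_false_positive_rates(n_replicates=100, seed=42, n_cases=2000)
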