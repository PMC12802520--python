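"""Core record types shared across the package.

The unit of analysis throughout is the *safety report*: one spontaneous
adverse-event report linking one or more drugs (each with a reporter-assigned
role code) to one or more MedDRA preferred terms (PTs), plus demographics,
outcome classes and a receipt date.  Spontaneous-reporting databases version
reports under a stable case identifier; :func:`pvsignal.io.deduplicate`
collapses each case to its latest version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import NamedTuple

#: Closed set of reporter-assigned drug role codes.
ROLES = ("primary_suspect", "secondary_suspect", "concomitant", "interacting")

#: The six regulatory outcome classes of a spontaneous report.
OUTCOMES = (
    "death",
    "disability",
    "hospitalisation",
    "life_threatening",
    "required_intervention",
    "other",
)

SEX_LEVELS = ("female", "male", "not_specified")

#: Sentinel level used whenever an optional categorical field is absent.
NOT_SPECIFIED = "not_specified"


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (probabilities, vocabularies, weights)."""


class FormatError(ValueError):
    """Malformed input file (missing columns, conflicting map rows)."""


class DrugEntry(NamedTuple):
    name: str
    role: str


@dataclass(frozen=True)
class SafetyReport:
    """One adverse-event report (one version of one case).

    ``age_years``, ``country``, ``indication`` and ``dose_mg_per_day`` are
    ``None`` when the reporter did not supply them; descriptive summaries map
    these to explicit not-specified levels so that denominators always equal
    the full report count.
    """

    report_id: str
    case_id: str
    receipt_date: date
    drugs: tuple[DrugEntry, ...]
    pts: tuple[str, ...]
    sex: str = NOT_SPECIFIED
    age_years: float | None = None
    country: str | None = None
    indication: str | None = None
    outcomes: tuple[str, ...] = ()
    dose_mg_per_day: float | None = None

    @property
    def year(self) -> int:
        return self.receipt_date.year

    def has_drug(self, name: str, roles: tuple[str, ...] | None = None,
                 synonyms: tuple[str, ...] = ()) -> bool:
        """Case-insensitive drug-name test, optionally restricted to roles."""
        names = {name.casefold()} | {s.casefold() for s in synonyms}
        for entry in self.drugs:
            if entry.name.casefold() in names and (roles is None or entry.role in roles):
                return True
        return False

    def is_primary_suspect(self, name: str, synonyms: tuple[str, ...] = ()) -> bool:
        return self.has_drug(name, roles=("primary_suspect",), synonyms=synonyms)

    def has_pt(self, pt: str) -> bool:
        key = pt.casefold()
        return any(p.casefold() == key for p in self.pts)

    def with_pts(self, pts: tuple[str, ...]) -> "SafetyReport":
        return replace(self, pts=pts)


@dataclass(frozen=True)
class MedDRAMap:
    """PT → (SOC name, SOC code) dictionary supplied by the user.

    MedDRA content is licensed and never shipped; callers load their own
    extract with :func:`pvsignal.io.load_meddra_map`.  Matching is
    case-insensitive because PT capitalisation varies across FAERS exports.
    """

    pt_to_soc: dict[str, tuple[str, str]]
    pt_codes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_norm", {pt.casefold(): (pt, soc) for pt, soc in self.pt_to_soc.items()}
        )

    def __contains__(self, pt: str) -> bool:
        return pt.casefold() in self._norm

    def __len__(self) -> int:
        return len(self.pt_to_soc)

    def soc_of(self, pt: str) -> tuple[str, str]:
        """Return (SOC name, SOC code) for a PT; KeyError names the term."""
        try:
            return self._norm[pt.casefold()][1]
        except KeyError:
            raise KeyError(f"PT not present in MedDRA map: {pt!r}") from None
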