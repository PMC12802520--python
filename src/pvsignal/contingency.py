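"""2×2 contingency tables for drug–event pairs.

The counting unit is the deduplicated report.  For a drug D and preferred
term E over a report set of size N:

======================  ==============  =================
(reports)                E reported      other events only
======================  ==============  =================
D primary suspect        a               b
all other drugs          c               d
======================  ==============  =================

A report "has the drug" iff the drug appears with the primary-suspect role
(any additional role of the same drug in the same report is ignored); it
"has the event" iff the PT appears in its validated PT list, multiplicity
ignored.  Every report falls in exactly one cell, so a+b+c+d = N identically
for every pair built from the same set — a conservation law the tests pin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import SafetyReport


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    pt: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_table(reports: Sequence[SafetyReport], drug: str, pt: str,
                synonyms: Sequence[str] = ()) -> ContingencyTable:
    """Count the 2×2 cells for one (drug, pt) pair.

    An absent drug or PT gives zero rows/columns, not an error.
    """
    syn = tuple(synonyms)
    a = b = c = d = 0
    for r in reports:
        has_drug = r.is_primary_suspect(drug, syn)
        has_pt = r.has_pt(pt)
        if has_drug and has_pt:
            a += 1
        elif has_drug:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, drug=drug, pt=pt)


def build_all_tables(reports: Sequence[SafetyReport], drug: str,
                     synonyms: Sequence[str] = ()) -> dict[str, ContingencyTable]:
    """One table per distinct PT occurring in the drug's primary-suspect reports.

    Equivalent to calling :func:`build_table` per PT but in a single pass:
    per-PT totals over the whole set give a+c, and per-PT totals within the
    drug subset give a.
    """
    syn = tuple(synonyms)
    total = len(reports)
    n_drug = 0
    pt_total: dict[str, int] = {}    # normalised pt -> reports containing it
    pt_drug: dict[str, int] = {}     # normalised pt -> drug reports containing it
    display: dict[str, str] = {}     # normalised pt -> first-seen spelling
    for r in reports:
        has_drug = r.is_primary_suspect(drug, syn)
        if has_drug:
            n_drug += 1
        seen = set()
        for pt in r.pts:
            key = pt.casefold()
            if key in seen:
                continue
            seen.add(key)
            display.setdefault(key, pt)
            pt_total[key] = pt_total.get(key, 0) + 1
            if has_drug:
                pt_drug[key] = pt_drug.get(key, 0) + 1
    out: dict[str, ContingencyTable] = {}
    for key in sorted(pt_drug):
        a = pt_drug[key]
        b = n_drug - a
        c = pt_total[key] - a
        d = total - a - b - c
        out[display[key]] = ContingencyTable(a, b, c, d, drug=drug, pt=display[key])
    return out


def pair_counts(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Vectorised a/b/c/d counts for every (primary-suspect drug, PT) pair.

    Builds a report×PT boolean incidence matrix and a report×drug
    primary-suspect indicator, then obtains all ``a`` cells with one matrix
    product.  Used for calibration grids where every pair in a vocabulary is
    screened at once.
    """
    n = len(reports)
    pts = sorted({pt.casefold() for r in reports for pt in r.pts})
    drugs = sorted({d.name.casefold() for r in reports for d in r.drugs
                    if d.role == "primary_suspect"})
    pt_idx = {p: j for j, p in enumerate(pts)}
    drug_idx = {g: j for j, g in enumerate(drugs)}
    P = np.zeros((n, len(pts)), dtype=np.int64)
    D = np.zeros((n, len(drugs)), dtype=np.int64)
    for i, r in enumerate(reports):
        for pt in r.pts:
            P[i, pt_idx[pt.casefold()]] = 1
        for entry in r.drugs:
            if entry.role == "primary_suspect":
                D[i, drug_idx[entry.name.casefold()]] = 1
    a = D.T @ P                              # n_drugs × n_pts
    n_drug = D.sum(axis=0)[:, None]
    n_pt = P.sum(axis=0)[None, :]
    b = n_drug - a
    c = n_pt - a
    d = n - a - b - c
    dg, pt = np.meshgrid(np.arange(len(drugs)), np.arange(len(pts)), indexing="ij")
    return pd.DataFrame({
        "drug": [drugs[i] for i in dg.ravel()],
        "pt": [pts[j] for j in pt.ravel()],
        "a": a.ravel(),
        "b": b.ravel(),
        "c": c.ravel(),
        "d": d.ravel(),
    })


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    rows = [{"drug": t.drug, "pt": t.pt, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for t in tables]
    return pd.DataFrame(rows, columns=["drug", "pt", "a", "b", "c", "d"])


def write_tables(tables: Iterable[ContingencyTable], path: str | Path) -> None:
    tables_to_frame(tables).to_csv(path, sep="\t", index=False)
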