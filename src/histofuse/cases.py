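"""Case-manifest bookkeeping for the glioblastoma cohort.

A case manifest is a CSV of clinical records, one row per biopsy.  A row can
be flagged as a subsequent biopsy of another case (``duplicate_of``), in
which case the two rows count as a single case; ``included`` flags the cases
whose adjacent sections for all three markers were judged suitable for
heatmap analysis.  A transcription of the published 34-row cohort manifest
(33 unique cases, 15 included) ships with the package as
``data/table1_cases.csv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    sex: str
    age_at_diagnosis: float
    survival_months: float | None
    localization: str
    included: bool
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ManifestError(f"sex must be F or M, got {self.sex!r}")


def read_case_manifest(path: str | Path) -> list[CaseRecord]:
    records: list[CaseRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            survival = row.get("survival_months", "").strip()
            records.append(CaseRecord(
                case_id=row["case_id"].strip(),
                sex=row["sex"].strip(),
                age_at_diagnosis=float(row["age_at_diagnosis"]),
                survival_months=float(survival) if survival else None,
                localization=row["localization"].strip(),
                included=row["included"].strip().lower() in ("true", "1", "yes"),
                duplicate_of=row["duplicate_of"].strip() or None,
            ))
    return records


def bundled_cohort_manifest() -> list[CaseRecord]:
    """The packaged 34-row cohort manifest."""
    ref = resources.files("histofuse").joinpath("data/table1_cases.csv")
    with resources.as_file(ref) as path:
        return read_case_manifest(path)


def count_cases(manifest: list[CaseRecord]) -> tuple[int, int]:
    """(n_unique_cases, n_included).

    Unique cases collapse ``duplicate_of`` chains to their root; the
    included count is the number of rows explicitly flagged as fulfilling
    all inclusion criteria.  Cyclic or dangling duplicate references raise a
    ManifestError.
    """
    by_id = {r.case_id: r for r in manifest}
    if len(by_id) != len(manifest):
        raise ManifestError("duplicate case_id rows in manifest")

    def root(case_id: str) -> str:
        seen = set()
        current = case_id
        while True:
            rec = by_id.get(current)
            if rec is None:
                raise ManifestError(f"duplicate_of references unknown case {current!r}")
            if rec.duplicate_of is None:
                return current
            if current in seen:
                raise ManifestError(f"cyclic duplicate_of chain at case {current!r}")
            seen.add(current)
            current = rec.duplicate_of

    roots = {root(r.case_id) for r in manifest}
    n_included = sum(1 for r in manifest if r.included)
    return len(roots), n_included
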