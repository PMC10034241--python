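"""Cohort construction by ICD-10 code policy and age-bin summarization.

The analysis cohort consists of patients carrying a liver-cancer inclusion
code (by default C22.0 "liver cell carcinoma" or C22.7 "other specified
carcinoma of the liver") and none of a configurable list of exclusion codes
for chronic liver inflammation.  Validated fibrolamellar (FLC) diagnoses are
tallied per 10-year age bin below a configurable cap; these per-bin counts
drive the beta-binomial incidence model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

DEFAULT_INCLUDE_CODES = frozenset({"C22.0", "C22.7"})

LABELS = ("FLC", "HCC", "OTHER", "UNKNOWN")


@dataclass(frozen=True)
class AgeBin:
    """Half-open age interval [lower, upper) in years."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"age bin requires lower < upper, got [{self.lower}, {self.upper})")

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"


def decade_bins(age_cap: int = 50) -> list[AgeBin]:
    """Default 10-year bins partitioning [0, age_cap)."""
    if age_cap <= 0 or age_cap % 10 != 0:
        raise ValueError("age_cap must be a positive multiple of 10")
    return [AgeBin(lo, lo + 10) for lo in range(0, age_cap, 10)]


def validate_partition(bins: Sequence[AgeBin], age_cap: int) -> list[AgeBin]:
    """Check that bins partition [0, age_cap) without gaps or overlap."""
    ordered = sorted(bins, key=lambda b: b.lower)
    edge = 0
    for b in ordered:
        if b.lower != edge:
            raise ValueError(f"bins do not partition [0, {age_cap}): gap/overlap at {b.lower}")
        edge = b.upper
    if edge != age_cap:
        raise ValueError(f"bins end at {edge}, expected {age_cap}")
    return ordered


@dataclass(frozen=True)
class PatientRecord:
    """One EMR patient: age at diagnosis, ICD-10-CM codes, validated label, zip3."""

    patient_id: str
    age_at_diagnosis: int
    codes: frozenset[str]
    label: str = "UNKNOWN"
    zip3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_at_diagnosis < 0:
            raise ValueError("age_at_diagnosis must be >= 0")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def normalize_code(code: str) -> str:
    return code.strip().upper()


@dataclass(frozen=True)
class CodePolicy:
    """Inclusion/exclusion ICD code policy.

    Matching is exact on normalized (uppercased, dot-preserved) codes.  With
    ``prefix_match`` an exclusion code like ``B18`` also removes carriers of
    ``B18.2``; the default is exact matching because the study enumerates
    explicit codes.
    """

    include_codes: frozenset[str] = DEFAULT_INCLUDE_CODES
    exclude_codes: frozenset[str] = frozenset()
    prefix_match: bool = False

    def __post_init__(self) -> None:
        if not self.include_codes:
            raise ValueError("include_codes must be non-empty")
        inc = frozenset(normalize_code(c) for c in self.include_codes)
        exc = frozenset(normalize_code(c) for c in self.exclude_codes)
        if inc & exc:
            raise ValueError(f"include/exclude overlap: {sorted(inc & exc)}")
        object.__setattr__(self, "include_codes", inc)
        object.__setattr__(self, "exclude_codes", exc)

    def _matches_exclusion(self, codes: frozenset[str]) -> bool:
        if self.prefix_match:
            return any(c.startswith(e) for c in codes for e in self.exclude_codes)
        return bool(codes & self.exclude_codes)

    def admits(self, patient: PatientRecord) -> bool:
        codes = frozenset(normalize_code(c) for c in patient.codes)
        return bool(codes & self.include_codes) and not self._matches_exclusion(codes)


def apply_code_policy(
    patients: Sequence[PatientRecord], policy: CodePolicy
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Filter patients by the code policy, preserving input order.

    Returns the retained patients and an audit dict with counts of inputs,
    patients lacking any inclusion code, patients removed by exclusion codes,
    and patients retained.  Idempotent: re-applying to the output is a no-op.
    """
    retained: list[PatientRecord] = []
    n_no_include = 0
    n_excluded = 0
    for p in patients:
        codes = frozenset(normalize_code(c) for c in p.codes)
        if not codes & policy.include_codes:
            n_no_include += 1
        elif policy._matches_exclusion(codes):
            n_excluded += 1
        else:
            retained.append(p)
    audit = {
        "n_input": len(patients),
        "n_no_include": n_no_include,
        "n_excluded": n_excluded,
        "n_retained": len(retained),
    }
    return retained, audit


@dataclass(frozen=True)
class AgeBinCounts:
    """FLC and total patient tallies for one age bin.

    ``n_total`` may be real-valued after missing-zip renormalization; raw
    tallies are integers.
    """

    bin: AgeBin
    n_flc: float
    n_total: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_flc <= self.n_total):
            raise ValueError(
                f"require 0 <= n_flc <= n_total, got ({self.n_flc}, {self.n_total})"
            )


def bin_counts(
    patients: Iterable[PatientRecord],
    bins: Sequence[AgeBin] | None = None,
    age_cap: int = 50,
) -> list[AgeBinCounts]:
    """Tally FLC / total patients per age bin, ignoring ages >= age_cap.

    Bins are half-open, so age exactly equal to the cap is excluded.  Patients
    with UNKNOWN or OTHER labels count toward ``n_total`` but never ``n_flc``:
    chart validation is the only source of FLC truth.
    """
    if bins is None:
        bins = decade_bins(age_cap)
    ordered = validate_partition(bins, age_cap)
    flc = {b: 0 for b in ordered}
    total = {b: 0 for b in ordered}
    for p in patients:
        if p.age_at_diagnosis >= age_cap:
            continue
        for b in ordered:
            if b.contains(p.age_at_diagnosis):
                total[b] += 1
                if p.label == "FLC":
                    flc[b] += 1
                break
    return [AgeBinCounts(bin=b, n_flc=flc[b], n_total=total[b]) for b in ordered]


def code_cooccurrence_rate(
    patients: Sequence[PatientRecord], code_set: Iterable[str]
) -> tuple[int, float]:
    """Count and fraction of patients carrying >= 1 code from ``code_set``.

    Used e.g. to measure how often a hyperammonemia diagnosis code co-occurs
    with liver-cancer coding in the policy-filtered cohort.
    """
    wanted = frozenset(normalize_code(c) for c in code_set)
    n = sum(1 for p in patients if frozenset(normalize_code(c) for c in p.codes) & wanted)
    frac = n / len(patients) if patients else 0.0
    return n, frac


def read_code_list(path) -> frozenset[str]:
    """Read a one-code-per-line plain-text code list (blank lines, # comments skipped)."""
    codes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                codes.append(normalize_code(line))
    return frozenset(codes)
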