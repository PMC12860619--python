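"""Genotype-stratified trial contingency tables.

A :class:`StratifiedTrialTable` holds the eight counts of a 2 (genotype
stratum: APOE ε4-homozygote vs not) × 2 (trial arm: active vs placebo) ×
2 (event vs no event) contingency table for one adverse-event outcome in
one trial.  The package ships the published phase-3 tables for lecanemab
(Clarity-AD) and donanemab (TRAILBLAZER-ALZ 2) as built-in fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "StratifiedTrialTable",
    "builtin_tables",
    "get_builtin",
    "load_table",
    "write_table",
]

_GENOTYPES = ("e4e4", "non-e4e4")
_ARMS = ("active", "placebo")


@dataclass(frozen=True)
class StratifiedTrialTable:
    """Eight event/non-event counts, stratified by genotype and arm.

    Cell naming follows the conventional 2×2 layout within each stratum:
    A = events on active, B = non-events on active, C = events on placebo,
    D = non-events on placebo; suffix ``_h`` is the ε4/ε4 stratum, ``_n``
    everyone else.
    """

    drug_label: str
    outcome_label: str
    A_h: int
    B_h: int
    C_h: int
    D_h: int
    A_n: int
    B_n: int
    C_n: int
    D_n: int

    def __post_init__(self) -> None:
        for name in ("A_h", "B_h", "C_h", "D_h", "A_n", "B_n", "C_n", "D_n"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int,)):
                # numpy integers pass through via int() below
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise ValueError(f"count {name} must be an integer, got {v!r}")
                if iv != v:
                    raise ValueError(f"count {name} must be an integer, got {v!r}")
                object.__setattr__(self, name, iv)
                v = iv
            if v < 0:
                raise ValueError(f"count {name} must be non-negative, got {v}")
        for label, total in {
            "e4e4/active": self.A_h + self.B_h,
            "e4e4/placebo": self.C_h + self.D_h,
            "non-e4e4/active": self.A_n + self.B_n,
            "non-e4e4/placebo": self.C_n + self.D_n,
        }.items():
            if total <= 0:
                raise ValueError(f"arm {label} is empty (zero total)")

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def n_homozygote(self) -> int:
        """Randomized ε4/ε4 patients across both arms."""
        return self.A_h + self.B_h + self.C_h + self.D_h

    @property
    def n_non_homozygote(self) -> int:
        return self.A_n + self.B_n + self.C_n + self.D_n

    @property
    def n_total(self) -> int:
        return self.n_homozygote + self.n_non_homozygote

    def pi_hat(self, override: float | None = None) -> float:
        """ε4/ε4 prevalence π among all randomized patients.

        π = (A_h + B_h + C_h + D_h) / N_total.  ``override`` substitutes a
        site-specific prevalence (e.g. from a local registry) for the
        trial-derived one; it must lie in (0, 1).
        """
        if override is not None:
            if not 0.0 < override < 1.0:
                raise ValueError(f"prevalence override must be in (0,1), got {override}")
            return float(override)
        return self.n_homozygote / self.n_total

    def counts(self) -> tuple[int, int, int, int, int, int, int, int]:
        return (self.A_h, self.B_h, self.C_h, self.D_h,
                self.A_n, self.B_n, self.C_n, self.D_n)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per stratum × arm."""
        rows = [
            ("e4e4", "active", self.A_h, self.B_h),
            ("e4e4", "placebo", self.C_h, self.D_h),
            ("non-e4e4", "active", self.A_n, self.B_n),
            ("non-e4e4", "placebo", self.C_n, self.D_n),
        ]
        return pd.DataFrame(rows, columns=["genotype", "arm", "events", "non_events"])


# ----------------------------------------------------------------------
# built-in fixtures: published phase-3 counts
# ----------------------------------------------------------------------
# (A_h, B_h, C_h, D_h, A_n, B_n, C_n, D_n) per drug × outcome.
_BUILTIN_COUNTS: dict[tuple[str, str], tuple[int, ...]] = {
    ("lecanemab", "any-ARIA-E"): (46, 95, 5, 128, 67, 690, 10, 754),
    ("lecanemab", "any-ARIA-H"): (55, 86, 28, 105, 100, 657, 53, 711),
    ("lecanemab", "symptomatic-ARIA-E"): (13, 128, 0, 133, 12, 745, 0, 764),
    ("donanemab", "any-ARIA-E"): (58, 85, 5, 141, 143, 564, 11, 713),
    ("donanemab", "any-ARIA-H"): (72, 71, 30, 116, 194, 513, 85, 639),
}


def builtin_tables() -> list[StratifiedTrialTable]:
    """All five published tables.

    Three outcomes for lecanemab (any ARIA-E, any ARIA-H, symptomatic
    ARIA-E) and two for donanemab (genotype-stratified symptomatic counts
    were not published for TRAILBLAZER-ALZ 2).
    """
    return [
        StratifiedTrialTable(drug, outcome, *counts)
        for (drug, outcome), counts in _BUILTIN_COUNTS.items()
    ]


def get_builtin(drug: str, outcome: str) -> StratifiedTrialTable:
    """Look up one built-in table by (drug, outcome) pair."""
    key = (drug, outcome)
    if key not in _BUILTIN_COUNTS:
        avail = ", ".join(f"{d}/{o}" for d, o in _BUILTIN_COUNTS)
        raise KeyError(f"no built-in table {drug}/{outcome}; available: {avail}")
    return StratifiedTrialTable(drug, outcome, *_BUILTIN_COUNTS[key])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
_CELL_NAMES = {
    ("e4e4", "active"): ("A_h", "B_h"),
    ("e4e4", "placebo"): ("C_h", "D_h"),
    ("non-e4e4", "active"): ("A_n", "B_n"),
    ("non-e4e4", "placebo"): ("C_n", "D_n"),
}


def _table_from_records(records: Iterable[dict], drug: str, outcome: str) -> StratifiedTrialTable:
    cells: dict[str, int] = {}
    for rec in records:
        try:
            genotype = str(rec["genotype"]).strip()
            arm = str(rec["arm"]).strip()
            events = rec["events"]
            non_events = rec["non_events"]
        except KeyError as e:
            raise ValueError(f"record missing field {e.args[0]!r}: {rec}") from None
        key = (genotype, arm)
        if key not in _CELL_NAMES:
            raise ValueError(
                f"unknown stratum/arm {genotype!r}/{arm!r}; expected genotype in "
                f"{_GENOTYPES} and arm in {_ARMS}"
            )
        ev_name, ne_name = _CELL_NAMES[key]
        for name, value in ((ev_name, events), (ne_name, non_events)):
            if name in cells:
                raise ValueError(f"duplicate record for cell {name} ({genotype}/{arm})")
            fv = float(value)
            if fv != int(fv):
                raise ValueError(f"cell {name} ({genotype}/{arm}) is not an integer: {value!r}")
            cells[name] = int(fv)
    missing = [n for names in _CELL_NAMES.values() for n in names if n not in cells]
    if missing:
        raise ValueError(f"missing cells: {', '.join(missing)}")
    return StratifiedTrialTable(drug, outcome, **cells)


def load_table(path: str | Path, format: str | None = None) -> StratifiedTrialTable:
    """Read a stratified table from a delimited or structured-config file.

    Delimited files carry ``# drug:`` / ``# outcome:`` metadata comment
    lines above a ``genotype,arm,events,non_events`` header (comma or tab
    separated).  Structured config is YAML (JSON is valid YAML) with keys
    ``drug``, ``outcome`` and a ``records`` list of the same four fields.
    ``format`` is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "structured-config" if path.suffix.lower() in {".yaml", ".yml", ".json"} else "delimited"

    if format == "structured-config":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "records" not in doc:
            raise ValueError(f"{path}: expected a mapping with a 'records' list")
        return _table_from_records(
            doc["records"], str(doc.get("drug", "")), str(doc.get("outcome", ""))
        )

    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    drug = outcome = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                if k.strip().lower() == "drug":
                    drug = v.strip()
                elif k.strip().lower() == "outcome":
                    outcome = v.strip()
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, comment="#", sep=sep)
    required = {"genotype", "arm", "events", "non_events"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return _table_from_records(df.to_dict("records"), drug, outcome)


def write_table(table: StratifiedTrialTable, path: str | Path) -> None:
    """Write a table in the delimited (or YAML, by extension) format read
    back by :func:`load_table`."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        doc = {
            "drug": table.drug_label,
            "outcome": table.outcome_label,
            "records": table.to_frame().to_dict("records"),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        return
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w") as fh:
        fh.write(f"# drug: {table.drug_label}\n")
        fh.write(f"# outcome: {table.outcome_label}\n")
        table.to_frame().to_csv(fh, index=False, sep=sep)
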