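"""Kinome selectivity-panel analysis.

A kinome panel assays one compound against a set of purified kinases and
reports the percentage of kinase activity remaining.  This module parses
such tables, partitions the kinases of a panel into an *inhibited* group
(remaining activity at or below a low cutoff, default 50%), a
*non-inhibited* group (at or above a high cutoff, default 99%) and an
explicit *unclassified* band in between, and computes compound-overlap
(Venn) partitions between two such groupings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PanelRecord",
    "SelectivityGroups",
    "VennPartition",
    "PanelFormatError",
    "load_panel_table",
    "write_panel_table",
    "classify_groups",
    "overlap",
]


class PanelFormatError(ValueError):
    """Raised when a panel table is missing columns or contains bad rows."""


def normalize_kinase_id(kinase_id: str) -> str:
    """Canonical form used for comparisons: stripped and upper-cased.

    No alias resolution is attempted; two spellings of the same kinase that
    differ beyond case/whitespace remain distinct identifiers.
    """
    return str(kinase_id).strip().upper()


@dataclass(frozen=True)
class PanelRecord:
    """One (kinase, compound) measurement of percent remaining activity."""

    kinase_id: str
    compound_id: str
    remaining_activity: float
    sem: float | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if not str(self.kinase_id).strip():
            raise ValueError("kinase_id must be non-empty")
        a = float(self.remaining_activity)
        if not (a == a) or a in (float("inf"), float("-inf")) or a < 0:
            raise ValueError(
                f"remaining_activity must be finite and >= 0, got {self.remaining_activity!r}"
            )


@dataclass
class SelectivityGroups:
    """Three-way partition of a panel's kinases for one compound."""

    compound_id: str
    inhibited: set[str]
    noninhibited: set[str]
    unclassified: set[str]
    inhibited_cutoff: float
    noninhibited_cutoff: float

    @property
    def universe(self) -> set[str]:
        return self.inhibited | self.noninhibited | self.unclassified

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "compound_id": self.compound_id,
            "inhibited": sorted(self.inhibited),
            "noninhibited": sorted(self.noninhibited),
            "unclassified": sorted(self.unclassified),
            "inhibited_cutoff": self.inhibited_cutoff,
            "noninhibited_cutoff": self.noninhibited_cutoff,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SelectivityGroups":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            compound_id=d["compound_id"],
            inhibited=set(d["inhibited"]),
            noninhibited=set(d["noninhibited"]),
            unclassified=set(d["unclassified"]),
            inhibited_cutoff=float(d["inhibited_cutoff"]),
            noninhibited_cutoff=float(d["noninhibited_cutoff"]),
        )


@dataclass
class VennPartition:
    """Two-set overlap of inhibited kinases: only A, only B, both."""

    only_a: set[str]
    only_b: set[str]
    both: set[str]
    compound_a: str = ""
    compound_b: str = ""

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "both": len(self.both),
        }


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def load_panel_table(
    source: str | Path,
    *,
    kinase_col: str = "kinase_id",
    compound_col: str = "compound_id",
    activity_col: str = "remaining_activity",
    sem_col: str = "sem",
    n_col: str = "n_replicates",
    sep: str | None = None,
) -> list[PanelRecord]:
    """Parse a CSV/TSV panel table into :class:`PanelRecord` objects.

    Column names are configurable.  Duplicate measurements for the same
    (kinase, compound) pair are averaged (mean activity; SEM of the first
    duplicate retained for reporting).  Malformed activity values are
    collected and reported together with their 1-based data line numbers.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (kinase_col, compound_col, activity_col):
        if col not in df.columns:
            raise PanelFormatError(
                f"{path}: missing required column {col!r} (found {list(df.columns)})"
            )

    records: dict[tuple[str, str], list[PanelRecord]] = {}
    bad_rows: list[str] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        raw = row[activity_col]
        try:
            activity = float(raw)
        except (TypeError, ValueError):
            bad_rows.append(f"line {lineno}: non-numeric activity {raw!r}")
            continue
        sem = None
        if sem_col in df.columns and str(row[sem_col]).strip():
            try:
                sem = float(row[sem_col])
            except ValueError:
                bad_rows.append(f"line {lineno}: non-numeric SEM {row[sem_col]!r}")
                continue
        n_rep = None
        if n_col in df.columns and str(row[n_col]).strip():
            n_rep = int(float(row[n_col]))
        try:
            rec = PanelRecord(
                kinase_id=row[kinase_col],
                compound_id=str(row[compound_col]).strip(),
                remaining_activity=activity,
                sem=sem,
                n_replicates=n_rep,
            )
        except ValueError as exc:
            bad_rows.append(f"line {lineno}: {exc}")
            continue
        key = (normalize_kinase_id(rec.kinase_id), rec.compound_id)
        records.setdefault(key, []).append(rec)

    if bad_rows:
        raise PanelFormatError(f"{path}: {len(bad_rows)} malformed row(s): " + "; ".join(bad_rows))

    out: list[PanelRecord] = []
    for recs in records.values():
        if len(recs) == 1:
            out.append(recs[0])
        else:
            mean = sum(r.remaining_activity for r in recs) / len(recs)
            out.append(
                PanelRecord(
                    kinase_id=recs[0].kinase_id,
                    compound_id=recs[0].compound_id,
                    remaining_activity=mean,
                    sem=recs[0].sem,
                    n_replicates=len(recs),
                )
            )
    return out


def write_panel_table(records: Iterable[PanelRecord], path: str | Path) -> None:
    """Write records back out as CSV/TSV (inverse of :func:`load_panel_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame([asdict(r) for r in records])
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def classify_groups(
    records: Sequence[PanelRecord],
    compound_id: str,
    inhibited_cutoff: float = 50.0,
    noninhibited_cutoff: float = 99.0,
) -> SelectivityGroups:
    """Partition a compound's panel into inhibited / non-inhibited / between.

    A kinase is *inhibited* iff its remaining activity is at or below
    ``inhibited_cutoff`` (boundary inclusive: exactly 50.0% counts) and
    *non-inhibited* iff at or above ``noninhibited_cutoff`` (99.0% counts);
    everything strictly between the two cutoffs lands in ``unclassified``.
    """
    if not inhibited_cutoff < noninhibited_cutoff:
        raise ValueError(
            f"inhibited_cutoff ({inhibited_cutoff}) must be < noninhibited_cutoff "
            f"({noninhibited_cutoff})"
        )
    selected = [r for r in records if r.compound_id == compound_id]
    if not selected:
        raise ValueError(f"no panel records for compound {compound_id!r}")

    groups = SelectivityGroups(
        compound_id=compound_id,
        inhibited=set(),
        noninhibited=set(),
        unclassified=set(),
        inhibited_cutoff=inhibited_cutoff,
        noninhibited_cutoff=noninhibited_cutoff,
    )
    for rec in selected:
        kid = normalize_kinase_id(rec.kinase_id)
        if rec.remaining_activity <= inhibited_cutoff:
            groups.inhibited.add(kid)
        elif rec.remaining_activity >= noninhibited_cutoff:
            groups.noninhibited.add(kid)
        else:
            groups.unclassified.add(kid)
    return groups


def overlap(groups_a: SelectivityGroups, groups_b: SelectivityGroups) -> VennPartition:
    """Venn partition of the inhibited sets of two compounds.

    Warns (does not fail) if the two groupings were derived from different
    kinase universes.
    """
    if groups_a.universe != groups_b.universe:
        warnings.warn(
            "selectivity groups come from different kinase universes "
            f"({len(groups_a.universe)} vs {len(groups_b.universe)} kinases)",
            stacklevel=2,
        )
    a, b = groups_a.inhibited, groups_b.inhibited
    return VennPartition(
        only_a=a - b,
        only_b=b - a,
        both=a & b,
        compound_a=groups_a.compound_id,
        compound_b=groups_b.compound_id,
    )
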