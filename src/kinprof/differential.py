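"""Group-differential conservation screening.

Given conservation profiles for two kinase groups (e.g. compound-inhibited
vs non-inhibited) mapped to a common reference numbering, extract residues
whose 1-9 conservation grade differs by at least ``min_delta`` points and
assign each to a structural region of the kinase domain.

Delta is signed as (inhibited - non-inhibited), so a residue conserved in
the inhibited group but variable in the non-inhibited group appears with a
positive delta; filtering is on the absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .conservation import ConservationProfile

__all__ = [
    "ResidueDelta",
    "load_region_spans",
    "grade_delta",
    "assign_regions",
    "deltas_to_tsv",
]

UNASSIGNED = "unassigned"


@dataclass
class ResidueDelta:
    residue_number: int
    grade_inhibited: int
    grade_noninhibited: int
    delta: int
    either_low_confidence: bool
    region: str = UNASSIGNED

    def __post_init__(self) -> None:
        assert self.delta == self.grade_inhibited - self.grade_noninhibited


def load_region_spans(
    source: str | Path | Mapping[str, Sequence[Sequence[int]]] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Region -> list of inclusive (start, end) residue ranges.

    Defaults to the packaged spans (AMPKalpha2 numbering).  Raises if any
    two spans overlap.
    """
    if source is None:
        raw = yaml.safe_load(
            resources.files("kinprof.data").joinpath("region_spans.yaml").read_text()
        )
    elif isinstance(source, Mapping):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text())
    spans: dict[str, list[tuple[int, int]]] = {}
    flat: list[tuple[int, int, str]] = []
    for region, ranges in raw.items():
        spans[region] = []
        for rng in ranges:
            start, end = int(rng[0]), int(rng[1])
            if end < start:
                raise ValueError(f"region {region!r}: inverted range {rng}")
            spans[region].append((start, end))
            flat.append((start, end, region))
    flat.sort()
    for (s1, e1, r1), (s2, e2, r2) in zip(flat, flat[1:]):
        if s2 <= e1:
            raise ValueError(
                f"overlapping region spans: {r1} [{s1},{e1}] and {r2} [{s2},{e2}]"
            )
    return spans


def grade_delta(
    profile_inhibited: ConservationProfile,
    profile_noninhibited: ConservationProfile,
    min_delta: int = 3,
    omit_low_confidence: bool = True,
) -> list[ResidueDelta]:
    """Residues covered by both profiles with |grade difference| >= min_delta.

    Residues flagged low-confidence in either profile are dropped when
    ``omit_low_confidence`` is set.  Result is sorted by residue number.
    """
    if min_delta < 1:
        raise ValueError("min_delta must be >= 1")
    if not profile_inhibited.column_to_residue or not profile_noninhibited.column_to_residue:
        raise ValueError("both profiles must be mapped to reference numbering")
    by_res_a = profile_inhibited.by_residue()
    by_res_b = profile_noninhibited.by_residue()
    shared = sorted(set(by_res_a) & set(by_res_b))
    if not shared:
        warnings.warn("profiles cover disjoint residue sets; empty differential result")
        return []
    out: list[ResidueDelta] = []
    for resnum in shared:
        a, b = by_res_a[resnum], by_res_b[resnum]
        low = a.low_confidence or b.low_confidence
        if omit_low_confidence and low:
            continue
        d = a.grade - b.grade
        if abs(d) >= min_delta:
            out.append(
                ResidueDelta(
                    residue_number=resnum,
                    grade_inhibited=a.grade,
                    grade_noninhibited=b.grade,
                    delta=d,
                    either_low_confidence=low,
                )
            )
    return out


def coverage_difference(
    profile_inhibited: ConservationProfile, profile_noninhibited: ConservationProfile
) -> dict[str, list[int]]:
    """Residues covered by only one of the two profiles (reported, not dropped)."""
    a = set(profile_inhibited.by_residue())
    b = set(profile_noninhibited.by_residue())
    return {"only_inhibited": sorted(a - b), "only_noninhibited": sorted(b - a)}


def assign_regions(
    deltas: Sequence[ResidueDelta],
    region_spans: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[ResidueDelta]:
    """Fill each delta's region from the span whose range contains it."""
    spans = load_region_spans(region_spans)
    for d in deltas:
        d.region = UNASSIGNED
        for region, ranges in spans.items():
            if any(start <= d.residue_number <= end for start, end in ranges):
                d.region = region
                break
    return list(deltas)


def deltas_to_tsv(deltas: Sequence[ResidueDelta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "residue_number": d.residue_number,
                "grade_inhibited": d.grade_inhibited,
                "grade_noninhibited": d.grade_noninhibited,
                "delta": d.delta,
                "either_low_confidence": int(d.either_low_confidence),
                "region": d.region,
            }
            for d in deltas
        ],
        columns=[
            "residue_number",
            "grade_inhibited",
            "grade_noninhibited",
            "delta",
            "either_low_confidence",
            "region",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
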