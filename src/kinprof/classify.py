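"""Conformational-state calls from geometric measurements.

Three independent, pure decision rules:

* a DFG spatial label from the (D1, D2) distance pair — DFG-out when the
  DFG-Phe ring sits close to the beta3 lysine (small D2), DFG-in when it
  is far from the lysine and clearly farther than from the alphaC anchor,
  and DFG-inter otherwise;
* an alphaC in/out label from the beta3-Lys/alphaC-Glu distance (a long
  distance means the salt bridge is broken and the helix is out);
* a dihedral-cluster assignment of the x-DFG-x Phi/Psi angles against a
  centroid library by mean circular distance, with an explicit
  "unassigned" outcome when no centroid is close enough.

Every call echoes the thresholds it used, so identical measurements and
thresholds always produce identical labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .structure import (
    AMPK_ALPHA2_ANCHORS,
    DihedralRecord,
    GeometryReport,
    KinaseAnchors,
    StructureModel,
    geometry_report,
)

__all__ = [
    "SpatialThresholds",
    "DihedralClusterLibrary",
    "ClusterAssignment",
    "ConformationCall",
    "circular_distance",
    "mean_circular_distance",
    "spatial_label",
    "alphaC_label",
    "dihedral_cluster",
    "classify",
    "load_cluster_library",
    "DFG_IN",
    "DFG_OUT",
    "DFG_INTER",
    "UNASSIGNED",
]

DFG_IN = "DFG-in"
DFG_OUT = "DFG-out"
DFG_INTER = "DFG-inter"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SpatialThresholds:
    """Decision constants for the (D1, D2) spatial rule and the alphaC rule."""

    dfg_out_d2_max: float = 11.0   # Angstrom: D2 at or below this is DFG-out
    dfg_in_min_separation: float = 2.0  # Angstrom: D2 - D1 at or above this is DFG-in
    alphac_out_min: float = 10.0   # Angstrom: Lys-Glu strictly above this is alphaC-out


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance in degrees, respecting wraparound (<= 180)."""
    d = abs(a - b) % 360.0
    return d if d <= 180.0 else 360.0 - d


def mean_circular_distance(
    angles: Sequence[float | None], centroid: Sequence[float | None]
) -> float | None:
    """Mean circular distance over the angle pairs defined on both sides.

    Missing angles (None on either side) are excluded and the mean is
    renormalized over the remaining pairs; returns None if no pair is
    defined.
    """
    dists = [
        circular_distance(a, c)
        for a, c in zip(angles, centroid)
        if a is not None and c is not None
    ]
    if not dists:
        return None
    return sum(dists) / len(dists)


@dataclass
class DihedralClusterLibrary:
    """Named centroids of x-DFG-x Phi/Psi angles plus an assignment cutoff."""

    clusters: dict[str, list[tuple[float | None, float | None]]]
    assignment_cutoff: float = 45.0

    def __post_init__(self) -> None:
        for name, angles in self.clusters.items():
            if len(angles) != 5:
                raise ValueError(f"cluster {name!r}: expected 5 (phi, psi) pairs")
            for phi, psi in angles:
                for ang in (phi, psi):
                    if ang is not None and not (-180.0 < ang <= 180.0):
                        raise ValueError(f"cluster {name!r}: angle {ang} outside (-180, 180]")


def load_cluster_library(source: str | Path | None = None) -> DihedralClusterLibrary:
    """Load a cluster library from YAML; defaults to the packaged library."""
    if source is None:
        raw = yaml.safe_load(
            resources.files("kinprof.data").joinpath("dihedral_clusters.yaml").read_text()
        )
    else:
        raw = yaml.safe_load(Path(source).read_text())
    clusters = {}
    for name, d in raw["clusters"].items():
        clusters[name] = [
            (None if p is None else float(p), None if s is None else float(s))
            for p, s in zip(d["phi"], d["psi"])
        ]
    return DihedralClusterLibrary(
        clusters=clusters, assignment_cutoff=float(raw.get("assignment_cutoff", 45.0))
    )


@dataclass
class ClusterAssignment:
    cluster: str  # cluster name or "unassigned"
    best_cluster: str
    best_distance: float
    second_cluster: str | None
    second_distance: float | None
    assignment_cutoff: float


def _interleave(xdfgx: Sequence[DihedralRecord]) -> list[float | None]:
    out: list[float | None] = []
    for rec in xdfgx:
        out.extend((rec.phi, rec.psi))
    return out


def dihedral_cluster(
    xdfgx: Sequence[DihedralRecord], library: DihedralClusterLibrary
) -> ClusterAssignment:
    """Nearest centroid by mean circular distance, or "unassigned"."""
    if not library.clusters:
        raise ValueError("empty dihedral cluster library")
    if len(xdfgx) != 5:
        raise ValueError(f"expected 5 x-DFG-x residues, got {len(xdfgx)}")
    angles = _interleave(xdfgx)
    ranked: list[tuple[float, str]] = []
    for name, centroid_pairs in library.clusters.items():
        centroid: list[float | None] = []
        for phi, psi in centroid_pairs:
            centroid.extend((phi, psi))
        d = mean_circular_distance(angles, centroid)
        if d is not None:
            ranked.append((d, name))
    if not ranked:
        raise ValueError("no cluster shares a defined angle with the measurements")
    ranked.sort()
    best_d, best_name = ranked[0]
    second_d, second_name = ranked[1] if len(ranked) > 1 else (None, None)
    assigned = best_name if best_d <= library.assignment_cutoff else UNASSIGNED
    return ClusterAssignment(
        cluster=assigned,
        best_cluster=best_name,
        best_distance=best_d,
        second_cluster=second_name,
        second_distance=second_d,
        assignment_cutoff=library.assignment_cutoff,
    )


def spatial_label(d1: float, d2: float, thresholds: SpatialThresholds = SpatialThresholds()) -> str:
    """DFG spatial label from the two diagnostic distances.

    DFG-out iff D2 <= dfg_out_d2_max; else DFG-in iff D2 - D1 >=
    dfg_in_min_separation; else DFG-inter.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("distances must be positive")
    if d2 <= thresholds.dfg_out_d2_max:
        return DFG_OUT
    if d2 - d1 >= thresholds.dfg_in_min_separation:
        return DFG_IN
    return DFG_INTER


def alphaC_label(lys_glu_distance: float, cutoff: float = 10.0) -> str:
    """"out" iff the Lys-Glu distance is strictly greater than the cutoff."""
    if lys_glu_distance <= 0:
        raise ValueError("distance must be positive")
    return "out" if lys_glu_distance > cutoff else "in"


@dataclass
class ConformationCall:
    spatial_label: str
    alphaC_label: str
    dihedral_cluster: ClusterAssignment
    d1: float
    d2: float
    lys_glu_distance: float
    thresholds_used: SpatialThresholds
    geometry: GeometryReport | None = None

    def to_dict(self) -> dict:
        return {
            "spatial_label": self.spatial_label,
            "alphaC_label": self.alphaC_label,
            "dihedral_cluster": asdict(self.dihedral_cluster),
            "d1": round(self.d1, 1),
            "d2": round(self.d2, 1),
            "lys_glu_distance": round(self.lys_glu_distance, 1),
            "thresholds_used": asdict(self.thresholds_used),
            "geometry": None if self.geometry is None else self.geometry.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def classify(
    model: StructureModel,
    anchors: KinaseAnchors = AMPK_ALPHA2_ANCHORS,
    library: DihedralClusterLibrary | None = None,
    thresholds: SpatialThresholds = SpatialThresholds(),
) -> ConformationCall:
    """Measure a structure and turn the measurements into conformational calls."""
    if library is None:
        library = load_cluster_library()
    report = geometry_report(model, anchors)
    assignment = dihedral_cluster(report.xdfgx_dihedrals, library)
    return ConformationCall(
        spatial_label=spatial_label(report.d1, report.d2, thresholds),
        alphaC_label=alphaC_label(report.lys_glu_distance, thresholds.alphac_out_min),
        dihedral_cluster=assignment,
        d1=report.d1,
        d2=report.d2,
        lys_glu_distance=report.lys_glu_distance,
        thresholds_used=thresholds,
        geometry=report,
    )
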