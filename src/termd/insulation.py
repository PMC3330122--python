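"""Rule model for Ter-macrodomain insulation and per-marker mobility classes.

The model encodes the working picture of Ter-region insulation in E. coli:

* MatP structures the Ter macrodomain; ZapB tethers it to the divisome at
  mid-cell for roughly the second half of the cell cycle.
* While the Ter MD is anchored, a constraining process spreads in *cis* from
  both Ter borders along the chromosome, reducing locus mobility and delaying
  sister segregation wherever it reaches.
* The spread is blocked by the first *functional* insulator met on each arm —
  a 12-bp site matching the GYTGACGTCAGC consensus exactly (tidR/tidL in the
  wild type) — and insulator function additionally requires the membrane
  protein YfbV.  With no insulator on an arm the spread runs to the Ori MD
  boundary (a model assumption: Ori markers are unaffected in every construct,
  and nothing in the data says what stops the spread there).

Everything here is symbolic: classes map to motion/cohesion parameters only in
:mod:`termd.simulate`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .genome import CircularGenome, Feature, GenomeError, _arc_len, _norm
from .motifs import TID_CONSENSUS, mismatch_count

__all__ = [
    "MobilityClass", "CellCycleStage", "Genotype", "StrainModel",
    "SpreadInterval", "functional_insulators", "spread_intervals",
    "classify_marker", "predict_strain_profile", "segregation_class",
]


class MobilityClass(enum.Enum):
    """Discrete mobility/segregation class of a chromosomal marker.

    Expected mobility ordering (consumed by the simulator defaults):
    FREE > STRUCTURED ≈ CONSTRAINED > TER_STRUCTURED > TER_ANCHORED.
    CONSTRAINED is the insulation-failure state of a locus reached by the
    Ter-borne constraining process; its mobility matches macrodomain levels,
    which is why the spread is invisible inside the Right/Left MDs.
    """

    FREE = "FREE"
    STRUCTURED = "STRUCTURED"
    TER_STRUCTURED = "TER_STRUCTURED"
    TER_ANCHORED = "TER_ANCHORED"
    CONSTRAINED = "CONSTRAINED"


class CellCycleStage(enum.Enum):
    """Is the Ter MD currently tethered to the divisome at mid-cell?

    ANCHORED covers roughly the second half of the cycle (ages 0.5–1.0 of the
    doubling time by default); PRE_ANCHORING the small-cell stage before the
    Ter MD is recruited to mid-cell.
    """

    PRE_ANCHORING = "pre_anchoring"
    ANCHORED = "anchored"


#: default anchored-age window, as fractions of the doubling time
ANCHORED_WINDOW = (0.5, 1.0)


@dataclass(frozen=True)
class Genotype:
    matP: bool = True
    zapB: bool = True
    yfbV: bool = True
    yihI: bool = True  # optional modifier; absence releases Right/Left structuring


@dataclass
class StrainModel:
    """A genome (possibly rearranged) plus its relevant genotype flags."""

    genome: CircularGenome
    genotype: Genotype = field(default_factory=Genotype)
    name: str = ""
    ter_label: str = "Ter"
    ori_label: str = "Ori"
    md_labels: frozenset[str] = frozenset({"Ori", "Right", "Left"})
    spread_bounded_by_ori: bool = True

    def __post_init__(self):
        if not self.name:
            self.name = self.genome.name
        if not any(r.source_label == self.ter_label for r in self.genome.regions):
            raise GenomeError(f"strain genome has no {self.ter_label!r} region")


@dataclass(frozen=True)
class SpreadInterval:
    """Arc reached by the constraining process from one Ter border.

    ``border`` is the Ter border coordinate; ``direction`` +1 walks ascending
    (away from Ter), -1 descending; positions at arc distance 1..``span_bp``
    from the border are inside.  A marker sitting exactly on a blocking
    insulator is *outside* (the insulator blocks at its own coordinate).
    """

    border: int
    direction: int
    span_bp: int
    length_bp: int
    stopped_by: str = ""

    def contains(self, pos: int) -> bool:
        if self.direction == 1:
            d = (pos - self.border) % self.length_bp
        else:
            d = (self.border - pos) % self.length_bp
        return 1 <= d <= self.span_bp


def functional_insulators(strain: StrainModel) -> list[Feature]:
    """Insulator features able to block the spread in this strain.

    Functional = carries a 12-base sequence matching the GYTGACGTCAGC
    consensus with zero mismatches, in a yfbV+ background.
    """
    out = []
    for f in strain.genome.features:
        if f.kind != "insulator":
            continue
        if not f.sequence:
            raise GenomeError(f"insulator {f.name!r} lacks a sequence")
        if strain.genotype.yfbV and mismatch_count(f.sequence, TID_CONSENSUS) == 0:
            out.append(f)
    return out


def _ter_borders(strain: StrainModel) -> tuple[int, int]:
    """(low border, high border) of the contiguous Ter span, circularly.

    Returns borders such that the Ter span is the ascending arc
    ``(low, high]``; adjacent Ter pieces are merged, non-contiguous Ter spans
    are rejected.
    """
    g = strain.genome
    L = g.length_bp
    pieces = [r for r in g.ordered_regions() if r.source_label == strain.ter_label]
    if not pieces:
        raise GenomeError("no Ter region")
    borders = {r.start_bp % L for r in pieces}
    ends = {r.end_bp % L for r in pieces}
    starts = borders - ends
    stops = ends - borders
    if len(starts) != 1 or len(stops) != 1:
        raise GenomeError("Ter region is not contiguous after rearrangement")
    lo, hi = starts.pop(), stops.pop()
    if sum(r.length(L) for r in pieces) != _arc_len(lo, hi, L):
        raise GenomeError("Ter region is not contiguous after rearrangement")
    return lo, hi


def spread_intervals(strain: StrainModel,
                     stage: CellCycleStage = CellCycleStage.ANCHORED
                     ) -> list[SpreadInterval]:
    """Arcs reached by the constraining process, one per Ter border.

    Empty when the process cannot run at all: matP or zapB absent, or the Ter
    MD not yet anchored at mid-cell (PRE_ANCHORING stage).
    """
    gt = strain.genotype
    if not gt.matP or not gt.zapB or stage is CellCycleStage.PRE_ANCHORING:
        return []
    g = strain.genome
    L = g.length_bp
    lo, hi = _ter_borders(strain)
    insulators = functional_insulators(strain)
    out = []
    for border, direction in ((hi, +1), (lo, -1)):
        stops: list[tuple[int, str]] = []
        for f in insulators:
            if direction == 1:
                d = (f.position_bp - border) % L
            else:
                d = (border - f.position_bp) % L
            stops.append((d - 1, f.name))  # insulator position itself excluded
        if strain.spread_bounded_by_ori:
            for r in g.ordered_regions():
                if r.source_label != strain.ori_label:
                    continue
                if direction == 1:
                    # first Ori position ascending is r.start_bp + 1
                    d = (r.start_bp - border) % L
                else:
                    d = (border - r.end_bp) % L
                stops.append((d, f"{strain.ori_label} boundary"))
        if not stops:
            stops.append((L - _arc_len(lo, hi, L), "full circle"))
        span, stopped_by = min(stops)
        out.append(SpreadInterval(border, direction, max(span, 0), L, stopped_by))
    return out


def classify_marker(strain: StrainModel, marker: Feature | str,
                    stage: CellCycleStage = CellCycleStage.ANCHORED
                    ) -> MobilityClass:
    """Mobility class of one marker in this strain at this cell-cycle stage."""
    if isinstance(marker, str):
        marker = strain.genome.feature(marker)
    g = strain.genome
    if not 1 <= marker.position_bp <= g.length_bp:
        raise GenomeError(f"marker {marker.name!r} outside genome")
    gt = strain.genotype
    region = g.region_at(marker.position_bp)
    label = region.source_label
    if label == strain.ter_label:
        if not gt.matP:
            return MobilityClass.FREE
        if gt.zapB and stage is CellCycleStage.ANCHORED:
            return MobilityClass.TER_ANCHORED
        return MobilityClass.TER_STRUCTURED
    for iv in spread_intervals(strain, stage):
        if iv.contains(marker.position_bp):
            return MobilityClass.CONSTRAINED
    if label in strain.md_labels and label != strain.ter_label:
        if not gt.yihI and label != strain.ori_label:
            return MobilityClass.FREE  # yihI- releases Right/Left MD structuring
        return MobilityClass.STRUCTURED
    return MobilityClass.FREE


def segregation_class(mclass: MobilityClass) -> str:
    """Expected sister-segregation behaviour of a mobility class."""
    return "immediate" if mclass is MobilityClass.FREE else "delayed"


def predict_strain_profile(strain: StrainModel,
                           markers: list[Feature | str] | None = None,
                           stage: CellCycleStage = CellCycleStage.ANCHORED
                           ) -> pd.DataFrame:
    """Classify a batch of markers; defaults to every marker feature.

    Returns a DataFrame with columns strain, marker, stage, mobility_class,
    segregation, comparable row-for-row to the packaged expectation table.
    """
    if markers is None:
        markers = [f for f in strain.genome.features if f.kind == "marker"]
    rows = []
    for m in markers:
        feat = strain.genome.feature(m) if isinstance(m, str) else m
        mc = classify_marker(strain, feat, stage)
        rows.append({
            "strain": strain.name,
            "marker": feat.name,
            "stage": stage.value,
            "mobility_class": mc.value,
            "segregation": segregation_class(mc),
        })
    return pd.DataFrame(rows, columns=[
        "strain", "marker", "stage", "mobility_class", "segregation",
    ])
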