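"""Circular bacterial chromosome model with macrodomain regions and point features.

The chromosome is a ring of ``length_bp`` positions (1-based).  Regions tile the
circle; each region owns the half-open arc ``(start_bp, end_bp]`` walking in
ascending coordinate order (wrapping through the origin where needed), i.e. the
``start_bp``/``end_bp`` values are *border* coordinates shared with the
neighbouring regions.  Features (fluorescent markers, att sites, insulator
sequences, genes) are zero-length points.

Two rearrangements are supported, mirroring the lambda Int/Xis engineering used
to shuffle the E. coli map:

* :func:`transpose` — excise the arc between two directly repeated att sites as
  a circle and reinsert it at an ectopic attB' site, preserving the internal
  orientation of the segment (a "cut and paste" move that leaves every gene in
  its original orientation relative to replication).
* :func:`invert` — reverse an arc in place, flipping strands inside it.

Every rearrangement returns the new genome together with a
:class:`CoordinateMap`, an exact piecewise bijection from old to new
coordinates, so features and downstream statistics can be lifted over without
loss.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Region",
    "Feature",
    "CircularGenome",
    "CoordinateMap",
    "MapPiece",
    "transpose",
    "invert",
    "configuration_string",
    "segment_length",
    "GenomeError",
]

FEATURE_KINDS = {
    "marker", "attL", "attR", "attB", "attBprime", "insulator", "matS", "gene",
}


class GenomeError(ValueError):
    """Raised for invalid genome definitions or rejected rearrangements."""


def _arc_len(start: int, end: int, length: int) -> int:
    """Ascending arc length from border ``start`` to border ``end`` (mod length)."""
    return (end - start) % length


def _in_arc(pos: int, start: int, end: int, length: int) -> bool:
    """Is ``pos`` inside the half-open ascending arc ``(start, end]``?"""
    span = _arc_len(start, end, length)
    if span == 0:
        return False
    return 0 < (pos - start) % length <= span


def _norm(pos: int, length: int) -> int:
    """Normalise a coordinate into 1..length."""
    return (pos - 1) % length + 1


@dataclass(frozen=True)
class Region:
    """A region of the circle owning the half-open arc ``(start_bp, end_bp]``.

    ``source`` and ``orig_start_bp``/``orig_end_bp`` carry provenance through
    rearrangements: a piece of a split region keeps the label of, and its
    coordinate span within, the region it came from.  ``orient`` is -1 for
    pieces that were reversed by an inversion.
    """

    label: str
    start_bp: int
    end_bp: int
    source: str | None = None
    orig_start_bp: int | None = None
    orig_end_bp: int | None = None
    orient: int = 1
    note: str = ""

    @property
    def source_label(self) -> str:
        return self.source if self.source is not None else self.label

    @property
    def orig_span(self) -> tuple[int, int]:
        s = self.orig_start_bp if self.orig_start_bp is not None else self.start_bp
        e = self.orig_end_bp if self.orig_end_bp is not None else self.end_bp
        return (s, e)

    def length(self, genome_length: int) -> int:
        return _arc_len(self.start_bp, self.end_bp, genome_length)

    @property
    def wraps(self) -> bool:
        return self.end_bp < self.start_bp


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str
    position_bp: int
    strand: str = "."
    sequence: str | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise GenomeError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.strand not in {"+", "-", "."}:
            raise GenomeError(f"bad strand {self.strand!r} for feature {self.name!r}")


@dataclass(frozen=True)
class MapPiece:
    """One order-preserving (or order-reversing) piece of a coordinate map.

    Source positions ``src_start+1 .. src_start+span`` (ascending, mod L) map to
    destination positions ``dst_start+1 .. dst_start+span`` in the same order
    when ``direction=+1``, or in reversed order when ``direction=-1``.
    """

    src_start: int
    dst_start: int
    span: int
    direction: int = 1


class CoordinateMap:
    """Piecewise bijection on 1..length produced by a rearrangement."""

    def __init__(self, length: int, pieces: Sequence[MapPiece]):
        self.length = length
        self.pieces = list(pieces)
        if sum(p.span for p in self.pieces) != length:
            raise GenomeError("coordinate map pieces do not cover the genome")

    def __call__(self, pos: int) -> int:
        L = self.length
        pos = _norm(pos, L)
        for p in self.pieces:
            off = (pos - p.src_start) % L
            if 0 < off <= p.span:
                if p.direction == 1:
                    return _norm(p.dst_start + off, L)
                return _norm(p.dst_start + (p.span - off) + 1, L)
        raise GenomeError(f"position {pos} not covered by map")  # pragma: no cover

    def strand_factor(self, pos: int) -> int:
        """+1 if the piece containing ``pos`` preserves orientation, else -1."""
        L = self.length
        pos = _norm(pos, L)
        for p in self.pieces:
            if 0 < (pos - p.src_start) % L <= p.span:
                return p.direction
        raise GenomeError(f"position {pos} not covered by map")  # pragma: no cover

    def inverse(self) -> "CoordinateMap":
        inv = []
        for p in self.pieces:
            if p.direction == 1:
                inv.append(MapPiece(p.dst_start, p.src_start, p.span, 1))
            else:
                inv.append(MapPiece(p.dst_start, p.src_start, p.span, -1))
        return CoordinateMap(self.length, inv)

    def to_tsv(self) -> str:
        """Two-column-style lift-over table (interval form)."""
        buf = io.StringIO()
        buf.write("src_start\tsrc_end\tdst_start\tdst_end\tdirection\n")
        L = self.length
        for p in self.pieces:
            s1 = _norm(p.src_start + 1, L)
            s2 = _norm(p.src_start + p.span, L)
            if p.direction == 1:
                d1 = _norm(p.dst_start + 1, L)
                d2 = _norm(p.dst_start + p.span, L)
            else:
                d1 = _norm(p.dst_start + p.span, L)
                d2 = _norm(p.dst_start + 1, L)
            buf.write(f"{s1}\t{s2}\t{d1}\t{d2}\t{p.direction:+d}\n")
        return buf.getvalue()


@dataclass
class CircularGenome:
    """A circular replicon with a region tiling and point features."""

    name: str
    length_bp: int
    regions: list[Region] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if self.length_bp <= 0:
            raise GenomeError("genome length must be positive")
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        L = self.length_bp
        if self.regions:
            total = sum(r.length(L) or (L if len(self.regions) == 1 else 0)
                        for r in self.regions)
            if total != L:
                raise GenomeError(
                    f"regions cover {total} bp, genome is {L} bp: tiling broken"
                )
            ordered = sorted(self.regions, key=lambda r: r.start_bp)
            for a, b in zip(ordered, ordered[1:] + ordered[:1]):
                if a.end_bp % L != b.start_bp % L and len(ordered) > 1:
                    raise GenomeError(
                        f"regions {a.label!r} and {b.label!r} do not abut "
                        f"({a.end_bp} vs {b.start_bp}): gap or overlap"
                    )
        for f in self.features:
            if not 1 <= f.position_bp <= L:
                raise GenomeError(
                    f"feature {f.name!r} at {f.position_bp} outside [1, {L}]"
                )

    # -- queries ----------------------------------------------------------

    def region_at(self, pos: int) -> Region:
        pos = _norm(pos, self.length_bp)
        for r in self.regions:
            if _in_arc(pos, r.start_bp, r.end_bp, self.length_bp):
                return r
        if len(self.regions) == 1:  # single region covering the full circle
            return self.regions[0]
        raise GenomeError(f"position {pos} not in any region")

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise GenomeError(f"no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def ordered_regions(self) -> list[Region]:
        """Regions sorted by circular position (ascending start border)."""
        return sorted(self.regions, key=lambda r: r.start_bp % self.length_bp)

    # -- exports -----------------------------------------------------------

    def features_to_bed(self) -> str:
        """BED6 (0-based half-open) of all point features."""
        lines = []
        for f in sorted(self.features, key=lambda f: f.position_bp):
            lines.append(
                f"{self.name}\t{f.position_bp - 1}\t{f.position_bp}\t"
                f"{f.name}\t0\t{f.strand if f.strand != '.' else '.'}"
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def regions_to_gff3(self) -> str:
        out = ["##gff-version 3"]
        for r in self.ordered_regions():
            # wrap-around regions are emitted as two lines split at the origin
            spans = []
            if r.wraps:
                spans = [(r.start_bp + 1, self.length_bp), (1, r.end_bp)]
            else:
                spans = [(r.start_bp + 1, r.end_bp)]
            for s, e in spans:
                strand = "+" if r.orient == 1 else "-"
                out.append(
                    f"{self.name}\ttermd\tregion\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"Name={r.label};source_region={r.source_label}"
                )
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------


def segment_length(genome: CircularGenome, start: int, end: int,
                   direction: str = "ascending") -> int:
    """Arc length in bp from ``start`` to ``end`` in the given direction.

    A zero-length arc (``start == end``) returns 0, never a full turn.
    """
    if direction not in {"ascending", "descending"}:
        raise GenomeError(f"direction must be ascending|descending, got {direction!r}")
    L = genome.length_bp
    if direction == "ascending":
        return _arc_len(start, end, L)
    return _arc_len(end, start, L)


def _map_region_through(r: Region, cmap: CoordinateMap, L: int) -> list[Region]:
    """Image of a region under a coordinate map, split at map-piece borders."""
    out: list[Region] = []
    span_r = _arc_len(r.start_bp, r.end_bp, L)
    if span_r == 0:
        span_r = L  # single full-circle region
    os, oe = r.orig_span
    for p in cmap.pieces:
        # Work in offsets from the region start border.  The piece covers
        # offsets (o, o+span] on the circle; intersect with the region's
        # (0, span_r], trying both unrollings of the circular offset.
        o = (p.src_start - r.start_bp) % L
        for o_lin in (o, o - L):
            lo = max(o_lin, 0)
            hi = min(o_lin + p.span, span_r)
            if hi <= lo:
                continue
            seg = hi - lo
            within_piece = lo - o_lin  # offset of the chunk inside the piece
            # provenance sub-span inside the original region coordinates
            if r.orient == 1:
                sub_os, sub_oe = (os + lo) % L, (os + hi) % L
            else:
                sub_os, sub_oe = (oe - hi) % L, (oe - lo) % L
            if p.direction == 1:
                d_lo = (p.dst_start + within_piece) % L
            else:
                d_lo = (p.dst_start + (p.span - (within_piece + seg))) % L
            out.append(Region(
                label=r.label,
                start_bp=d_lo,
                end_bp=(d_lo + seg) % L,
                source=r.source_label,
                orig_start_bp=sub_os,
                orig_end_bp=sub_oe,
                orient=r.orient * p.direction,
            ))
    return out


def _merge_adjacent(pieces: list[Region], L: int) -> list[Region]:
    """Merge circularly adjacent pieces that are contiguous in source coords."""
    if not pieces:
        return pieces
    pieces = sorted(pieces, key=lambda r: r.start_bp % L)
    merged: list[Region] = []
    for r in pieces:
        if merged:
            prev = merged[-1]
            if (
                prev.end_bp % L == r.start_bp % L
                and prev.source_label == r.source_label
                and prev.orient == r.orient
                and (
                    (prev.orient == 1 and prev.orig_span[1] % L == r.orig_span[0] % L)
                    or (prev.orient == -1 and prev.orig_span[0] % L == r.orig_span[1] % L)
                )
            ):
                os = prev.orig_span[0] if prev.orient == 1 else r.orig_span[0]
                oe = r.orig_span[1] if prev.orient == 1 else prev.orig_span[1]
                merged[-1] = replace(
                    prev, end_bp=r.end_bp, orig_start_bp=os, orig_end_bp=oe
                )
                continue
        merged.append(r)
    # wrap-around join of last into first
    if len(merged) > 1:
        first, last = merged[0], merged[-1]
        if (
            last.end_bp % L == first.start_bp % L
            and last.source_label == first.source_label
            and last.orient == first.orient
            and (
                (last.orient == 1 and last.orig_span[1] % L == first.orig_span[0] % L)
                or (last.orient == -1 and last.orig_span[0] % L == first.orig_span[1] % L)
            )
        ):
            os = last.orig_span[0] if last.orient == 1 else first.orig_span[0]
            oe = first.orig_span[1] if last.orient == 1 else last.orig_span[1]
            merged[0] = replace(
                first, start_bp=last.start_bp,
                orig_start_bp=os, orig_end_bp=oe,
            )
            merged.pop()
    return merged


def _apply_map(genome: CircularGenome, cmap: CoordinateMap,
               new_name: str) -> CircularGenome:
    L = genome.length_bp
    new_regions: list[Region] = []
    for r in genome.regions:
        new_regions.extend(_map_region_through(r, cmap, L))
    new_regions = _merge_adjacent(new_regions, L)
    new_features = []
    for f in genome.features:
        npos = cmap(f.position_bp)
        strand = f.strand
        if strand in {"+", "-"} and cmap.strand_factor(f.position_bp) == -1:
            strand = "-" if strand == "+" else "+"
        new_features.append(replace(f, position_bp=npos, strand=strand))
    return CircularGenome(new_name, L, new_regions, new_features)


def transpose(genome: CircularGenome, attL_pos: int, attR_pos: int,
              attBprime_pos: int) -> tuple[CircularGenome, CoordinateMap]:
    """Excise the ascending arc from attR to attL and reinsert it after attB'.

    Mirrors the two-step lambda Int/Xis engineering: excisive recombination
    between the directly repeated attL/attR sites releases the intervening
    segment as a circle, which is then reintegrated at the ectopic attB' site
    with its internal gene order and orientation preserved.

    Returns the rearranged genome and the exact old→new :class:`CoordinateMap`.
    New coordinates are anchored so that old position 1 keeps coordinate 1
    whenever it lies outside the excised arc.
    """
    L = genome.length_bp
    a_l, a_r, a_b = (_norm(attL_pos, L), _norm(attR_pos, L), _norm(attBprime_pos, L))
    if len({a_l, a_r, a_b}) < 3:
        raise GenomeError("coincident att positions rejected")
    exc = _arc_len(a_r, a_l, L)  # excised = (attR, attL]
    if _in_arc(a_b, a_r, a_l, L):
        raise GenomeError(
            "attB' lies inside the excised arc: reinsertion target destroyed"
        )
    # new order, starting after attL: (attL, attB'] + excised (attR, attL]
    # + (attB', attR]
    segs = [
        (a_l, _arc_len(a_l, a_b, L)),
        (a_r, exc),
        (a_b, _arc_len(a_b, a_r, L)),
    ]
    pieces = []
    cursor = 0
    for start, span in segs:
        if span == 0:
            continue
        pieces.append(MapPiece(src_start=start, dst_start=cursor, span=span))
        cursor += span
    cmap = CoordinateMap(L, pieces)
    # re-anchor: old position 1 -> new position 1 when 1 was not excised
    if not _in_arc(1, a_r, a_l, L):
        shift = (1 - cmap(1)) % L
        pieces = [
            MapPiece(p.src_start, (p.dst_start + shift) % L, p.span, p.direction)
            for p in cmap.pieces
        ]
        cmap = CoordinateMap(L, pieces)
    new = _apply_map(genome, cmap, f"{genome.name}::transposed")
    return new, cmap


def invert(genome: CircularGenome, pos_a: int, pos_b: int
           ) -> tuple[CircularGenome, CoordinateMap]:
    """Reverse the ascending arc ``(pos_a, pos_b]`` in place.

    Coordinates outside the arc are unchanged; a marker at the arc start maps
    to the arc end and vice versa, and strands inside flip.
    """
    L = genome.length_bp
    a, b = _norm(pos_a, L), _norm(pos_b, L)
    if a == b:
        raise GenomeError("inversion endpoints coincide")
    span_in = _arc_len(a, b, L)
    span_out = L - span_in
    pieces = [MapPiece(src_start=a, dst_start=a, span=span_in, direction=-1)]
    if span_out:
        pieces.append(MapPiece(src_start=b, dst_start=b, span=span_out, direction=1))
    cmap = CoordinateMap(L, pieces)
    new = _apply_map(genome, cmap, f"{genome.name}::inverted")
    return new, cmap


# ---------------------------------------------------------------------------
# configuration strings
# ---------------------------------------------------------------------------


def configuration_string(genome: CircularGenome, start_label: str = "Ori",
                         min_piece_bp: int = 100_000) -> str:
    """Hyphen-separated region labels in circular order, starting at ``start_label``.

    Pieces of regions that were split by a rearrangement carry their original
    kb sub-range, e.g. ``Right(651-914)``.  Residual slivers shorter than
    ``min_piece_bp`` are left out of the string (they remain part of the
    genome), and a region surviving as a single displayed piece keeps its bare
    label — this matches how rearranged strain maps are conventionally
    annotated.
    """
    L = genome.length_bp
    pieces = [r for r in genome.ordered_regions()]
    if not pieces:
        raise GenomeError("genome has no regions")
    if len(pieces) == 1:
        return pieces[0].label
    shown = [r for r in pieces if r.length(L) >= min_piece_bp]
    if not shown:
        raise GenomeError("no region piece reaches the display threshold")
    counts: dict[str, int] = {}
    for r in shown:
        counts[r.source_label] = counts.get(r.source_label, 0) + 1
    # rotate to start at the largest displayed piece of the start region
    start_candidates = [r for r in shown if r.source_label == start_label]
    if start_candidates:
        anchor = max(start_candidates, key=lambda r: r.length(L))
        i = shown.index(anchor)
        shown = shown[i:] + shown[:i]
    labels = []
    for r in shown:
        if counts[r.source_label] > 1:
            os, oe = r.orig_span
            lo, hi = os // 1000, oe // 1000
            if r.orient == -1:
                lo, hi = min(lo, hi), max(lo, hi)
            labels.append(f"{r.source_label}({lo}-{hi})")
        else:
            labels.append(r.source_label)
    return "-".join(labels)
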