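"""Genome-graph data model.

A genome graph is a directed graph whose vertices are *strands* of
chromosomal segments and whose edges are segmental adjacencies: reference
edges between genomic neighbours, variant edges created by rearrangement
junctions, loose-end edges that absorb local violations of mass balance,
and telomere edges capping chromosome ends.

The graph is stored once per reverse-complement pair: each segment carries
one copy-number value shared by its two strands, and each edge object
represents the edge together with its reverse complement.  Skew symmetry
(equal copy number on an element and its reverse-complement image) is
therefore enforced structurally.

Coordinates are 0-based half-open internally.  A breakend is a segment
boundary plus the reference strand whose 3' terminus abuts it: strand '+'
means the retained segment lies 5' (left) of the position, strand '-'
means it lies 3' (right).
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

LEFT = "L"
RIGHT = "R"

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Breakend:
    """One end of a junction: a boundary coordinate with an orientation."""

    chrom: str
    pos: int
    strand: str  # '+' or '-'

    @property
    def side(self) -> str:
        """Side of the retained segment: '+' abuts the right side, '-' the left."""
        return RIGHT if self.strand == "+" else LEFT

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"breakend strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Junction:
    """An adjacency between two breakends created by rearrangement."""

    b1: Breakend
    b2: Breakend
    tier: str = "high"  # 'high' or 'low' confidence
    name: str = ""
    mechanism: str = "other"  # simulation/annotation label: NAHR, AHR, other
    forced: bool = False  # force-incorporate (CN >= 1) in the balance MIP

    @property
    def span(self) -> int | None:
        """Distance between breakends for intrachromosomal junctions."""
        if self.b1.chrom != self.b2.chrom:
            return None
        return abs(self.b1.pos - self.b2.pos)

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.b1, self.b2)


@dataclass
class Segment:
    """A genomic segment; both strands share one CN value."""

    chrom: str
    start: int
    end: int
    bins: np.ndarray | None = None  # indices into the depth profile of this chrom
    rho: float | None = None  # mean transformed depth over unmasked bins
    nbins: int = 0
    scale_b: float = 1.0  # Laplace scale, max(1, sqrt(rho))
    cn: int | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def weight(self) -> float:
        """Likelihood weight |J(v)| / b(v)."""
        return self.nbins / self.scale_b if self.nbins else 0.0


@dataclass
class Edge:
    """An adjacency edge together with its reverse complement.

    Attachment points are (segment index, side).  Reference edges attach at
    (i, R)-(i+1, L); variant edges at the two junction breakends; loose and
    telomere edges attach at a single (segment, side).
    """

    kind: str  # 'reference' | 'variant' | 'loose' | 'telomere'
    seg1: int
    side1: str
    seg2: int | None = None
    side2: str | None = None
    cn: int | None = None
    forced: bool = False
    name: str = ""
    tier: str = ""
    mechanism: str = ""

    @property
    def ends(self):
        if self.seg2 is None:
            return ((self.seg1, self.side1),)
        return ((self.seg1, self.side1), (self.seg2, self.side2))


class GenomeGraph:
    """Double-stranded genome graph over a segmentation of the genome."""

    def __init__(self, chrom_lengths: dict[str, int], segments: list[Segment],
                 edges: list[Edge], meta: dict | None = None):
        self.chrom_lengths = dict(chrom_lengths)
        self.segments = segments
        self.edges = edges
        self.meta = meta or {}
        self._index()

    def _index(self):
        self._chrom_range: dict[str, tuple[int, int]] = {}
        self._starts: dict[str, list[int]] = {}
        for i, s in enumerate(self.segments):
            if s.chrom not in self._chrom_range:
                self._chrom_range[s.chrom] = (i, i + 1)
                self._starts[s.chrom] = [s.start]
            else:
                lo, _ = self._chrom_range[s.chrom]
                self._chrom_range[s.chrom] = (lo, i + 1)
                self._starts[s.chrom].append(s.start)
        self._incidence: dict[tuple[int, str], list[tuple[int, int]]] = {}
        for eid, e in enumerate(self.edges):
            counts: dict[tuple[int, str], int] = {}
            for end in e.ends:
                counts[end] = counts.get(end, 0) + 1
            for end, m in counts.items():
                self._incidence.setdefault(end, []).append((eid, m))

    # -- lookups ---------------------------------------------------------
    def chrom_segments(self, chrom: str) -> range:
        lo, hi = self._chrom_range[chrom]
        return range(lo, hi)

    def seg_index_at(self, chrom: str, pos: int, side: str) -> int:
        """Segment whose boundary at `pos` matches `side`."""
        starts = self._starts[chrom]
        lo, hi = self._chrom_range[chrom]
        if side == LEFT:
            k = bisect.bisect_left(starts, pos)
            if k >= len(starts) or starts[k] != pos:
                raise KeyError(f"no segment starting at {chrom}:{pos}")
            return lo + k
        k = bisect.bisect_left(starts, pos) - 1
        idx = lo + k
        if k < 0 or self.segments[idx].end != pos:
            raise KeyError(f"no segment ending at {chrom}:{pos}")
        return idx

    def incident(self, seg: int, side: str) -> list[tuple[int, int]]:
        """(edge id, multiplicity) pairs attached at a boundary side."""
        return self._incidence.get((seg, side), [])

    def breakend(self, seg: int, side: str) -> Breakend:
        s = self.segments[seg]
        if side == RIGHT:
            return Breakend(s.chrom, s.end, "+")
        return Breakend(s.chrom, s.start, "-")

    def internal_boundaries(self) -> dict[str, list[int]]:
        out = {}
        for chrom in self.chrom_lengths:
            if chrom not in self._chrom_range:
                continue
            idx = list(self.chrom_segments(chrom))
            out[chrom] = [self.segments[i].start for i in idx[1:]]
        return out

    def edges_of_kind(self, kind: str):
        return [(i, e) for i, e in enumerate(self.edges) if e.kind == kind]

    def loose_ends(self) -> list[tuple[Breakend, int]]:
        """Fitted loose ends: breakend coordinates of loose edges with CN > 0."""
        out = []
        for _, e in self.edges_of_kind("loose"):
            if e.cn and e.cn > 0:
                out.append((self.breakend(e.seg1, e.side1), e.cn))
        return out

    def n_fitted_loose(self) -> int:
        return sum(1 for _, e in self.edges_of_kind("loose") if e.cn and e.cn > 0)

    def copy(self) -> "GenomeGraph":
        segs = [replace(s, bins=None if s.bins is None else s.bins.copy())
                for s in self.segments]
        edges = [replace(e) for e in self.edges]
        return GenomeGraph(self.chrom_lengths, segs, edges, dict(self.meta))

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        verts = []
        for s in self.segments:
            for strand in "+-":
                verts.append({"chrom": s.chrom, "start": s.start, "end": s.end,
                              "strand": strand, "cn": s.cn})
        edges = []
        for e in self.edges:
            edges.append({"kind": e.kind, "src": e.seg1, "src_side": e.side1,
                          "tgt": e.seg2, "tgt_side": e.side2, "cn": e.cn,
                          "forced": e.forced, "name": e.name, "tier": e.tier,
                          "mechanism": e.mechanism})
        doc = {"schema_version": SCHEMA_VERSION,
               "chrom_lengths": self.chrom_lengths,
               "vertices": verts, "edges": edges, "meta": self.meta}
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GenomeGraph":
        doc = json.loads(text)
        segs = []
        for v in doc["vertices"]:
            if v["strand"] != "+":
                continue
            segs.append(Segment(v["chrom"], v["start"], v["end"], cn=v["cn"]))
        edges = [Edge(kind=e["kind"], seg1=e["src"], side1=e["src_side"],
                      seg2=e["tgt"], side2=e["tgt_side"], cn=e["cn"],
                      forced=e["forced"], name=e.get("name", ""),
                      tier=e.get("tier", ""), mechanism=e.get("mechanism", ""))
                 for e in doc["edges"]]
        return cls(doc["chrom_lengths"], segs, edges, doc.get("meta", {}))


def _snap(pos: int, boundaries: list[int], tol: int) -> int | None:
    """Nearest boundary within tol, or None."""
    if not boundaries:
        return None
    k = bisect.bisect_left(boundaries, pos)
    best, bd = None, tol + 1
    for j in (k - 1, k):
        if 0 <= j < len(boundaries) and abs(boundaries[j] - pos) < bd:
            best, bd = boundaries[j], abs(boundaries[j] - pos)
    return best if bd <= tol else None


def build_graph(chrom_lengths: dict[str, int],
                breakpoints: dict[str, list[int]] | None,
                junctions: list[Junction],
                snap_tol: int = 1000,
                allow_new_boundaries: bool = True) -> GenomeGraph:
    """Construct a genome graph from segment breakpoints and junctions.

    Junction breakends are snapped to the nearest existing boundary within
    one depth bin (`snap_tol`); otherwise they are inserted as new
    boundaries (or rejected when `allow_new_boundaries` is False).  Every
    segment receives incoming/outgoing loose-end edges; chromosome-end
    boundaries receive telomere edges with unconstrained CN.
    """
    breakpoints = breakpoints or {}
    bsets: dict[str, list[int]] = {}
    junction_bnds: dict[str, set[int]] = {}
    for chrom, length in chrom_lengths.items():
        bps = sorted({int(b) for b in breakpoints.get(chrom, [])
                      if 0 < int(b) < length})
        bsets[chrom] = [0] + bps + [length]
        junction_bnds[chrom] = {0, length}

    # Reconcile junction breakends with depth-derived boundaries: breakends
    # are base-resolution, so a breakend within one bin of a depth
    # breakpoint replaces it; two breakends within one bin of each other
    # share the first one's coordinate.
    snapped: list[Junction] = []
    for j in junctions:
        if j.b1 == j.b2:
            raise ValueError(f"degenerate junction (identical breakends): {j.b1}")
        new_b = []
        for b in j.breakends:
            if b.chrom not in chrom_lengths:
                raise ValueError(f"junction breakend on unknown chromosome {b.chrom}")
            L = chrom_lengths[b.chrom]
            if not (0 <= b.pos <= L):
                raise ValueError(f"breakend {b} outside chromosome of length {L}")
            bl = bsets[b.chrom]
            jb = junction_bnds[b.chrom]

            def ok(p):
                return not (b.strand == "+" and p == 0) and \
                    not (b.strand == "-" and p == L)

            if not ok(b.pos):
                raise ValueError(f"breakend orientation invalid at "
                                 f"chromosome end: {b}")
            pos = b.pos
            if pos not in bl:
                hit = _snap(pos, bl, snap_tol)
                if hit is not None and hit not in jb:
                    bl.remove(hit)  # breakend supersedes depth breakpoint
                elif hit is None and not allow_new_boundaries:
                    raise ValueError(
                        f"junction breakend {b} is farther than "
                        f"{snap_tol} bp from any segment boundary")
                bisect.insort(bl, pos)
            jb.add(pos)
            new_b.append(Breakend(b.chrom, pos, b.strand))
        snapped.append(replace(j, b1=new_b[0], b2=new_b[1]))

    segments: list[Segment] = []
    for chrom in chrom_lengths:
        bl = bsets[chrom]
        for a, b in zip(bl[:-1], bl[1:]):
            segments.append(Segment(chrom, a, b))

    g = GenomeGraph(chrom_lengths, segments, [])

    edges: list[Edge] = []
    for chrom in chrom_lengths:
        idx = list(g.chrom_segments(chrom))
        edges.append(Edge("telomere", idx[0], LEFT))
        edges.append(Edge("telomere", idx[-1], RIGHT))
        for i, j2 in zip(idx[:-1], idx[1:]):
            edges.append(Edge("reference", i, RIGHT, j2, LEFT))
        for i in idx:
            edges.append(Edge("loose", i, LEFT))
            edges.append(Edge("loose", i, RIGHT))

    seen: dict[frozenset, int] = {}
    for j in snapped:
        e1 = (g.seg_index_at(j.b1.chrom, j.b1.pos, j.b1.side), j.b1.side)
        e2 = (g.seg_index_at(j.b2.chrom, j.b2.pos, j.b2.side), j.b2.side)
        if e1 == e2:
            raise ValueError(f"degenerate junction after snapping: {j.b1}, {j.b2}")
        key = frozenset((e1, e2)) if e1 != e2 else frozenset((e1,))
        if key in seen:
            logger.warning("duplicate junction collapsed: %s -- %s", j.b1, j.b2)
            prev = edges[seen[key]]
            prev.forced = prev.forced or j.forced
            if j.tier == "high":
                prev.tier = "high"
            continue
        e = Edge("variant", e1[0], e1[1], e2[0], e2[1], name=j.name,
                 tier=j.tier, mechanism=j.mechanism, forced=j.forced)
        edges.append(e)
        seen[key] = len(edges) - 1

    return GenomeGraph(chrom_lengths, segments, edges)


def attach_depth(graph: GenomeGraph, profile) -> None:
    """Assign depth bins J(v), segment means rho and Laplace scales b."""
    w = profile.bin_width
    for chrom in graph.chrom_lengths:
        vals = profile.values[chrom]
        mids = (np.arange(len(vals)) + 0.5) * w
        for i in graph.chrom_segments(chrom):
            s = graph.segments[i]
            lo = int(np.searchsorted(mids, s.start))
            hi = int(np.searchsorted(mids, s.end))
            idx = np.arange(lo, hi)
            sub = vals[lo:hi]
            ok = ~np.isnan(sub)
            s.bins = idx[ok]
            s.nbins = int(ok.sum())
            if s.nbins:
                s.rho = float(sub[ok].mean())
                s.scale_b = max(1.0, float(np.sqrt(max(s.rho, 0.0))))
            else:
                s.rho, s.scale_b = None, 1.0


def validate_balance(graph: GenomeGraph) -> list[tuple[int, str, int, int]]:
    """Junction-balance violations: (segment, side, kappa(v), edge sum).

    Empty iff every interstitial vertex satisfies mass balance on both its
    incoming and outgoing side (checking the '+' strand covers the '-'
    strand by skew symmetry of the shared-CN representation).
    """
    bad = []
    for i, s in enumerate(graph.segments):
        if s.cn is None:
            raise ValueError("copy numbers not assigned")
        for side in (LEFT, RIGHT):
            tot = 0
            for eid, m in graph.incident(i, side):
                e = graph.edges[eid]
                if e.cn is None:
                    raise ValueError("edge copy numbers not assigned")
                tot += m * e.cn
            if tot != s.cn:
                bad.append((i, side, s.cn, tot))
    return bad


def merge_reference_adjacent(graph: GenomeGraph, profile=None) -> GenomeGraph:
    """Fuse adjacent segments whose interface carries no fitted signal.

    Two reference-adjacent segments merge when no loose-end or variant edge
    with CN > 0 attaches at their shared boundary.  Zero-CN variant edges at
    a dropped boundary are removed.  J, rho and b are recomputed on the
    fused segments when a depth profile is supplied.
    """
    drop: set[tuple[str, int]] = set()  # boundaries to remove, (chrom, pos)
    for chrom in graph.chrom_lengths:
        idx = list(graph.chrom_segments(chrom))
        for i, j in zip(idx[:-1], idx[1:]):
            blocking = False
            for seg, side in ((i, RIGHT), (j, LEFT)):
                for eid, _ in graph.incident(seg, side):
                    e = graph.edges[eid]
                    if e.kind in ("loose", "variant") and (e.cn or 0) > 0:
                        blocking = True
            if not blocking and graph.segments[i].cn == graph.segments[j].cn:
                drop.add((chrom, graph.segments[j].start))

    if not drop:
        return graph.copy()

    # new segmentation
    new_bps = {c: [p for p in bl if (c, p) not in drop]
               for c, bl in graph.internal_boundaries().items()}
    segments: list[Segment] = []
    seg_map: dict[int, int] = {}  # old seg index -> new seg index
    for chrom in graph.chrom_lengths:
        bl = [0] + new_bps.get(chrom, []) + [graph.chrom_lengths[chrom]]
        first_new = len(segments)
        for a, b in zip(bl[:-1], bl[1:]):
            segments.append(Segment(chrom, a, b))
        for i in graph.chrom_segments(chrom):
            s = graph.segments[i]
            k = bisect.bisect_right([x.start for x in segments[first_new:]], s.start) - 1
            seg_map[i] = first_new + k
            segments[first_new + k].cn = s.cn

    new = GenomeGraph(graph.chrom_lengths, segments, [], dict(graph.meta))
    edges: list[Edge] = []
    # loose skeleton on the new segmentation
    for chrom in graph.chrom_lengths:
        idx = list(new.chrom_segments(chrom))
        for i in idx:
            edges.append(Edge("loose", i, LEFT, cn=0))
            edges.append(Edge("loose", i, RIGHT, cn=0))
    # carry over CN of surviving boundary-attached edges
    loose_cn: dict[tuple[int, str], int] = {}
    for e in graph.edges:
        if e.kind == "loose":
            tgt = (seg_map[e.seg1], e.side1)
            old_bnd = graph.breakend(e.seg1, e.side1)
            new_bnd = new.breakend(*tgt)
            if old_bnd.pos == new_bnd.pos:  # boundary survived
                loose_cn[tgt] = max(loose_cn.get(tgt, 0), e.cn or 0)
    for ed in edges:
        if ed.kind == "loose":
            ed.cn = loose_cn.get((ed.seg1, ed.side1), 0)
    for e in graph.edges:
        if e.kind == "telomere":
            edges.append(Edge("telomere", seg_map[e.seg1], e.side1, cn=e.cn))
        elif e.kind == "variant":
            b1, b2 = graph.breakend(e.seg1, e.side1), graph.breakend(e.seg2, e.side2)
            if (b1.chrom, b1.pos) in drop or (b2.chrom, b2.pos) in drop:
                if (e.cn or 0) > 0:  # cannot happen: CN>0 blocks the merge
                    raise AssertionError("merged away a fitted variant edge")
                logger.debug("dropping zero-CN variant edge at merged boundary")
                continue
            edges.append(Edge("variant",
                              new.seg_index_at(b1.chrom, b1.pos, b1.side), b1.side,
                              new.seg_index_at(b2.chrom, b2.pos, b2.side), b2.side,
                              cn=e.cn, forced=e.forced, name=e.name,
                              tier=e.tier, mechanism=e.mechanism))
    # reference edges between consecutive new segments
    for chrom in graph.chrom_lengths:
        idx = list(new.chrom_segments(chrom))
        for i, j in zip(idx[:-1], idx[1:]):
            # reference CN restored from balance: kappa(v) minus other inflow
            edges.append(Edge("reference", i, RIGHT, j, LEFT))

    out = GenomeGraph(graph.chrom_lengths, segments, edges, dict(graph.meta))
    # set reference CN from balance at each surviving interface
    for eid, e in out.edges_of_kind("reference"):
        j = e.seg2
        other = 0
        for oid, m in out.incident(j, LEFT):
            oe = out.edges[oid]
            if oid != eid and oe.cn is not None:
                other += m * oe.cn
        e.cn = out.segments[j].cn - other
        if e.cn < 0:
            raise AssertionError("negative reference CN after merge")
    if profile is not None:
        attach_depth(out, profile)
    return out


def insert_boundaries(graph: GenomeGraph, extra: dict[str, list[int]],
                      profile=None) -> GenomeGraph:
    """Split segments at additional boundaries, preserving copy numbers.

    New interfaces receive a reference edge carrying the parent segment's CN
    and zero-CN loose-end placeholders, so balance is preserved.
    """
    old_b = graph.internal_boundaries()
    bps = {c: sorted(set(old_b.get(c, [])) |
                     {int(p) for p in extra.get(c, [])
                      if 0 < int(p) < graph.chrom_lengths[c]})
           for c in graph.chrom_lengths}
    segments: list[Segment] = []
    for chrom in graph.chrom_lengths:
        bl = [0] + bps[chrom] + [graph.chrom_lengths[chrom]]
        for a, b in zip(bl[:-1], bl[1:]):
            segments.append(Segment(chrom, a, b))
    new = GenomeGraph(graph.chrom_lengths, segments, [], dict(graph.meta))
    # copy CN down from covering parent
    for i, s in enumerate(new.segments):
        lo, hi = graph._chrom_range[s.chrom]
        k = bisect.bisect_right(graph._starts[s.chrom], s.start) - 1
        parent = graph.segments[lo + k]
        s.cn = parent.cn
    edges: list[Edge] = []
    old_bset = {(graph.segments[i].chrom, graph.segments[i].start)
                for c in graph.chrom_lengths for i in list(graph.chrom_segments(c))[1:]}
    for e in graph.edges:
        if e.kind == "loose" or e.kind == "telomere":
            b = graph.breakend(e.seg1, e.side1)
            edges.append(replace(e, seg1=new.seg_index_at(b.chrom, b.pos, e.side1)))
        elif e.kind == "variant":
            b1, b2 = graph.breakend(e.seg1, e.side1), graph.breakend(e.seg2, e.side2)
            edges.append(replace(e,
                                 seg1=new.seg_index_at(b1.chrom, b1.pos, b1.side),
                                 seg2=new.seg_index_at(b2.chrom, b2.pos, b2.side)))
    for chrom in graph.chrom_lengths:
        idx = list(new.chrom_segments(chrom))
        for i, j in zip(idx[:-1], idx[1:]):
            s = new.segments[j]
            if (s.chrom, s.start) in old_bset:
                old_j = graph.seg_index_at(s.chrom, s.start, LEFT)
                old_ref = next(graph.edges[eid] for eid, _ in graph.incident(old_j, LEFT)
                               if graph.edges[eid].kind == "reference")
                edges.append(Edge("reference", i, RIGHT, j, LEFT, cn=old_ref.cn))
            else:
                edges.append(Edge("reference", i, RIGHT, j, LEFT, cn=s.cn))
                edges.append(Edge("loose", i, RIGHT, cn=0))
                edges.append(Edge("loose", j, LEFT, cn=0))
    out = GenomeGraph(graph.chrom_lengths, segments, edges, dict(graph.meta))
    if profile is not None:
        attach_depth(out, profile)
    return out
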