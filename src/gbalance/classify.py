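"""Mechanistic annotation of breakends and loose ends.

Classifications: reciprocal (an opposite-orientation breakend within
10 kb), copy-altered vs copy-neutral (fitted CN differs across the
breakend), putative NAHR (long near-identical homology tracts flank both
breakends with consistent strand geometry), AHR-UPD vs P-UPD (uniparental
disomy reached by homolog crossover vs progressive loss-then-gain), and
telomere-repeat content (G-rich vs C-rich repeat arrays, the forward-
strand G-rich signature marking candidate neotelomeres).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .graph import LEFT, Breakend, GenomeGraph

logger = logging.getLogger(__name__)

GRTR_UNIT = "TTAGGG"
CRTR_UNIT = "CCCTAA"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class UpdCall:
    chrom: str
    start: int
    end: int
    mechanism: str  # 'AHR_UPD' | 'P_UPD'

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class LooseEndAnnotation:
    breakend: Breakend
    kind: str                  # 'loose' | 'junction'
    cn: int
    reciprocal: bool = False
    copy_altered: bool = False
    mapping_class: str = ""    # input label, not computed from reads
    nahr: bool = False
    telomere_class: str = ""


def classify_reciprocal(breakends: list[Breakend],
                        radius: int = 10_000) -> list[bool]:
    """Flag breakends with an opposite-orientation partner within radius."""
    out = []
    for i, b in enumerate(breakends):
        hit = any(j != i and o.chrom == b.chrom and o.strand != b.strand
                  and abs(o.pos - b.pos) <= radius
                  for j, o in enumerate(breakends))
        out.append(hit)
    return out


def classify_copy(breakend: Breakend, graph: GenomeGraph,
                  ploidy: float | None = None) -> str:
    """'copy_altered' iff fitted total CN differs across the breakend.

    At a chromosome end the single flanking segment is compared against the
    rounded ploidy baseline (logged, since only one side exists).
    """
    chrom, pos = breakend.chrom, breakend.pos
    L = graph.chrom_lengths[chrom]
    if pos in (0, L):
        i = graph.seg_index_at(chrom, pos, LEFT if pos == 0 else "R")
        base = round(ploidy if ploidy is not None
                     else graph.meta.get("ploidy", 2.0))
        logger.info("breakend at chromosome end %s:%d compared to ploidy", chrom, pos)
        return ("copy_altered" if graph.segments[i].cn != base
                else "copy_neutral")
    try:
        left = graph.segments[graph.seg_index_at(chrom, pos, "R")].cn
        right = graph.segments[graph.seg_index_at(chrom, pos, "L")].cn
    except KeyError:
        # breakend interior to a merged uniform-CN segment
        return "copy_neutral"
    return "copy_altered" if left != right else "copy_neutral"


def _tract_near(pos: int, tract_start: int, tract: int, radius: int) -> bool:
    """Distance from a breakend to a homology tract interval <= radius."""
    lo, hi = tract_start, tract_start + tract
    return lo - radius <= pos <= hi + radius


def nahr_pair(b1: Breakend, b2: Breakend, homology: pd.DataFrame,
              radius: int = 10_000, tract: int = 500) -> bool:
    """Do two breakends bracket a registered homologous tract pair?

    Requires a homology row with one tract within `radius` of each breakend
    and strand geometry consistent with a crossover producing this
    breakend pair: a direct repeat ('+') pairs opposite-orientation
    breakends, an inverted repeat ('-') pairs same-orientation breakends.
    """
    want = "+" if b1.strand != b2.strand else "-"
    for r in homology.itertuples():
        if r.strand2 != want:
            continue
        fwd = (r.chrom1 == b1.chrom and _tract_near(b1.pos, r.pos1, tract, radius)
               and r.chrom2 == b2.chrom and _tract_near(b2.pos, r.pos2, tract, radius))
        rev = (r.chrom1 == b2.chrom and _tract_near(b2.pos, r.pos1, tract, radius)
               and r.chrom2 == b1.chrom and _tract_near(b1.pos, r.pos2, tract, radius))
        if fwd or rev:
            return True
    return False


def annotate_nahr(junctions, loose_breakends, homology: pd.DataFrame,
                  radius: int = 10_000, tract: int = 500):
    """NAHR flags for junctions and NAHR-consistent loose-end pairs.

    Returns (junction_flags, loose_pairs): one bool per junction (its own
    breakend pair satisfies the homology geometry) and the list of loose
    breakend index pairs that do.
    """
    jflags = [nahr_pair(j.b1, j.b2, homology, radius, tract) for j in junctions]
    pairs = []
    for i in range(len(loose_breakends)):
        for k in range(i + 1, len(loose_breakends)):
            if nahr_pair(loose_breakends[i], loose_breakends[k],
                         homology, radius, tract):
                pairs.append((i, k))
    return jflags, pairs


def classify_upd(segments) -> list[UpdCall]:
    """Label UPD segments (total CN 2, minor CN 0) by mechanism.

    A UPD segment reference-adjacent to a segment of total CN 2 without
    LOH (minor CN 1) is AHR-UPD; otherwise P-UPD.  `segments` is an
    ordered per-chromosome list of (chrom, start, end, total, minor, ...)
    tuples covering the genome.
    """
    calls = []
    for i, seg in enumerate(segments):
        chrom, start, end, total, minor = seg[:5]
        if not (total == 2 and minor == 0):
            continue
        mech = "P_UPD"
        for j in (i - 1, i + 1):
            if 0 <= j < len(segments):
                nb = segments[j]
                if nb[0] == chrom and nb[3] == 2 and nb[4] == 1 \
                        and (nb[2] == start or nb[1] == end):
                    mech = "AHR_UPD"
        calls.append(UpdCall(chrom, start, end, mech))
    return calls


def _rotations(unit: str, copies: int = 3) -> list[str]:
    return [(unit[k:] + unit[:k]) * copies for k in range(len(unit))]


def classify_telomere_repeat(seq: str, strand: str = "+") -> str:
    """Telomere-repeat class of a breakend-associated contig sequence.

    Matches three tandem copies of the G-rich (TTAGGG) or C-rich (CCCTAA)
    telomere hexamer in any of the six cyclic rotation frames, on the loose
    end's forward strand.  A sequence matching both panels is inconsistent
    and raises.
    """
    seq = seq.upper()
    if strand == "-":
        seq = seq.translate(_COMP)[::-1]
    if len(seq) < 18:
        logger.warning("sequence shorter than 18 bp; telomere class negative")
        return "negative"
    g = any(pat in seq for pat in _rotations(GRTR_UNIT))
    c = any(pat in seq for pat in _rotations(CRTR_UNIT))
    if g and c:
        raise ValueError("sequence matches both G-rich and C-rich telomere "
                         "repeat panels; inconsistent orientation")
    if g:
        return "GRTR_pos"
    if c:
        return "CRTR_pos"
    return "negative"


def annotate_graph(graph: GenomeGraph, homology: pd.DataFrame | None = None,
                   contigs: dict[str, str] | None = None,
                   mapping_class: dict | None = None) -> pd.DataFrame:
    """Annotation table for all fitted breakends of a balanced graph.

    `contigs` maps "chrom:pos:strand" keys to breakend-associated assembly
    sequences; `mapping_class` likewise supplies externally derived mapping
    labels (read-level classification is out of scope here).
    """
    items: list[LooseEndAnnotation] = []
    juncs = []
    for _, e in graph.edges_of_kind("variant"):
        if (e.cn or 0) > 0:
            b1 = graph.breakend(e.seg1, e.side1)
            b2 = graph.breakend(e.seg2, e.side2)
            juncs.append((b1, b2, e))
            items.append(LooseEndAnnotation(b1, "junction", e.cn))
            items.append(LooseEndAnnotation(b2, "junction", e.cn))
    loose = [(b, cn) for b, cn in graph.loose_ends()]
    for b, cn in loose:
        items.append(LooseEndAnnotation(b, "loose", cn))

    flags = classify_reciprocal([a.breakend for a in items])
    for a, f in zip(items, flags):
        a.reciprocal = f
        a.copy_altered = classify_copy(a.breakend, graph) == "copy_altered"
        key = f"{a.breakend.chrom}:{a.breakend.pos}:{a.breakend.strand}"
        if mapping_class:
            a.mapping_class = mapping_class.get(key, "")
        if contigs and key in contigs:
            a.telomere_class = classify_telomere_repeat(
                contigs[key], a.breakend.strand)
    if homology is not None and len(homology):
        jf = {id(e): nahr_pair(b1, b2, homology) for b1, b2, e in juncs}
        k = 0
        for _, _, e in juncs:
            items[k].nahr = items[k + 1].nahr = jf[id(e)]
            k += 2
        lb = [b for b, _ in loose]
        _, pairs = annotate_nahr([], lb, homology)
        for i, j in pairs:
            items[len(juncs) * 2 + i].nahr = True
            items[len(juncs) * 2 + j].nahr = True
    return pd.DataFrame([{
        "chrom": a.breakend.chrom, "pos": a.breakend.pos,
        "strand": a.breakend.strand, "kind": a.kind, "cn": a.cn,
        "reciprocal": a.reciprocal, "copy_altered": a.copy_altered,
        "mapping_class": a.mapping_class, "nahr": a.nahr,
        "telomere_class": a.telomere_class} for a in items])
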