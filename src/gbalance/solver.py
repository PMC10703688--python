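"""Total copy-number fitting by mixed-integer programming.

The model: given a genome graph G and purity/ploidy-transformed depth x,
assign a non-negative integer CN kappa to every vertex and edge minimizing

    f(G, kappa, x, J, lambda) =
        sum_v |J(v)|/b(v) * |rho(v) - kappa(v)|  +  lambda * #fitted loose ends

subject to junction balance (the CN of each vertex equals the sum of its
incoming edge CNs and the sum of its outgoing edge CNs), skew symmetry,
non-negativity and integrality, with user-specified forced edges held at
CN >= 1.  rho(v) is the mean transformed depth over the bins J(v) of the
segment and b(v) = max(1, sqrt(rho(v))) is a Laplace noise scale.  The
absolute deviations are linearized with auxiliary variables and the
loose-end count with big-M indicator binaries, which keeps the program a
linear MIP; it is solved exactly with HiGHS.

`fit_pipeline` wraps three MIP iterations: (1) changepoint breakpoints
plus large high-confidence junctions, with clusters of reciprocal
junctions force-incorporated; (2) rescue of low-confidence junctions whose
breakends fall within 10 kb (same strand) of a fitted loose end; (3) a
refit adding a bounded continuous per-chromosome depth offset that guards
against hypersegmentation from small purity/ploidy inaccuracies.  After
each iteration, reference-adjacent segments with no fitted interface
signal are merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import (LEFT, RIGHT, GenomeGraph, Junction, attach_depth,
                    build_graph, merge_reference_adjacent)
from .profiles import DepthProfile
from .segmentation import segment_depth

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tunable parameters of the balance fit."""

    lam: float = 15.0             # loose-end penalty
    cn_cap: int | None = None     # max CN considered; None -> automatic
    offset_bound: float = 0.3     # per-chromosome offset limit, CN units
    time_limit: float = 120.0     # seconds per MIP solve
    mip_gap: float = 0.0          # relative optimality gap tolerance
    seg_penalty_mult: float = 4.0  # changepoint BIC penalty multiplier
    seg_min_width: int = 3        # minimum segment width, bins
    snap_tol: int = 1000          # breakend snapping tolerance, bp
    rescue_radius: int = 10_000   # loose-end rescue radius, bp
    recip_radius: int = 10_000    # reciprocal-cluster radius, bp
    min_span: int = 10_000        # iteration-1 junction span filter, bp
    tie_break: float = 1e-5       # per-unit reward for variant-edge CN

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0 <= self.offset_bound <= 0.5:
            raise ValueError("offset_bound must be in [0, 0.5]")


@dataclass
class FitResult:
    graph: GenomeGraph
    objective: float
    offsets: dict[str, float] = field(default_factory=dict)
    loose_ends: list = field(default_factory=list)
    status: str = "optimal"
    mip_gap: float = 0.0


def auto_cap(graph: GenomeGraph, tau: float) -> int:
    rhos = [s.rho for s in graph.segments if s.rho is not None]
    top = math.ceil(max(rhos)) + 1 if rhos else 0
    return max(10, math.ceil(3 * tau), top)


def laplace_objective(graph: GenomeGraph, lam: float,
                      offsets: dict[str, float] | None = None) -> float:
    """Evaluate the objective f on an assigned graph."""
    tot = 0.0
    for s in graph.segments:
        if s.cn is None:
            raise ValueError("copy numbers not assigned")
        if s.nbins and s.rho is not None:
            d = s.rho - s.cn
            if offsets:
                d -= offsets.get(s.chrom, 0.0)
            tot += s.weight * abs(d)
    tot += lam * graph.n_fitted_loose()
    return tot


def balance_total(graph: GenomeGraph, config: FitConfig,
                  use_offsets: bool = False,
                  tau: float | None = None) -> FitResult:
    """Solve the junction-balance MIP on a depth-annotated graph."""
    segs = graph.segments
    n_seg = len(segs)
    n_edge = len(graph.edges)
    cap = config.cn_cap or auto_cap(graph, tau or 2.0)

    # variable layout: [seg | edge | resid | z_loose | offsets]
    resid_segs = [i for i, s in enumerate(segs) if s.weight > 0]
    loose_ids = [i for i, e in enumerate(graph.edges) if e.kind == "loose"]
    chroms = [c for c in graph.chrom_lengths] if use_offsets else []
    i_edge = n_seg
    i_res = i_edge + n_edge
    i_z = i_res + len(resid_segs)
    i_off = i_z + len(loose_ids)
    n_var = i_off + len(chroms)
    res_of = {s: i_res + k for k, s in enumerate(resid_segs)}
    z_of = {e: i_z + k for k, e in enumerate(loose_ids)}
    off_of = {c: i_off + k for k, c in enumerate(chroms)}

    lb = np.zeros(n_var)
    ub = np.full(n_var, float(cap))
    integrality = np.zeros(n_var)
    integrality[:i_res] = 1
    ub[i_res:i_z] = np.inf
    ub[i_z:i_off] = 1.0
    integrality[i_z:i_off] = 1
    if chroms:
        lb[i_off:] = -config.offset_bound
        ub[i_off:] = config.offset_bound
    for eid, e in enumerate(graph.edges):
        if e.forced:
            lb[i_edge + eid] = 1.0

    c = np.zeros(n_var)
    for i in resid_segs:
        c[res_of[i]] = segs[i].weight
    for e in loose_ids:
        c[z_of[e]] = config.lam
    # tie-break: prefer routing flow through junctions over reference edges,
    # so copy-neutral junctions (objective-indifferent) are incorporated
    for eid, e in enumerate(graph.edges):
        if e.kind == "variant":
            c[i_edge + eid] = -config.tie_break

    rows, cols, vals, clo, cup = [], [], [], [], []
    r = 0
    for i in range(n_seg):
        for side in (LEFT, RIGHT):
            rows.append(r); cols.append(i); vals.append(1.0)
            for eid, m in graph.incident(i, side):
                rows.append(r); cols.append(i_edge + eid); vals.append(-float(m))
            clo.append(0.0); cup.append(0.0)
            r += 1
    for i in resid_segs:
        s = segs[i]
        ocol = off_of.get(s.chrom)
        # resid + kappa (+ offset) >= rho
        rows += [r, r]; cols += [res_of[i], i]; vals += [1.0, 1.0]
        if ocol is not None:
            rows.append(r); cols.append(ocol); vals.append(1.0)
        clo.append(s.rho); cup.append(np.inf); r += 1
        # resid - kappa (- offset) >= -rho
        rows += [r, r]; cols += [res_of[i], i]; vals += [1.0, -1.0]
        if ocol is not None:
            rows.append(r); cols.append(ocol); vals.append(-1.0)
        clo.append(-s.rho); cup.append(np.inf); r += 1
    for e in loose_ids:
        rows += [r, r]; cols += [i_edge + e, z_of[e]]; vals += [1.0, -float(cap)]
        clo.append(-np.inf); cup.append(0.0); r += 1

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    res = milp(c, constraints=LinearConstraint(A, clo, cup),
               integrality=integrality, bounds=Bounds(lb, ub),
               options={"time_limit": config.time_limit,
                        "mip_rel_gap": config.mip_gap})
    if res.x is None:
        forced = [graph.edges[eid].name or str(eid)
                  for eid in range(n_edge) if graph.edges[eid].forced]
        raise RuntimeError(
            f"balance MIP infeasible or failed (status {res.status}: "
            f"{res.message}); forced edges: {forced or 'none'}")
    status = "optimal" if res.status == 0 else "incumbent"
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    if status != "optimal":
        logger.warning("MIP stopped before proven optimality (gap %.3g)", gap)

    out = graph.copy()
    x = res.x
    for i, s in enumerate(out.segments):
        s.cn = int(round(x[i]))
    for eid, e in enumerate(out.edges):
        e.cn = int(round(x[i_edge + eid]))
    offsets = {ch: float(x[off_of[ch]]) for ch in chroms}
    obj = laplace_objective(out, config.lam, offsets if use_offsets else None)
    return FitResult(out, obj, offsets, out.loose_ends(), status, gap)


def force_reciprocal_clusters(junctions: list[Junction],
                              radius: int = 10_000) -> set[int]:
    """Indices of junctions in reciprocal clusters.

    A cluster requires breakends from two distinct junctions within
    `radius` on the same chromosome with opposite orientation.
    """
    forced: set[int] = set()
    for i in range(len(junctions)):
        for j in range(i + 1, len(junctions)):
            hit = False
            for b1 in junctions[i].breakends:
                for b2 in junctions[j].breakends:
                    if (b1.chrom == b2.chrom and b1.strand != b2.strand
                            and abs(b1.pos - b2.pos) <= radius):
                        hit = True
            if hit:
                forced.add(i)
                forced.add(j)
    return forced


def _near_loose(j: Junction, loose, radius: int) -> bool:
    for b, _ in loose:
        for jb in j.breakends:
            if (jb.chrom == b.chrom and jb.strand == b.strand
                    and abs(jb.pos - b.pos) <= radius):
                return True
    return False


def fit_pipeline(depth: DepthProfile, junctions: list[Junction],
                 config: FitConfig | None = None) -> FitResult:
    """Three-iteration junction-balance fit; returns the final merged graph."""
    config = config or FitConfig()

    hi = [j for j in junctions
          if j.tier == "high" and (j.span is None or j.span > config.min_span)]
    lo = [j for j in junctions if j.tier == "low"]
    for k in force_reciprocal_clusters(hi, config.recip_radius):
        hi[k].forced = True

    bps = segment_depth(depth, config.seg_penalty_mult, config.seg_min_width)

    def solve(bounds, juncs, offsets=False):
        g = build_graph(depth.chrom_lengths, bounds, juncs, config.snap_tol)
        attach_depth(g, depth)
        r = balance_total(g, config, use_offsets=offsets, tau=depth.tau)
        merged = merge_reference_adjacent(r.graph, depth)
        merged.meta.update({"purity": depth.alpha, "ploidy": depth.tau,
                            "lambda": config.lam})
        return r, merged

    r1, g1 = solve(bps, hi)

    rescued = [j for j in lo if _near_loose(j, g1.loose_ends(), config.rescue_radius)]
    if rescued:
        logger.info("iteration 2 rescues %d low-confidence junctions", len(rescued))
        _, g2 = solve(g1.internal_boundaries(), hi + rescued)
    else:
        g2 = g1

    r3, g3 = solve(g2.internal_boundaries(), hi + rescued, offsets=True)
    obj = laplace_objective(g3, config.lam, r3.offsets)
    g3.meta["objective"] = obj
    g3.meta["offsets"] = r3.offsets
    return FitResult(g3, obj, r3.offsets, g3.loose_ends(), r3.status, r3.mip_gap)
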