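"""Synthetic tumor/normal SV-profile generator.

Simulates a phased diploid genome, rearranges its haplotypes with
deletion/duplication/inversion/translocation events (plus NAHR junctions
between registered homologous position pairs, allelic-homologous-
recombination crossovers, and progressive loss-then-gain UPD), derives
ground-truth phased copy number by counting segment occurrences in the
haplotype walks, and emits Poisson read depth and allelic SNP counts.

Junction detection is imperfect: each true junction is reported with
probability proportional to tumor purity, emulating the sensitivity of a
short-read SV caller under stromal admixture; undetected junction
breakends are the ground truth for loose-end benchmarks.

All randomness flows through one numpy Generator, so a seed fixes the
full output stream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import Breakend, Junction
from .profiles import DepthProfile, SnpCounts, transform_depth

logger = logging.getLogger(__name__)


def default_chroms() -> dict[str, int]:
    return {f"chr{i}": 5_000_000 for i in range(1, 5)}


@dataclass
class SimConfig:
    """Study conditions of the simulation."""

    chrom_lengths: dict[str, int] = field(default_factory=default_chroms)
    bin_width: int = 1000
    read_length: int = 150
    snp_density: float = 1.0 / 1500
    n_junctions: int = 50
    event_weights: dict[str, float] = field(default_factory=lambda: {
        "del": 0.40, "dup": 0.30, "inv": 0.15, "tra": 0.10, "tra_recip": 0.05})
    sv_size_range: tuple[float, float] = (1e4, 2e6)   # log-uniform, bp
    inv_flank_range: tuple[float, float] = (1e4, 2e5)  # inversion flank loss
    nahr_prevalence: float = 0.02       # fraction of junctions that are NAHR
    n_homology_pairs: int = 12
    homology_tract: int = 600           # planted repeat tract length, bp
    homology_identity: float = 0.98
    homology_sep_range: tuple[float, float] = (1e5, 2e6)
    n_ahr_events: int = 0
    n_pupd_events: int = 0
    pupd_size_range: tuple[float, float] = (5e5, 2e6)
    pupd_collar_range: tuple[float, float] = (2e3, 3e5)
    purity: float | None = None         # None -> Uniform(0.5, 0.95)
    ploidy: float | None = None         # None -> Uniform(1.8, 4.2)
    ploidy_tol: float = 0.3
    tumor_coverage: float = 80.0        # target per-base depth
    normal_coverage: float = 40.0
    bias_sigma: float = 0.1             # lognormal per-bin bias sd
    detection_s: float = 1.0            # detection rate = s * purity
    withhold_frac: float | None = None  # fixed withholding overrides s*purity
    frac_high_conf: float = 0.85
    with_sequence: bool = False
    noiseless: bool = False  # emit exact means (no Poisson, no bias)
    # keep background SVs out of AHR/P-UPD territory; emulates genome-scale
    # collision rates when mechanism events cover much of a desk-scale genome
    events_avoid_occupied: bool = False

    @property
    def haploid_size(self) -> int:
        return sum(self.chrom_lengths.values())


# walk elements: (chrom, start, end, orient, hap); traversal order is list
# order, a '-' element is traversed end -> start.
Elem = tuple[str, int, int, str, str]


def _elem_len(e: Elem) -> int:
    return e[2] - e[1]


def _rc_elems(elems: list[Elem]) -> list[Elem]:
    return [(c, s, t, "-" if o == "+" else "+", h)
            for c, s, t, o, h in reversed(elems)]


def _cut(e: Elem, pos: int) -> tuple[Elem, Elem]:
    """Split one element at reference position pos; traversal order."""
    c, s, t, o, h = e
    if not s < pos < t:
        raise ValueError("cut outside element")
    if o == "+":
        return (c, s, pos, o, h), (c, pos, t, o, h)
    return (c, pos, t, o, h), (c, s, pos, o, h)


def _end_bnd(e: Elem) -> Breakend:
    """Breakend abutting the 3' terminus of a traversed element."""
    c, s, t, o, _ = e
    return Breakend(c, t, "+") if o == "+" else Breakend(c, s, "-")


def _start_bnd(e: Elem) -> Breakend:
    """Breakend abutting the 5' terminus of a traversed element."""
    c, s, t, o, _ = e
    return Breakend(c, s, "-") if o == "+" else Breakend(c, t, "+")


@dataclass
class SimGenome:
    chrom_lengths: dict[str, int]
    snps: dict[str, np.ndarray]
    homology: pd.DataFrame       # chrom1,pos1,chrom2,pos2,strand2,identity
    sequences: dict[str, str] | None = None


@dataclass
class UpdEvent:
    chrom: str
    start: int
    end: int
    mechanism: str  # 'AHR_UPD' | 'P_UPD'


@dataclass
class SimTruth:
    genome: SimGenome
    walks: list[list[Elem]]
    junctions: list[Junction]        # with CN >= 1 in the final karyotype
    junction_cn: list[int]
    detected: np.ndarray             # bool per junction
    tiers: list[str]
    upd_events: list[UpdEvent]
    alpha: float
    tau_target: float
    tau_realized: float

    def detected_junctions(self) -> list[Junction]:
        return [replace(j, tier=t) for j, t, d in
                zip(self.junctions, self.tiers, self.detected) if d]

    def withheld_junctions(self) -> list[Junction]:
        return [j for j, d in zip(self.junctions, self.detected) if not d]

    def breakends(self, junctions=None) -> list[Breakend]:
        js = self.junctions if junctions is None else junctions
        return [b for j in js for b in j.breakends]

    def atoms(self, chrom: str):
        """Disjoint intervals with constant phased CN: (bounds, cnA, cnB)."""
        cuts = {0, self.genome.chrom_lengths[chrom]}
        for w in self.walks:
            for c, s, t, _, _ in w:
                if c == chrom:
                    cuts.update((s, t))
        bounds = np.array(sorted(cuts))
        mids = (bounds[:-1] + bounds[1:]) / 2
        cn = {"A": np.zeros(len(mids), dtype=int),
              "B": np.zeros(len(mids), dtype=int)}
        for w in self.walks:
            for c, s, t, _, h in w:
                if c == chrom:
                    cn[h][(mids > s) & (mids < t)] += 1
        return bounds, cn["A"], cn["B"]

    def cn_bins(self, chrom: str, bin_width: int):
        """(total, hapA, hapB) length-weighted mean CN per bin."""
        L = self.genome.chrom_lengths[chrom]
        nb = math.ceil(L / bin_width)
        out = [np.zeros(nb), np.zeros(nb)]
        bounds, a, b = self.atoms(chrom)
        for vals, arr in ((a, out[0]), (b, out[1])):
            for (s, t, v) in zip(bounds[:-1], bounds[1:], vals):
                if v == 0:
                    continue
                fb, lb = int(s // bin_width), int((t - 1) // bin_width)
                for k in range(fb, lb + 1):
                    lo = max(s, k * bin_width)
                    hi = min(t, (k + 1) * bin_width)
                    arr[k] += v * (hi - lo)
        wlast = L - (nb - 1) * bin_width
        widths = np.full(nb, float(bin_width))
        widths[-1] = wlast
        hapA, hapB = out[0] / widths, out[1] / widths
        return hapA + hapB, hapA, hapB


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> SimGenome:
    """Random phased reference scaffold with het SNPs and planted repeats."""
    snps = {}
    for chrom, L in config.chrom_lengths.items():
        n = rng.binomial(L, config.snp_density)
        snps[chrom] = np.sort(rng.choice(L, size=n, replace=False))

    rows = []
    chroms = list(config.chrom_lengths)
    tract = config.homology_tract
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(config.n_homology_pairs):
        for _attempt in range(100):
            chrom = chroms[rng.integers(len(chroms))]
            L = config.chrom_lengths[chrom]
            lo, hi = config.homology_sep_range
            sep = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if sep <= 10_000 or sep + 2 * tract + 200_000 >= L:
                continue
            p1 = int(rng.integers(50_000, L - sep - tract - 50_000))
            p2 = p1 + sep
            spans = [(p1, p1 + tract), (p2, p2 + tract)]
            if any(s < te and ts < e for s, e in spans for ts, te in taken[chrom]):
                continue
            taken[chrom].extend(spans)
            rows.append((chrom, p1, chrom, p2, "+", config.homology_identity))
            break
    hom = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2",
                                      "strand2", "identity"])

    seqs = None
    if config.with_sequence:
        seqs = {}
        bases = np.array(list("ACGT"))
        for chrom, L in config.chrom_lengths.items():
            arr = rng.integers(0, 4, size=L)
            seqs[chrom] = arr
        for _, r in hom.iterrows():
            arr = seqs[r.chrom2]
            src = seqs[r.chrom1][r.pos1:r.pos1 + tract].copy()
            mut = rng.random(tract) > config.homology_identity
            src[mut] = (src[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            arr[r.pos2:r.pos2 + tract] = src
        seqs = {c: "".join(bases[a]) for c, a in seqs.items()}
    return SimGenome(dict(config.chrom_lengths), snps, hom, seqs)


def _walk_find(walks, chrom, lo, hi, orient="+"):
    """(walk idx, elem idx) of elements covering [lo, hi] on chrom."""
    out = []
    for wi, w in enumerate(walks):
        for ei, e in enumerate(w):
            if e[0] == chrom and e[3] == orient and e[1] < lo and hi < e[2]:
                out.append((wi, ei))
    return out


def _apply_del(walks, wi, ei, a, b, mech, junctions, name):
    w = walks[wi]
    e = w[ei]
    p1, rest = _cut(e, a)
    mid, p2 = _cut(rest, b)
    junctions.append(Junction(_end_bnd(p1), _start_bnd(p2),
                              mechanism=mech, name=name))
    walks[wi] = w[:ei] + [p1, p2] + w[ei + 1:]


def _apply_dup(walks, wi, ei, a, b, junctions, name):
    w = walks[wi]
    e = w[ei]
    p1, rest = _cut(e, a)
    mid, p2 = _cut(rest, b)
    junctions.append(Junction(_end_bnd(mid), _start_bnd(mid),
                              mechanism="other", name=name))
    walks[wi] = w[:ei] + [p1, mid, mid, p2] + w[ei + 1:]


def _apply_inv(walks, wi, ei, a, b, c, d, junctions, name):
    """Somatic inversion with flanking losses: [a,d) -> rc([b,c))."""
    w = walks[wi]
    e = w[ei]
    p1, rest = _cut(e, a)
    _, rest = _cut(rest, b)
    mid, rest = _cut(rest, c)
    _, p2 = _cut(rest, d)
    inv = _rc_elems([mid])
    junctions.append(Junction(_end_bnd(p1), _start_bnd(inv[0]),
                              mechanism="other", name=name + "a"))
    junctions.append(Junction(_end_bnd(inv[-1]), _start_bnd(p2),
                              mechanism="other", name=name + "b"))
    walks[wi] = w[:ei] + [p1] + inv + [p2] + w[ei + 1:]


def _apply_tra(walks, wi1, ei1, a, wi2, ei2, b, junctions, name,
               reciprocal: bool):
    """Translocation: unbalanced keeps only the derivative chromosome."""
    w1, w2 = walks[wi1], walks[wi2]
    x1, y1 = _cut(w1[ei1], a)
    x2, y2 = _cut(w2[ei2], b)
    junctions.append(Junction(_end_bnd(x1), _start_bnd(y2),
                              mechanism="other", name=name + "a"))
    if reciprocal:
        junctions.append(Junction(_end_bnd(x2), _start_bnd(y1),
                                  mechanism="other", name=name + "b"))
        walks[wi1] = w1[:ei1] + [x1, y2] + w2[ei2 + 1:]
        walks[wi2] = w2[:ei2] + [x2, y1] + w1[ei1 + 1:]
    else:
        # reciprocal product lost: terminal deletions flank the derivative
        walks[wi1] = w1[:ei1] + [x1, y2] + w2[ei2 + 1:]
        del walks[wi2]


def _pick_elem(walks, rng, size, orient="+", margin=2000):
    """Element able to host an intra-element event of `size` bp."""
    cands = []
    weights = []
    for wi, w in enumerate(walks):
        for ei, e in enumerate(w):
            room = _elem_len(e) - size - 2 * margin
            if e[3] == orient and room > 0:
                cands.append((wi, ei))
                weights.append(room)
    if not cands:
        return None
    k = rng.choice(len(cands), p=np.array(weights) / sum(weights))
    return cands[int(k)]


def simulate_karyotype(config: SimConfig, genome: SimGenome,
                       rng: np.random.Generator) -> SimTruth:
    """Rearranged phased karyotype with ground truth."""
    alpha = config.purity if config.purity is not None else rng.uniform(0.5, 0.95)
    tau = config.ploidy if config.ploidy is not None else rng.uniform(1.8, 4.2)

    walks: list[list[Elem]] = []
    for chrom, L in genome.chrom_lengths.items():
        walks.append([(chrom, 0, L, "+", "A")])
        walks.append([(chrom, 0, L, "+", "B")])

    junctions: list[Junction] = []
    upd_events: list[UpdEvent] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_lengths}

    def free_interval(chrom, lo, hi):
        return not any(s < hi and lo < e for s, e in occupied[chrom])

    # --- AHR crossovers (on pristine chromosomes) -----------------------
    chroms = list(genome.chrom_lengths)
    for k in range(config.n_ahr_events):
        for _try in range(50):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = genome.chrom_lengths[chrom]
            p = int(rng.uniform(0.2 * L, min(0.8 * L, L - 1.5e6)))
            if not free_interval(chrom, p, L):
                continue
            wb = next(i for i, w in enumerate(walks)
                      if len(w) == 1 and w[0][0] == chrom and w[0][4] == "B")
            walks[wb] = [(chrom, 0, p, "+", "B"), (chrom, p, L, "+", "A")]
            upd_events.append(UpdEvent(chrom, p, L, "AHR_UPD"))
            occupied[chrom].append((p, L))
            break

    # --- progressive UPD: loss on one homolog, gain on the other --------
    for k in range(config.n_pupd_events):
        for _try in range(50):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = genome.chrom_lengths[chrom]
            lo, hi = config.pupd_size_range
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            cl, ch = config.pupd_collar_range
            col1 = int(np.exp(rng.uniform(np.log(cl), np.log(ch))))
            col2 = int(np.exp(rng.uniform(np.log(cl), np.log(ch))))
            a = int(rng.uniform(0.05 * L, 0.9 * L - size - col1 - col2))
            b, c, d = a + col1, a + col1 + size, a + col1 + size + col2
            if not free_interval(chrom, a, d):
                continue
            hitB = _walk_find(walks, chrom, a, d)
            hitB = [(wi, ei) for wi, ei in hitB if walks[wi][ei][4] == "B"]
            hitA = _walk_find(walks, chrom, b, c)
            hitA = [(wi, ei) for wi, ei in hitA if walks[wi][ei][4] == "A"]
            if not hitB or not hitA:
                continue
            _apply_del(walks, *hitB[0], a, d, "other", junctions,
                       f"pupd{k}_loss")
            hitA = _walk_find(walks, chrom, b, c)
            hitA = [(wi, ei) for wi, ei in hitA if walks[wi][ei][4] == "A"]
            _apply_dup(walks, *hitA[0], b, c, junctions, f"pupd{k}_gain")
            upd_events.append(UpdEvent(chrom, b, c, "P_UPD"))
            occupied[chrom].append((a, d))
            break

    # --- NAHR junctions between registered homologous pairs -------------
    n_nahr = round(config.nahr_prevalence * config.n_junctions)
    hom = genome.homology
    pair_order = rng.permutation(len(hom)) if len(hom) else []
    placed = 0
    for pi in pair_order:
        if placed >= n_nahr:
            break
        r = hom.iloc[int(pi)]
        if r.chrom1 != r.chrom2 or r.strand2 != "+":
            continue
        mid1 = int(r.pos1) + config.homology_tract // 2
        mid2 = int(r.pos2) + config.homology_tract // 2
        hits = _walk_find(walks, r.chrom1, mid1, mid2)
        if not hits:
            continue
        wi, ei = hits[int(rng.integers(len(hits)))]
        _apply_del(walks, wi, ei, mid1, mid2, "NAHR", junctions,
                   f"nahr{placed}")
        placed += 1
    if placed < n_nahr:
        logger.warning("placed %d/%d NAHR junctions", placed, n_nahr)

    # --- random rearrangements up to the junction budget ----------------
    kinds = list(config.event_weights)
    probs = np.array([config.event_weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    def clear(chrom, lo, hi):
        return (not config.events_avoid_occupied
                or free_interval(chrom, lo - 50_000, hi + 50_000))

    guard = 0
    while len(junctions) < config.n_junctions and guard < 10 * config.n_junctions:
        guard += 1
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        lo, hi = config.sv_size_range
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        name = f"j{len(junctions)}"
        if kind in ("tra", "tra_recip"):
            pick1 = _pick_elem(walks, rng, 0, margin=100_000)
            if pick1 is None:
                continue
            wi1, ei1 = pick1
            c1 = walks[wi1][ei1][0]
            cands = [(wi, ei) for wi, w in enumerate(walks)
                     for ei, e in enumerate(w)
                     if e[0] != c1 and e[3] == "+"
                     and _elem_len(e) > 200_000 and wi != wi1]
            if not cands:
                continue
            wi2, ei2 = cands[int(rng.integers(len(cands)))]
            e1, e2 = walks[wi1][ei1], walks[wi2][ei2]
            a = int(rng.integers(e1[1] + 50_000, e1[2] - 50_000))
            b = int(rng.integers(e2[1] + 50_000, e2[2] - 50_000))
            if not (clear(e1[0], a, a) and clear(e2[0], b, b)):
                continue
            _apply_tra(walks, wi1, ei1, a, wi2, ei2, b, junctions, name,
                       reciprocal=kind == "tra_recip")
            continue
        if kind == "inv":
            flo, fhi = config.inv_flank_range
            f1 = int(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
            f2 = int(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
            span = f1 + max(size, 2000) + f2
            pick = _pick_elem(walks, rng, span)
            if pick is None:
                continue
            wi, ei = pick
            e = walks[wi][ei]
            a = int(rng.integers(e[1] + 1000, e[2] - span - 1000))
            if not clear(e[0], a, a + span):
                continue
            _apply_inv(walks, wi, ei, a, a + f1, a + span - f2, a + span,
                       junctions, name)
            continue
        pick = _pick_elem(walks, rng, size)
        if pick is None:
            continue
        wi, ei = pick
        e = walks[wi][ei]
        a = int(rng.integers(e[1] + 1000, e[2] - size - 1000))
        b = a + size
        if not clear(e[0], a, b):
            continue
        if kind == "del":
            _apply_del(walks, wi, ei, a, b, "other", junctions, name)
        elif kind == "dup":
            _apply_dup(walks, wi, ei, a, b, junctions, name)

    # --- approach the target ploidy with whole-walk gains/losses --------
    hap = config.haploid_size

    def realized():
        return sum(_elem_len(e) for w in walks for e in w) / hap

    def has_junc(w):
        return len(w) > 1

    guard = 0
    while realized() < tau - config.ploidy_tol / 2 and guard < 200:
        guard += 1
        wi = int(rng.integers(len(walks)))
        walks.append([e for e in walks[wi]])
    while realized() > tau + config.ploidy_tol / 2 and guard < 400:
        guard += 1
        frees = [i for i, w in enumerate(walks) if not has_junc(w)]
        if not frees:
            break
        walks.pop(frees[int(rng.integers(len(frees)))])
    tau_r = realized()
    if abs(tau_r - tau) > config.ploidy_tol:
        logger.warning("realized ploidy %.2f misses target %.2f", tau_r, tau)

    # --- retain only junctions present in the final karyotype -----------
    adj: dict[frozenset, int] = {}
    for w in walks:
        for e1, e2 in zip(w[:-1], w[1:]):
            key = frozenset(((b.chrom, b.pos, b.strand)
                             for b in (_end_bnd(e1), _start_bnd(e2))))
            adj[key] = adj.get(key, 0) + 1
    kept, cns = [], []
    for j in junctions:
        key = frozenset((b.chrom, b.pos, b.strand) for b in j.breakends)
        cn = adj.get(key, 0)
        if cn > 0:
            kept.append(j)
            cns.append(cn)
    if len(kept) < len(junctions):
        logger.info("%d junctions lost to later events",
                    len(junctions) - len(kept))

    # --- junction detection and confidence tiers ------------------------
    if config.withhold_frac is not None:
        p_det = 1.0 - config.withhold_frac
    else:
        p_det = min(1.0, config.detection_s * alpha)
    detected = rng.random(len(kept)) < p_det
    tiers = ["high" if rng.random() < config.frac_high_conf else "low"
             for _ in kept]

    truth = SimTruth(genome, walks, kept, cns, detected, tiers, upd_events,
                     alpha, tau, tau_r)
    # keep only UPD events whose region still shows (total 2, minor 0) in
    # the final karyotype (later gains/losses can undo a planted event)
    truth.upd_events = [u for u in upd_events if _upd_intact(truth, u)]
    if len(truth.upd_events) < len(upd_events):
        logger.info("%d UPD events undone by later events",
                    len(upd_events) - len(truth.upd_events))
    return truth


def _upd_intact(truth: "SimTruth", u: UpdEvent, min_frac: float = 0.9) -> bool:
    bounds, a, b = truth.atoms(u.chrom)
    good = 0
    for s, t, ca, cb in zip(bounds[:-1], bounds[1:], a, b):
        lo, hi = max(s, u.start), min(t, u.end)
        if hi > lo and ca + cb == 2 and min(ca, cb) == 0:
            good += hi - lo
    return good >= min_frac * (u.end - u.start)


@dataclass
class SimProfiles:
    tumor_raw: dict[str, np.ndarray]
    normal_raw: dict[str, np.ndarray]
    snps: SnpCounts
    junction_calls: list[Junction]

    def tumor_depth(self, alpha: float, tau: float,
                    bin_width: int = 1000) -> DepthProfile:
        return transform_depth(self.tumor_raw, alpha, tau, bin_width=bin_width)


def emit_profiles(truth: SimTruth, config: SimConfig,
                  rng: np.random.Generator) -> SimProfiles:
    """Poisson depth/SNP-count emission plus the detected junction calls."""
    a, tau = truth.alpha, truth.tau_realized
    mix = a * tau + 2 * (1 - a)
    factor = config.tumor_coverage * config.bin_width / config.read_length
    nfactor = config.normal_coverage * config.bin_width / config.read_length
    mu, sig = -config.bias_sigma ** 2 / 2, config.bias_sigma
    if config.noiseless:
        sig = 0.0

    tumor, normal = {}, {}
    snp_rows = []
    for chrom, L in truth.genome.chrom_lengths.items():
        total, hapA, hapB = truth.cn_bins(chrom, config.bin_width)
        bias = rng.lognormal(mu, sig, size=len(total)) if sig > 0 else 1.0
        mean_t = factor * bias * (a * total + 2 * (1 - a)) / mix
        nbias = rng.lognormal(mu, sig, size=len(total)) if sig > 0 else 1.0
        mean_n = nfactor * nbias * np.ones(len(total))
        if config.noiseless:
            tumor[chrom] = np.asarray(mean_t, dtype=float).copy()
            normal[chrom] = mean_n
        else:
            tumor[chrom] = rng.poisson(mean_t).astype(float)
            normal[chrom] = rng.poisson(mean_n).astype(float)

        pos = truth.genome.snps[chrom]
        bins = np.minimum(pos // config.bin_width, len(total) - 1)
        for h, arr in (("1", hapA), ("2", hapB)):
            c_h = arr[bins]
            mean = config.tumor_coverage * (a * c_h + (1 - a)) / mix
            counts = mean if config.noiseless else rng.poisson(mean)
            if h == "1":
                c1 = counts
            else:
                snp_rows.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos,
                    "count_hap1": c1, "count_hap2": counts}))
    snp_table = (pd.concat(snp_rows, ignore_index=True) if snp_rows
                 else pd.DataFrame(columns=["chrom", "pos", "count_hap1",
                                            "count_hap2"]))
    snps = SnpCounts(snp_table, alpha=a, tau=tau, phased=True)
    return SimProfiles(tumor, normal, snps, truth.detected_junctions())


def simulate(config: SimConfig, seed) -> tuple[SimTruth, SimProfiles]:
    """One tumor profile: genome, karyotype and emitted data."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome(config, rng)
    truth = simulate_karyotype(config, genome, rng)
    profiles = emit_profiles(truth, config, rng)
    return truth, profiles
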