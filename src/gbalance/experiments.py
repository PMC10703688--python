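"""Seeded benchmark experiments.

Each experiment regenerates its inputs with the built-in simulator, runs
the full fitting pipeline, and scores the result against ground truth.
These are the desk-scale analogues of the published simulation benchmarks:
breakend detection precision/recall over high-purity tumor profiles,
loose-end localization of withheld junctions, AHR-UPD vs P-UPD mechanism
classification, and the NAHR burden estimator.

Problem sizes (documented in the methods note): 20-Mb genomes with ~50
junctions for breakend/loose-end benchmarks, 16-Mb near-diploid genomes
for UPD, 10-Mb genomes for the NAHR estimator.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .allelic import balance_allelic, split_minor_allele
from .benchmark import PRResult, called_breakends, score_breakends, score_upd
from .classify import classify_upd, nahr_pair
from .simulate import SimConfig, simulate
from .solver import FitConfig, fit_pipeline

logger = logging.getLogger(__name__)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _fit_one(truth, profiles, fit_config):
    depth = profiles.tumor_depth(truth.alpha, truth.tau_realized)
    return fit_pipeline(depth, profiles.junction_calls, fit_config)


def run_breakend_benchmark(n_genomes: int = 30, seed: int = 0,
                           sim_config: SimConfig | None = None,
                           fit_config: FitConfig | None = None) -> dict:
    """Breakend detection P/R of the full pipeline on high-purity genomes."""
    cfg = sim_config or SimConfig()
    prec, rec = [], []
    for s in spawn_seeds(seed, n_genomes):
        truth, prof = simulate(cfg, s)
        fit = _fit_one(truth, prof, fit_config)
        pr = score_breakends(called_breakends(fit.graph), truth.breakends())
        prec.append(100 * pr.precision)
        rec.append(100 * pr.recall)
        logger.info("seed %d: precision %.1f recall %.1f", s, prec[-1], rec[-1])
    return {"precision": prec, "recall": rec,
            "median_precision": float(np.median(prec)),
            "median_recall": float(np.median(rec)),
            "n_genomes": n_genomes}


def run_loose_benchmark(n_genomes: int = 30, seed: int = 0,
                        withhold_frac: float = 0.3,
                        sim_config: SimConfig | None = None,
                        fit_config: FitConfig | None = None) -> dict:
    """Loose-end localization of withheld junction breakends.

    Same simulated genomes as the breakend benchmark (same child seeds),
    but a fixed fraction of true junctions is withheld from the caller
    input; fitted loose ends are scored against the withheld breakends.
    """
    cfg = dataclasses.replace(sim_config or SimConfig(),
                              withhold_frac=withhold_frac)
    prec, rec = [], []
    for s in spawn_seeds(seed, n_genomes):
        truth, prof = simulate(cfg, s)
        fit = _fit_one(truth, prof, fit_config)
        withheld = [b for j in truth.withheld_junctions() for b in j.breakends]
        loose = [b for b, _ in fit.graph.loose_ends()]
        pr = score_breakends(loose, withheld)
        prec.append(100 * pr.precision)
        rec.append(100 * pr.recall)
        logger.info("seed %d: loose precision %.1f recall %.1f",
                    s, prec[-1], rec[-1])
    return {"precision": prec, "recall": rec,
            "median_precision": float(np.median(prec)),
            "median_recall": float(np.median(rec)),
            "n_genomes": n_genomes}


def upd_sim_config(rng: np.random.Generator) -> SimConfig:
    """Per-genome UPD study conditions: near-diploid, mixed mechanisms."""
    return SimConfig(
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        n_junctions=6,
        nahr_prevalence=0.0,
        n_homology_pairs=0,
        ploidy=2.0,
        events_avoid_occupied=True,
        n_ahr_events=int(rng.integers(1, 3)),
        n_pupd_events=int(rng.integers(1, 3)))


def run_upd_benchmark(n_genomes: int = 50, seed: int = 0,
                      fit_config: FitConfig | None = None) -> dict:
    """AHR-UPD vs P-UPD classification over mixed-mechanism genomes.

    Pipeline per genome: total balance fit, minor-allele splitting of
    large segments, allelic balance, then the UPD mechanism rule; calls
    are pooled over genomes before computing precision/recall.
    """
    meta = np.random.default_rng(seed)
    tp = {"AHR_UPD": 0, "P_UPD": 0}
    n_called = {"AHR_UPD": 0, "P_UPD": 0}
    n_true = {"AHR_UPD": 0, "P_UPD": 0}
    for s in spawn_seeds(seed, n_genomes):
        cfg = upd_sim_config(meta)
        truth, prof = simulate(cfg, s)
        fit = _fit_one(truth, prof, fit_config)
        g2 = split_minor_allele(fit.graph, prof.snps)
        ag = balance_allelic(g2, prof.snps, fit_config)
        calls = classify_upd(ag.merged_segments())
        res = score_upd(calls, truth.upd_events)
        for mech, pr in res.items():
            tp[mech] += pr.n_tp
            n_called[mech] += pr.n_called
            n_true[mech] += pr.n_true
        logger.info("seed %d: %d UPD calls / %d true events",
                    s, len(calls), len(truth.upd_events))
    out = {}
    for mech in tp:
        pr = PRResult(n_true[mech], n_called[mech], tp[mech])
        out[mech] = {"precision": 100 * pr.precision,
                     "recall": 100 * pr.recall,
                     "n_true": pr.n_true, "n_called": pr.n_called,
                     "n_tp": pr.n_tp}
    out["n_genomes"] = n_genomes
    return out


def estimate_nahr_breakends(graph, homology) -> int:
    """NAHR breakend count asserted by a fitted graph.

    Counts breakends of CN>0 junctions whose own breakend pair satisfies
    the homology geometry, plus loose-end pairs that do.
    """
    n = 0
    for _, e in graph.edges_of_kind("variant"):
        if (e.cn or 0) > 0:
            b1 = graph.breakend(e.seg1, e.side1)
            b2 = graph.breakend(e.seg2, e.side2)
            if nahr_pair(b1, b2, homology):
                n += 2
    loose = [b for b, _ in graph.loose_ends()]
    for i in range(len(loose)):
        for j in range(i + 1, len(loose)):
            if nahr_pair(loose[i], loose[j], homology):
                n += 2
    return n


def nahr_sim_config(rng: np.random.Generator) -> SimConfig:
    """Per-sample NAHR estimator conditions: prevalence 0.1-10%."""
    return SimConfig(
        chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
        n_junctions=60,
        sv_size_range=(1e4, 1e6),
        nahr_prevalence=float(rng.uniform(0.001, 0.10)),
        n_homology_pairs=14)


def run_nahr_correlation(n_samples: int = 40, seed: int = 0,
                         fit_config: FitConfig | None = None) -> dict:
    """Correlation of estimated vs true NAHR breakend burden."""
    meta = np.random.default_rng(seed)
    est, true = [], []
    for s in spawn_seeds(seed, n_samples):
        cfg = nahr_sim_config(meta)
        truth, prof = simulate(cfg, s)
        fit = _fit_one(truth, prof, fit_config)
        est.append(estimate_nahr_breakends(fit.graph, truth.genome.homology))
        true.append(2 * sum(1 for j in truth.junctions
                            if j.mechanism == "NAHR"))
        logger.info("seed %d: true %d est %d NAHR breakends",
                    s, true[-1], est[-1])
    r = float(np.corrcoef(true, est)[0, 1])
    return {"pearson_r": r, "true": true, "estimated": est,
            "n_samples": n_samples}
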