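import numpy as np
import pytest

from gbalance.graph import attach_depth, build_graph
from gbalance.profiles import DepthProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_profile(values_by_chrom, alpha=1.0, tau=2.0, bin_width=1000):
    """Depth profile directly in CN units (already transformed)."""
    lengths = {c: len(v) * bin_width for c, v in values_by_chrom.items()}
    return DepthProfile(lengths, {c: np.asarray(v, dtype=float)
                                  for c, v in values_by_chrom.items()},
                        alpha, tau, bin_width)


def make_graph(values_by_chrom, breakpoints=None, junctions=(), **kw):
    """Graph over a CN-unit profile with depth attached."""
    prof = make_profile(values_by_chrom, **kw)
    g = build_graph(prof.chrom_lengths, breakpoints or {}, list(junctions))
    attach_depth(g, prof)
    return g, prof


# ---------------------------------------------------------------------------
# session-scoped benchmark runs shared by the acceptance tests
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def breakend_benchmark():
    from gbalance.experiments import run_breakend_benchmark
    return run_breakend_benchmark(n_genomes=30, seed=20240901)


@pytest.fixture(scope="session")
def loose_benchmark():
    from gbalance.experiments import run_loose_benchmark
    return run_loose_benchmark(n_genomes=30, seed=20240901, withhold_frac=0.3)


@pytest.fixture(scope="session")
def upd_benchmark():
    from gbalance.experiments import run_upd_benchmark
    return run_upd_benchmark(n_genomes=50, seed=20240901)


@pytest.fixture(scope="session")
def nahr_benchmark():
    from gbalance.experiments import run_nahr_correlation
    return run_nahr_correlation(n_samples=40, seed=20240901)
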