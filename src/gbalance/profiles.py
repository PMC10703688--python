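"""Binned read-depth and allelic SNP-count containers.

Read depth enters the model already normalized to copy-number units: a bin
whose true tumor copy number is c has expected transformed depth x = c.
The transform inverts the standard purity/ploidy mixture model, in which
the expected depth of a bin of tumor CN c in a sample of purity alpha is
proportional to alpha*c + 2*(1-alpha), and the genome-wide mean depth
corresponds to alpha*tau + 2*(1-alpha), tau being tumor ploidy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DepthProfile:
    """Purity/ploidy-transformed 1-kb binned read depth, NaN = masked bin."""

    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    alpha: float
    tau: float
    bin_width: int = 1000

    @property
    def n(self) -> int:
        """Number of unmasked bins."""
        return int(sum(np.sum(~np.isnan(v)) for v in self.values.values()))

    def chrom_bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.values[chrom])) * self.bin_width


def transform_depth(raw_depth: dict[str, np.ndarray], alpha: float, tau: float,
                    chrom_lengths: dict[str, int] | None = None,
                    mask: dict[str, np.ndarray] | None = None,
                    bin_width: int = 1000) -> DepthProfile:
    """Transform raw binned depth into CN units.

    x_i = (r_i / rbar * (alpha*tau + 2*(1-alpha)) - 2*(1-alpha)) / alpha,
    where rbar is the mean of the unmasked raw depth.  Masked bins become
    NaN; negative transformed values are clipped to zero.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"purity must be in (0, 1], got {alpha}")
    if tau <= 0:
        raise ValueError(f"ploidy must be positive, got {tau}")
    raw = {c: np.asarray(v, dtype=float).copy() for c, v in raw_depth.items()}
    if mask is not None:
        for c, m in mask.items():
            if c in raw:
                raw[c][np.asarray(m, dtype=bool)] = np.nan
    allv = np.concatenate([v for v in raw.values()])
    rbar = np.nanmean(allv)
    if not np.isfinite(rbar) or rbar <= 0:
        raise ValueError("mean unmasked raw depth must be positive")
    mix = alpha * tau + 2.0 * (1.0 - alpha)
    values = {}
    n_clip = 0
    for c, v in raw.items():
        x = (v / rbar * mix - 2.0 * (1.0 - alpha)) / alpha
        neg = x < 0
        n_clip += int(np.nansum(neg))
        x[neg & ~np.isnan(x)] = 0.0
        values[c] = x
    if n_clip:
        logger.info("clipped %d negative transformed depth bins to 0", n_clip)
    if chrom_lengths is None:
        chrom_lengths = {c: len(v) * bin_width for c, v in values.items()}
    return DepthProfile(chrom_lengths, values, alpha, tau, bin_width)


@dataclass
class SnpCounts:
    """Heterozygous-SNP allelic read counts.

    `table` columns: chrom, pos, count_hap1, count_hap2.  When `phased`,
    hap1/hap2 are consistent parental homolog labels along each chromosome;
    otherwise they carry no phase information and only the (major, minor)
    pair is meaningful.
    """

    table: pd.DataFrame
    alpha: float
    tau: float
    phased: bool = True
    _mean_allele: float = field(init=False, default=np.nan)

    def __post_init__(self):
        need = {"chrom", "pos", "count_hap1", "count_hap2"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"SNP table needs columns {sorted(need)}")
        if (self.table[["count_hap1", "count_hap2"]] < 0).any().any():
            raise ValueError("negative SNP counts")
        tot = self.table["count_hap1"] + self.table["count_hap2"]
        self._mean_allele = float(tot.mean()) / 2.0 if len(tot) else np.nan

    def cn_units(self) -> pd.DataFrame:
        """Per-SNP haplotype copy number estimates (cn_hap1, cn_hap2).

        Inverts the per-allele mixture: expected allele count for haplotype
        CN c is m(c) ~ (alpha*c + (1-alpha)), normalized so the genome mean
        allele count maps to alpha*tau/2 + (1-alpha).
        """
        a, t = self.alpha, self.tau
        scale = (a * t / 2.0 + (1.0 - a)) / self._mean_allele
        out = self.table.copy()
        for h in ("1", "2"):
            cn = (out[f"count_hap{h}"] * scale - (1.0 - a)) / a
            out[f"cn_hap{h}"] = np.clip(cn, 0.0, None)
        return out

    def in_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        t = self.table
        return t[(t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] < end)]
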