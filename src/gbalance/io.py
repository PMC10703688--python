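"""Readers and writers for the tool's text formats.

Coordinate dialects: internally everything is 0-based half-open.  BED,
bedGraph and BEDPE keep their native 0-based half-open convention; VCF
positions are 1-based and converted on read.

BEDPE strand dialect: strand1/strand2 give each breakend's forward strand
-- the reference strand whose 3' terminus abuts the breakend.  A '+'
breakend retains sequence to its left, so its boundary coordinate is the
interval end; a '-' breakend retains sequence to its right and uses the
interval start:

        strand '+':  ...retained][lost...      boundary = end
        strand '-':  ...lost][retained...      boundary = start
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import Breakend, GenomeGraph, Junction
from .profiles import DepthProfile, SnpCounts, transform_depth

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------
def read_depth(path) -> tuple[dict[str, np.ndarray], int]:
    """Read 4-column bedGraph/TSV binned depth -> (per-chrom arrays, bin width).

    Bins absent from the file are NaN (masked).
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        raise ValueError(f"{path}: no depth records")
    widths = (df["end"] - df["start"])
    w = int(widths.mode().iloc[0])
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n = int(np.ceil(sub["end"].max() / w))
        arr = np.full(n, np.nan)
        idx = (sub["start"] // w).to_numpy()
        arr[idx] = sub["value"].to_numpy(dtype=float)
        out[str(chrom)] = arr
    return out, w


def write_depth(path, values: dict[str, np.ndarray], bin_width: int) -> None:
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            for i, v in enumerate(arr):
                if not np.isnan(v):
                    fh.write(f"{chrom}\t{i * bin_width}"
                             f"\t{(i + 1) * bin_width}\t{v:.6g}\n")


def read_mask(path) -> dict[str, list[tuple[int, int]]]:
    """BED intervals of CN-unmappable regions."""
    df = pd.read_csv(path, sep="\t", comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
    return out


def apply_mask(values: dict[str, np.ndarray], mask, bin_width: int):
    """NaN-mask bins whose midpoint falls in a masked interval."""
    out = {c: v.copy() for c, v in values.items()}
    for chrom, ivs in mask.items():
        if chrom not in out:
            continue
        mids = (np.arange(len(out[chrom])) + 0.5) * bin_width
        for a, b in ivs:
            out[chrom][(mids >= a) & (mids < b)] = np.nan
    return out


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------
def read_bedpe(path) -> list[Junction]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 10:
        raise ValueError(f"{path}: BEDPE needs >= 10 columns")
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2"]
    df = df.rename(columns=dict(enumerate(cols + ["tier"][:df.shape[1] - 10])))
    out = []
    for k, r in enumerate(df.itertuples(index=False)):
        try:
            b1 = Breakend(str(r.chrom1),
                          int(r.end1 if r.strand1 == "+" else r.start1),
                          str(r.strand1))
            b2 = Breakend(str(r.chrom2),
                          int(r.end2 if r.strand2 == "+" else r.start2),
                          str(r.strand2))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed BEDPE record at line {k + 1}: "
                             f"{exc}") from exc
        tier = str(getattr(r, "tier", "high"))
        out.append(Junction(b1, b2, tier=tier if tier in ("high", "low")
                            else "high", name=str(r.name)))
    return out


def write_bedpe(path, junctions: list[Junction]) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            f1 = [j.b1.pos - 1, j.b1.pos] if j.b1.strand == "+" \
                else [j.b1.pos, j.b1.pos + 1]
            f2 = [j.b2.pos - 1, j.b2.pos] if j.b2.strand == "+" \
                else [j.b2.pos, j.b2.pos + 1]
            fh.write("\t".join(map(str, [
                j.b1.chrom, *f1, j.b2.chrom, *f2, j.name or ".",
                0, j.b1.strand, j.b2.strand, j.tier])) + "\n")


_BND_RE = re.compile(r"^([ACGTNacgtn]*)([\[\]])([^:\[\]]+):(\d+)([\[\]])"
                     r"([ACGTNacgtn]*)$")


def _bnd_breakends(chrom: str, pos1: int, alt: str):
    """Internal breakend pair of one VCF BND record (pos1 is 1-based)."""
    m = _BND_RE.match(alt)
    if not m:
        raise ValueError(f"unsupported BND ALT {alt!r}")
    t1, br, mchrom, mpos, _, t2 = m.groups()
    if bool(t1) == bool(t2):
        raise ValueError(f"ambiguous BND ALT {alt!r}")
    s1 = "+" if t1 else "-"
    s2 = "-" if br == "[" else "+"
    b1 = Breakend(chrom, pos1 if s1 == "+" else pos1 - 1, s1)
    p2 = int(mpos)
    b2 = Breakend(mchrom, p2 if s2 == "+" else p2 - 1, s2)
    return b1, b2


def read_vcf_bnd(path) -> list[Junction]:
    """Junctions from VCF BND records; FILTER=PASS maps to the high tier.

    Mate records describing the same junction are deduplicated.
    """
    import pysam

    out = []
    seen = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if "[" not in alt and "]" not in alt:
                    continue
                try:
                    b1, b2 = _bnd_breakends(rec.chrom, rec.pos, alt)
                except ValueError as exc:
                    raise ValueError(f"{path}: record {rec.id or rec.pos}: "
                                     f"{exc}") from exc
                key = frozenset([(b1.chrom, b1.pos, b1.strand),
                                 (b2.chrom, b2.pos, b2.strand)])
                if key in seen:
                    continue
                seen.add(key)
                filters = list(rec.filter.keys())
                tier = "high" if (not filters or filters == ["PASS"]) else "low"
                out.append(Junction(b1, b2, tier=tier, name=rec.id or ""))
    return out


def read_junctions(path) -> list[Junction]:
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return read_vcf_bnd(path)
    return read_bedpe(path)


# ---------------------------------------------------------------------------
# SNPs, homology, graphs
# ---------------------------------------------------------------------------
def read_snps(path, alpha: float, tau: float, phased: bool = True) -> SnpCounts:
    df = pd.read_csv(path, sep="\t")
    if {"ref_count", "alt_count"}.issubset(df.columns):
        df = df.rename(columns={"ref_count": "count_hap1",
                                "alt_count": "count_hap2"})
    return SnpCounts(df, alpha=alpha, tau=tau, phased=phased)


def write_snps(path, snps: SnpCounts) -> None:
    snps.table.to_csv(path, sep="\t", index=False)


def read_homology(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_homology(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_graph(path, graph: GenomeGraph) -> None:
    Path(path).write_text(graph.to_json())


def read_graph(path) -> GenomeGraph:
    return GenomeGraph.from_json(Path(path).read_text())


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_depth_profile(depth_path, alpha: float, tau: float,
                       mask_path=None) -> DepthProfile:
    raw, w = read_depth(depth_path)
    if mask_path:
        raw = apply_mask(raw, read_mask(mask_path), w)
    return transform_depth(raw, alpha, tau, bin_width=w)
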