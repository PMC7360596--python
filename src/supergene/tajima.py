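"""Tajima's D in sliding windows, with depth filters and beta significance.

D contrasts two estimators of the population mutation parameter: mean
pairwise diversity (pi) and the normalized segregating-site count (S/a1).
An excess of rare alleles — the signature of a bottleneck-founded group —
drives D negative. The statistic is computed from the classic constants
(a1, a2, b1, b2, c1, c2, e1, e2 as functions of sample size n), and
per-window significance uses the beta approximation of D's null
distribution on its theoretical support [Dmin, Dmax].

Windows tile the chromosome (step = width): the tooling convention behind
reported "sliding window" scans of this kind; the step is exposed should an
overlapping scan be wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = [
    "GenotypeMatrix",
    "WindowStat",
    "depth_filter",
    "tajima_constants",
    "tajimas_d",
    "windowed_scan",
    "significance",
    "segment_summary",
    "write_vcf",
    "read_vcf",
    "write_window_tsv",
]


@dataclass
class GenotypeMatrix:
    """Haploid biallelic calls with read depths on one chromosome.

    ``genotypes[i, j]`` is sample j's allele (0 ref / 1 alt / -1 missing) at
    ``positions[i]`` (1-based bp, strictly increasing).
    """

    chrom: str
    positions: np.ndarray
    samples: list[str]
    genotypes: np.ndarray
    depths: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)
    chrom_length_bp: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths)
        n_sites, n_samp = self.genotypes.shape
        if len(self.positions) != n_sites or n_samp != len(self.samples):
            raise ValueError("genotype matrix shape mismatch")
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depths must match genotypes in shape")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[0])

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(self.chrom, self.positions.copy(), list(keep),
                              self.genotypes[:, idx].copy(),
                              self.depths[:, idx].copy(),
                              {s: self.groups.get(s, "unknown") for s in keep},
                              self.chrom_length_bp)

    def subset_group(self, group: str) -> "GenotypeMatrix":
        keep = [s for s in self.samples if self.groups.get(s) == group]
        if not keep:
            raise KeyError(f"no samples in group {group!r}")
        return self.subset_samples(keep)


def depth_filter(matrix: GenotypeMatrix, mode: str,
                 min_depth: int = 6) -> GenotypeMatrix:
    """Site-level depth filtering.

    ``whole_genome``: keep sites where at most one individual is below
    ``min_depth`` (loci with less than 6 reads in more than one individual
    are removed). ``rad``: keep sites where every individual has at least
    ``min_depth`` reads.
    """
    low = matrix.depths < min_depth
    if mode == "whole_genome":
        keep = low.sum(axis=1) <= 1
    elif mode == "rad":
        keep = ~low.any(axis=1)
    else:
        raise ValueError(f"unknown depth-filter mode {mode!r}")
    return GenotypeMatrix(matrix.chrom, matrix.positions[keep],
                          list(matrix.samples), matrix.genotypes[keep],
                          matrix.depths[keep], dict(matrix.groups),
                          matrix.chrom_length_bp)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants a1..e2 as functions of sample size n >= 2."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, pi: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diff.

    ``pi`` is the absolute mean number of pairwise differences over the
    region that yielded ``S``. Undefined (raises) when S = 0.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if S < 1:
        raise ValueError("D is undefined when S = 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        # degenerate (e.g. n = 3 with S = 1): the null variance vanishes
        return float("nan")
    return (pi - S / k["a1"]) / math.sqrt(var)


def significance(D: float, n: int, alpha: float = 0.05) -> str:
    """Two-sided beta-approximation flag for one window's D.

    D is mapped onto its theoretical support [Dmin, Dmax] (functions of n)
    and compared with the moment-matched beta distribution. Returns one of
    ``significantly_negative`` / ``significantly_positive`` / ``ns`` /
    ``undefined`` (n < 4: the approximation is unreliable).
    """
    if not np.isfinite(D):
        return "undefined"
    if n < 4:
        return "undefined"
    k = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    dmax = ((n + 1) / (2.0 * n) - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    if D <= dmin:
        return "significantly_negative"
    if D >= dmax:
        return "significantly_positive"
    rng_ = dmax - dmin
    phi = 1.0 + dmin * dmax
    a = -phi * dmax / rng_
    b = phi * dmin / rng_
    # D' = (Dmax - D)/range ~ Beta(b, a) under neutrality (moment-matched)
    x = (dmax - D) / rng_
    cdf = beta_dist.cdf(x, b, a)
    p = 2.0 * min(cdf, 1.0 - cdf)
    if p >= alpha:
        return "ns"
    return "significantly_negative" if D < 0 else "significantly_positive"


@dataclass
class WindowStat:
    chrom: str
    start: int   # 1-based inclusive
    end: int     # inclusive
    n: int
    S: int
    pi: float
    D: float     # NaN when undefined (S = 0)
    p_flag: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.D)


def _window_stats(geno: np.ndarray) -> tuple[int, int, float]:
    """(n, S, pi) for one window's complete-call site block."""
    n = geno.shape[1]
    if geno.shape[0] == 0:
        return n, 0, 0.0
    counts = geno.sum(axis=1)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    c = counts[seg].astype(float)
    # mean pairwise differences summed over sites: sum 2*c*(n-c)/(n*(n-1))
    pi = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    return n, S, pi


def windowed_scan(matrix: GenotypeMatrix, window_bp: int = 100_000,
                  step_bp: int | None = None,
                  chrom_length_bp: int | None = None,
                  alpha: float = 0.05) -> list[WindowStat]:
    """Per-window n, S, pi, Tajima's D and significance flag.

    Windows tile [1, chrom_length] with step = width by default. Sites with
    any missing call are dropped listwise within their window.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    step = step_bp or window_bp
    if step < 1:
        raise ValueError("step_bp must be >= 1")
    length = chrom_length_bp or matrix.chrom_length_bp
    if length is None:
        length = int(matrix.positions[-1]) if matrix.n_sites else window_bp
    n = len(matrix.samples)
    out: list[WindowStat] = []
    start = 1
    while start <= length:
        end = min(start + window_bp - 1, length)
        lo = np.searchsorted(matrix.positions, start, side="left")
        hi = np.searchsorted(matrix.positions, end, side="right")
        geno = matrix.genotypes[lo:hi]
        complete = ~(geno < 0).any(axis=1)
        nw, S, pi = _window_stats(geno[complete])
        if S > 0:
            D = tajimas_d(n, S, pi)
            flag = significance(D, n, alpha=alpha)
        else:
            D, flag = float("nan"), "undefined"
        out.append(WindowStat(matrix.chrom, start, end, n, S, pi, D, flag))
        start += step
    return out


def segment_summary(stats: Sequence[WindowStat],
                    segment_interval: tuple[int, int]) -> dict[str, float]:
    """Counts and mean D over the windows lying inside a segment.

    Mean D is taken over windows with defined D only; a segment with no
    defined window reports mean NaN and zero counts.
    """
    s0, s1 = segment_interval
    inside = [w for w in stats if w.start >= s0 and w.end <= s1]
    if not inside:
        raise ValueError("segment contains no scanned windows")
    defined = [w for w in inside if w.defined]
    mean_d = float(np.mean([w.D for w in defined])) if defined else float("nan")
    return {
        "n_windows": len(inside),
        "n_defined": len(defined),
        "mean_D": mean_d,
        "n_negative": sum(1 for w in defined if w.D < 0),
        "n_significant_negative": sum(
            1 for w in defined if w.p_flag == "significantly_negative"),
        "n_positive": sum(1 for w in defined if w.D > 0),
        "n_significant_positive": sum(
            1 for w in defined if w.p_flag == "significantly_positive"),
    }


# ----------------------------------------------------------------- text IO

def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 subset: CHROM POS REF ALT with haploid GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = matrix.chrom_length_bp or (
            int(matrix.positions[-1]) if matrix.n_sites else 1)
        fh.write(f"##contig=<ID={matrix.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            cells = []
            for j in range(len(matrix.samples)):
                g = matrix.genotypes[i, j]
                gt = "." if g < 0 else str(int(g))
                cells.append(f"{gt}:{int(matrix.depths[i, j])}")
            fh.write(f"{matrix.chrom}\t{int(matrix.positions[i])}\t.\tA\tT\t.\t"
                     "PASS\t.\tGT:DP\t" + "\t".join(cells) + "\n")


def read_vcf(path, groups: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read the VCF subset written by :func:`write_vcf` (plain text, haploid)."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chrom = None
        length = None
        for ctg in vf.header.contigs.values():
            chrom, length = ctg.name, ctg.length
        pos, geno, depth = [], [], []
        for rec in vf:
            chrom = rec.chrom
            row_g, row_d = [], []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"][0] if call["GT"] else None
                row_g.append(-1 if gt is None else int(gt))
                row_d.append(int(call["DP"]) if call["DP"] is not None else 0)
            pos.append(rec.pos)
            geno.append(row_g)
            depth.append(row_d)
    return GenotypeMatrix(
        chrom or "chr16", np.array(pos, dtype=np.int64), samples,
        np.array(geno, dtype=np.int8) if geno else
        np.zeros((0, len(samples)), dtype=np.int8),
        np.array(depth, dtype=np.int32) if depth else
        np.zeros((0, len(samples)), dtype=np.int32),
        groups or {}, length)


def write_window_tsv(stats: Sequence[WindowStat], path) -> None:
    rows = [(w.chrom, w.start, w.end, w.n, w.S, f"{w.pi:.6f}",
             "NA" if not w.defined else f"{w.D:.6f}", w.p_flag)
            for w in stats]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "S", "pi",
                                "D", "flag"]) \
        .to_csv(path, sep="\t", index=False)
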