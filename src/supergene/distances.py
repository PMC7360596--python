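"""Pairwise evolutionary distances with Jukes–Cantor (1969) correction.

Substitutions are counted over QC'd alignment blocks with pairwise deletion:
a column is excluded for a pair only when either member carries a gap or an
ambiguous base at it. Counts are pooled across blocks per pair *before* the
(nonlinear) JC correction, so each pair contributes a single observed mismatch
proportion p and d = -(3/4) ln(1 - 4p/3).

Distances are stored in substitutions per site; reporting helpers scale to
substitutions per 1,000 sites, the unit used throughout the fire-ant
supergene literature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "GroupAssignment",
    "count_substitutions",
    "jc69_correct",
    "pairwise_matrix",
    "select_one_read_per_locus",
    "group_distance_summary",
]

_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True


def _as_u8(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype=np.uint8)


def count_substitutions(row_a, row_b) -> tuple[int, int]:
    """(n_differences, n_valid_sites) between two aligned rows.

    Columns where either row has a gap or an N are excluded from both counts.
    """
    a, b = _as_u8(row_a), _as_u8(row_b)
    if a.shape != b.shape:
        raise ValueError("rows have unequal lengths")
    valid = _VALID[a] & _VALID[b]
    n_valid = int(valid.sum())
    n_diff = int(((a != b) & valid).sum())
    return n_diff, n_valid


class SaturationError(ValueError):
    """Observed mismatch proportion at or beyond the JC69 saturation bound (3/4)."""


def jc69_correct(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p) for p in [0, 0.75)."""
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"p = {p} >= 0.75: distance saturated under JC69")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


@dataclass
class DistanceMatrix:
    """Symmetric JC-corrected distances plus per-pair valid-site counts.

    ``d`` is NaN where a pair had zero valid sites or a saturated mismatch
    proportion; such entries are flagged, never silently zero.
    """

    ids: list[str]
    d: np.ndarray            # substitutions/site
    valid_sites: np.ndarray  # compared sites per pair

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.valid_sites = np.asarray(self.valid_sites)
        n = len(self.ids)
        if self.d.shape != (n, n) or self.valid_sites.shape != (n, n):
            raise ValueError("matrix shapes must match number of ids")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(x) for x in keep]
        return DistanceMatrix(list(keep), self.d[np.ix_(idx, idx)].copy(),
                              self.valid_sites[np.ix_(idx, idx)].copy())

    # ------------------------------------------------------------- text IO
    def to_square_tsv(self, path, per_1000: bool = True) -> None:
        scale = 1000.0 if per_1000 else 1.0
        df = pd.DataFrame(self.d * scale, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.6f", index_label="sample")

    def to_long_tsv(self, path) -> None:
        recs = []
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            recs.append((self.ids[i], self.ids[j], self.d[i, j] * 1000.0,
                         int(self.valid_sites[i, j])))
        pd.DataFrame(recs, columns=["sample_a", "sample_b", "d_per_1000",
                                    "valid_sites"]) \
            .to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class GroupAssignment:
    """sample -> (haplotype group, range). Every sample assigned exactly once."""

    groups: dict[str, str]
    ranges: dict[str, str] = field(default_factory=dict)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def read_tsv(cls, path) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t")
        groups = dict(zip(df["sample"], df["group"]))
        ranges = dict(zip(df["sample"], df.get("range", ["unknown"] * len(df))))
        return cls(groups, ranges)

    def write_tsv(self, path) -> None:
        rows = [(s, g, self.ranges.get(s, "unknown"))
                for s, g in self.groups.items()]
        pd.DataFrame(rows, columns=["sample", "group", "range"]) \
            .to_csv(path, sep="\t", index=False)


def pairwise_matrix(blocks, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Pooled-count JC distance matrix over a set of alignment blocks.

    Counts are summed over every block in which both samples of a pair are
    present, then corrected once; this is the consistent estimator because
    the JC correction is nonlinear.
    """
    blocks = list(blocks)
    if sample_ids is None:
        sample_ids = list(blocks[0].sample_ids) if blocks else []
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need at least two samples")
    diff = np.zeros((n, n), dtype=np.int64)
    valid = np.zeros((n, n), dtype=np.int64)
    for blk in blocks:
        present = [s for s in sample_ids if s in blk.sample_ids]
        rows = {s: blk.row(s) for s in present}
        vmask = {s: _VALID[rows[s]] for s in present}
        for sa, sb in itertools.combinations(present, 2):
            i, j = sample_ids.index(sa), sample_ids.index(sb)
            v = vmask[sa] & vmask[sb]
            nd = int(((rows[sa] != rows[sb]) & v).sum())
            nv = int(v.sum())
            diff[i, j] += nd
            diff[j, i] += nd
            valid[i, j] += nv
            valid[j, i] += nv
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        if valid[i, j] > 0:
            p = diff[i, j] / valid[i, j]
            try:
                d[i, j] = d[j, i] = jc69_correct(p)
            except SaturationError:
                pass  # stays NaN (flagged undefined)
    return DistanceMatrix(list(sample_ids), d, valid)


def select_one_read_per_locus(rad_dataset, seed: int):
    """Pick one read per sample at every locus covered in all samples.

    Loci lacking a read in any sample are dropped (the analysis requires every
    sample aligned at a locus). Returns one AlignmentBlock per retained locus,
    deterministically under a fixed seed.
    """
    from .qc import AlignmentBlock  # local import to avoid cycle

    loci = rad_dataset.loci
    if not loci:
        raise ValueError("empty RAD dataset")
    samples = rad_dataset.sample_ids
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks = []
    for loc in loci:
        stacks = rad_dataset.reads[loc.locus_id]
        if any(len(stacks.get(s, ())) == 0 for s in samples):
            continue
        rows = {}
        for s in samples:
            reads = stacks[s]
            k = int(rng.integers(0, len(reads)))
            rows[s] = reads[k]
        blocks.append(AlignmentBlock.from_strings(
            loc.locus_id, rows, chrom=rad_dataset.chrom,
            start=loc.start, end=loc.start + loc.length))
    if not blocks:
        raise ValueError("no locus is covered in every sample")
    return blocks


def group_distance_summary(matrix: DistanceMatrix,
                           assignment: GroupAssignment,
                           group_pairs: list[tuple[str, str]] | None = None
                           ) -> pd.DataFrame:
    """Mean/SD of pairwise distances per haplotype-group pair.

    Within-group summaries use unordered distinct pairs; between-group
    summaries use all cross pairs. Values reported in substitutions per
    1,000 sites.
    """
    if group_pairs is None:
        gs = sorted(set(assignment.groups.values()))
        group_pairs = [(a, b) for a, b in
                       itertools.combinations_with_replacement(gs, 2)]
    recs = []
    for ga, gb in group_pairs:
        ma = [s for s in assignment.members(ga) if s in matrix.ids]
        mb = [s for s in assignment.members(gb) if s in matrix.ids]
        if ga == gb:
            if len(ma) < 2:
                raise ValueError(
                    f"group {ga!r} has fewer than 2 members for a "
                    "within-group summary")
            pairs = list(itertools.combinations(ma, 2))
        else:
            if not ma or not mb:
                raise ValueError(f"no pairs for group pair ({ga}, {gb})")
            pairs = [(x, y) for x in ma for y in mb]
        vals = np.array([matrix.get(a, b) for a, b in pairs]) * 1000.0
        recs.append({"group_a": ga, "group_b": gb,
                     "mean_per_1000": float(np.nanmean(vals)),
                     "sd_per_1000": float(np.nanstd(vals, ddof=1))
                     if len(vals) > 1 else 0.0,
                     "n_pairs": len(pairs)})
    return pd.DataFrame(recs)
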