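"""Multi-sample alignment blocks: length filtering, confidence masking, coverage.

An :class:`AlignmentBlock` is one slice of the multiple genome alignment of the
non-recombining region: equal-length rows over ``{A,C,G,T,N,-}``, one per
sample, with an optional per-column confidence score in ``[0, 100]`` (such
scores are produced by external alignment-QC tools and are consumed here, never
computed). Internally coordinates are 0-based half-open; the text formats emit
1-based fully-closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignmentBlock",
    "filter_short_blocks",
    "apply_confidence_mask",
    "coverage_summary",
    "write_maf_like",
    "read_maf_like",
    "write_block_fasta",
    "read_block_fasta",
    "write_confidence_tsv",
    "read_confidence_tsv",
    "attach_confidence",
]

_ALPHABET = frozenset(b"ACGTN-")


def _as_u8(seq: str | bytes | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype=np.uint8).copy()


@dataclass
class AlignmentBlock:
    """One alignment block; ``rows[i]`` is the sequence of ``sample_ids[i]``."""

    block_id: str
    sample_ids: list[str]
    rows: np.ndarray  # (n_samples, n_columns) uint8 ASCII
    confidence: np.ndarray | None = None  # per-column score in [0, 100]
    chrom: str = "chr16"
    start: int = 0  # 0-based half-open reference interval spanned
    end: int = 0

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=np.uint8))
        if self.rows.shape[0] != len(self.sample_ids):
            raise ValueError("one row per sample required")
        if self.rows.shape[1] < 1:
            raise ValueError("empty alignment block")
        bad = set(np.unique(self.rows).tobytes()) - set(_ALPHABET)
        if bad:
            raise ValueError(f"unexpected characters in block: {bad}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (self.rows.shape[1],):
                raise ValueError("confidence vector must have one entry per column")
            if np.any((self.confidence < 0) | (self.confidence > 100)):
                raise ValueError("confidence scores must lie in [0, 100]")

    @classmethod
    def from_strings(cls, block_id: str, rows: dict[str, str], **kw) -> "AlignmentBlock":
        ids = list(rows)
        mat = np.vstack([_as_u8(rows[s]) for s in ids])
        return cls(block_id, ids, mat, **kw)

    @property
    def n_columns(self) -> int:
        return int(self.rows.shape[1])

    def row(self, sample_id: str) -> np.ndarray:
        return self.rows[self.sample_ids.index(sample_id)]

    def row_str(self, sample_id: str) -> str:
        return self.row(sample_id).tobytes().decode("ascii")


def filter_short_blocks(blocks: Iterable[AlignmentBlock],
                        min_len: int = 60) -> list[AlignmentBlock]:
    """Drop blocks shorter than ``min_len`` alignment columns (gap columns count).

    The boundary is strict: a block of exactly ``min_len`` columns is retained.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [b for b in blocks if b.n_columns >= min_len]


def apply_confidence_mask(block: AlignmentBlock,
                          threshold: float = 60.0) -> AlignmentBlock:
    """Set every column with confidence < ``threshold`` to ``N`` in all rows.

    Strict inequality: a column scored exactly at the threshold is kept.
    Idempotent; raises if the block carries no confidence vector.
    """
    if block.confidence is None:
        raise ValueError(f"block {block.block_id!r} has no confidence vector")
    rows = block.rows.copy()
    rows[:, block.confidence < threshold] = ord("N")
    return AlignmentBlock(block.block_id, list(block.sample_ids), rows,
                          confidence=block.confidence.copy(),
                          chrom=block.chrom, start=block.start, end=block.end)


def coverage_summary(blocks: Iterable[AlignmentBlock],
                     region_length: int) -> tuple[int, float]:
    """Distinct reference positions spanned by the blocks, and their fraction.

    Overlapping blocks are counted once (set union of reference intervals).
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    ivals = sorted((b.start, b.end) for b in blocks if b.end > b.start)
    covered = 0
    cur_s, cur_e = None, None
    for s, e in ivals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered, covered / region_length


# ----------------------------------------------------------------- text IO

def write_maf_like(blocks: Sequence[AlignmentBlock], path) -> None:
    """Write blocks in a minimal MAF-like dialect (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##maf-like supergene v1\n")
        for b in blocks:
            fh.write(f"a block={b.block_id} chrom={b.chrom} "
                     f"start={b.start + 1} end={b.end}\n")
            for sid in b.sample_ids:
                fh.write(f"s {sid} {b.row_str(sid)}\n")
            fh.write("\n")


def read_maf_like(path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    meta = None
    rows: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                if meta is not None and rows:
                    blocks.append(_block_from(meta, rows))
                    meta, rows = None, {}
                continue
            if line.startswith("a "):
                if meta is not None and rows:
                    blocks.append(_block_from(meta, rows))
                    rows = {}
                meta = dict(kv.split("=", 1) for kv in line[2:].split())
            elif line.startswith("s "):
                _, sid, seq = line.split(maxsplit=2)
                rows[sid] = seq
    if meta is not None and rows:
        blocks.append(_block_from(meta, rows))
    return blocks


def _block_from(meta: dict, rows: dict[str, str]) -> AlignmentBlock:
    return AlignmentBlock.from_strings(
        meta["block"], rows, chrom=meta.get("chrom", "chr16"),
        start=int(meta.get("start", 1)) - 1, end=int(meta.get("end", 0)))


def write_block_fasta(block: AlignmentBlock, path) -> None:
    """One alignment block as multi-FASTA (1-based closed interval in headers)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(block.row_str(sid)), id=sid,
                  description=f"{block.block_id} {block.chrom}:"
                              f"{block.start + 1}-{block.end}")
        for sid in block.sample_ids]
    SeqIO.write(records, str(path), "fasta")


def read_block_fasta(path, block_id: str | None = None,
                     chrom: str = "chr16", start: int = 0) -> AlignmentBlock:
    """Read one multi-FASTA alignment back into a block (no confidence)."""
    from Bio import SeqIO

    rows: dict[str, str] = {}
    meta_id = block_id
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
        if meta_id is None and rec.description:
            parts = rec.description.split()
            if len(parts) >= 2:
                meta_id = parts[1]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    ncol = len(next(iter(rows.values())))
    return AlignmentBlock.from_strings(meta_id or "block", rows,
                                       chrom=chrom, start=start,
                                       end=start + ncol)


def write_confidence_tsv(blocks: Sequence[AlignmentBlock], path) -> None:
    """Sidecar TSV of per-column confidence (column_index is 1-based)."""
    with open(path, "w") as fh:
        fh.write("block_id\tcolumn_index\tscore\n")
        for b in blocks:
            if b.confidence is None:
                continue
            for i, sc in enumerate(b.confidence, start=1):
                fh.write(f"{b.block_id}\t{i}\t{sc:.6g}\n")


def read_confidence_tsv(path) -> dict[str, np.ndarray]:
    per_block: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            bid, idx, sc = line.rstrip("\n").split("\t")
            per_block.setdefault(bid, []).append((int(idx), float(sc)))
    out = {}
    for bid, items in per_block.items():
        items.sort()
        out[bid] = np.array([sc for _, sc in items])
    return out


def attach_confidence(blocks: Sequence[AlignmentBlock],
                      conf: dict[str, np.ndarray]) -> list[AlignmentBlock]:
    """Return blocks with confidence vectors attached where available."""
    out = []
    for b in blocks:
        c = conf.get(b.block_id)
        out.append(AlignmentBlock(b.block_id, list(b.sample_ids), b.rows.copy(),
                                  confidence=None if c is None else c.copy(),
                                  chrom=b.chrom, start=b.start, end=b.end))
    return out
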