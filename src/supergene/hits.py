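"""Uniqueness filters assigning queries to the non-recombining region.

Two dialects of the same idea, applied before any distance is measured:

* genome mode (BLAST-style scaffold hits): accept a scaffold only when its top
  hit lands in the region with E <= 1e-4 and there is no competitive second
  hit — a second hit disqualifies the query if its E-value is itself <= 1e-4,
  or it has at least half the base matches of the top hit, or at most half
  the top hit's mismatch percentage. All three second-hit clauses are
  inclusive at the boundary, following the filtering rules verbatim.
* RAD mode (Bowtie-style read alignments, ranked by mismatches): accept when
  the top hit has at most 4 mismatches and any second hit has more than
  double the top hit's mismatches.

Rejection reasons name the first failing clause, in rule order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "HitGroup",
    "FilterDecision",
    "filter_genome_scaffold",
    "filter_rad_alignment",
    "collect_region_queries",
    "write_blast_tabular",
    "read_blast_tabular",
    "read_sam_hits",
    "write_decisions_tsv",
]

EVALUE_MAX = 1e-4
RAD_MAX_MISMATCHES = 4

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


@dataclass
class HitRecord:
    """One ranked alignment hit of a query against a subject sequence."""

    query_id: str
    subject_id: str
    evalue: float = 0.0
    n_base_matches: int = 0
    pct_mismatch: float = 0.0
    n_mismatches: int | None = None      # RAD mode
    subject_interval: tuple[int, int] = (1, 1)  # 1-based closed
    # raw BLAST-tabular payload kept for bit-exact round trips
    length: int | None = None
    gapopen: int = 0
    qstart: int = 1
    qend: int = 1
    bitscore: float = 0.0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not 0 <= self.pct_mismatch <= 100:
            raise ValueError("pct_mismatch must lie in [0, 100]")
        if self.n_base_matches < 0:
            raise ValueError("n_base_matches must be >= 0")


@dataclass
class HitGroup:
    """All hits of one query, sorted best-first.

    Genome mode ranks by ascending E-value, RAD mode by ascending mismatch
    count; ties break by (bitscore descending, subject_id ascending).
    """

    query_id: str
    hits: list[HitRecord] = field(default_factory=list)
    mode: str = "genome"  # or "rad"

    def __post_init__(self):
        if not self.hits:
            raise ValueError(f"query {self.query_id!r} has no hits")
        if any(h.query_id != self.query_id for h in self.hits):
            raise ValueError("hit query_id mismatch within group")
        if self.mode == "rad" and any(h.n_mismatches is None for h in self.hits):
            raise ValueError("RAD mode requires mismatch counts on every hit")
        if self._sort_keys() != sorted(self._sort_keys()):
            raise ValueError(f"hits of {self.query_id!r} are not sorted best-first")

    def _sort_keys(self):
        if self.mode == "rad":
            return [(h.n_mismatches, -h.bitscore, h.subject_id) for h in self.hits]
        return [(h.evalue, -h.bitscore, h.subject_id) for h in self.hits]

    @classmethod
    def from_records(cls, query_id: str, hits: Iterable[HitRecord],
                     mode: str = "genome") -> "HitGroup":
        hits = list(hits)
        if mode == "rad":
            hits.sort(key=lambda h: (h.n_mismatches, -h.bitscore, h.subject_id))
        else:
            hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        return cls(query_id, hits, mode=mode)

    @property
    def top(self) -> HitRecord:
        return self.hits[0]

    @property
    def second(self) -> HitRecord | None:
        return self.hits[1] if len(self.hits) > 1 else None


@dataclass
class FilterDecision:
    query_id: str
    accepted: bool
    reason: str  # "ok" or the first failing clause


def filter_genome_scaffold(group: HitGroup,
                           region_subjects: set[str],
                           evalue_max: float = EVALUE_MAX) -> FilterDecision:
    """Apply the scaffold-uniqueness rules to one query's ranked BLAST hits."""
    top, second = group.top, group.second
    if top.subject_id not in region_subjects:
        return FilterDecision(group.query_id, False, "top_hit_outside_region")
    if not top.evalue <= evalue_max:
        return FilterDecision(group.query_id, False, "top_evalue_above_threshold")
    if second is not None:
        if second.evalue <= evalue_max:
            return FilterDecision(group.query_id, False,
                                  "second_evalue_significant")
        if second.n_base_matches >= 0.5 * top.n_base_matches:
            return FilterDecision(group.query_id, False,
                                  "second_matches_half_or_more")
        if second.pct_mismatch <= 0.5 * top.pct_mismatch:
            return FilterDecision(group.query_id, False,
                                  "second_mismatch_pct_half_or_less")
    return FilterDecision(group.query_id, True, "ok")


def filter_rad_alignment(group: HitGroup,
                         max_mismatches: int = RAD_MAX_MISMATCHES
                         ) -> FilterDecision:
    """Apply the RAD read-uniqueness rules (mismatch-ranked hits)."""
    top, second = group.top, group.second
    if top.n_mismatches is None:
        raise ValueError("RAD filtering requires mismatch counts")
    if top.n_mismatches > max_mismatches:
        return FilterDecision(group.query_id, False, "top_mismatches_above_max")
    if second is not None and second.n_mismatches <= 2 * top.n_mismatches:
        return FilterDecision(group.query_id, False,
                              "second_mismatches_within_double")
    return FilterDecision(group.query_id, True, "ok")


def collect_region_queries(groups: Sequence[HitGroup],
                           region_subjects: set[str] | None = None,
                           mode: str = "genome") -> dict[str, FilterDecision]:
    """Filter every group; returns {query_id: decision} in sorted query order."""
    out: dict[str, FilterDecision] = {}
    for g in sorted(groups, key=lambda g: g.query_id):
        if mode == "rad" or g.mode == "rad":
            out[g.query_id] = filter_rad_alignment(g)
        else:
            if region_subjects is None:
                raise ValueError("genome mode requires region_subjects")
            out[g.query_id] = filter_genome_scaffold(g, region_subjects)
    return out


def accepted_queries(decisions: dict[str, FilterDecision]) -> list[str]:
    return sorted(q for q, d in decisions.items() if d.accepted)


# ----------------------------------------------------------------- text IO

def write_blast_tabular(groups: Sequence[HitGroup], path) -> None:
    """12-column BLAST outfmt-6 dialect; one line per hit, best-first."""
    with open(path, "w") as fh:
        for g in groups:
            for h in g.hits:
                length = h.length if h.length is not None else (
                    h.n_base_matches + (h.n_mismatches or 0))
                mism = h.n_mismatches if h.n_mismatches is not None else (
                    length - h.n_base_matches)
                pident = 100.0 - h.pct_mismatch
                fh.write("\t".join(map(str, [
                    g.query_id, h.subject_id, f"{pident:.3f}", length, mism,
                    h.gapopen, h.qstart, h.qend,
                    h.subject_interval[0], h.subject_interval[1],
                    f"{h.evalue:.3g}", f"{h.bitscore:.1f}"])) + "\n")


def read_blast_tabular(path, mode: str = "genome") -> list[HitGroup]:
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    groups = []
    for qid, sub in df.groupby("qseqid", sort=True):
        hits = []
        for r in sub.itertuples(index=False):
            hits.append(HitRecord(
                query_id=str(qid), subject_id=str(r.sseqid),
                evalue=float(r.evalue),
                n_base_matches=int(r.length) - int(r.mismatch),
                pct_mismatch=100.0 - float(r.pident),
                n_mismatches=int(r.mismatch),
                subject_interval=(int(r.sstart), int(r.send)),
                length=int(r.length), gapopen=int(r.gapopen),
                qstart=int(r.qstart), qend=int(r.qend),
                bitscore=float(r.bitscore)))
        groups.append(HitGroup.from_records(str(qid), hits, mode=mode))
    return groups


def read_sam_hits(path) -> list[HitGroup]:
    """Ranked RAD hit groups from a SAM file (uses the NM tag as mismatches).

    Secondary alignments (FLAG 0x100) of a read rank after its primary hit by
    mismatch count. Unmapped records are skipped.
    """
    import pysam

    per_query: dict[str, list[HitRecord]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            qlen = rec.query_length or (rec.query_alignment_length or 0)
            per_query.setdefault(rec.query_name, []).append(HitRecord(
                query_id=rec.query_name, subject_id=rec.reference_name,
                evalue=0.0, n_base_matches=max(qlen - nm, 0),
                pct_mismatch=100.0 * nm / qlen if qlen else 0.0,
                n_mismatches=nm,
                subject_interval=(rec.reference_start + 1, rec.reference_end or
                                  rec.reference_start + 1)))
    return [HitGroup.from_records(q, hits, mode="rad")
            for q, hits in sorted(per_query.items())]


def write_decisions_tsv(decisions: dict[str, FilterDecision], path) -> None:
    rows = [(q, "accept" if d.accepted else "reject", d.reason)
            for q, d in sorted(decisions.items())]
    pd.DataFrame(rows, columns=["query_id", "decision", "reason"]) \
        .to_csv(path, sep="\t", index=False)
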