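"""Synthetic data with known truth for the supergene dating pipeline.

The generator emulates the study's evolutionary scenario:

* haplotype sequences evolved under JC69 (equal base frequencies, one rate
  parameter, no indels) along a species/haplotype tree: an outgroup splits
  from the ingroup at ``root_age``; inside the ingroup, the SB haplotypes of
  the two species and the monophyletic Sb clade are arranged according to
  which of ``speciation_age`` / ``supergene_age`` is older. Every branch
  inside the Sb clade — including its stem — evolves at
  ``sb_rate_multiplier`` times the base rate, modelling the relaxed purifying
  selection on the non-recombining haplotype.
* RAD-style loci: short windows of those haplotypes re-observed as read
  stacks with per-sample depths and an optional per-base error rate.
* SNP genotype tables: independent neutral coalescent windows per haplotype
  group (msprime), with the introduced-range Sb group passed through a
  founder bottleneck (founder resampling plus fresh private mutations).
* toy BLAST-tabular hit tables for exercising the uniqueness filters.

Every output is a deterministic function of ``seed``; one global seed expands
into per-stage child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylogeny import PhyloTree
from .qc import AlignmentBlock
from .hits import HitGroup, HitRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "RadLocus",
    "RadDataset",
    "simulate_haplotypes",
    "simulate_rad_dataset",
    "simulate_genotype_matrix",
    "make_hit_fixture",
    "make_random_hit_groups",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage indices for child-seed derivation
_STAGES = {"haplotypes": 0, "confidence": 1, "rad": 2, "genotypes": 3,
           "hits": 4, "read_pick": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimulationConfig:
    """Study-scale defaults for the fire-ant supergene scenario.

    Times are MY, rates substitutions/site/MY. The defaults put the SB depth
    below the SB/Sb divergence near 2.1 per 1,000 sites and the outgroup
    divergence at 25 MY, i.e. the reported scale of the system.
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: {
        "outgroup": 1, "invicta_SB": 7, "richteri_SB": 0, "Sb": 7})
    root_age: float = 25.0
    speciation_age: float = 1.26
    supergene_age: float = 1.1
    crown_age: float = 0.2
    base_rate: float = 1.9e-3
    sb_rate_multiplier: float = 1.4
    seq_length: int = 200_000
    n_blocks: int = 40
    low_confidence_fraction: float = 0.02
    # RAD emulation
    rad_locus_length: int = 90
    rad_locus_count: int = 400
    depth_distribution: tuple = ("poisson", 8.0)
    error_rate: float = 0.0
    # SNP-table emulation
    chrom: str = "chr16"
    chrom_length_bp: int = 5_000_000
    genotype_window_bp: int = 100_000
    genotype_groups: Mapping[str, tuple[int, str]] = field(
        default_factory=lambda: {
            "native_SB": (4, "neutral"),
            "native_Sb": (4, "neutral"),
            "introduced_SB": (7, "neutral"),
            "introduced_Sb": (6, "bottleneck")})
    pop_size: float = 75_000.0
    mutation_rate: float = 2e-8        # per site per generation
    founders: int = 1
    founder_private_rate: float = 5e-5  # expected private subs/site since founding
    seed: int = 0

    def __post_init__(self):
        for name in ("root_age", "speciation_age", "supergene_age",
                     "crown_age", "base_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sb_rate_multiplier < 0:
            raise ValueError("sb_rate_multiplier must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.rad_locus_length < 1:
            raise ValueError("rad_locus_length must be >= 1")
        if self.n_blocks < 1 or self.n_blocks > self.seq_length:
            raise ValueError("n_blocks must be in [1, seq_length]")
        sizes = dict(self.group_sizes)
        if sizes.get("outgroup", 0) < 1:
            raise ValueError("an outgroup haplotype is required")
        if sizes.get("invicta_SB", 0) < 1:
            raise ValueError("at least one invicta_SB haplotype is required")
        if any(v < 0 for v in sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.founders < 1:
            raise ValueError("founders must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")

    @classmethod
    def rad_default(cls, **kw) -> "SimulationConfig":
        """The 12-sample native-range RAD scenario (4+4+4 plus outgroup)."""
        kw.setdefault("group_sizes", {"outgroup": 1, "invicta_SB": 4,
                                      "richteri_SB": 4, "Sb": 4})
        return cls(**kw)


@dataclass
class _SimNode:
    age: float
    children: list = field(default_factory=list)
    label: str | None = None
    group: str | None = None
    in_sb: bool = False


def _crown(group: str, n: int, age: float, in_sb: bool) -> _SimNode:
    tips = [_SimNode(0.0, label=f"{group}_{i + 1}", group=group, in_sb=in_sb)
            for i in range(n)]
    if n == 1:
        return tips[0]
    return _SimNode(age, children=tips, in_sb=in_sb)


def _build_topology(cfg: SimulationConfig) -> _SimNode:
    sizes = dict(cfg.group_sizes)
    nI = sizes.get("invicta_SB", 0)
    nR = sizes.get("richteri_SB", 0)
    nS = sizes.get("Sb", 0)
    crown = min(cfg.crown_age, 0.5 * min(cfg.supergene_age, cfg.speciation_age))
    og = _crown("outgroup", sizes["outgroup"], crown, False)
    inv = _crown("invicta_SB", nI, crown, False)
    ric = _crown("richteri_SB", nR, crown, False) if nR else None
    sb = _crown("Sb", nS, crown, True) if nS else None
    t, s = cfg.supergene_age, cfg.speciation_age
    if sb is not None and ric is not None:
        if s >= t:
            # species split first; Sb nested inside the richteri subtree
            ingroup = _SimNode(s, children=[
                inv, _SimNode(t, children=[ric, sb])])
        else:
            # supergene older than speciation: SB clade nested under SB/Sb split
            ingroup = _SimNode(t, children=[
                sb, _SimNode(s, children=[inv, ric])])
    elif sb is not None:
        ingroup = _SimNode(t, children=[inv, sb])
    elif ric is not None:
        ingroup = _SimNode(s, children=[inv, ric])
    else:
        ingroup = inv
    if ingroup.age >= cfg.root_age:
        raise ValueError("root_age must exceed every ingroup divergence age")
    return _SimNode(cfg.root_age, children=[og, ingroup])


@dataclass
class TruthRecord:
    """Ground truth carried alongside every simulated dataset."""

    true_tree: PhyloTree                 # rooted, branch lengths subst/site
    true_lambda: float
    true_supergene_age: float
    true_speciation_age: float
    true_root_age: float
    base_rate: float
    groups: dict[str, str]               # tip label -> haplotype group
    mutation_counts: np.ndarray          # per-site substitution events
    sb_paths: np.ndarray                 # true SB/Sb-node -> Sb tip lengths
    sB_paths: np.ndarray                 # true SB/Sb-node -> sister-SB tip lengths

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)


def _evolve_jc69(seq: np.ndarray, d: float, rng: np.random.Generator,
                 counts: np.ndarray | None = None) -> np.ndarray:
    """One JC69 branch: each site differs from its parent w.p. (3/4)(1-e^{-4d/3})."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    child = seq.copy()
    if p > 0:
        mask = rng.random(seq.size) < p
        k = int(mask.sum())
        if k:
            child[mask] = (seq[mask] + rng.integers(1, 4, k)) % 4
            if counts is not None:
                counts[mask] += 1
    return child


def simulate_haplotypes(cfg: SimulationConfig
                        ) -> tuple[list[AlignmentBlock], TruthRecord]:
    """Evolve haplotype sequences on the configured tree and slice into blocks."""
    import dendropy

    rng = stage_rng(cfg.seed, "haplotypes")
    root = _build_topology(cfg)
    L = cfg.seq_length
    lam = cfg.sb_rate_multiplier
    counts = np.zeros(L, dtype=np.int32)
    seqs: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}

    labels = []

    def collect(node):
        if node.label is not None:
            labels.append(node.label)
        for c in node.children:
            collect(c)

    collect(root)
    ns = dendropy.TaxonNamespace(labels)

    def walk(node: _SimNode, seq: np.ndarray) -> "dendropy.Node":
        dnode = dendropy.Node()
        if node.label is not None:
            dnode.taxon = ns.get_taxon(node.label)
            seqs[node.label] = seq
            groups[node.label] = node.group
        for child in node.children:
            dt = node.age - child.age
            rate = cfg.base_rate * (lam if child.in_sb else 1.0)
            d = dt * rate
            cseq = _evolve_jc69(seq, d, rng, counts)
            cnode = walk(child, cseq)
            dnode.add_child(cnode)
            cnode.edge.length = d
        return dnode

    ancestral = rng.integers(0, 4, L, dtype=np.int8).astype(np.uint8)
    seed_node = walk(root, ancestral)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=seed_node)
    tree.is_rooted = True
    truth_tree = PhyloTree(tree)

    # true path lengths from the SB/Sb divergence node
    sb_tips = sorted(l for l, g in groups.items() if g == "Sb")
    sB_side = "richteri_SB" if any(g == "richteri_SB" for g in groups.values()) \
        and cfg.speciation_age >= cfg.supergene_age else "invicta_SB"
    sB_tips = sorted(l for l, g in groups.items() if g == sB_side)
    if sb_tips:
        div = truth_tree.mrca(sb_tips + sB_tips)
        sb_paths = truth_tree.path_lengths_from_node(div, sb_tips)
        sB_paths = truth_tree.path_lengths_from_node(div, sB_tips)
    else:
        sb_paths = np.array([])
        sB_paths = np.array([])

    truth = TruthRecord(
        true_tree=truth_tree, true_lambda=lam,
        true_supergene_age=cfg.supergene_age,
        true_speciation_age=cfg.speciation_age,
        true_root_age=cfg.root_age, base_rate=cfg.base_rate,
        groups=groups, mutation_counts=counts,
        sb_paths=sb_paths, sB_paths=sB_paths)

    # slice the concatenated alignment into contiguous blocks
    crng = stage_rng(cfg.seed, "confidence")
    bounds = np.linspace(0, L, cfg.n_blocks + 1).astype(int)
    sample_ids = sorted(seqs)
    blocks = []
    for bi in range(cfg.n_blocks):
        s, e = int(bounds[bi]), int(bounds[bi + 1])
        if e <= s:
            continue
        rows = np.vstack([_BASES[seqs[sid][s:e]] for sid in sample_ids])
        ncol = e - s
        low = crng.random(ncol) < cfg.low_confidence_fraction
        conf = np.where(low, crng.uniform(0.0, 60.0, ncol),
                        crng.uniform(60.0, 100.0, ncol))
        blocks.append(AlignmentBlock(
            f"blk{bi + 1:05d}", list(sample_ids), rows, confidence=conf,
            chrom=cfg.chrom, start=s, end=e))
    return blocks, truth


# ------------------------------------------------------------------- RAD

@dataclass
class RadLocus:
    locus_id: str
    start: int   # 0-based on the simulated haplotype coordinate
    length: int


@dataclass
class RadDataset:
    """Per-locus read stacks per sample, plus the generating truth."""

    chrom: str
    sample_ids: list[str]
    loci: list[RadLocus]
    reads: dict[str, dict[str, list[str]]]  # locus_id -> sample -> reads
    truth: TruthRecord
    true_haplotypes: dict[str, np.ndarray]  # sample -> uint8 letter codes


def _draw_depth(dist: tuple, rng: np.random.Generator) -> int:
    kind, par = dist
    if kind == "constant":
        return int(par)
    if kind == "poisson":
        return int(rng.poisson(par))
    raise ValueError(f"unknown depth distribution {kind!r}")


def simulate_rad_dataset(cfg: SimulationConfig) -> RadDataset:
    """Re-observe simulated haplotypes as RAD-style read stacks."""
    if cfg.rad_locus_length < 1:
        raise ValueError("rad_locus_length must be >= 1")
    blocks, truth = simulate_haplotypes(cfg)
    # reconstruct full per-sample sequences from the blocks
    sample_ids = list(blocks[0].sample_ids)
    full = {s: np.concatenate([b.row(s) for b in blocks]) for s in sample_ids}
    rng = stage_rng(cfg.seed, "rad")
    n_slots = cfg.seq_length // cfg.rad_locus_length
    count = min(cfg.rad_locus_count, n_slots)
    slots = np.sort(rng.choice(n_slots, size=count, replace=False))
    loci = [RadLocus(f"locus{i + 1:05d}", int(sl) * cfg.rad_locus_length,
                     cfg.rad_locus_length) for i, sl in enumerate(slots)]
    reads: dict[str, dict[str, list[str]]] = {}
    for loc in loci:
        sl = slice(loc.start, loc.start + loc.length)
        stacks: dict[str, list[str]] = {}
        for s in sample_ids:
            hap = full[s][sl]
            depth = _draw_depth(cfg.depth_distribution, rng)
            rlist = []
            for _ in range(depth):
                read = hap.copy()
                if cfg.error_rate > 0:
                    mask = rng.random(read.size) < cfg.error_rate
                    k = int(mask.sum())
                    if k:
                        cur = read[mask]
                        # map letters back to 0..3, shift, map forward
                        code = np.searchsorted(_BASES, cur)
                        read[mask] = _BASES[(code + rng.integers(1, 4, k)) % 4]
                rlist.append(read.tobytes().decode("ascii"))
            stacks[s] = rlist
        reads[loc.locus_id] = stacks
    return RadDataset(cfg.chrom, sample_ids, loci, reads, truth, full)


# -------------------------------------------------------------- SNP tables

def simulate_genotype_matrix(cfg: SimulationConfig):
    """SNP table with per-sample depths; independent coalescent windows.

    Each haplotype group is simulated independently. Neutral groups are
    constant-size panmictic coalescent samples (msprime); sites segregating
    in one group are monomorphic reference in the others. Bottleneck groups
    descend from ``cfg.founders`` founder haplotype(s) drawn from a neutral
    native panel, then accumulate private mutations at
    ``cfg.founder_private_rate`` per site per sample.
    """
    import msprime

    from .tajima import GenotypeMatrix

    rng = stage_rng(cfg.seed, "genotypes")
    samples: list[str] = []
    groups: dict[str, str] = {}
    specs = []
    for gname, (n, demog) in cfg.genotype_groups.items():
        if n < 1:
            raise ValueError(f"group {gname!r} has size < 1")
        ids = [f"{gname}_{i + 1}" for i in range(n)]
        samples.extend(ids)
        for s in ids:
            groups[s] = gname
        specs.append((gname, ids, demog))

    W = cfg.genotype_window_bp
    n_windows = max(1, cfg.chrom_length_bp // W)
    site_pos: list[int] = []
    site_geno: list[np.ndarray] = []
    used: set[int] = set()

    def add_site(pos: int, geno_row: np.ndarray):
        while pos in used:
            pos += 1
        used.add(pos)
        site_pos.append(pos)
        site_geno.append(geno_row)

    col_of = {s: k for k, s in enumerate(samples)}
    for w in range(n_windows):
        w_start = w * W
        for gname, ids, demog in specs:
            mseed = int(rng.integers(1, 2**31 - 1))
            if demog == "neutral":
                ts = msprime.sim_ancestry(
                    samples=len(ids), ploidy=1,
                    population_size=cfg.pop_size,
                    sequence_length=W, random_seed=mseed)
                mts = msprime.sim_mutations(
                    ts, rate=cfg.mutation_rate,
                    random_seed=mseed + 1,
                    model=msprime.BinaryMutationModel())
                for var in mts.variants():
                    g = np.asarray(var.genotypes, dtype=np.int8)
                    g = (g > 0).astype(np.int8)
                    if 0 < g.sum() < len(ids):
                        row = np.zeros(len(samples), dtype=np.int8)
                        for sid, allele in zip(ids, g):
                            row[col_of[sid]] = allele
                        add_site(w_start + int(var.site.position) + 1, row)
            elif demog == "bottleneck":
                nf = cfg.founders
                founder_geno = {}
                if nf > 1:
                    ts = msprime.sim_ancestry(
                        samples=nf, ploidy=1, population_size=cfg.pop_size,
                        sequence_length=W, random_seed=mseed)
                    mts = msprime.sim_mutations(
                        ts, rate=cfg.mutation_rate, random_seed=mseed + 1,
                        model=msprime.BinaryMutationModel())
                    assign = rng.integers(0, nf, len(ids))
                    for var in mts.variants():
                        g = (np.asarray(var.genotypes) > 0).astype(np.int8)
                        inherited = g[assign]
                        if 0 < inherited.sum() < len(ids):
                            row = np.zeros(len(samples), dtype=np.int8)
                            for sid, allele in zip(ids, inherited):
                                row[col_of[sid]] = allele
                            add_site(w_start + int(var.site.position) + 1, row)
                # fresh private mutations: singletons per introduced sample
                for sid in ids:
                    k = rng.poisson(cfg.founder_private_rate * W)
                    for pos in rng.integers(0, W, int(k)):
                        row = np.zeros(len(samples), dtype=np.int8)
                        row[col_of[sid]] = 1
                        add_site(w_start + int(pos) + 1, row)
            else:
                raise ValueError(f"unknown demography {demog!r}")

    order = np.argsort(site_pos, kind="stable")
    positions = np.array(site_pos, dtype=np.int64)[order]
    geno = (np.vstack(site_geno)[order] if site_geno
            else np.zeros((0, len(samples)), dtype=np.int8))
    depths = np.empty(geno.shape, dtype=np.int32)
    kind, par = cfg.depth_distribution
    if kind == "constant":
        depths[:] = int(par)
    elif kind == "poisson":
        depths[:] = rng.poisson(par, size=geno.shape)
    else:
        raise ValueError(f"unknown depth distribution {kind!r}")
    return GenotypeMatrix(chrom=cfg.chrom, positions=positions,
                          samples=samples, genotypes=geno, depths=depths,
                          groups=groups,
                          chrom_length_bp=cfg.chrom_length_bp)


# ------------------------------------------------------------ hit fixtures

def make_hit_fixture(spec: Sequence[tuple[str, Sequence[dict]]],
                     mode: str = "genome") -> list[HitGroup]:
    """HitGroups from an explicit (query, ranked-hit-dicts) description.

    Hits must already be listed best-first; an unsorted list raises. The
    result round-trips through the BLAST-tabular writer/reader bit-exactly.
    """
    groups = []
    for query_id, hitdicts in spec:
        hits = [HitRecord(query_id=query_id, **hd) for hd in hitdicts]
        groups.append(HitGroup(query_id, hits, mode=mode))
    return groups


def make_random_hit_groups(n: int, seed: int, mode: str = "genome",
                           region_subjects: Sequence[str] = ("chr16_nr",),
                           other_subjects: Sequence[str] = ("chr3", "chr7"),
                           ) -> list[HitGroup]:
    """Randomized hit groups spanning the filters' decision boundaries."""
    rng = stage_rng(seed, "hits")
    subjects = list(region_subjects) + list(other_subjects)
    groups = []
    for i in range(n):
        nh = int(rng.integers(1, 4))
        hits = []
        for j in range(nh):
            length = int(rng.integers(40, 400))
            mism = int(rng.integers(0, max(2, length // 8)))
            hits.append(HitRecord(
                query_id=f"q{i + 1}",
                subject_id=subjects[int(rng.integers(0, len(subjects)))],
                evalue=float(10.0 ** rng.uniform(-12, -2)),
                n_base_matches=length - mism,
                pct_mismatch=100.0 * mism / length,
                n_mismatches=mism,
                subject_interval=(1, length),
                length=length,
                bitscore=float(rng.uniform(30, 500))))
        groups.append(HitGroup.from_records(f"q{i + 1}", hits, mode=mode))
    return groups


# ----------------------------------------------------------------- truth IO

def write_truth(truth: TruthRecord, path) -> None:
    """Flat key=value text file plus the true tree in newick."""
    with open(path, "w") as fh:
        fh.write(f"true_lambda={truth.true_lambda!r}\n")
        fh.write(f"true_supergene_age={truth.true_supergene_age!r}\n")
        fh.write(f"true_speciation_age={truth.true_speciation_age!r}\n")
        fh.write(f"true_root_age={truth.true_root_age!r}\n")
        fh.write(f"base_rate={truth.base_rate!r}\n")
        fh.write(f"total_mutations={int(truth.mutation_counts.sum())}\n")
        fh.write(f"true_tree={truth.true_tree.to_newick()}\n")


def read_truth(path) -> dict[str, object]:
    out: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("=", 1)
            if key == "true_tree":
                out[key] = PhyloTree.from_newick(val)
            elif key == "total_mutations":
                out[key] = int(val)
            else:
                out[key] = float(val)
    return out
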