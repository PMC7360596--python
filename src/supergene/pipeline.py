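"""End-to-end orchestration: simulate -> filter -> QC -> distances -> tree ->
date -> Tajima scan -> report.

Every stage reads and writes plain-text files inside one output directory, so
any stage can be rerun or inspected in isolation. A manifest records a
checksum of each stage's inputs (including the resolved configuration) and
outputs; reruns skip stages whose checksums still match. The resolved
configuration is written next to the outputs of every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distances as dist_mod
from . import hits as hits_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from . import tajima as taj_mod
from .dating import (CalibrationSpec, DatingResult, acceleration_factor,
                     calibrated_age, ordering_test, relative_ratio)
from .phylogeny import PhyloTree, build_nj_tree

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ["simulate", "filter_hits", "qc", "distances", "tree", "date",
          "tajima", "report"]


@dataclass
class RunConfig:
    """Pipeline settings; the threshold defaults are the study's settings."""

    outdir: str = "run"
    seed: int = 1
    simulate: bool = True
    sim: sim_mod.SimulationConfig = field(default_factory=lambda:
        sim_mod.SimulationConfig(group_sizes={
            "outgroup": 1, "invicta_SB": 4, "richteri_SB": 4, "Sb": 4}))
    evalue_max: float = 1e-4
    min_block_len: int = 60
    mask_threshold: float = 60.0
    rad_max_mismatches: int = 4
    min_depth: int = 6
    depth_mode: str = "whole_genome"
    window_bp: int = 100_000
    calibration: tuple = (25.0, 18.0, 32.0)
    region_length: int | None = None   # defaults to sim.seq_length
    resume: bool = True
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # external inputs (used when simulate=False)
    blocks_path: str | None = None
    confidence_path: str | None = None
    hits_path: str | None = None
    groups_path: str | None = None
    vcf_path: str | None = None

    def __post_init__(self):
        if self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # ------------------------------------------------------------- yaml IO
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["group_sizes"] = dict(d["sim"]["group_sizes"])
        d["sim"]["genotype_groups"] = {
            k: list(v) for k, v in d["sim"]["genotype_groups"].items()}
        d["sim"]["depth_distribution"] = list(d["sim"]["depth_distribution"])
        d["calibration"] = list(d["calibration"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        simd = dict(d.pop("sim", {}))
        if "genotype_groups" in simd:
            simd["genotype_groups"] = {
                k: (int(v[0]), str(v[1]))
                for k, v in simd["genotype_groups"].items()}
        if "depth_distribution" in simd:
            dd = simd["depth_distribution"]
            simd["depth_distribution"] = (str(dd[0]), float(dd[1]))
        if "calibration" in d:
            d["calibration"] = tuple(float(x) for x in d["calibration"])
        cfg = cls(**{**d, "sim": sim_mod.SimulationConfig(**simd)})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------- caching

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, inputs_hash: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if not rec or rec["inputs_hash"] != inputs_hash:
            return False
        for f, digest in rec["outputs"].items():
            p = Path(f)
            if not p.exists() or _sha256(p) != digest:
                return False
        return set(rec["outputs"]) == {str(p) for p in outputs}

    def record(self, stage: str, inputs_hash: str, outputs: list[Path]):
        self.data[stage] = {
            "inputs_hash": inputs_hash,
            "outputs": {str(p): _sha256(p) for p in outputs}}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _inputs_hash(cfg: RunConfig, files: list[Path]) -> str:
    h = hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode())
    for f in files:
        h.update(str(f).encode())
        if f.exists():
            h.update(_sha256(f).encode())
    return h.hexdigest()


# ---------------------------------------------------------------- stages

def _float_fmt(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(cfg: RunConfig, log=print) -> dict:
    """Run the configured stages in dependency order; returns report values."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.write_yaml(out / "resolved_config.yaml")
    man = _Manifest(out)
    want = set(cfg.stages)
    report: dict = {"seed": cfg.seed}

    paths = {
        "blocks": out / "blocks.maf",
        "confidence": out / "confidence.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.txt",
        "hits": out / "hits.tsv",
        "vcf": out / "genotypes.vcf",
        "decisions": out / "hit_decisions.tsv",
        "qc_blocks": out / "qc_blocks.maf",
        "coverage": out / "coverage.tsv",
        "dist_sq": out / "distances_square.tsv",
        "dist_long": out / "distances_long.tsv",
        "group_summary": out / "group_summary.tsv",
        "tree": out / "tree_rooted.nwk",
        "dating": out / "dating.tsv",
        "windows": out / "tajima_windows.tsv",
        "segments": out / "tajima_segments.tsv",
        "report": out / "report.txt",
    }
    if not cfg.simulate:
        for key, attr in [("blocks", "blocks_path"),
                          ("confidence", "confidence_path"),
                          ("hits", "hits_path"), ("groups", "groups_path"),
                          ("vcf", "vcf_path")]:
            p = getattr(cfg, attr)
            if p is not None:
                paths[key] = Path(p)

    def stage(name, inputs, outputs, fn):
        if name not in want:
            return
        for p in inputs:
            if not p.exists():
                raise FileNotFoundError(
                    f"stage {name!r}: missing input {p}")
        ih = _inputs_hash(cfg, inputs)
        if cfg.resume and man.fresh(name, ih, outputs):
            log(f"[{name}] cached, skipping")
            return
        log(f"[{name}] running")
        fn()
        man.record(name, ih, outputs)

    # ------------------------------------------------------------ simulate
    def do_simulate():
        blocks, truth = sim_mod.simulate_haplotypes(cfg.sim)
        qc_mod.write_maf_like(blocks, paths["blocks"])
        qc_mod.write_confidence_tsv(blocks, paths["confidence"])
        ga = dist_mod.GroupAssignment(
            dict(truth.groups),
            {s: "simulated" for s in truth.groups})
        ga.write_tsv(paths["groups"])
        sim_mod.write_truth(truth, paths["truth"])
        truth.true_tree.write_newick(out / "true_tree.nwk")
        hit_groups = sim_mod.make_random_hit_groups(200, cfg.seed)
        hits_mod.write_blast_tabular(hit_groups, paths["hits"])
        gm = sim_mod.simulate_genotype_matrix(cfg.sim)
        taj_mod.write_vcf(gm, paths["vcf"])

    if cfg.simulate:
        stage("simulate", [],
              [paths[k] for k in ("blocks", "confidence", "groups", "truth",
                                  "hits", "vcf")] + [out / "true_tree.nwk"],
              do_simulate)

    # --------------------------------------------------------- filter hits
    def do_filter_hits():
        groups = hits_mod.read_blast_tabular(paths["hits"])
        decisions = hits_mod.collect_region_queries(
            groups, region_subjects={"chr16_nr"})
        hits_mod.write_decisions_tsv(decisions, paths["decisions"])
        report["n_hits_accepted"] = sum(
            1 for d in decisions.values() if d.accepted)
        report["n_hits_total"] = len(decisions)

    stage("filter_hits", [paths["hits"]], [paths["decisions"]],
          do_filter_hits)

    # ----------------------------------------------------------------- qc
    def do_qc():
        blocks = qc_mod.read_maf_like(paths["blocks"])
        conf = qc_mod.read_confidence_tsv(paths["confidence"])
        blocks = qc_mod.attach_confidence(blocks, conf)
        blocks = qc_mod.filter_short_blocks(blocks, cfg.min_block_len)
        blocks = [qc_mod.apply_confidence_mask(b, cfg.mask_threshold)
                  if b.confidence is not None else b for b in blocks]
        qc_mod.write_maf_like(blocks, paths["qc_blocks"])
        region_len = cfg.region_length or cfg.sim.seq_length
        covered, frac = qc_mod.coverage_summary(blocks, region_len)
        pd.DataFrame([{"covered_bases": covered, "region_length": region_len,
                       "fraction": round(frac, 6)}]) \
            .to_csv(paths["coverage"], sep="\t", index=False)
        report["covered_bases"] = covered
        report["coverage_fraction"] = frac

    stage("qc", [paths["blocks"], paths["confidence"]],
          [paths["qc_blocks"], paths["coverage"]], do_qc)

    # ------------------------------------------------------------ distances
    def do_distances():
        blocks = qc_mod.read_maf_like(paths["qc_blocks"])
        dm = dist_mod.pairwise_matrix(blocks)
        dm.to_square_tsv(paths["dist_sq"], per_1000=True)
        dm.to_long_tsv(paths["dist_long"])
        ga = dist_mod.GroupAssignment.read_tsv(paths["groups"])
        pairs = _summary_pairs(ga)
        summ = dist_mod.group_distance_summary(dm, ga, pairs)
        summ.to_csv(paths["group_summary"], sep="\t", index=False,
                    float_format="%.6f")

    stage("distances", [paths["qc_blocks"], paths["groups"]],
          [paths["dist_sq"], paths["dist_long"], paths["group_summary"]],
          do_distances)

    # ---------------------------------------------------------------- tree
    def do_tree():
        dm = _read_square_tsv(paths["dist_sq"])
        ga = dist_mod.GroupAssignment.read_tsv(paths["groups"])
        tree = build_nj_tree(dm)
        og = ga.members("outgroup")
        rooted = tree.root_with_outgroup(og)
        rooted.write_newick(paths["tree"])

    stage("tree", [paths["dist_sq"], paths["groups"]], [paths["tree"]],
          do_tree)

    # ---------------------------------------------------------------- date
    def do_date():
        tree = PhyloTree.read_newick(paths["tree"])
        ga = dist_mod.GroupAssignment.read_tsv(paths["groups"])
        dm = _read_square_tsv(paths["dist_sq"])
        res = date_from_tree(tree, ga, dm,
                             CalibrationSpec(*cfg.calibration), seed=cfg.seed)
        rows = [("lambda_hat", res.lambda_hat), ("lambda_sd", res.lambda_sd),
                ("wilcoxon_p", res.wilcoxon_p), ("ratio_R", res.ratio_R),
                ("age_point_mya", res.age_point),
                ("age_ci_low_mya", res.age_ci[0]),
                ("age_ci_high_mya", res.age_ci[1]),
                ("t_rB_per_1000", res.t_rB), ("s_rB_per_1000", res.s_rB),
                ("ordering", res.ordering),
                ("ordering_p", res.ordering_p)]
        with open(paths["dating"], "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in rows:
                v = _float_fmt(v) if isinstance(v, float) else str(v)
                fh.write(f"{k}\t{v}\n")
        report["dating"] = {k: v for k, v in rows}

    stage("date", [paths["tree"], paths["groups"], paths["dist_sq"]],
          [paths["dating"]], do_date)

    # -------------------------------------------------------------- tajima
    def do_tajima():
        gm = taj_mod.read_vcf(paths["vcf"])
        gm.groups = {s: s.rsplit("_", 1)[0] for s in gm.samples}
        seg_rows = []
        all_windows = []
        for group in sorted(set(gm.groups.values())):
            sub = gm.subset_group(group)
            sub = taj_mod.depth_filter(sub, cfg.depth_mode, cfg.min_depth)
            stats = taj_mod.windowed_scan(sub, cfg.window_bp)
            for w in stats:
                all_windows.append((group, w))
            length = sub.chrom_length_bp or (
                int(sub.positions[-1]) if sub.n_sites else cfg.window_bp)
            seg = taj_mod.segment_summary(stats, (1, length))
            seg_rows.append({"group": group, **seg})
        with open(paths["windows"], "w") as fh:
            fh.write("group\tchrom\tstart\tend\tn\tS\tpi\tD\tflag\n")
            for group, w in all_windows:
                d = "NA" if not w.defined else f"{w.D:.6f}"
                fh.write(f"{group}\t{w.chrom}\t{w.start}\t{w.end}\t{w.n}\t"
                         f"{w.S}\t{w.pi:.6f}\t{d}\t{w.p_flag}\n")
        pd.DataFrame(seg_rows).to_csv(paths["segments"], sep="\t",
                                      index=False, float_format="%.6f")
        report["tajima_segments"] = seg_rows

    stage("tajima", [paths["vcf"]], [paths["windows"], paths["segments"]],
          do_tajima)

    # -------------------------------------------------------------- report
    def do_report():
        lines = ["supergene pipeline report", "=" * 40,
                 f"seed: {cfg.seed}"]
        if paths["dating"].exists():
            lines.append("\n[dating]")
            lines.extend(paths["dating"].read_text().splitlines()[1:])
        if paths["group_summary"].exists():
            lines.append("\n[group distances, substitutions/1000 sites]")
            lines.extend(paths["group_summary"].read_text().splitlines())
        if paths["segments"].exists():
            lines.append("\n[Tajima's D segments]")
            lines.extend(paths["segments"].read_text().splitlines())
        paths["report"].write_text("\n".join(lines) + "\n")

    stage("report",
          [p for p in (paths["dating"], paths["group_summary"],
                       paths["segments"]) if p.exists()],
          [paths["report"]], do_report)

    return report


def _summary_pairs(ga: dist_mod.GroupAssignment) -> list[tuple[str, str]]:
    groups = sorted(set(ga.groups.values()) - {"outgroup"})
    pairs = [(g, g) for g in groups if len(ga.members(g)) >= 2]
    import itertools
    pairs += list(itertools.combinations(groups, 2))
    return pairs


def _read_square_tsv(path) -> dist_mod.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = list(df.columns)
    d = df.to_numpy(dtype=float) / 1000.0
    valid = np.zeros_like(d, dtype=np.int64)
    return dist_mod.DistanceMatrix(ids, d, valid)


def date_from_tree(tree: PhyloTree, ga: dist_mod.GroupAssignment,
                   dm: dist_mod.DistanceMatrix | None,
                   cal: CalibrationSpec, seed: int = 0) -> DatingResult:
    """The full dating chain on a rooted tree with group assignments.

    Acceleration and ratio use tree paths; the ordering test uses matrix
    distances between the relevant groups when a matrix is supplied (and the
    richteri SB group exists), and is reported as not-available otherwise.
    """
    sb_tips = ga.members("Sb")
    og = ga.members("outgroup")
    ric = [t for t in ga.members("richteri_SB") if t in tree.tip_labels]
    inv = [t for t in ga.members("invicta_SB") if t in tree.tip_labels]
    sB_near = ric if ric else inv  # SB group sister to the Sb clade
    div = tree.mrca(sB_near + sb_tips)
    lam, lam_sd, wp = acceleration_factor(
        tree.path_lengths_from_node(div, sb_tips),
        tree.path_lengths_from_node(div, sB_near))
    R, num, den = relative_ratio(tree, sB_near, sb_tips, og)
    age, ci = calibrated_age(R, cal, (num, den), seed=seed)
    t_rB = s_rB = float("nan")
    ordering, op = "not_available", None
    if ric and inv and dm is not None:
        morph_pairs = [dm.get(a, b) * 1000.0 for a in ric for b in sb_tips]
        species_pairs = [dm.get(a, b) * 1000.0 for a in inv for b in ric]
        t_rB, s_rB, ordering, op = ordering_test(
            float(np.mean(morph_pairs)), float(np.mean(species_pairs)), lam,
            morph_pairs, species_pairs)
    return DatingResult(lam, lam_sd, wp, R, age, ci, t_rB, s_rB, ordering, op)
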