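"""End-to-end orchestration of the eRNA discovery pipeline.

A run directory holds ``inputs/`` (written by the simulate stage or
supplied by the user), ``outputs/`` with one TSV/BED per stage, a
``summary.tsv`` of cohort counts and a machine-readable provenance record.
Stage functions are thin file-level wrappers over the library modules; the
CLI exposes them as subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, expression, inducibility, io, motifs, pairing
from . import chromatin as chromatin_mod
from . import synteny as synteny_mod
from .intervals import GenomicInterval
from .simulate import (SimConfig, simulate_3c, simulate_genome, simulate_kd,
                       simulate_marks, simulate_orthomap, simulate_timecourse)

log = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "quantify", "induce", "pair", "motif",
          "synteny", "chromatin")


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus stage toggles; unknown keys rejected."""

    run_dir: str = "run"
    stages: tuple = STAGES
    seed: int = 0
    d5: int = 1000
    d3: int = 10_000
    rpkm_detect: float = 0.5
    ai_thr: float = 1.0
    ci_thr: float = 0.2
    window: int = 200_000
    binsize: int = 100_000
    top_frac: float = 0.3
    bottom_frac: float = 0.3
    proximity: int = 500_000
    efold_thr: float = 0.7
    pseudocount: float = 0.5
    n_background: int = 2000
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def threshold_comments(self) -> list[str]:
        return [
            f"d5={self.d5} d3={self.d3} rpkm_detect={self.rpkm_detect} "
            f"ai_thr={self.ai_thr} ci_thr={self.ci_thr} window={self.window} "
            f"binsize={self.binsize} top_frac={self.top_frac} "
            f"proximity={self.proximity} efold_thr={self.efold_thr} "
            f"pseudocount={self.pseudocount} seed={self.seed}"
        ]


def _inputs(run_dir) -> Path:
    return Path(run_dir) / "inputs"


def _outputs(run_dir) -> Path:
    p = Path(run_dir) / "outputs"
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(cfg: PipelineConfig):
    """Generate every downstream input file plus the truth tables."""
    sim = SimConfig(seed=cfg.seed, **cfg.sim)
    genes, enhancers, seqs, truth = simulate_genome(sim)
    gene_em, enh_em, _ = simulate_timecourse(truth, sim)
    indir = _inputs(cfg.run_dir)
    indir.mkdir(parents=True, exist_ok=True)
    io.write_gtf_genes(indir / "genes.gtf", genes)
    io.write_bed(indir / "transcripts.bed", enhancers)
    io.write_bed(indir / "marks.bed", simulate_marks(truth))
    io.write_fasta(indir / "genome.fa", seqs)
    io.write_pwms(indir / "motifs.pwm", [sim.motif_pwm])
    for name, em in (("gene", gene_em), ("enhancer", enh_em)):
        io.write_matrix_tsv(indir / f"{name}_counts.tsv", em.values)
        em.lengths.rename("length").to_csv(indir / f"{name}_lengths.tsv", sep="\t")
    pd.Series(dict(zip(gene_em.values.columns, gene_em.library_sizes)),
              name="library_size").to_csv(indir / "library_sizes.tsv", sep="\t")
    simulate_orthomap(truth).to_csv(indir / "orthomap.tsv", sep="\t", index=False)
    ct, groups = simulate_3c(truth)
    ct.to_csv(indir / "ct_3c.tsv", sep="\t", index=False)
    groups.to_csv(indir / "groups_3c.tsv", sep="\t", index=False)
    kd, kd_truth = simulate_kd(truth)
    kd.to_csv(indir / "kd.tsv", sep="\t", index=False)
    truth.write(Path(cfg.run_dir) / "truth")
    kd_truth.to_csv(Path(cfg.run_dir) / "truth" / "kd.tsv", sep="\t", index=False)
    return truth


def _read_counts(indir, name, timegrid=None):
    vals = io.read_matrix_tsv(indir / f"{name}_counts.tsv")
    if timegrid is None:
        timegrid = expression.TimeGrid.from_labels(vals.columns)
    lengths = pd.read_csv(indir / f"{name}_lengths.tsv", sep="\t", index_col=0)["length"]
    lib = pd.read_csv(indir / "library_sizes.tsv", sep="\t", index_col=0)["library_size"]
    return expression.ExpressionMatrix(vals, timegrid, lengths, lib, unit="counts")


def stage_annotate(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    transcripts = io.read_bed(indir / "transcripts.bed")
    genes = io.read_gtf_genes(indir / "genes.gtf")
    peaks = io.read_bed(indir / "marks.bed")
    merged = annotation.merge_same_strand(transcripts)
    intergenic = annotation.classify_intergenic(merged, genes, cfg.d5, cfg.d3)
    marked, unmarked = annotation.filter_by_marks(intergenic, [peaks])
    io.write_bed(outdir / "eRNA.bed", [l.interval for l in marked])
    io.write_bed(outdir / "unmarked.bed", [l.interval for l in unmarked])
    return dict(n_transcripts=len(transcripts), n_intergenic=len(intergenic),
                n_marked=len(marked), n_unmarked=len(unmarked),
                mean_erna_length=float(np.mean([len(l.interval) for l in marked]))
                if marked else np.nan)


def stage_quantify(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    res = {}
    for name in ("gene", "enhancer"):
        em = _read_counts(indir, name)
        rp = expression.rpkm(em)
        io.write_matrix_tsv(outdir / f"{name}_rpkm.tsv", rp.values,
                            cfg.threshold_comments())
        res[f"n_{name}s_expressed"] = int(
            expression.detection_call(rp, cfg.rpkm_detect, "mean").sum())
        res[f"frac_{name}s_undetected_0h"] = float(
            1 - expression.detection_call(rp, cfg.rpkm_detect, "time0").mean())
    return res


def stage_induce(cfg: PipelineConfig):
    outdir = _outputs(cfg.run_dir)
    res = {}
    for name in ("gene", "enhancer"):
        vals = io.read_matrix_tsv(outdir / f"{name}_rpkm.tsv")
        tg = expression.TimeGrid.from_labels(vals.columns)
        em = expression.ExpressionMatrix(vals, tg, unit="rpkm")
        scores = inducibility.score_inducibility(
            em, cfg.ai_thr, cfg.ci_thr, pseudocount=cfg.pseudocount)
        profiles = inducibility.select_responsive(em, cfg.ci_thr,
                                                  pseudocount=cfg.pseudocount)
        scores["cluster"] = "none"
        if len(profiles) >= 3:
            labels = inducibility.pam_cluster_profiles(profiles, tg, k=3)
            scores.loc[labels.index, "cluster"] = labels.values
        io.write_matrix_tsv(outdir / f"{name}_inducibility.tsv", scores,
                            cfg.threshold_comments())
        res[f"n_inducible_{name}s"] = int(scores.inducible.sum())
    return res


def _load_inducible(outdir, name) -> set[str]:
    df = io.read_matrix_tsv(outdir / f"{name}_inducibility.tsv")
    flags = df.inducible.map(lambda v: str(v).lower() in ("true", "1"))
    return set(df.index[flags])


def stage_pair(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    genes = io.read_gtf_genes(indir / "genes.gtf")
    ernas = io.read_bed(outdir / "eRNA.bed")
    ind_e = _load_inducible(outdir, "enhancer")
    ind_g = _load_inducible(outdir, "gene")
    inducible_ernas = [e for e in ernas if e.id in ind_e]
    pairs = pairing.pair_nearest(inducible_ernas, genes, ind_g, cfg.window)
    erna_rpkm = io.read_matrix_tsv(outdir / "enhancer_rpkm.tsv")
    gene_rpkm = io.read_matrix_tsv(outdir / "gene_rpkm.tsv")
    pairs = pairing.concordance_classes(pairs, erna_rpkm, gene_rpkm,
                                        cfg.top_frac, cfg.bottom_frac)
    df = pairing.pairs_to_frame(pairs)
    df.to_csv(outdir / "ep_pairs.tsv", sep="\t", index=False)
    if inducible_ernas and genes:
        enr = pairing.distance_enrichment(inducible_ernas, genes, ind_g, cfg.binsize)
        enr.to_csv(outdir / "distance_enrichment.tsv", sep="\t", index=False)
    counts = df.concordance.value_counts().to_dict() if len(df) else {}
    return dict(n_ep_pairs=len(df),
                n_concordant=int(counts.get("concordant", 0)),
                n_discordant=int(counts.get("discordant", 0)),
                n_intermediate=int(counts.get("intermediate", 0)))


def _erna_anchor_windows(cfg, half: int = motifs.WINDOW_HALF):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    seqs = io.read_fasta(indir / "genome.fa")
    ernas = io.read_bed(outdir / "eRNA.bed")
    ind_e = _load_inducible(outdir, "enhancer")
    wins = {}
    for e in ernas:
        if e.id not in ind_e:
            continue
        tss = e.start if e.strand != "-" else e.end - 1
        seq = seqs.get(e.chrom, "")
        if tss - half < 0 or tss + half + 1 > len(seq):
            continue
        wins[e.id] = seq[tss - half : tss + half + 1]
    return wins


def stage_motif(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    pwms = io.read_pwms(indir / "motifs.pwm")
    wins = _erna_anchor_windows(cfg)
    rows, hit_rows = [], []
    for pwm in pwms:
        hits = motifs.scan_pwm(wins, pwm)
        res = motifs.sbp_enrichment(hits, len(wins), len(pwm), pwm.name)
        rows.append(dict(motif=pwm.name, absolute=res.absolute,
                         relative=res.relative, n_anchors=res.n_anchors,
                         n_hits=len(hits)))
        hit_rows += [dict(motif=pwm.name, locus=h.locus, offset=h.offset,
                          strand=h.strand, score=round(h.score, 3)) for h in hits]
    pd.DataFrame(rows).to_csv(outdir / "sbp.tsv", sep="\t", index=False)
    pd.DataFrame(hit_rows).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    first = rows[0] if rows else dict(absolute=np.nan, relative=np.nan)
    return dict(sbp_absolute=float(first["absolute"]),
                sbp_relative=float(first["relative"]), n_motif_anchors=len(wins))


def stage_synteny(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    maps = synteny_mod.OrthologMap.read_tsv(indir / "orthomap.tsv")
    genes = io.read_gtf_genes(indir / "genes.gtf")
    ernas = {e.id: e for e in io.read_bed(outdir / "eRNA.bed")}
    gmap = {g.interval.id: g for g in genes}
    pairs_df = pd.read_csv(outdir / "ep_pairs.tsv", sep="\t")
    anchors = []
    for r in pairs_df.itertuples():
        e = ernas.get(r.enhancer)
        g = gmap.get(r.gene)
        if e is None or g is None:
            continue
        etss = e.start if e.strand != "-" else e.end - 1
        anchors.append((
            GenomicInterval(e.chrom, max(etss - 500, 0), etss + 500, ".", e.id),
            GenomicInterval(g.chrom, max(g.tss - 1000, 0), g.tss + 1000, ".",
                            g.interval.id),
        ))
    sizes = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end + 200_000)
    for e in ernas.values():
        sizes[e.chrom] = max(sizes.get(e.chrom, 0), e.end + 200_000)
    cands = synteny_mod.intergenic_candidates(genes, sizes)
    proms = [GenomicInterval(g.chrom, max(g.tss - 1000, 0), g.tss + 1000, ".",
                             g.interval.id) for g in genes]
    target = list(pairs_df.distance)
    bg = synteny_mod.matched_background(proms, cands, target,
                                        n=cfg.n_background, seed=cfg.seed)
    D, p, ok = synteny_mod.background_self_check(bg, target)
    table = synteny_mod.synteny_table(anchors, bg, maps, cfg.proximity)
    table.to_csv(outdir / "synteny.tsv", sep="\t", index=False)
    return dict(
        synteny_rate_same_chrom=float(table.rate_same_chrom.mean()),
        synteny_bg_rate_same_chrom=float(table.bg_rate_same_chrom.mean()),
        synteny_rate_proximal=float(table.rate_proximal.mean()),
        background_ks_ok=bool(ok),
    )


def stage_chromatin(cfg: PipelineConfig):
    indir, outdir = _inputs(cfg.run_dir), _outputs(cfg.run_dir)
    ct = chromatin_mod.read_ct_table(indir / "ct_3c.tsv")
    groups_path = indir / "groups_3c.tsv"
    groups = (pd.read_csv(groups_path, sep="\t").set_index("pair_id").group.to_dict()
              if groups_path.exists() else {})
    rows = []
    for pid in sorted(ct.pair_id.unique()):
        freqs = chromatin_mod.frequency_trajectory(ct, pid)
        lfc = chromatin_mod.interaction_fold_change(freqs)
        rows.append(dict(pair_id=pid, group=groups.get(pid, "unknown"),
                         lfc_12h_vs_0h=round(lfc, 4),
                         **{f"f_{t:g}h": round(v, 4) for t, v in freqs.items()}))
    traj = pd.DataFrame(rows)
    traj.to_csv(outdir / "interaction_folds.tsv", sep="\t", index=False)
    res = {}
    ind = traj[traj.group == "induced"].lfc_12h_vs_0h
    ctl = traj[traj.group == "control"].lfc_12h_vs_0h
    if len(ind) >= 2 and len(ctl) >= 2:
        D, p = chromatin_mod.ks_compare(ind, ctl)
        res.update(ks_D_3c=float(D), ks_p_3c=float(p))
    kd_path = indir / "kd.tsv"
    if kd_path.exists():
        records = chromatin_mod.read_kd_table(kd_path)
        eff = chromatin_mod.kd_effect(records, cfg.efold_thr)
        eff.to_csv(outdir / "kd_effects.tsv", sep="\t", index=False)
        res["n_kd_effective_pairs"] = len(eff)
        res["n_kd_repressed"] = int((eff.effect == "repressed").sum())
    return res


_STAGE_FUNCS = dict(simulate=stage_simulate, annotate=stage_annotate,
                    quantify=stage_quantify, induce=stage_induce,
                    pair=stage_pair, motif=stage_motif,
                    synteny=stage_synteny, chromatin=stage_chromatin)

# files each stage needs before it can run
_REQUIRES = {
    "annotate": ["inputs/transcripts.bed", "inputs/genes.gtf", "inputs/marks.bed"],
    "quantify": ["inputs/gene_counts.tsv", "inputs/enhancer_counts.tsv",
                 "inputs/library_sizes.tsv"],
    "induce": ["outputs/gene_rpkm.tsv", "outputs/enhancer_rpkm.tsv"],
    "pair": ["outputs/eRNA.bed", "outputs/gene_inducibility.tsv",
             "outputs/enhancer_inducibility.tsv"],
    "motif": ["inputs/genome.fa", "inputs/motifs.pwm", "outputs/eRNA.bed",
              "outputs/enhancer_inducibility.tsv"],
    "synteny": ["inputs/orthomap.tsv", "outputs/ep_pairs.tsv"],
    "chromatin": ["inputs/ct_3c.tsv"],
}


class StageDependencyError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run the enabled stages in order; returns the summary table.

    Fails before any stage runs if an enabled stage's inputs will not exist
    (either on disk already or produced by an earlier enabled stage).
    """
    enabled = [s for s in STAGES if s in cfg.stages]
    run_dir = Path(cfg.run_dir)
    produced = set()
    if "simulate" in enabled:
        produced |= {f"inputs/{n}" for n in
                     ("transcripts.bed", "genes.gtf", "marks.bed", "genome.fa",
                      "motifs.pwm", "gene_counts.tsv", "enhancer_counts.tsv",
                      "gene_lengths.tsv", "enhancer_lengths.tsv",
                      "library_sizes.tsv", "orthomap.tsv", "ct_3c.tsv",
                      "groups_3c.tsv", "kd.tsv")}
    stage_outputs = {
        "annotate": ["outputs/eRNA.bed", "outputs/unmarked.bed"],
        "quantify": ["outputs/gene_rpkm.tsv", "outputs/enhancer_rpkm.tsv"],
        "induce": ["outputs/gene_inducibility.tsv", "outputs/enhancer_inducibility.tsv"],
        "pair": ["outputs/ep_pairs.tsv"],
    }
    for s in enabled:
        for req in _REQUIRES.get(s, []):
            if req not in produced and not (run_dir / req).exists():
                raise StageDependencyError(
                    f"stage '{s}' requires {req}, which no earlier enabled "
                    f"stage produces")
        produced |= set(stage_outputs.get(s, []))

    summary = {}
    for s in enabled:
        t0 = time.time()
        log.info("stage %s ...", s)
        out = _STAGE_FUNCS[s](cfg)
        if isinstance(out, dict):
            summary.update(out)
        log.info("stage %s done in %.1fs", s, time.time() - t0)

    outdir = _outputs(cfg.run_dir)
    sdf = pd.DataFrame(sorted(summary.items()), columns=["metric", "value"])
    with open(outdir / "summary.tsv", "w") as fh:
        for c in cfg.threshold_comments():
            fh.write(f"# {c}\n")
        sdf.to_csv(fh, sep="\t", index=False)
    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    prov = dict(tool="ernadyn", version=__version__,
                config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
                config=json.loads(cfg_json), stages=enabled)
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
    return sdf
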