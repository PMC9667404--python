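"""End-to-end pipeline: stats -> trios -> SFS -> fit -> rank -> bootstrap.

Driven by a single YAML config with a mandatory master seed.  Every
stochastic stage consumes a seed derived as ``sha256(master_seed, stage
name)``, so adding stages never perturbs earlier ones and a rerun with the
same config is byte-identical.  Each stage writes tidy TSV outputs into the
output directory and is individually invokable; a machine-readable manifest
records versions, seeds and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

import haplodem
from haplodem import abba_baba, genotype_io, inference, popgen_stats, sfs as sfs_mod
from haplodem.models import model_zoo
from haplodem.synthetic import generate_dataset, preset_rad_shape

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stats", "trios", "sfs", "fit", "bootstrap")


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must set a master 'seed'")
    if "output_dir" not in cfg:
        raise ValueError("config must set 'output_dir'")
    return cfg


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineContext:
    """Holds the loaded inputs and accumulating manifest for one run."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = Path(cfg["output_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(cfg["seed"])
        self.matrix = None
        self.pmap = None
        self.manifest: dict = {
            "haplodem_version": haplodem.__version__,
            "master_seed": self.seed,
            "stage_seeds": {s: stage_seed(self.seed, s) for s in STAGES},
            "outputs": {},
            "stages_run": [],
        }

    def record(self, stage: str, paths: list[Path], t0: float) -> None:
        self.manifest["stages_run"].append(stage)
        for p in paths:
            self.manifest["outputs"][str(p.relative_to(self.out))] = _file_hash(p)
        logger.info("stage %s finished in %.1fs", stage, time.time() - t0)

    def load_inputs(self) -> None:
        if self.matrix is not None:
            return
        inp = self.cfg.get("input", {})
        if "matrix" in inp:
            self.matrix = genotype_io.read_matrix(
                inp["matrix"], format=inp.get("format", "tabular")
            )
            self.pmap = genotype_io.read_popmap(inp["popmap"])
        else:
            mat = self.out / "data" / "matrix.tsv"
            if not mat.exists():
                raise FileNotFoundError(
                    "no input matrix configured and no simulate stage output "
                    f"at {mat}; run the simulate stage or set input.matrix"
                )
            self.matrix = genotype_io.read_matrix(mat)
            self.pmap = genotype_io.read_popmap(self.out / "data" / "popmap.tsv")
        min_presence = self.cfg.get("min_locus_presence")
        if min_presence:
            before = len(self.matrix.locus_ids)
            self.matrix = genotype_io.filter_locus_presence(self.matrix, min_presence)
            logger.info(
                "locus-presence filter (%.0f%%): %d -> %d loci",
                100 * min_presence, before, len(self.matrix.locus_ids),
            )
        self.pmap.check_covers(self.matrix)


def stage_simulate(ctx: PipelineContext) -> None:
    scfg = ctx.cfg["simulate"]
    t0 = time.time()
    if scfg.get("preset", "rad-shape") != "rad-shape":
        raise ValueError(f"unknown preset {scfg['preset']!r}")
    truth = preset_rad_shape(
        seed=stage_seed(ctx.seed, "simulate"),
        n_loci=scfg.get("n_loci", 1000),
        missingness=scfg.get("missingness", 0.10),
        sample_layout=scfg.get("sample_layout"),
    )
    out = ctx.out / "data"
    # later stages reload from disk so that the locus-presence filter and
    # stage-only invocations follow the identical code path
    generate_dataset(truth, out_dir=out)
    ctx.record(
        "simulate",
        [out / "matrix.tsv", out / "popmap.tsv", out / "truth.json"],
        t0,
    )


def _resolve_groups(ctx: PipelineContext, spec) -> dict[str, list[str]]:
    groups = {}
    for name, val in spec.items():
        if val is None:
            groups[name] = [
                s for s in ctx.pmap.samples_for(name) if s in ctx.matrix.samples
            ]
        else:
            groups[name] = list(val)
    return groups


def stage_stats(ctx: PipelineContext) -> None:
    cfg = ctx.cfg["stats"]
    t0 = time.time()
    ctx.load_inputs()
    groups = _resolve_groups(ctx, cfg["groups"])
    total_sites = cfg.get("total_sites")
    within, pairwise = popgen_stats.diversity_table(ctx.matrix, groups, total_sites)
    p1 = ctx.out / "diversity_within.tsv"
    p2 = ctx.out / "diversity_pairwise.tsv"
    within.to_csv(p1, sep="\t", index=False)
    pairwise.to_csv(p2, sep="\t", index=False)
    paths = [p1, p2]
    if "regions" in cfg:
        regions = _resolve_groups(ctx, cfg["regions"])
        estimates = {}
        rows = []
        for name, samples in regions.items():
            jk = popgen_stats.jackknife(
                lambda m, s: popgen_stats.nucleotide_diversity(m, s, total_sites),
                ctx.matrix,
                samples,
            )
            estimates[name] = jk.pseudovalues
            rows.append(
                {"region": name, "n": len(samples), "pi": jk.point, "sd": jk.sd}
            )
        comparison = popgen_stats.compare_groups(estimates)
        summary = pd.DataFrame(rows)
        summary["anova_F"] = comparison.anova_f
        summary["anova_p"] = comparison.anova_p
        p3 = ctx.out / "region_diversity.tsv"
        p4 = ctx.out / "region_ttests.tsv"
        summary.to_csv(p3, sep="\t", index=False)
        comparison.pairwise.to_csv(p4, sep="\t", index=False)
        paths += [p3, p4]
    ctx.record("stats", paths, t0)


def stage_trios(ctx: PipelineContext) -> None:
    cfg = ctx.cfg["trios"]
    t0 = time.time()
    ctx.load_inputs()
    rows = []
    for trio in cfg:
        res = abba_baba.compute_trio(
            ctx.matrix,
            ctx.pmap,
            trio["p1"],
            trio["p2"],
            trio["p3"],
            trio["outgroup"],
            n_blocks=trio.get("blocks", 20),
            orient=trio.get("orient", False),
        )
        rows.append(res.as_row())
    path = ctx.out / "trios.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    ctx.record("trios", [path], t0)


def stage_sfs(ctx: PipelineContext) -> None:
    cfg = ctx.cfg["sfs"]
    t0 = time.time()
    ctx.load_inputs()
    seed = stage_seed(ctx.seed, "sfs")
    projections = cfg["projections"]
    paths = []
    for mode, fname in (
        ("all_snps", "sfs_all_snps.txt"),
        ("one_per_locus", "sfs_one_per_locus.txt"),
    ):
        js = sfs_mod.build_joint_sfs(
            ctx.matrix, ctx.pmap, projections, mode=mode, seed=seed
        )
        path = ctx.out / fname
        js.save(path)
        paths.append(path)
    ctx.record("sfs", paths, t0)


def _zoo_for(ctx: PipelineContext, projections: dict) -> dict:
    fit_cfg = ctx.cfg.get("fit", {})
    return model_zoo(
        sample_sizes={k: int(v) for k, v in projections.items()},
        mutation_rate=fit_cfg.get("mutation_rate", 2.8e-8),
        locus_length=fit_cfg.get("locus_length", 90),
    )


def stage_fit(ctx: PipelineContext) -> None:
    cfg = ctx.cfg["fit"]
    t0 = time.time()
    obs_all = sfs_mod.JointSFS.load(ctx.out / "sfs_all_snps.txt")
    obs_1pl = sfs_mod.JointSFS.load(ctx.out / "sfs_one_per_locus.txt")
    projections = dict(zip(obs_all.pop_labels, obs_all.sample_sizes))
    zoo = _zoo_for(ctx, projections)
    seed = stage_seed(ctx.seed, "fit")
    fit_dir = ctx.out / "fits"
    fit_dir.mkdir(exist_ok=True)
    results = []
    paths = []
    for name in cfg["models"]:
        builder = zoo[name]
        fit = inference.fit_model(
            obs_all,
            builder,
            n_runs=cfg.get("n_runs", 10),
            n_sims=cfg.get("n_sims", 5000),
            n_cycles=cfg.get("n_cycles", 10),
            seed=seed,
        )
        fit = inference.evaluate_model(
            fit, builder, obs_1pl,
            n_sims_eval=cfg.get("n_sims_eval", 100_000), seed=seed,
        )
        path = fit_dir / f"{name}.json"
        fit.to_json(path)
        results.append(fit)
        paths.append(path)
    ranking = inference.rank_models(results)
    rank_path = ctx.out / "model_ranking.tsv"
    ranking.to_csv(rank_path, sep="\t", index=False)
    ctx.record("fit", paths + [rank_path], t0)


def stage_bootstrap(ctx: PipelineContext) -> None:
    cfg = ctx.cfg["bootstrap"]
    t0 = time.time()
    ranking = pd.read_csv(ctx.out / "model_ranking.tsv", sep="\t")
    model_name = cfg.get("model") or ranking["model"].iloc[0]
    fit = inference.FitResult.from_json(ctx.out / "fits" / f"{model_name}.json")
    obs_all = sfs_mod.JointSFS.load(ctx.out / "sfs_all_snps.txt")
    projections = dict(zip(obs_all.pop_labels, obs_all.sample_sizes))
    zoo = _zoo_for(ctx, projections)
    boot = inference.parametric_bootstrap(
        fit,
        zoo[model_name],
        n_loci=cfg.get("n_loci", 1000),
        n_reps=cfg.get("n_reps", 100),
        n_runs_per_rep=cfg.get("n_runs_per_rep", 10),
        n_sims=cfg.get("n_sims", 50_000),
        n_cycles=cfg.get("n_cycles", 40),
        seed=stage_seed(ctx.seed, "bootstrap"),
    )
    p1 = ctx.out / "bootstrap_replicates.tsv"
    p2 = ctx.out / "bootstrap_ci.tsv"
    boot.replicates.to_csv(p1, sep="\t", index=False)
    boot.ci.to_csv(p2, sep="\t", index_label="parameter")
    ctx.record("bootstrap", [p1, p2], t0)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "stats": stage_stats,
    "trios": stage_trios,
    "sfs": stage_sfs,
    "fit": stage_fit,
    "bootstrap": stage_bootstrap,
}


def run_pipeline(cfg: dict, only: str | None = None) -> dict:
    """Run all configured stages (or a single one) and write the manifest.

    Any stage failure raises with a stage-tagged message; outputs of earlier
    stages are retained on disk.
    """
    ctx = PipelineContext(cfg)
    log_handler = logging.FileHandler(ctx.out / "pipeline.log")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("haplodem")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    stages = [only] if only else [s for s in STAGES if s in cfg]
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            if stage not in cfg:
                raise ValueError(f"stage {stage!r} not configured")
            try:
                _STAGE_FUNCS[stage](ctx)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    manifest_path = ctx.out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(ctx.manifest, fh, indent=2, sort_keys=True)
    return ctx.manifest
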