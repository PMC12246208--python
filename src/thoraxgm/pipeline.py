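"""Pipeline orchestration: simulate -> reconstruct -> analyze.

Each stage reads/writes plain-text artifacts (CSV, TPS, Newick, JSON) under
the configured output directory and records a manifest (config digest,
seed, package version) sufficient to reproduce its outputs bit-identically.
A single mandatory top-level seed drives every stage; stage-level
generators derive sub-seeds deterministically from it.

Stage ordering inside ``cmd_analyze`` is fixed: symmetrization and removal
of ribs 11-12 always precede the Procrustes superimposition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .landmarks import LandmarkConfiguration, SpecimenMeta
from .procrustes import centroid_size, drop_floating_ribs, gpa, pca_shape, \
    symmetrize
from .reconstruct import KyphosisModel, reconstruct_fossil
from .stats import group_distance_matrix, pairwise_perm_tests, \
    pc_perm_tests, upgma
from .synthetic import ThoraxParams, apply_pattern, builtin_patterns, \
    generate_sample
from .template import analysis_template, default_template

log = logging.getLogger("thoraxgm")

#: climate group each built-in fossil pattern is drawn from
PATTERN_GROUPS = {"complete": "cold", "oetzi": "temperate",
                  "nazlet_khater_2": "warm", "ohalo_2": "temperate"}


@dataclass
class PipelineConfig:
    """Run configuration; ``seed`` is mandatory."""

    seed: int
    output_dir: str = "results/run"
    template: str = "full"            # "full", "analysis", or a CSV path
    thorax: dict = field(default_factory=dict)
    patterns: list = field(default_factory=lambda: list(PATTERN_GROUPS))
    kyphosis: dict | None = None      # {"intercept": ..., "slope": ...}
    n_permutations: int = 10_000
    n_distance_replicates: int = 1_000
    adjust: str = "none"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        unknown = set(self.patterns) - set(PATTERN_GROUPS)
        if unknown:
            raise ValueError(f"unknown patterns: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def resolve_template(self):
        if self.template == "full":
            return default_template()
        if self.template == "analysis":
            return analysis_template()
        return tio.read_template(self.template)

    def kyphosis_model(self) -> KyphosisModel | None:
        if not self.kyphosis:
            return None
        return KyphosisModel(float(self.kyphosis["intercept"]),
                             float(self.kyphosis["slope"]))


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _write_manifest(outdir: Path, config: PipelineConfig,
                    stage: str, outputs: list[str]) -> None:
    from . import __version__
    manifest = {"stage": stage, "seed": config.seed,
                "config_digest": config.digest(),
                "version": __version__, "outputs": sorted(outputs)}
    (outdir / f"{stage}_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")


def cmd_simulate(config: PipelineConfig) -> dict:
    """Write the synthetic reference sample and masked fossil inputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = config.resolve_template()
    params = ThoraxParams(seed=config.seed, **config.thorax)
    configs, metas = generate_sample(params, template)
    log.info("simulated %d reference specimens (seed %d)",
             len(configs), config.seed)

    tio.write_coords_csv(configs, outdir / "reference_coords.csv")
    tio.write_meta_csv(metas, outdir / "reference_meta.csv")
    tio.write_tps(configs, outdir / "reference.tps")
    tio.write_template(template, outdir / "template.csv")
    outputs = ["reference_coords.csv", "reference_meta.csv",
               "reference.tps", "template.csv"]

    patterns = {p.name: p for p in builtin_patterns(template)}
    fossil_metas = []
    for name in config.patterns:
        group = PATTERN_GROUPS[name]
        fparams = dataclasses.replace(
            params, n_per_group={group: 1},
            seed=_stage_seed(config.seed, f"fossil:{name}"))
        (truth,), _ = generate_sample(fparams, template)
        truth = truth.with_coords(truth.coords,
                                  specimen_id=f"fossil_{name}")
        masked = apply_pattern(truth, patterns[name])
        tio.write_coords_csv([truth], outdir / f"fossil_{name}_truth.csv")
        tio.write_coords_csv([masked], outdir / f"fossil_{name}.csv")
        outputs += [f"fossil_{name}.csv", f"fossil_{name}_truth.csv"]
        fossil_metas.append(SpecimenMeta(
            specimen_id=f"fossil_{name}", taxon="fossil_sapiens",
            climate_group=group,
            population=f"synthetic_fossil_{name}"))
        log.info("fossil %s: %d/%d points retained", name,
                 masked.n_present, len(template))
    tio.write_meta_csv(fossil_metas, outdir / "fossil_meta.csv")
    outputs.append("fossil_meta.csv")
    _write_manifest(outdir, config, "simulate", outputs)
    return {"n_reference": len(configs), "fossils": list(config.patterns)}


def cmd_reconstruct(config: PipelineConfig) -> dict:
    """Reconstruct each masked fossil against the reference sample."""
    outdir = Path(config.output_dir)
    ref_path = outdir / "reference_coords.csv"
    if not ref_path.exists():
        raise FileNotFoundError(f"reference file not found: {ref_path}; "
                                "run the simulate stage first")
    template = tio.read_template(outdir / "template.csv")
    reference = tio.read_coords_csv(ref_path, template)
    kmodel = config.kyphosis_model()
    outputs = []
    reports = {}
    for name in config.patterns:
        fpath = outdir / f"fossil_{name}.csv"
        if not fpath.exists():
            raise FileNotFoundError(f"fossil input not found: {fpath}")
        (partial,) = tio.read_coords_csv(fpath, template)
        recon, report = reconstruct_fossil(
            partial, reference, reference, kmodel, template)
        tio.write_coords_csv([recon],
                             outdir / f"reconstructed_{name}.csv")
        (outdir / f"report_{name}.json").write_text(
            json.dumps(report, indent=2, default=str) + "\n")
        outputs += [f"reconstructed_{name}.csv", f"report_{name}.json"]
        reports[name] = {k: v for k, v in report.items()
                         if k != "provenance"}
        log.info("reconstructed %s: %d estimated points", name,
                 report["n_estimated"])
    _write_manifest(outdir, config, "reconstruct", outputs)
    return reports


def cmd_analyze(config: PipelineConfig) -> dict:
    """Symmetrize, drop ribs 11-12, superimpose, and compare groups."""
    outdir = Path(config.output_dir)
    template = tio.read_template(outdir / "template.csv")
    reference = tio.read_coords_csv(outdir / "reference_coords.csv",
                                    template)
    metas = {m.specimen_id: m
             for m in tio.read_meta_csv(outdir / "reference_meta.csv")}
    fossil_meta_path = outdir / "fossil_meta.csv"
    if fossil_meta_path.exists():
        for m in tio.read_meta_csv(fossil_meta_path):
            metas[m.specimen_id] = m
    fossils = []
    for name in config.patterns:
        fpath = outdir / f"reconstructed_{name}.csv"
        if fpath.exists():
            fossils += tio.read_coords_csv(fpath, template)

    configs = list(reference) + fossils
    # fixed preprocessing order: symmetrize, drop ribs 11-12, then GPA
    processed = [drop_floating_ribs(symmetrize(c, template))
                 for c in configs]
    group_of = {}
    for c in configs:
        m = metas.get(c.specimen_id)
        if m is not None and m.taxon == "recent_sapiens":
            group_of[c.specimen_id] = m.climate_group
        else:
            group_of[c.specimen_id] = c.specimen_id  # singleton fossils
    groups = sorted(set(group_of.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to analyze")

    sizes = {c.specimen_id: centroid_size(p)
             for c, p in zip(configs, processed)}
    size_groups = {g: [sizes[s] for s, gg in group_of.items() if gg == g]
                   for g in groups}

    # Table-2-style summary + pairwise permutation tests on centroid size
    summary = pd.DataFrame([
        {"group": g, "n": len(v), "mean_cs": np.mean(v),
         "sd_cs": np.std(v, ddof=1) if len(v) > 1 else np.nan}
        for g, v in size_groups.items()])
    summary.to_csv(outdir / "size_table.csv", index=False)
    ptable = pairwise_perm_tests(size_groups, n=config.n_permutations,
                                 seed=_stage_seed(config.seed, "cs_perm"),
                                 adjust=config.adjust)
    ptable.to_csv(outdir / "size_pvalues.csv", index=False)

    # UPGMA on resampling-averaged group mean distances
    D, labels = group_distance_matrix(
        size_groups, n=config.n_distance_replicates,
        seed=_stage_seed(config.seed, "cs_dist"))
    tree = upgma(D, labels)
    (outdir / "upgma.nwk").write_text(tree.newick() + "\n")
    pd.DataFrame(D, index=labels, columns=labels).to_csv(
        outdir / "size_distances.csv")

    # shape-space PCA + PC permutation tests
    fit = gpa(processed, space="shape")
    pca = pca_shape(fit)
    ids = [c.specimen_id for c in configs]
    n_show = min(5, pca.scores.shape[1])
    scores_df = pd.DataFrame(
        pca.scores[:, :n_show],
        columns=[f"PC{i + 1}" for i in range(n_show)])
    scores_df.insert(0, "specimen_id", ids)
    scores_df.insert(1, "group", [group_of[s] for s in ids])
    scores_df.to_csv(outdir / "pca_scores.csv", index=False)
    pd.DataFrame({
        "component": np.arange(1, len(pca.variance_fractions) + 1),
        "variance_fraction": pca.variance_fractions,
    }).to_csv(outdir / "pca_variance.csv", index=False)
    idx_groups = {g: [i for i, s in enumerate(ids) if group_of[s] == g]
                  for g in groups}
    pc_table = pc_perm_tests(pca, idx_groups, components=(1, 2),
                             n=config.n_permutations,
                             seed=_stage_seed(config.seed, "pc_perm"))
    pc_table.to_csv(outdir / "pc_pvalues.csv", index=False)

    outputs = ["size_table.csv", "size_pvalues.csv", "size_distances.csv",
               "upgma.nwk", "pca_scores.csv", "pca_variance.csv",
               "pc_pvalues.csv"]
    _write_manifest(outdir, config, "analyze", outputs)
    log.info("analyzed %d specimens in %d groups", len(configs),
             len(groups))
    return {"summary": summary, "size_pvalues": ptable,
            "pc_pvalues": pc_table, "newick": tree.newick(),
            "variance_fractions": pca.variance_fractions}
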