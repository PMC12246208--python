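"""Validation experiments: calibration, power, recovery and end-to-end
group-effect detection on synthetic thoraces.

These are the repeatable numerical experiments behind the analysis
scripts; each function runs the package's own machinery on freshly
generated data and returns summary numbers.
"""

from __future__ import annotations

import dataclasses
import tempfile

import numpy as np

from .landmarks import LandmarkConfiguration
from .pipeline import PipelineConfig, cmd_analyze, cmd_reconstruct, \
    cmd_simulate
from .procrustes import align_case, centroid_size
from .reconstruct import fit_pls, predict_full
from .reference_sample import population_count, total_recent_n
from .stats import perm_test
from .synthetic import ThoraxParams, apply_pattern, builtin_patterns, \
    generate_sample, one_factor_sample
from .template import default_template


def sample_arithmetic() -> dict:
    """Reference-sample composition totals."""
    return {"total_recent": total_recent_n(),
            "n_populations": population_count()}


def null_rejection_rate(n_reps: int = 400, n_per_group: int = 10,
                        n_perms: int = 999, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Type-I error of the permutation test under the null.

    Both groups are drawn from one normal distribution; returns the
    fraction of replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        res = perm_test(a, b, n=n_perms, rng=rng)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def power_rate(n_reps: int = 200, n_per_group: int = 15,
               effect_sd: float = 1.5, n_perms: int = 999,
               alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate under a mean shift of ``effect_sd`` pooled SDs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(effect_sd, 1.0, n_per_group)
        res = perm_test(a, b, n=n_perms, rng=rng)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def pls_holdout_recovery(n: int = 30, seed: int = 0,
                         pattern: str = "ohalo_2") -> float:
    """Relative RMS error of PLS completion on a noise-free one-factor
    sample with a held-out specimen masked to a fossil pattern.

    Returns RMS error divided by the held-out specimen's centroid size.
    """
    template = default_template()
    pats = {p.name: p for p in builtin_patterns(template)}
    partial = tuple(sorted(pats[pattern].retained_labels,
                           key=template.index_of))
    configs, _, _ = one_factor_sample(template, partial, n, seed=seed)
    held, ref = configs[-1], configs[:-1]
    model = fit_pls(ref, partial)
    masked = apply_pattern(held, pats[pattern])
    pred = predict_full(model, masked)
    truth = align_case(held, model.full_fit)
    rms = float(np.sqrt(((pred.coords - truth.coords) ** 2).mean()))
    return rms / centroid_size(held)


def pls_vs_mean_baseline(n_reps: int = 20,
                         n_per_group: int | dict | None = None,
                         seed: int = 0, pattern: str = "ohalo_2"
                         ) -> tuple[int, float, float]:
    """Paired comparison of PLS completion against mean substitution.

    Each replicate draws a fresh noisy sample (the reference-sample
    composition by default), holds one specimen out, masks it to the
    fossil pattern, and compares the RMS error at the missing landmarks of
    the PLS prediction vs the reference consensus.  Returns
    (wins, mean PLS error, mean baseline error), errors in mm.
    """
    template = default_template()
    pats = {p.name: p for p in builtin_patterns(template)}
    wins = 0
    errs_pls, errs_mean = [], []
    for rep in range(n_reps):
        params = ThoraxParams(seed=seed + rep, n_per_group=n_per_group)
        configs, _ = generate_sample(params, template)
        held, ref = configs[-1], configs[:-1]
        model = fit_pls(ref, tuple(sorted(pats[pattern].retained_labels,
                                          key=template.index_of)))
        masked = apply_pattern(held, pats[pattern])
        pred = predict_full(model, masked)
        truth = align_case(held, model.full_fit)
        miss = np.array([lab not in pats[pattern].retained_labels
                         for lab in model.full_labels])
        e_pls = float(np.sqrt(((pred.coords - truth.coords)[miss] ** 2
                               ).mean()))
        e_mean = float(np.sqrt(((model.full_fit.consensus
                                 - truth.coords)[miss] ** 2).mean()))
        errs_pls.append(e_pls)
        errs_mean.append(e_mean)
        wins += e_pls < e_mean
    return wins, float(np.mean(errs_pls)), float(np.mean(errs_mean))


#: configured ecogeographic gradient for the end-to-end recovery
#: experiment: a monotone cold > temperate > warm centroid-size effect
END_TO_END_SIZE_MEANS = {"cold": 2800.0, "temperate": 2650.0,
                         "warm": 2470.0}


def end_to_end_recovery(seed: int = 0, n_permutations: int = 10_000,
                        output_dir: str | None = None) -> dict:
    """Simulate, reconstruct two masked fossils, and analyze.

    Uses the configured monotone climate gradient on centroid size and the
    reference-sample group sizes; returns the recovered group means, the
    cold-vs-warm permutation p-value, whether the configured size ordering
    was recovered, and the leading shape-PC variance fractions.
    """
    def run(outdir: str) -> dict:
        config = PipelineConfig(
            seed=seed, output_dir=outdir,
            thorax={"group_size_means": END_TO_END_SIZE_MEANS},
            patterns=["ohalo_2", "nazlet_khater_2"],
            kyphosis={"intercept": 10.0, "slope": 30.0},
            n_permutations=n_permutations)
        cmd_simulate(config)
        cmd_reconstruct(config)
        out = cmd_analyze(config)
        summary = out["summary"].set_index("group")
        means = {g: float(summary.loc[g, "mean_cs"])
                 for g in ("cold", "temperate", "warm")}
        ordered = means["cold"] > means["temperate"] > means["warm"]
        pv = out["size_pvalues"]
        row = pv[(pv["group_a"] == "cold") & (pv["group_b"] == "warm")]
        vf = out["variance_fractions"]
        return {"group_means": means,
                "ordering_recovered": bool(ordered),
                "cold_warm_p": float(row["p_value"].iloc[0]),
                "pc1_variance_fraction": float(vf[0]),
                "pc2_variance_fraction": float(vf[1])}

    if output_dir is not None:
        return run(output_dir)
    with tempfile.TemporaryDirectory() as tmp:
        return run(tmp)
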