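"""Seeded reproduction experiments: parameter recovery on synthetic cohorts.

Each experiment generates many independent synthetic cohorts with a known
injected effect, runs the corresponding pipeline stage, and reports how
often (or how accurately) the stage recovers the effect.  They are the
package's self-calibration: the expression experiment checks the paired
delta-Log2 stage against a closed-form injected fold change; the
selection and enrichment experiments check detection rates of the
purifying-selection and tumour-suppressor-targeting knobs; the bootstrap
experiment checks the empirical coverage of the excess-ratio confidence
interval under a Poisson null.

Problem sizes are desk scale: a few hundred genes and one to two hundred
samples per cohort, with seed counts of 50-100, sized so that each
experiment completes in minutes on one CPU while leaving the injected
effects comfortably detectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate as sim
from .classify import build_records
from .enrichment import bootstrap_ci, census_enrichment
from .expression import Eligibility, delta_expression
from .scoring import SurrogateScorer
from .selection import af_comparison, singleton_enrichment


def _spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    """Derive n independent 31-bit child seeds from one master seed."""
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)


def expression_recovery(
    base_seed: int,
    effect_fold: float = 1.25,
    n_genes: int = 200,
    n_samples: int = 10,
    n_seeds: int = 50,
    expr_sigma: float = 0.4,
) -> dict:
    """Recover an injected knockdown through the paired expression stage.

    Per seed: *n_genes* eligible tumour suppressors, each with one mutant
    and n_samples-1 wild-type samples, copy number fixed at 2, FPKM
    knocked down *effect_fold*-fold in the mutant sample.  The paired
    delta-Log2(nFPKM) stage runs per seed; reported is the mean of the
    per-seed pooled medians, also as a fold change (2**-median), plus the
    worst one-tailed signed-rank p across seeds.
    """
    seeds = _spawn_seeds(base_seed, n_seeds)
    samples = [f"T{t:04d}" for t in range(n_samples)]
    medians, pvals = [], []
    for seed in seeds:
        cfg = sim.SimConfig(
            seed=int(seed),
            n_genes=n_genes,
            n_tumours=n_samples,
            effect_fold=effect_fold,
            expr_sigma=expr_sigma,
            cnv_state_probs={2: 1.0},
            tsg_fraction=1.0, oncogene_fraction=0.0, both_fraction=0.0,
        )
        genes = [f"G{i:04d}" for i in range(n_genes)]
        roles = pd.DataFrame(
            {"gene_id": genes, "role": "TSG", "hallmark": False}
        )
        rng = np.random.default_rng(int(seed))
        mutant_of = {g: samples[int(rng.integers(0, n_samples))] for g in genes}
        down_events = pd.DataFrame(
            {"gene_id": genes, "sample_id": [mutant_of[g] for g in genes]}
        )
        expr = sim.make_expression(cfg, roles, samples, down_events)
        elig = Eligibility(
            mutant={g: [mutant_of[g]] for g in genes},
            wildtype={g: [s for s in samples if s != mutant_of[g]] for g in genes},
        )
        result = delta_expression(expr, elig)
        medians.append(result["pooled_median"])
        pvals.append(result["p_value"])
    mean_median = float(np.mean(medians))
    return {
        "mean_pooled_median": mean_median,
        "fold": float(2.0 ** (-mean_median)),
        "max_p": float(np.max(pvals)),
        "n_seeds": n_seeds,
        "n_pairs_per_seed": n_genes * (n_samples - 1),
    }


def selection_recovery(
    base_seed: int,
    sel_strength: float,
    n_seeds: int = 100,
    n_genes: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Detection rates of the purifying-selection signal in population cohorts.

    Per seed: a cohort generated at the given *sel_strength*, classified,
    then tested with the allele-frequency rank-sum and singleton Fisher
    diagnostics.  A seed counts as detected when the test is significant
    at *alpha* in the selection direction (lower DOWN frequencies, higher
    DOWN singleton fraction).
    """
    seeds = _spawn_seeds(base_seed, n_seeds)
    scorer = SurrogateScorer()
    af_hits = singleton_hits = 0
    for seed in seeds:
        cfg = sim.SimConfig(seed=int(seed), n_genes=n_genes, sel_strength=sel_strength)
        genome, sites, _roles = sim.make_genome(cfg)
        cohort = sim.make_normal_cohort(cfg, genome, sites, scorer)
        records, _qc = build_records(cohort, sites, genome, scorer)
        down = records[records["category"] == "DOWN"]
        bg = records[records["category"] == "BG"]
        af = af_comparison(down["af"], bg["af"])
        if (
            af["p_value"] is not None
            and af["p_value"] < alpha
            and af["down_median"] < af["bg_median"]
        ):
            af_hits += 1
        se = singleton_enrichment(down["ac"], bg["ac"])
        if (
            se["p_value"] is not None
            and se["p_value"] < alpha
            and se["down_singleton_fraction"] > se["bg_singleton_fraction"]
        ):
            singleton_hits += 1
    return {
        "af_significant_fraction": af_hits / n_seeds,
        "singleton_significant_fraction": singleton_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def enrichment_recovery(
    base_seed: int,
    tsg_boost: float,
    n_seeds: int = 100,
    n_genes: int = 200,
    n_tumours: int = 150,
    alpha: float = 0.05,
) -> dict:
    """Detection rates of tumour-suppressor targeting in somatic cohorts.

    Per seed: a somatic cohort generated at the given *tsg_boost*,
    classified, then tested for TSG and (specificity control) oncogene
    over-representation among DOWN-mutated vs background-mutated genes.
    """
    seeds = _spawn_seeds(base_seed, n_seeds)
    scorer = SurrogateScorer()
    tsg_hits = onc_hits = 0
    for seed in seeds:
        cfg = sim.SimConfig(
            seed=int(seed), n_genes=n_genes, n_tumours=n_tumours, tsg_boost=tsg_boost
        )
        genome, sites, roles = sim.make_genome(cfg)
        cohort = sim.make_cancer_cohort(cfg, genome, sites, roles, scorer)
        records, _qc = build_records(cohort, sites, genome, scorer)
        down_genes = set(records.loc[records["category"] == "DOWN", "gene_id"])
        bg_genes = set(records.loc[records["category"] == "BG", "gene_id"])
        for role, counter in (("TSG", "tsg"), ("oncogene", "onc")):
            res = census_enrichment(down_genes, bg_genes, roles, target_role=role)
            hit = (
                res["p_value"] is not None
                and res["p_value"] < alpha
                and res["odds_ratio"] > 1
            )
            if role == "TSG":
                tsg_hits += hit
            else:
                onc_hits += hit
    return {
        "tsg_significant_fraction": tsg_hits / n_seeds,
        "oncogene_significant_fraction": onc_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def bootstrap_coverage(
    base_seed: int,
    n_replicates: int = 500,
    genes_per_stratum: int = 50,
    iterations: int = 1000,
) -> dict:
    """Empirical coverage of the excess-ratio bootstrap CI under a Poisson null.

    Each replicate draws observed ~ Poisson(expected) for two strata
    (category and non-Census genes) with per-gene expected counts uniform
    on [5, 15]; the true excess ratio is 1, so the fraction of replicates
    whose 95% CI contains 1.0 estimates the interval's coverage.
    """
    rng = np.random.default_rng(base_seed)
    covered = 0
    genes_c = [f"C{i:03d}" for i in range(genes_per_stratum)]
    genes_n = [f"N{i:03d}" for i in range(genes_per_stratum)]
    roles = pd.DataFrame(
        {
            "gene_id": genes_c + genes_n,
            "role": ["TSG"] * genes_per_stratum + ["non-census"] * genes_per_stratum,
            "hallmark": False,
        }
    )
    for _ in range(n_replicates):
        expected = rng.uniform(5.0, 15.0, size=2 * genes_per_stratum)
        observed = rng.poisson(expected)
        burden = pd.DataFrame(
            {
                "gene_id": genes_c + genes_n,
                "mutation_class": "DOWN-paSNV",
                "observed": observed,
                "expected": expected,
            }
        )
        ci = bootstrap_ci(
            burden, roles, "TSG", "DOWN-paSNV", iterations=iterations, seed=rng
        )
        if ci["lo"] <= 1.0 <= ci["hi"]:
            covered += 1
    return {"coverage": covered / n_replicates, "n_replicates": n_replicates}
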