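"""Cancer-gene enrichment and the observed/expected mutation-excess ratio.

Gene roles follow the Cancer Gene Census convention: a *tumour suppressor*
is a gene labelled TSG but not Oncogene, an *oncogene* the reverse, and
genes labelled as both are excluded from the primary contrasts (they can
alternatively be analysed as their own group or merged with tumour
suppressors into "TSG+").

The excess ratio compares mutation burden against a neutral expectation
supplied per gene (e.g. by a genomic mutation-rate model)::

    excess = (sum obs / sum exp over category genes)
             / (sum obs / sum exp over non-Census genes)

with a 95% CI from bootstrap resampling of genes within each role stratum
(2.5th / 97.5th percentiles of the resampled ratios).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ROLES = ("TSG", "oncogene", "both", "non-census")
MUTATION_CLASSES = (
    "DOWN-paSNV", "UP-paSNV", "BG-paSNV", "nonsense", "missense", "synonymous"
)


def role_gene_sets(roles: pd.DataFrame, both_mode: str = "exclude") -> dict[str, set]:
    """Partition genes into role sets under the chosen handling of 'both'.

    ``both_mode``: 'exclude' drops both-labelled genes from the TSG and
    oncogene sets (the default analysis mode); 'separate' keeps them as
    their own set; 'merge' folds them into the tumour-suppressor set
    ("TSG+").  Non-Census genes are unaffected.
    """
    if both_mode not in {"exclude", "separate", "merge"}:
        raise ValueError(f"unknown both_mode {both_mode!r}")
    by_role = {
        role: set(roles.loc[roles["role"] == role, "gene_id"]) for role in ROLES
    }
    tsg = set(by_role["TSG"])
    onc = set(by_role["oncogene"])
    if both_mode == "merge":
        tsg |= by_role["both"]
    return {
        "TSG": tsg,
        "oncogene": onc,
        "both": by_role["both"],
        "non-census": by_role["non-census"],
    }


def census_enrichment(
    down_genes: Iterable[str],
    bg_genes: Iterable[str],
    roles: pd.DataFrame,
    target_role: str = "TSG",
    both_mode: str = "exclude",
    extra_gene_sets: dict[str, set] | None = None,
) -> dict:
    """Role enrichment among DOWN-mutated genes relative to BG-mutated genes.

    2x2 two-tailed Fisher on (gene in *target_role*) x (DOWN gene set vs
    BG gene set).  Genes labelled 'both' are dropped from the universe in
    'exclude' mode so neither margin counts them.  ``extra_gene_sets``
    (e.g. nonsense / missense / synonymous gene sets) get their raw role
    fractions reported alongside, as does the all-genes baseline.
    """
    sets = role_gene_sets(roles, both_mode)
    target = sets[target_role]
    excluded = sets["both"] if both_mode == "exclude" else set()
    universe = set(roles["gene_id"]) - excluded

    def _prep(genes):
        return set(genes) & universe

    down = _prep(down_genes)
    bg = _prep(bg_genes)
    if not down or not bg:
        logger.warning("census_enrichment: empty gene set")
        return {"odds_ratio": None, "p_value": None,
                "down_fraction": None, "bg_fraction": None, "fractions": {}}
    a, b = len(down & target), len(down - target)
    c, d = len(bg & target), len(bg - target)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    fractions = {"all_genes": len(universe & target) / len(universe)}
    for name, genes in {"DOWN": down, "BG": bg, **(extra_gene_sets or {})}.items():
        genes = _prep(genes)
        fractions[name] = (len(genes & target) / len(genes)) if genes else None
    return {
        "target_role": target_role,
        "odds_ratio": float(odds),
        "p_value": float(p),
        "down_fraction": a / len(down),
        "bg_fraction": c / len(bg),
        "n_down_genes": len(down),
        "n_bg_genes": len(bg),
        "fractions": fractions,
    }


def _sums(burden: pd.DataFrame, genes: set, mutation_class: str) -> tuple[float, float]:
    sub = burden[
        (burden["mutation_class"] == mutation_class) & burden["gene_id"].isin(genes)
    ]
    return float(sub["observed"].sum()), float(sub["expected"].sum())


def excess_ratio(
    burden: pd.DataFrame,
    roles: pd.DataFrame,
    category_role: str = "TSG",
    mutation_class: str = "DOWN-paSNV",
    both_mode: str = "exclude",
) -> float | None:
    """Observed/expected mutation excess of a gene-role category.

    Ratio of (sum observed / sum expected) over *category_role* genes to
    the same quantity over non-Census genes, within one mutation class.
    Invariant to gene order and to uniform rescaling of expected counts.
    Returns None (with a warning) on a zero denominator.
    """
    sets = role_gene_sets(roles, both_mode)
    obs_c, exp_c = _sums(burden, sets[category_role], mutation_class)
    obs_n, exp_n = _sums(burden, sets["non-census"], mutation_class)
    if exp_c == 0 or exp_n == 0 or obs_n == 0:
        logger.warning(
            "excess_ratio: zero denominator for %s/%s", category_role, mutation_class
        )
        return None
    return (obs_c / exp_c) / (obs_n / exp_n)


def bootstrap_ci(
    burden: pd.DataFrame,
    roles: pd.DataFrame,
    category_role: str = "TSG",
    mutation_class: str = "DOWN-paSNV",
    iterations: int = 1000,
    seed: int | np.random.Generator = 0,
    both_mode: str = "exclude",
    max_redraws: int = 100,
) -> dict:
    """Excess ratio with a bootstrap 95% confidence interval.

    Genes are resampled with replacement *within* each role stratum (the
    category stratum and the non-Census stratum); the excess ratio is
    recomputed per iteration and the 2.5th/97.5th percentiles of the
    resampled distribution (linear-interpolation definition) bound the CI.
    The point estimate comes from the unresampled data.  Iterations whose
    resample produces a zero denominator are redrawn and logged.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    sets = role_gene_sets(roles, both_mode)
    point = excess_ratio(burden, roles, category_role, mutation_class, both_mode)
    if point is None:
        return {"point": None, "lo": None, "hi": None, "n_iterations": 0}

    sub = burden[burden["mutation_class"] == mutation_class]
    by_gene = sub.set_index("gene_id")[["observed", "expected"]]

    def _stratum_arrays(genes: set) -> tuple[np.ndarray, np.ndarray]:
        genes = sorted(genes & set(by_gene.index))
        block = by_gene.loc[genes]
        return block["observed"].to_numpy(float), block["expected"].to_numpy(float)

    obs_c, exp_c = _stratum_arrays(sets[category_role])
    obs_n, exp_n = _stratum_arrays(sets["non-census"])
    if obs_c.size == 0 or obs_n.size == 0:
        raise ValueError("bootstrap_ci: empty stratum")

    samples = np.empty(iterations)
    for i in range(iterations):
        for _ in range(max_redraws):
            ic = rng.integers(0, obs_c.size, obs_c.size)
            inn = rng.integers(0, obs_n.size, obs_n.size)
            ec, en = exp_c[ic].sum(), exp_n[inn].sum()
            on = obs_n[inn].sum()
            if ec > 0 and en > 0 and on > 0:
                samples[i] = (obs_c[ic].sum() / ec) / (on / en)
                break
            logger.warning("bootstrap iteration %d redrawn (zero denominator)", i)
        else:  # pragma: no cover - pathological stratum
            raise RuntimeError("bootstrap_ci: could not draw a valid resample")
    lo, hi = np.percentile(samples, [2.5, 97.5], method="linear")
    return {
        "point": float(point),
        "lo": float(lo),
        "hi": float(hi),
        "n_iterations": iterations,
    }


def burden_report(
    burden: pd.DataFrame,
    roles: pd.DataFrame,
    iterations: int = 1000,
    seed: int = 0,
    both_mode: str = "exclude",
) -> dict:
    """Excess ratios with bootstrap CIs for every role x mutation class."""
    rng = np.random.default_rng(seed)
    out: dict = {}
    for role in ("TSG", "oncogene"):
        out[role] = {}
        for mclass in sorted(burden["mutation_class"].unique()):
            out[role][mclass] = bootstrap_ci(
                burden, roles, role, mclass,
                iterations=iterations, seed=rng, both_mode=both_mode,
            )
    return out
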