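"""Selection diagnostics and cancer-vs-normal cohort comparisons.

Purifying selection against variants that destroy functional
polyadenylation signals leaves two population-genetic footprints in a
healthy cohort: DOWN variants segregate at lower allele frequencies than
background variants, and they are enriched for singletons (allele count
of exactly 1).  In tumours the same class of variant is instead *more*
abundant, hits stronger signals, and falls on more conserved bases.
All tests are two-tailed (Fisher exact for 2x2 tables, Wilcoxon rank-sum
for distributions).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _fisher(table) -> tuple[float, float]:
    """Two-tailed Fisher exact test; returns (sample odds ratio, p)."""
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def singleton_enrichment(down_ac: Sequence[int], bg_ac: Sequence[int]) -> dict:
    """Singleton (AC = 1) enrichment of DOWN vs background variants.

    Builds the 2x2 table (singleton vs non-singleton) x (DOWN vs BG) and
    runs a two-tailed Fisher exact test.  Empty groups yield missing
    values rather than an error.
    """
    down_ac = np.asarray(list(down_ac), dtype=int)
    bg_ac = np.asarray(list(bg_ac), dtype=int)
    if down_ac.size == 0 or bg_ac.size == 0:
        return {
            "down_singleton_fraction": None,
            "bg_singleton_fraction": None,
            "odds_ratio": None,
            "p_value": None,
            "n_down": int(down_ac.size),
            "n_bg": int(bg_ac.size),
        }
    ds, dn = int((down_ac == 1).sum()), int((down_ac != 1).sum())
    bs, bn = int((bg_ac == 1).sum()), int((bg_ac != 1).sum())
    odds, p = _fisher([[ds, dn], [bs, bn]])
    return {
        "down_singleton_fraction": ds / down_ac.size,
        "bg_singleton_fraction": bs / bg_ac.size,
        "odds_ratio": odds,
        "p_value": p,
        "n_down": int(down_ac.size),
        "n_bg": int(bg_ac.size),
    }


def af_comparison(down_af: Sequence[float], bg_af: Sequence[float]) -> dict:
    """Two-tailed rank-sum comparison of allele frequencies (DOWN vs BG)."""
    down_af = np.asarray(list(down_af), dtype=float)
    bg_af = np.asarray(list(bg_af), dtype=float)
    if down_af.size < 2 or bg_af.size < 2:
        return {
            "down_median": None, "bg_median": None, "p_value": None,
            "n_down": int(down_af.size), "n_bg": int(bg_af.size),
        }
    stat = stats.mannwhitneyu(down_af, bg_af, alternative="two-sided")
    return {
        "down_median": float(np.median(down_af)),
        "bg_median": float(np.median(bg_af)),
        "p_value": float(stat.pvalue),
        "n_down": int(down_af.size),
        "n_bg": int(bg_af.size),
    }


def cohort_down_enrichment(cancer: pd.DataFrame, normal: pd.DataFrame) -> dict:
    """Enrichment of the DOWN class among somatic vs population variants.

    2x2 Fisher on (DOWN vs not-DOWN) x (cancer vs normal) over classified,
    deduplicated records.
    """
    if len(cancer) == 0 or len(normal) == 0:
        logger.warning("cohort_down_enrichment: empty cohort")
        return {
            "cancer_down_fraction": None, "normal_down_fraction": None,
            "odds_ratio": None, "p_value": None,
            "n_cancer": int(len(cancer)), "n_normal": int(len(normal)),
        }
    cd = int((cancer["category"] == "DOWN").sum())
    nd = int((normal["category"] == "DOWN").sum())
    odds, p = _fisher([[cd, len(cancer) - cd], [nd, len(normal) - nd]])
    return {
        "cancer_down_fraction": cd / len(cancer),
        "normal_down_fraction": nd / len(normal),
        "odds_ratio": odds,
        "p_value": p,
        "n_cancer": int(len(cancer)),
        "n_normal": int(len(normal)),
    }


def disrupted_signal_strength(
    cancer_wt: Sequence[float], normal_wt: Sequence[float]
) -> dict:
    """Compare wild-type signal strength of disrupted sites between cohorts.

    Two-tailed rank-sum on the wild-type cleavage probabilities of DOWN
    variants; a higher cancer median means somatic mutations hit stronger
    signals.
    """
    cancer_wt = np.asarray(list(cancer_wt), dtype=float)
    normal_wt = np.asarray(list(normal_wt), dtype=float)
    if cancer_wt.size < 2 or normal_wt.size < 2:
        return {
            "cancer_median": None, "normal_median": None, "p_value": None,
            "n_cancer": int(cancer_wt.size), "n_normal": int(normal_wt.size),
        }
    stat = stats.mannwhitneyu(cancer_wt, normal_wt, alternative="two-sided")
    return {
        "cancer_median": float(np.median(cancer_wt)),
        "normal_median": float(np.median(normal_wt)),
        "p_value": float(stat.pvalue),
        "n_cancer": int(cancer_wt.size),
        "n_normal": int(normal_wt.size),
    }


def lor_variance(lor: Sequence[float]) -> float | None:
    """Unbiased (n-1 denominator) sample variance of LOR values."""
    lor = np.asarray(list(lor), dtype=float)
    if lor.size < 2:
        return None
    return float(np.var(lor, ddof=1))


def conservation_window_mean(
    track: Mapping[tuple[str, int], float],
    chrom: str,
    pos: int,
    half_width: int = 7,
) -> tuple[float | None, bool]:
    """Mean conservation score in a (2*half_width + 1)-nt variant-centred window.

    Returns ``(mean, complete)``.  Positions missing from the track are
    averaged over (with ``complete=False`` and a logged flag); a window
    with no scored position at all returns ``(None, False)``.
    """
    values = [
        track[(chrom, p)]
        for p in range(pos - half_width, pos + half_width + 1)
        if (chrom, p) in track
    ]
    complete = len(values) == 2 * half_width + 1
    if not values:
        logger.warning("no conservation data around %s:%d", chrom, pos)
        return None, False
    if not complete:
        logger.warning(
            "conservation window at %s:%d has %d/%d positions",
            chrom, pos, len(values), 2 * half_width + 1,
        )
    return float(np.mean(values)), complete


def conservation_comparison(
    track: Mapping[tuple[str, int], float],
    cancer_down: pd.DataFrame,
    normal_down: pd.DataFrame,
    half_width: int = 7,
) -> dict:
    """Cancer-vs-normal comparison of conservation at DOWN variant loci.

    Reports both the exact-position scores and the windowed means, each
    with a two-tailed rank-sum p.
    """
    def _exact(df):
        return [
            track[(c, p)] for c, p in zip(df["chrom"], df["pos"]) if (c, p) in track
        ]

    def _window(df):
        out = []
        for c, p in zip(df["chrom"], df["pos"]):
            mean, _ = conservation_window_mean(track, c, int(p), half_width)
            if mean is not None:
                out.append(mean)
        return out

    result = {}
    for label, extractor in [("exact", _exact), ("window", _window)]:
        cvals = np.asarray(extractor(cancer_down), dtype=float)
        nvals = np.asarray(extractor(normal_down), dtype=float)
        if cvals.size < 2 or nvals.size < 2:
            result[label] = {"cancer_mean": None, "normal_mean": None, "p_value": None}
            continue
        stat = stats.mannwhitneyu(cvals, nvals, alternative="two-sided")
        result[label] = {
            "cancer_mean": float(cvals.mean()),
            "normal_mean": float(nvals.mean()),
            "p_value": float(stat.pvalue),
        }
    return result
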