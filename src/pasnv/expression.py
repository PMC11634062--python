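"""Paired expression differences, damaging-mutation co-occurrence and CNV direction.

Expression is copy-number normalized to a diploid reference before any
comparison::

    nFPKM = FPKM * 2 / CN        (entries with CN = 0 are masked)

For each eligible tumour-suppressor gene — one carrying a DOWN variant and
no other damaging mutation in at least one sample, and no mutation at all
in at least one other sample — every (mutant, wild-type) sample pair
contributes one paired difference::

    dLog2 = log2(nFPKM_mutant) - log2(nFPKM_wildtype)

and the pooled distribution is tested for a negative shift with a
one-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ExpressionSet:
    """Gene x sample FPKM and copy-number matrices with derived nFPKM."""

    def __init__(self, fpkm: pd.DataFrame, cn: pd.DataFrame):
        if not fpkm.index.equals(cn.index) or not fpkm.columns.equals(cn.columns):
            raise ValueError("fpkm and cn matrices must share genes and samples")
        if (fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.fpkm = fpkm
        self.cn = cn

    @property
    def nfpkm(self) -> pd.DataFrame:
        """FPKM normalized to a diploid reference; CN = 0 entries are NaN."""
        cn = self.cn.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = self.fpkm.to_numpy(float) * 2.0 / cn
        vals[cn == 0] = np.nan
        return pd.DataFrame(vals, index=self.fpkm.index, columns=self.fpkm.columns)


@dataclass
class Eligibility:
    """Mutant / wild-type sample split per eligible gene (disjoint sets)."""

    mutant: dict[str, list[str]] = field(default_factory=dict)
    wildtype: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.mutant)


def select_eligible(
    down_events: pd.DataFrame,
    pasnv_events: pd.DataFrame,
    damaging: pd.DataFrame,
    roles: pd.DataFrame,
    expression: ExpressionSet,
    min_mean_fpkm: float = 1.0,
) -> Eligibility:
    """Shortlist tumour suppressors with clean mutant and wild-type samples.

    A gene qualifies when it is a tumour suppressor (role TSG, not
    oncogene/both), detectably expressed (mean FPKM over its wild-type
    samples above *min_mean_fpkm*), and has

    * >= 1 "mutant" sample: carries a DOWN variant and no damaging mutation;
    * >= 1 "wild-type" sample: no variant of any category and no damaging
      mutation for this gene.

    ``down_events`` / ``pasnv_events`` carry (gene_id, sample_id) rows;
    ``damaging`` is a binary gene x sample matrix.
    """
    tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])
    samples = list(expression.fpkm.columns)
    dmg = damaging.reindex(index=expression.fpkm.index, columns=samples).fillna(0)

    by_gene_down = down_events.groupby("gene_id")["sample_id"].apply(set)
    by_gene_any = pasnv_events.groupby("gene_id")["sample_id"].apply(set)

    elig = Eligibility()
    for gene in sorted(set(by_gene_down.index) & tsg):
        if gene not in expression.fpkm.index:
            continue
        dmg_samples = {s for s in samples if dmg.loc[gene, s] > 0}
        mutant = sorted(by_gene_down[gene] - dmg_samples)
        touched = by_gene_any.get(gene, set()) | dmg_samples
        wildtype = sorted(set(samples) - touched)
        if not mutant or not wildtype:
            continue
        if expression.fpkm.loc[gene, wildtype].mean() <= min_mean_fpkm:
            continue
        elig.mutant[gene] = mutant
        elig.wildtype[gene] = wildtype
    return elig


def delta_expression(expression: ExpressionSet, eligibility: Eligibility) -> dict:
    """Pairwise dLog2(nFPKM) distributions and the one-tailed signed-rank test.

    Every (mutant, wild-type) sample pair of every eligible gene yields one
    difference; pairs where either member has masked or non-positive nFPKM
    are dropped and counted.  Returns per-gene medians, the pooled median
    (also expressed as a fold change, 2**-median), the one-tailed
    (negative-shift) Wilcoxon signed-rank p on pooled pairs, and a
    long-format table of the individual differences.
    """
    nf = expression.nfpkm
    deltas: list[dict] = []
    n_dropped = 0
    for gene in eligibility.genes:
        for ms in eligibility.mutant[gene]:
            for ws in eligibility.wildtype[gene]:
                a, b = nf.loc[gene, ms], nf.loc[gene, ws]
                if not (a > 0 and b > 0) or np.isnan(a) or np.isnan(b):
                    n_dropped += 1
                    continue
                deltas.append(
                    {
                        "gene_id": gene,
                        "mutant_sample": ms,
                        "wildtype_sample": ws,
                        "delta_log2": float(np.log2(a) - np.log2(b)),
                    }
                )
    table = pd.DataFrame(
        deltas, columns=["gene_id", "mutant_sample", "wildtype_sample", "delta_log2"]
    )
    if table.empty:
        return {
            "pooled_median": None, "pooled_fold": None, "p_value": None,
            "n_pairs": 0, "n_dropped": n_dropped, "n_genes": 0,
            "per_gene_median": {}, "pairs": table,
        }
    pooled = table["delta_log2"].to_numpy()
    per_gene = table.groupby("gene_id")["delta_log2"].median().to_dict()
    if np.all(pooled == 0):
        p = 1.0  # signed-rank undefined with all-zero differences
    else:
        p = float(stats.wilcoxon(pooled, alternative="less").pvalue)
    median = float(np.median(pooled))
    return {
        "pooled_median": median,
        "pooled_fold": float(2.0 ** (-median)),
        "p_value": p,
        "n_pairs": int(len(table)),
        "n_dropped": n_dropped,
        "n_genes": len(per_gene),
        "per_gene_median": {g: float(m) for g, m in per_gene.items()},
        "pairs": table,
    }


def _event_cooccurs(events: pd.DataFrame, damaging: pd.DataFrame) -> np.ndarray:
    flags = []
    for gene, sample in zip(events["gene_id"], events["sample_id"]):
        try:
            flags.append(bool(damaging.loc[gene, sample] > 0))
        except KeyError:
            flags.append(False)
    return np.asarray(flags, dtype=bool)


def cooccurrence_rate(
    events: pd.DataFrame,
    damaging: pd.DataFrame,
    roles: pd.DataFrame,
) -> dict:
    """Co-occurrence of variant events with damaging mutations in the same tumour.

    An event (gene, sample, category) co-occurs when the binary damaging
    table is 1 at that (gene, sample).  Reports rates and a two-tailed
    Fisher test of (co-occur vs not) x (DOWN vs BG), over all genes and
    over the tumour-suppressor subset.
    """
    tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])

    def _contrast(ev: pd.DataFrame) -> dict:
        down = ev[ev["category"] == "DOWN"]
        bg = ev[ev["category"] == "BG"]
        if down.empty or bg.empty:
            return {"down_rate": None, "bg_rate": None,
                    "odds_ratio": None, "p_value": None,
                    "n_down": int(len(down)), "n_bg": int(len(bg))}
        dc = int(_event_cooccurs(down, damaging).sum())
        bc = int(_event_cooccurs(bg, damaging).sum())
        table = [[dc, len(down) - dc], [bc, len(bg) - bc]]
        if dc == 0 and bc == 0:
            odds, p = None, None
        else:
            o, p = stats.fisher_exact(table, alternative="two-sided")
            odds = None if np.isinf(o) else float(o)
            p = float(p)
        return {
            "down_rate": dc / len(down),
            "bg_rate": bc / len(bg),
            "odds_ratio": odds,
            "p_value": p,
            "n_down": int(len(down)),
            "n_bg": int(len(bg)),
        }

    return {
        "all_genes": _contrast(events),
        "tsg_only": _contrast(events[events["gene_id"].isin(tsg)]),
    }


def damaging_frequency_compare(
    roles: pd.DataFrame,
    down_gene_set: set,
    damaging: pd.DataFrame,
) -> dict:
    """Damaging-mutation frequency in DOWN-containing vs DOWN-lacking TSGs.

    Per-gene frequency is the fraction of samples with a damaging
    mutation; the two tumour-suppressor groups are compared with a
    two-tailed rank-sum test.  Groups below two genes report missing.
    """
    tsg = sorted(set(roles.loc[roles["role"] == "TSG", "gene_id"]) & set(damaging.index))
    freq = damaging.loc[tsg].mean(axis=1)
    pos = freq[freq.index.isin(down_gene_set)]
    neg = freq[~freq.index.isin(down_gene_set)]
    if len(pos) < 2 or len(neg) < 2:
        return {"down_group_median": None, "other_group_median": None,
                "p_value": None, "n_down_group": int(len(pos)),
                "n_other_group": int(len(neg))}
    stat = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return {
        "down_group_median": float(pos.median()),
        "other_group_median": float(neg.median()),
        "p_value": float(stat.pvalue),
        "n_down_group": int(len(pos)),
        "n_other_group": int(len(neg)),
    }


def cnv_direction(events: pd.DataFrame, cnv_calls: pd.DataFrame) -> dict:
    """Copy-number gain vs loss at variant loci, DOWN against background.

    ``cnv_calls`` rows: (gene_id, sample_id, call) with call in
    {gain, loss, neutral}.  Reports gain/loss/neutral counts and the
    gain:loss ratio per category plus a two-tailed Fisher test of
    (gain vs loss) x (DOWN vs BG).  A category without losses reports an
    infinite ratio, flagged.
    """
    lookup = {
        (g, s): c
        for g, s, c in zip(
            cnv_calls["gene_id"], cnv_calls["sample_id"], cnv_calls["call"]
        )
    }

    def _counts(ev: pd.DataFrame) -> dict:
        calls = [lookup.get((g, s), "neutral")
                 for g, s in zip(ev["gene_id"], ev["sample_id"])]
        gain = calls.count("gain")
        loss = calls.count("loss")
        ratio: float | None
        flagged = False
        if gain == 0 and loss == 0:
            ratio = None
        elif loss == 0:
            ratio = float("inf")
            flagged = True
            logger.warning("cnv_direction: no losses; gain:loss ratio infinite")
        else:
            ratio = gain / loss
        return {"gain": gain, "loss": loss, "neutral": calls.count("neutral"),
                "gain_loss_ratio": ratio, "ratio_flagged": flagged}

    down = events[events["category"] == "DOWN"]
    bg = events[events["category"] == "BG"]
    dc, bc = _counts(down), _counts(bg)
    if min(dc["gain"] + dc["loss"], bc["gain"] + bc["loss"]) == 0:
        odds, p = None, None
    else:
        o, p = stats.fisher_exact(
            [[dc["gain"], dc["loss"]], [bc["gain"], bc["loss"]]],
            alternative="two-sided",
        )
        odds = None if np.isinf(o) else float(o)
        p = float(p)
    return {"down": dc, "bg": bc, "odds_ratio": odds, "p_value": p}
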