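"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the data the pipeline consumes on
real cohorts: per-gene 3'UTR contigs with one annotated cleavage site and
one planted polyadenylation-signal hexamer; a population cohort whose
allele counts follow the neutral infinite-sites site-frequency spectrum
P(AC = k) proportional to 1/k, with a tunable purifying-selection knob
that forces signal-destroying variants to singletons; a somatic cohort
with per-tumour Poisson mutation burdens and a positive-selection knob
boosting signal-destroying hits in tumour suppressors; log-normal
expression with an injected fold-knockdown in mutant samples; and the
auxiliary damaging-mutation, burden, conservation and copy-number tables.

Every generator is a pure function of a :class:`SimConfig`; a fixed seed
yields byte-identical outputs.  Each generator draws from its own seed
stream so that, e.g., regenerating the cancer cohort does not perturb the
genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import windows as W
from .classify import classify, count_awtaaa
from .enrichment import MUTATION_CLASSES
from .expression import ExpressionSet
from .scoring import Scorer, SurrogateScorer, WINDOW_FLANK, compute_lor

_BASES = np.array(list("ACGT"))

DEFAULT_CANCER_TYPE_WEIGHTS = {
    "ColoRect-AdenoCA": 0.46,
    "Liver-HCC": 0.12,
    "Panc-AdenoCA": 0.10,
    "Breast-AdenoCA": 0.08,
    "Lung-SCC": 0.08,
    "Eso-AdenoCA": 0.06,
    "CNS-GBM": 0.05,
    "Kidney-RCC": 0.05,
}


class ConfigurationError(ValueError):
    """Invalid :class:`SimConfig` field or combination."""


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the defaults the tests assume.

    Selection knobs: ``sel_strength`` is the probability that a DOWN
    variant in the population cohort is forced to a singleton (purifying
    selection); ``tsg_boost`` multiplies the sampling weight of tumour
    suppressors when placing signal-targeted somatic variants (positive
    selection); ``effect_fold`` divides FPKM in DOWN-carrying
    (gene, sample) pairs; ``cooccur_boost`` multiplies the damaging-mutation
    probability in the same pairs.  Setting all four to their null values
    (0, 1, 1, 1) produces data with no downstream signal.
    """

    seed: int = 0
    n_genes: int = 60
    utr_length: int = 600
    pas_hexamer_mix: float = 0.8       # fraction of genes planted with AATAAA (vs ATTAAA)
    pas_offset_range: tuple[int, int] = (-30, -15)
    n_individuals: int = 200
    n_tumours: int = 100
    mut_per_tumour: float = 2.5
    bg_mut_per_window: float = 3.0     # mean background variants per window, population cohort
    hex_hit_rate: float = 0.6          # per-window prob of a PAS-targeted population variant
    pas_target_fraction: float = 0.3   # fraction of somatic SNVs aimed at planted hexamers
    sel_strength: float = 0.0
    tsg_boost: float = 1.0
    effect_fold: float = 1.0
    expr_sigma: float = 0.4            # log-normal spread (natural-log sd) of FPKM
    cooccur_boost: float = 1.0
    damaging_baseline: float = 0.1
    cancer_type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CANCER_TYPE_WEIGHTS)
    )
    tsg_fraction: float = 0.2
    oncogene_fraction: float = 0.2
    both_fraction: float = 0.05
    hallmark_fraction: float = 0.3
    cnv_state_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.01, 1: 0.07, 2: 0.80, 3: 0.09, 4: 0.03}
    )
    cnv_neutral_prob: float = 0.8      # for the gain/loss/neutral call table
    cnv_gain_loss_odds: float = 4.0
    cnv_down_gain_factor: float = 1.0  # multiplies gain odds at DOWN loci
    burden_expected_range: tuple[float, float] = (5.0, 15.0)
    burden_inflation: Mapping[str, float] = field(default_factory=dict)
    burden_tsg_inflation: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.pas_offset_range
        if not (-WINDOW_FLANK <= lo <= hi <= -6):
            raise ConfigurationError(
                f"pas_offset_range must lie within [{-WINDOW_FLANK}, -6]"
            )
        if self.utr_length < 2 * WINDOW_FLANK + 1:
            raise ConfigurationError(
                f"utr_length must be at least {2 * WINDOW_FLANK + 1} nt"
            )
        if not 0.0 <= self.sel_strength <= 1.0:
            raise ConfigurationError("sel_strength must be in [0, 1]")
        if self.tsg_boost < 0:
            raise ConfigurationError("tsg_boost must be non-negative")
        if self.effect_fold <= 0:
            raise ConfigurationError("effect_fold must be positive")
        total = sum(self.cancer_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("cancer_type_weights must sum to 1")
        if abs(sum(self.cnv_state_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cnv_state_probs must sum to 1")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pas_offset_range"] = list(d["pas_offset_range"])
        d["burden_expected_range"] = list(d["burden_expected_range"])
        return d


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(config.seed), stream])


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_genome(
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate one contig per gene with a planted proximal PAS hexamer.

    Each contig carries exactly one annotated cleavage site; the planted
    AATAAA/ATTAAA start offset is drawn from ``pas_offset_range``.
    Background sequence is uniform over {A,C,G,T}; contigs with spurious
    AWTAAA starts in the proximal region [-40, -5] are rejected and
    re-sampled, so the planted hexamer is the only proximal signal.
    Distal AWTAAA occurrences are allowed (they exercise the background
    term of the scorer).  Strands are assigned at random; minus-strand
    contigs are stored reverse-complemented with the cleavage position
    mapped accordingly.

    Returns (genome, sites, roles).  The site table carries two extra
    truth columns (``pas_offset``, ``pas_kind``) used by downstream
    generators; exporters drop them.
    """
    rng = _rng(config, 1)
    L = config.utr_length
    cs_sense = WINDOW_FLANK + 1 + (L - 2 * WINDOW_FLANK - 1) // 2

    genome: dict[str, str] = {}
    site_rows, role_rows = [], []

    n = config.n_genes
    n_tsg = int(round(config.tsg_fraction * n))
    n_onc = int(round(config.oncogene_fraction * n))
    n_both = int(round(config.both_fraction * n))
    role_pool = (
        ["TSG"] * n_tsg + ["oncogene"] * n_onc + ["both"] * n_both
        + ["non-census"] * (n - n_tsg - n_onc - n_both)
    )
    role_assignment = np.array(role_pool, dtype=object)
    rng.shuffle(role_assignment)

    lo, hi = config.pas_offset_range
    for i in range(n):
        gene = f"G{i:04d}"
        chrom = f"ctg{i:04d}"
        site = f"S{i:04d}"
        offset = int(rng.integers(lo, hi + 1))
        hexamer = "AATAAA" if rng.random() < config.pas_hexamer_mix else "ATTAAA"
        start = cs_sense + offset  # 1-based sense position of hexamer start
        while True:
            seq = _random_seq(rng, L)
            seq[start - 1 : start + 5] = list(hexamer)
            proximal = "".join(
                seq[cs_sense - 40 - 1 : cs_sense - 5 + 5]
            )  # all starts with offset in [-40, -5]
            if count_awtaaa(proximal) == 1:
                break
        sense = "".join(seq)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genome[chrom] = sense
            cs_pos = cs_sense
        else:
            genome[chrom] = W.revcomp(sense)
            cs_pos = L - cs_sense + 1
        site_rows.append(
            {
                "site_id": site, "chrom": chrom, "strand": strand,
                "cs_pos": cs_pos, "gene_id": gene, "region": "3UTR",
                "pas_offset": offset, "pas_kind": hexamer,
            }
        )
        role = role_assignment[i]
        role_rows.append(
            {
                "gene_id": gene,
                "role": role,
                "hallmark": bool(
                    role != "non-census" and rng.random() < config.hallmark_fraction
                ),
            }
        )
    sites = pd.DataFrame(site_rows)
    roles = pd.DataFrame(role_rows)
    return genome, sites, roles


def _sense_to_plus(site_row, L: int, sense_pos: int, ref: str, alt: str):
    """Map a sense-coordinate substitution to plus-strand VCF convention."""
    if site_row.strand == "+":
        return sense_pos, ref, alt
    return L - sense_pos + 1, W.revcomp(ref), W.revcomp(alt)


def _sfs_probs(n_chromosomes: int) -> np.ndarray:
    k = np.arange(1, n_chromosomes + 1, dtype=float)
    p = 1.0 / k
    return p / p.sum()


def make_normal_cohort(
    config: SimConfig,
    genome: Mapping[str, str],
    sites: pd.DataFrame,
    scorer: Scorer | None = None,
) -> pd.DataFrame:
    """Population cohort with a neutral SFS and a purifying-selection knob.

    Each window receives Poisson(``bg_mut_per_window``) substitutions at
    distinct offsets plus, with probability ``hex_hit_rate``, one variant
    inside the planted hexamer.  Allele counts follow P(AC = k) ~ 1/k
    truncated at 2 * n_individuals; variants classifying as DOWN under the
    scorer are resampled to AC = 1 with probability ``sel_strength``
    (forced-singleton model: selection changes frequencies, not variant
    counts, so DOWN abundance stays comparable across modes).
    """
    rng = _rng(config, 2)
    scorer = scorer or SurrogateScorer()
    two_n = 2 * config.n_individuals
    sfs = _sfs_probs(two_n)
    L = config.utr_length
    rows = []
    for site_row in sites.itertuples(index=False):
        site = W.CleavageSite(
            site_id=site_row.site_id, gene_id=site_row.gene_id,
            chrom=site_row.chrom, strand=site_row.strand, cs_pos=site_row.cs_pos,
        )
        win = W.extract_window(genome, site)
        wt_score = scorer.score(win.sequence)
        wt_count = count_awtaaa(win.sequence)
        cs_sense = site_row.cs_pos if site_row.strand == "+" else L - site_row.cs_pos + 1

        offsets: list[int] = []
        if rng.random() < config.hex_hit_rate:
            offsets.append(int(site_row.pas_offset + rng.integers(0, 6)))
        n_bg = int(rng.poisson(config.bg_mut_per_window))
        pool = np.arange(-WINDOW_FLANK, WINDOW_FLANK + 1)
        picks = rng.choice(pool, size=min(n_bg, pool.size), replace=False)
        for off in picks:
            if int(off) not in offsets:
                offsets.append(int(off))

        for off in offsets:
            ref = win.base_at(off)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            mut_win = win.with_base(off, alt)
            lor = compute_lor(wt_score, scorer.score(mut_win.sequence))
            category = classify(lor, wt_count, count_awtaaa(mut_win.sequence))
            ac = int(rng.choice(two_n, p=sfs) + 1)
            if category == "DOWN" and rng.random() < config.sel_strength:
                ac = 1
            pos, pref, palt = _sense_to_plus(site_row, L, cs_sense + off, ref, alt)
            rows.append(
                {
                    "chrom": site_row.chrom, "pos": pos, "ref": pref, "alt": palt,
                    "cohort": "normal", "ac": ac, "af": ac / two_n,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "cohort", "ac", "af"]
    )


def make_cancer_cohort(
    config: SimConfig,
    genome: Mapping[str, str],
    sites: pd.DataFrame,
    roles: pd.DataFrame,
    scorer: Scorer | None = None,
) -> pd.DataFrame:
    """Somatic cohort with Poisson burdens and a TSG positive-selection knob.

    Each tumour receives Poisson(``mut_per_tumour``) SNVs.  A fraction
    ``pas_target_fraction`` of them target planted hexamers, with the gene
    drawn with weight ``tsg_boost`` for tumour suppressors (renormalized) —
    so signal-destroying candidates in TSGs are accepted
    proportionally more often; the remainder fall uniformly on non-hexamer
    window positions.  Every variant carries a sample id and a tumour-type
    label drawn from ``cancer_type_weights``.
    """
    if config.tsg_boost < 0:
        raise ConfigurationError("tsg_boost must be non-negative")
    rng = _rng(config, 3)
    L = config.utr_length
    tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])
    site_list = list(sites.itertuples(index=False))
    weights = np.array(
        [config.tsg_boost if s.gene_id in tsg else 1.0 for s in site_list]
    )
    if weights.sum() == 0:
        weights = np.ones(len(site_list))
    weights = weights / weights.sum()

    ttype_names = sorted(config.cancer_type_weights)
    ttype_probs = np.array([config.cancer_type_weights[t] for t in ttype_names])
    window_cache: dict[str, W.Window] = {}

    rows = []
    for t in range(config.n_tumours):
        sample = f"T{t:04d}"
        ttype = str(rng.choice(len(ttype_names), p=ttype_probs))
        ttype = ttype_names[int(ttype)]
        seen: set[tuple] = set()
        for _ in range(int(rng.poisson(config.mut_per_tumour))):
            targeted = rng.random() < config.pas_target_fraction
            if targeted:
                s = site_list[int(rng.choice(len(site_list), p=weights))]
                off = int(s.pas_offset + rng.integers(0, 6))
            else:
                s = site_list[int(rng.integers(0, len(site_list)))]
                pas_span = range(s.pas_offset, s.pas_offset + 6)
                while True:
                    off = int(rng.integers(-WINDOW_FLANK, WINDOW_FLANK + 1))
                    if off not in pas_span:
                        break
            if s.site_id not in window_cache:
                site = W.CleavageSite(
                    site_id=s.site_id, gene_id=s.gene_id, chrom=s.chrom,
                    strand=s.strand, cs_pos=s.cs_pos,
                )
                window_cache[s.site_id] = W.extract_window(genome, site)
            win = window_cache[s.site_id]
            ref = win.base_at(off)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            cs_sense = s.cs_pos if s.strand == "+" else L - s.cs_pos + 1
            pos, pref, palt = _sense_to_plus(s, L, cs_sense + off, ref, alt)
            key = (s.chrom, pos, pref, palt)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "chrom": s.chrom, "pos": pos, "ref": pref, "alt": palt,
                    "cohort": "cancer", "sample_id": sample, "tumour_type": ttype,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "cohort", "sample_id", "tumour_type"],
    )


def tumour_samples(config: SimConfig) -> list[str]:
    return [f"T{t:04d}" for t in range(config.n_tumours)]


def make_expression(
    config: SimConfig,
    roles: pd.DataFrame,
    samples: list[str],
    down_events: pd.DataFrame,
) -> ExpressionSet:
    """Log-normal FPKM with CNV scaling and an injected DOWN knockdown.

    Per-gene baselines are log-normal (gene-level mean drawn once, entry
    noise with sd ``expr_sigma`` on the natural-log scale).  Copy number
    is drawn per entry from ``cnv_state_probs`` and FPKM scales linearly
    with CN/2 *before* the knockdown; DOWN-carrying (gene, sample) pairs
    are then divided by ``effect_fold``.
    """
    if config.effect_fold <= 0:
        raise ConfigurationError("effect_fold must be positive")
    rng = _rng(config, 4)
    genes = list(roles["gene_id"])
    mu = rng.normal(np.log(20.0), 0.7, size=len(genes))
    fpkm = np.exp(
        mu[:, None] + rng.normal(0.0, config.expr_sigma, size=(len(genes), len(samples)))
    )
    states = sorted(config.cnv_state_probs)
    probs = np.array([config.cnv_state_probs[s] for s in states], dtype=float)
    cn = np.array(states)[
        rng.choice(len(states), size=(len(genes), len(samples)), p=probs)
    ]
    fpkm = fpkm * cn / 2.0
    fpkm_df = pd.DataFrame(fpkm, index=genes, columns=samples)
    for g, s in zip(down_events["gene_id"], down_events["sample_id"]):
        if g in fpkm_df.index and s in fpkm_df.columns:
            fpkm_df.loc[g, s] /= config.effect_fold
    cn_df = pd.DataFrame(cn, index=genes, columns=samples)
    return ExpressionSet(fpkm_df, cn_df)


def make_aux_tables(
    config: SimConfig,
    roles: pd.DataFrame,
    samples: list[str],
    down_events: pd.DataFrame,
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Damaging-mutation, burden, conservation and CNV-call tables.

    * damaging — binary gene x sample Bernoulli(``damaging_baseline``)
      matrix; the probability is multiplied by ``cooccur_boost`` (capped at
      1, logged if capped) in DOWN-carrying pairs.
    * burden — per gene and mutation class, a positive expected count
      (uniform over ``burden_expected_range``) and an observed count drawn
      Poisson(expected x inflation); inflation defaults to 1 and can be set
      per class and, additionally, per class for tumour suppressors.
    * conservation — per-base track over every site window: 0.9 over the
      planted hexamer, 0.1 elsewhere, plus Gaussian noise, clipped to [0, 1].
    * cnv_calls — gain/loss/neutral per (gene, sample), with configurable
      gain:loss odds, optionally damped at DOWN loci.
    """
    rng = _rng(config, 5)
    genes = list(roles["gene_id"])
    tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])
    down_pairs = set(zip(down_events["gene_id"], down_events["sample_id"]))

    # damaging matrix
    p = np.full((len(genes), len(samples)), config.damaging_baseline)
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            if (g, s) in down_pairs:
                p[i, j] = min(1.0, p[i, j] * config.cooccur_boost)
    damaging = pd.DataFrame(
        (rng.random(p.shape) < p).astype(int), index=genes, columns=samples
    )

    # burden table
    lo, hi = config.burden_expected_range
    burden_rows = []
    for g in genes:
        for mclass in MUTATION_CLASSES:
            expected = float(rng.uniform(lo, hi))
            infl = float(config.burden_inflation.get(mclass, 1.0))
            if g in tsg:
                infl *= float(config.burden_tsg_inflation.get(mclass, 1.0))
            burden_rows.append(
                {
                    "gene_id": g,
                    "mutation_class": mclass,
                    "observed": int(rng.poisson(expected * infl)),
                    "expected": expected,
                }
            )
    burden = pd.DataFrame(burden_rows)

    # conservation track over each site window (plus-strand positions)
    cons_rows = []
    L = config.utr_length
    for s in sites.itertuples(index=False):
        cs_sense = s.cs_pos if s.strand == "+" else L - s.cs_pos + 1
        hex_sense = range(cs_sense + s.pas_offset, cs_sense + s.pas_offset + 6)
        for sense_pos in range(cs_sense - WINDOW_FLANK, cs_sense + WINDOW_FLANK + 1):
            base = 0.9 if sense_pos in hex_sense else 0.1
            score = float(np.clip(base + rng.normal(0.0, 0.03), 0.0, 1.0))
            pos = sense_pos if s.strand == "+" else L - sense_pos + 1
            cons_rows.append({"chrom": s.chrom, "pos": pos, "score": score})
    conservation = pd.DataFrame(cons_rows).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    # CNV gain/loss/neutral calls
    odds = config.cnv_gain_loss_odds
    cnv_rows = []
    for g in genes:
        for s in samples:
            o = odds * (config.cnv_down_gain_factor if (g, s) in down_pairs else 1.0)
            p_gain = (1.0 - config.cnv_neutral_prob) * o / (1.0 + o)
            p_loss = (1.0 - config.cnv_neutral_prob) / (1.0 + o)
            u = rng.random()
            call = "gain" if u < p_gain else ("loss" if u < p_gain + p_loss else "neutral")
            cnv_rows.append({"gene_id": g, "sample_id": s, "call": call})
    cnv_calls = pd.DataFrame(cnv_rows)

    return damaging, burden, conservation, cnv_calls
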