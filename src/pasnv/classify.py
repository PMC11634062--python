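"""Classification of variants near cleavage sites into UP / DOWN / BG.

A variant is classified from two signals computed on its 205-nt window:
the LOR of mutant vs wild-type cleavage probability, and the change in
the number of AWTAAA polyadenylation-signal hexamers (AATAAA or ATTAAA,
overlapping occurrences counted):

* UP   — LOR >= +1 and the mutation creates an AWTAAA (count increases)
* DOWN — LOR <= -1 and the mutation disrupts an AWTAAA (count decreases)
* BG   — everything else; the background control group

Both thresholds are inclusive.  Hexamer gain/loss is assessed over the
whole window; a substitution converting AATAAA to ATTAAA leaves the count
unchanged and is therefore background.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd

from . import windows as W
from .scoring import Scorer, WINDOW_FLANK, compute_lor

logger = logging.getLogger(__name__)

LOR_UP = 1.0
LOR_DOWN = -1.0

_RE_AWTAAA = re.compile(r"(?=A[AT]TAAA)")

RECORD_COLUMNS = [
    "chrom", "pos", "ref", "alt", "cohort", "ac", "af", "sample_id",
    "tumour_type", "site_id", "gene_id", "offset", "wt", "mut", "lor",
    "awtaaa_wt", "awtaaa_mut", "category",
]


def count_awtaaa(sequence: str) -> int:
    """Number of AWTAAA start positions, overlapping occurrences included."""
    return sum(1 for _ in _RE_AWTAAA.finditer(sequence))


def classify(lor: float, awtaaa_wt: int, awtaaa_mut: int) -> str:
    """UP / DOWN / BG category from the LOR and the hexamer-count change."""
    if lor >= LOR_UP and awtaaa_mut > awtaaa_wt:
        return "UP"
    if lor <= LOR_DOWN and awtaaa_mut < awtaaa_wt:
        return "DOWN"
    return "BG"


def build_records(
    variants: pd.DataFrame,
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    scorer: Scorer,
    flank: int = WINDOW_FLANK,
) -> tuple[pd.DataFrame, dict]:
    """Score and classify every (variant, site-window) pair.

    Returns one row per pair (a variant spanning two windows appears
    twice; duplicates across tumour samples appear once per sample) plus a
    QC dict counting mapped, multi-mapped, out-of-bounds and ref-mismatch
    records.  Deduplication and strongest-effect resolution happen in
    :func:`dedupe_and_resolve`.
    """
    qc = W.QCCounters(n_variants=len(variants))
    site_objs = W.sites_from_frame(sites)

    # per-site caches: window extraction, wt score, wt hexamer count
    window_cache: dict[int, W.Window | None] = {}
    wt_score_cache: dict[int, float] = {}
    wt_count_cache: dict[int, int] = {}
    # per-(site, pos, alt) cache so recurrent somatic variants are scored once
    pair_cache: dict[tuple[int, int, str], tuple | None] = {}

    pairs = W.map_variants_to_sites(variants, sites, flank=flank)
    qc.n_pairs = len(pairs)
    per_variant = pairs.groupby("variant_idx").size()
    qc.n_multi_mapped = int((per_variant > 1).sum())

    rows = []
    for variant_idx, site_idx in pairs.itertuples(index=False):
        vrow = variants.loc[variant_idx]
        site = site_objs[site_idx]
        if site_idx not in window_cache:
            try:
                win = W.extract_window(genome, site, flank=flank)
            except W.WindowOutOfBounds as exc:
                logger.warning("skipping site: %s", exc)
                win = None
            window_cache[site_idx] = win
            if win is not None:
                wt_score_cache[site_idx] = scorer.score(win.sequence)
                wt_count_cache[site_idx] = count_awtaaa(win.sequence)
        win = window_cache[site_idx]
        if win is None:
            qc.n_out_of_bounds += 1
            continue

        variant = W.variant_from_row(vrow)
        key = (site_idx, variant.pos, variant.alt)
        if key not in pair_cache:
            try:
                mut_win = W.apply_variant(win, variant, site, flank=flank)
            except W.RefMismatch as exc:
                logger.warning("excluding variant: %s", exc)
                pair_cache[key] = None
            else:
                mut_score = scorer.score(mut_win.sequence)
                mut_count = count_awtaaa(mut_win.sequence)
                lor = compute_lor(wt_score_cache[site_idx], mut_score)
                pair_cache[key] = (mut_score, mut_count, lor)
        cached = pair_cache[key]
        if cached is None:
            qc.n_ref_mismatch += 1
            continue
        mut_score, mut_count, lor = cached
        rows.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "cohort": variant.cohort,
                "ac": variant.ac,
                "af": variant.af,
                "sample_id": variant.sample_id,
                "tumour_type": variant.tumour_type,
                "site_id": site.site_id,
                "gene_id": site.gene_id,
                "offset": W.variant_offset(site, variant.pos),
                "wt": wt_score_cache[site_idx],
                "mut": mut_score,
                "lor": lor,
                "awtaaa_wt": wt_count_cache[site_idx],
                "awtaaa_mut": mut_count,
                "category": classify(lor, wt_count_cache[site_idx], mut_count),
            }
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, qc.as_dict()


def dedupe_and_resolve(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse to one record per unique variant, keeping the strongest effect.

    One row per unique (chrom, pos, ref, alt, cohort).  Among the multiple
    (variant, site) pairs of a variant near several cleavage sites, the
    pair with maximal |LOR| wins; ties break by smaller |offset|, then by
    lexicographic site_id.  Output is independent of input row order.

    Recurrence columns (cancer cohort only):

    * ``mut_recurrence``   — number of tumours carrying this exact variant
    * ``signal_recurrence`` — number of tumours in which the retained site
      is hit by *any* DOWN variant
    """
    if records.empty:
        out = records.copy()
        out["mut_recurrence"] = pd.Series(dtype="Int64")
        out["signal_recurrence"] = pd.Series(dtype="Int64")
        return out

    df = records.copy()
    key = ["chrom", "pos", "ref", "alt", "cohort"]

    cancer = df[df["cohort"] == "cancer"]
    mut_rec = (
        cancer.groupby(key[:4])["sample_id"].nunique()
        if not cancer.empty
        else pd.Series(dtype=int)
    )
    down = cancer[cancer["category"] == "DOWN"]
    sig_rec = (
        down.groupby("site_id")["sample_id"].nunique()
        if not down.empty
        else pd.Series(dtype=int)
    )

    # deterministic strongest-effect pick, independent of input order
    df["_abs_lor"] = df["lor"].abs()
    df["_abs_off"] = df["offset"].abs()
    df["_sample"] = df["sample_id"].fillna("")
    df = df.sort_values(
        key + ["_abs_lor", "_abs_off", "site_id", "_sample"],
        ascending=[True] * 5 + [False, True, True, True],
        kind="stable",
    )
    resolved = df.drop_duplicates(subset=key, keep="first").drop(
        columns=["_abs_lor", "_abs_off", "_sample"]
    )

    def _mut_rec(row):
        if row["cohort"] != "cancer":
            return pd.NA
        return int(mut_rec.get((row["chrom"], row["pos"], row["ref"], row["alt"]), 0))

    def _sig_rec(row):
        if row["cohort"] != "cancer":
            return pd.NA
        return int(sig_rec.get(row["site_id"], 0))

    resolved = resolved.copy()
    resolved["mut_recurrence"] = resolved.apply(_mut_rec, axis=1).astype("Int64")
    resolved["signal_recurrence"] = resolved.apply(_sig_rec, axis=1).astype("Int64")
    return resolved.sort_values(key, kind="stable").reset_index(drop=True)


def positional_profile(records: pd.DataFrame, flank: int = WINDOW_FLANK) -> pd.DataFrame:
    """Per-offset, per-category LOR summary (mean, SEM, counts).

    Offsets run from -flank to +flank relative to the cleavage site.  Cells
    with no records report NaN means; SEM is NaN below two records.  The
    ``n_awtaaa_affecting`` column counts records whose mutation changes the
    AWTAAA hexamer count at that offset.
    """
    offsets = np.arange(-flank, flank + 1)
    categories = ["UP", "DOWN", "BG"]
    frames = []
    for cat in categories:
        sub = records[records["category"] == cat]
        grouped = sub.groupby("offset")["lor"]
        n = grouped.size().reindex(offsets, fill_value=0)
        mean = grouped.mean().reindex(offsets)
        sem = grouped.sem(ddof=1).reindex(offsets)
        sem[n < 2] = np.nan
        affecting = (
            sub[sub["awtaaa_wt"] != sub["awtaaa_mut"]]
            .groupby("offset")
            .size()
            .reindex(offsets, fill_value=0)
        )
        frames.append(
            pd.DataFrame(
                {
                    "offset": offsets,
                    "category": cat,
                    "n": n.to_numpy(),
                    "mean_lor": mean.to_numpy(),
                    "sem_lor": sem.to_numpy(),
                    "n_awtaaa_affecting": affecting.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def annotate_awtaaa_3utr(
    variants: pd.DataFrame,
    utr_intervals: pd.DataFrame,
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    scorer: Scorer,
    flank: int = WINDOW_FLANK,
    annotated_half_width: int = 50,
) -> pd.DataFrame:
    """Score AWTAAA-disrupting SNVs in 3'UTRs on variant-centred windows.

    Unlike the main pipeline, windows here are centred on the SNV itself.
    Each AWTAAA-disrupting SNV with LOR <= -1 is flagged ``annotated`` when
    it lies within *annotated_half_width* nt of an annotated cleavage site
    (a 2*annotated_half_width-nt interval centred on the CS).

    ``utr_intervals`` columns: chrom, start, end (1-based inclusive),
    strand, gene_id.
    """
    cs_by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(group["cs_pos"].to_numpy())
        for chrom, group in sites.groupby("chrom", sort=False)
    }
    rows = []
    for _, vrow in variants.iterrows():
        variant = W.variant_from_row(vrow)
        hits = utr_intervals[
            (utr_intervals["chrom"] == variant.chrom)
            & (utr_intervals["start"] <= variant.pos)
            & (utr_intervals["end"] >= variant.pos)
        ]
        if hits.empty:
            continue
        strand = str(hits.iloc[0]["strand"])
        pseudo = W.CleavageSite(
            site_id=f"snv:{variant.chrom}:{variant.pos}",
            gene_id=str(hits.iloc[0]["gene_id"]),
            chrom=variant.chrom,
            strand=strand,
            cs_pos=variant.pos,
        )
        try:
            win = W.extract_window(genome, pseudo, flank=flank)
            mut_win = W.apply_variant(win, variant, pseudo, flank=flank)
        except W.WindowError as exc:
            logger.warning("annotate_awtaaa_3utr: %s", exc)
            continue
        n_wt = count_awtaaa(win.sequence)
        n_mut = count_awtaaa(mut_win.sequence)
        if n_mut >= n_wt:
            continue  # only AWTAAA-disrupting SNVs enter this table
        lor = compute_lor(scorer.score(win.sequence), scorer.score(mut_win.sequence))
        cs = cs_by_chrom.get(variant.chrom, np.empty(0, dtype=int))
        dist = int(np.abs(cs - variant.pos).min()) if cs.size else np.inf
        rows.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "cohort": variant.cohort,
                "gene_id": pseudo.gene_id,
                "lor": lor,
                "cs_distance": dist if np.isfinite(dist) else pd.NA,
                "annotated": bool(dist <= annotated_half_width and lor <= LOR_DOWN),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "cohort", "gene_id", "lor",
            "cs_distance", "annotated",
        ],
    )
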