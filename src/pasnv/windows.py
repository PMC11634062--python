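"""Scoring-window construction around annotated cleavage sites.

Annotated 3'UTR cleavage sites are extended by a fixed flank (102 nt by
default) on both sides to form 205-nt scoring windows.  Windows are always
reported in *sense* orientation: for minus-strand sites the plus-strand
genomic slice is reverse-complemented, so that offset 0 is the cleavage
site and negative offsets are upstream in pre-mRNA coordinates.

All genomic coordinates are 1-based inclusive.  VCF variant records stay
in plus-strand convention; ref/alt complementation for minus-strand sites
happens inside :func:`apply_variant`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .scoring import WINDOW_FLANK

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive genomic interval."""
    return end - start + 1


class WindowError(ValueError):
    """Base class for record-level window construction failures."""


class WindowOutOfBounds(WindowError):
    """The flanked interval does not fit inside the contig."""


class RefMismatch(WindowError):
    """The window base at the variant offset does not match the VCF ref."""


@dataclass(frozen=True)
class CleavageSite:
    """One annotated 3'UTR pre-mRNA cleavage position."""

    site_id: str
    gene_id: str
    chrom: str
    strand: str
    cs_pos: int  # 1-based genomic coordinate of the cleavage site
    region: str = "3UTR"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-'; got {self.strand!r}")
        if self.cs_pos < 1:
            raise ValueError("cs_pos must be a positive 1-based coordinate")


@dataclass(frozen=True)
class Window:
    """Sense-strand scoring window with the cleavage site at offset 0."""

    site_id: str
    sequence: str
    flank: int = WINDOW_FLANK

    def __post_init__(self):
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.sequence)} != {2 * self.flank + 1}"
            )

    def base_at(self, offset: int) -> str:
        return self.sequence[offset + self.flank]

    def with_base(self, offset: int, base: str) -> "Window":
        idx = offset + self.flank
        seq = self.sequence[:idx] + base + self.sequence[idx + 1:]
        return replace(self, sequence=seq)


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution in plus-strand VCF convention."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    cohort: str = "normal"
    ac: int | None = None
    af: float | None = None
    sample_id: str | None = None
    tumour_type: str | None = None

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide substitutions are supported")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass
class QCCounters:
    """Per-run counts of mapped / excluded records, mirroring input QC."""

    n_variants: int = 0
    n_pairs: int = 0
    n_multi_mapped: int = 0
    n_ref_mismatch: int = 0
    n_out_of_bounds: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def extract_window(
    genome: Mapping[str, str], site: CleavageSite, flank: int = WINDOW_FLANK
) -> Window:
    """Extract the sense-strand scoring window around a cleavage site.

    Raises :class:`WindowOutOfBounds` when the flanked interval does not fit
    within the contig; callers doing batch work catch this and count the
    site in the QC report rather than aborting the run.
    """
    contig = genome[site.chrom]
    start = site.cs_pos - flank  # 1-based inclusive
    end = site.cs_pos + flank
    if start < 1 or end > len(contig):
        raise WindowOutOfBounds(
            f"site {site.site_id}: interval [{start}, {end}] outside contig "
            f"{site.chrom} (length {len(contig)})"
        )
    seq = str(contig[start - 1 : end]).upper()
    if site.strand == "-":
        seq = revcomp(seq)
    return Window(site_id=site.site_id, sequence=seq, flank=flank)


def variant_offset(site: CleavageSite, pos: int) -> int:
    """Sense-strand offset of a plus-strand genomic position from the CS."""
    return pos - site.cs_pos if site.strand == "+" else site.cs_pos - pos


def apply_variant(
    window: Window, variant: Variant, site: CleavageSite, flank: int | None = None
) -> Window:
    """Substitute a variant into its sense-strand window.

    VCF records are plus-strand; for minus-strand sites both ref and alt
    are complemented before the substitution.  A mismatch between the
    window base and the (strand-converted) ref raises :class:`RefMismatch`;
    batch callers exclude the record and count it.
    """
    flank = window.flank if flank is None else flank
    offset = variant_offset(site, variant.pos)
    if abs(offset) > flank:
        raise WindowError(
            f"variant {variant.chrom}:{variant.pos} outside window of {site.site_id}"
        )
    if site.strand == "+":
        ref, alt = variant.ref, variant.alt
    else:
        ref, alt = revcomp(variant.ref), revcomp(variant.alt)
    found = window.base_at(offset)
    if found != ref:
        raise RefMismatch(
            f"variant {variant.chrom}:{variant.pos} ref {variant.ref} (sense {ref}) "
            f"!= window base {found} at offset {offset} of {site.site_id}"
        )
    return window.with_base(offset, alt)


def map_variants_to_sites(
    variants: pd.DataFrame, sites: pd.DataFrame, flank: int = WINDOW_FLANK
) -> pd.DataFrame:
    """Join variants to every cleavage-site window containing them.

    A variant lying within the flanked interval of two sites yields two
    rows at this stage; the strongest-effect rule resolves the ambiguity
    after scoring.  Returns a DataFrame with a ``variant_idx`` column
    (index into *variants*) and the matching site columns.
    """
    pairs: list[tuple[int, int]] = []
    for chrom, site_group in sites.groupby("chrom", sort=False):
        vmask = variants["chrom"] == chrom
        if not vmask.any():
            continue
        cs = site_group["cs_pos"].to_numpy()
        order = np.argsort(cs, kind="stable")
        cs_sorted = cs[order]
        site_rows = site_group.index.to_numpy()[order]
        vpos = variants.loc[vmask, "pos"].to_numpy()
        vidx = variants.index[vmask].to_numpy()
        lo = np.searchsorted(cs_sorted, vpos - flank, side="left")
        hi = np.searchsorted(cs_sorted, vpos + flank, side="right")
        for v, a, b in zip(vidx, lo, hi):
            for s in site_rows[a:b]:
                pairs.append((v, s))
    if not pairs:
        return pd.DataFrame(columns=["variant_idx", "site_idx"])
    out = pd.DataFrame(pairs, columns=["variant_idx", "site_idx"])
    return out.sort_values(["variant_idx", "site_idx"], kind="stable").reset_index(
        drop=True
    )


def sites_from_frame(sites: pd.DataFrame) -> dict[int, CleavageSite]:
    """Materialise :class:`CleavageSite` objects keyed by DataFrame index."""
    out = {}
    for idx, row in sites.iterrows():
        out[idx] = CleavageSite(
            site_id=str(row["site_id"]),
            gene_id=str(row["gene_id"]),
            chrom=str(row["chrom"]),
            strand=str(row["strand"]),
            cs_pos=int(row["cs_pos"]),
            region=str(row.get("region", "3UTR")),
        )
    return out


def variant_from_row(row: pd.Series) -> Variant:
    def _opt(key):
        val = row.get(key)
        return None if val is None or (isinstance(val, float) and np.isnan(val)) else val

    ac = _opt("ac")
    af = _opt("af")
    return Variant(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        cohort=str(row.get("cohort", "normal")),
        ac=None if ac is None else int(ac),
        af=None if af is None else float(af),
        sample_id=None if _opt("sample_id") is None else str(row["sample_id"]),
        tumour_type=None if _opt("tumour_type") is None else str(row["tumour_type"]),
    )
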