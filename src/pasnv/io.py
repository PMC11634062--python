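"""Readers and writers for the pipeline's on-disk formats.

Genomes are FASTA, variant cohorts are VCF (allele counts in INFO for the
population cohort; sample and tumour-type labels in INFO for the somatic
cohort), and everything else is tab-separated.  Site annotations may also
be supplied as BED, whose 0-based half-open coordinates are converted to
the 1-based inclusive convention used internally at the reader boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam
from pyfaidx import Fasta

SITE_COLUMNS = ["site_id", "chrom", "strand", "cs_pos", "gene_id", "region"]


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into an in-memory contig -> sequence mapping."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated cleavage-site table, keeping 3'UTR sites only."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SITE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if "region" not in df.columns:
        df["region"] = "3UTR"
    df = df[df["region"] == "3UTR"].reset_index(drop=True)
    df["cs_pos"] = df["cs_pos"].astype(int)
    return df


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    sites[cols].to_csv(path, sep="\t", index=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    """Read cleavage sites from BED (0-based half-open; single-base features).

    The BED name field is ``site_id|gene_id``; the cleavage position is the
    feature's single base, converted to 1-based inclusive (cs_pos = start + 1).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            site_id, _, gene_id = name.partition("|")
            rows.append(
                {
                    "site_id": site_id,
                    "chrom": chrom,
                    "strand": strand,
                    "cs_pos": int(start) + 1,
                    "gene_id": gene_id or site_id,
                    "region": "3UTR",
                }
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def _vcf_header(genome_lengths: Mapping[str, int] | None, cohort: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    if genome_lengths:
        for name, length in genome_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    if cohort == "normal":
        lines.append('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">')
        lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    else:
        lines.append('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumour sample">')
        lines.append('##INFO=<ID=TTYPE,Number=1,Type=String,Description="Tumour type">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_vcf(
    variants: pd.DataFrame,
    path: str | Path,
    cohort: str,
    genome: Mapping[str, str] | None = None,
) -> None:
    """Write a cohort variant table as an uncompressed VCF."""
    lengths = {name: len(seq) for name, seq in genome.items()} if genome else None
    df = variants.sort_values(["chrom", "pos", "ref", "alt"], kind="stable")
    with open(path, "w") as fh:
        fh.write(_vcf_header(lengths, cohort))
        for _, row in df.iterrows():
            if cohort == "normal":
                info = f"AC={int(row['ac'])};AF={row['af']:.6g}"
            else:
                info = f"SAMPLE={row['sample_id']};TTYPE={row['tumour_type']}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path, cohort: str) -> pd.DataFrame:
    """Read a cohort VCF into the internal variant table.

    Multi-allelic records are split into bi-allelic rows, each inheriting
    its own per-allele AC; symbolic or multi-base alleles are skipped.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref
            if ref is None or len(ref) != 1:
                continue
            alts = rec.alts or ()
            info = rec.info
            acs = info.get("AC") if "AC" in info else None
            for i, alt in enumerate(alts):
                if alt is None or len(alt) != 1 or alt == ref:
                    continue
                row = {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "cohort": cohort,
                }
                if cohort == "normal":
                    ac = acs[i] if acs is not None else None
                    row["ac"] = None if ac is None else int(ac)
                    afs = info.get("AF") if "AF" in info else None
                    row["af"] = float(afs[i]) if afs is not None else None
                else:
                    row["sample_id"] = info.get("SAMPLE")
                    row["tumour_type"] = info.get("TTYPE")
                rows.append(row)
    return pd.DataFrame(rows)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample tab-separated matrix (genes as the index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_conservation(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a (chrom, pos, score) conservation track into a lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (c, int(p)): float(s)
        for c, p, s in zip(df["chrom"], df["pos"], df["score"])
    }


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
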