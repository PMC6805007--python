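"""Table/format readers and writers plus packaged fixtures.

TSV tables are schema-validated on load (missing columns and malformed
numbers are reported with row context).  Variant sites are read from
standard VCF through cyvcf2; mask intervals are BED (0-based half-open);
sequences go through Biopython.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "load_tables",
    "read_pedigree_table",
    "read_family_table",
    "read_sites_vcf",
    "read_bed",
    "read_fasta",
    "write_fasta",
    "write_sites_vcf",
    "write_run_summary",
    "table2_families",
    "threegen_pedigree",
]

PEDIGREE_SCHEMA = {
    "individual_id": str,
    "family_id": str,
    "mother_id": str,
    "father_id": str,
    "sex": str,
    "y_marker": str,
    "wolbachia": str,
    "qpcr_ratio": float,
}

FAMILY_SCHEMA = {
    "progeny_id": str,
    "mother_genotype": str,
    "father_genotype": str,
    "progeny_size": int,
    "n_females": int,
    "males_tested": int,
    "males_infected": int,
    "females_tested": int,
    "females_infected": int,
}


def load_tables(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Load a TSV and validate it against a column schema.

    Missing required columns raise a schema error naming them; numeric
    columns that fail to parse raise a row-level error with the offending
    line.  Optional float columns may be empty (NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns: {sorted(missing)}")
    out = {}
    for col, typ in schema.items():
        raw = df[col]
        if typ is str:
            out[col] = raw
        else:
            vals = []
            for i, v in enumerate(raw):
                if v == "" or v.upper() in ("NA", "NAN"):
                    if typ is float:
                        vals.append(np.nan)
                        continue
                    raise ValueError(f"{path.name} row {i + 2}: empty value in column {col!r}")
                try:
                    vals.append(typ(v))
                except ValueError as e:
                    raise ValueError(
                        f"{path.name} row {i + 2}, column {col!r}: malformed value {v!r}"
                    ) from e
            out[col] = vals
    return pd.DataFrame(out)


def read_pedigree_table(path: str | Path) -> pd.DataFrame:
    df = load_tables(path, PEDIGREE_SCHEMA)
    for col in ("mother_id", "father_id"):
        df[col] = df[col].replace("", None)
    return df


def read_family_table(path: str | Path) -> pd.DataFrame:
    return load_tables(path, FAMILY_SCHEMA)


def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    """Read variant sites into a table (chrom, pos 1-based, ref, alt, het).

    Records without genotype information are treated as heterozygous; with a
    genotyped sample, heterozygosity comes from the first sample's call.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        alt = v.ALT[0] if v.ALT else ""
        if has_samples:
            het = bool(v.gt_types[0] == 1)
        else:
            het = True
        rows.append(dict(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt, het=het))
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "het"])


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_sites_vcf(variants: pd.DataFrame, path: str | Path,
                    contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal sites-only VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for cid, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={cid},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t.\n")


def write_run_summary(path: str | Path, subcommand: str, params: dict,
                      headline: dict) -> None:
    from . import __version__

    payload = dict(subcommand=subcommand, version=__version__,
                   params=params, results=headline)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _fixture(name: str) -> Path:
    return Path(str(resources.files("wolbsex").joinpath("data", name)))


def table2_families() -> pd.DataFrame:
    """Packaged family summary table: 20 isopod families (mother and father
    genotype, progeny composition and infection testing counts)."""
    return read_family_table(_fixture("table2_families.tsv"))


def threegen_pedigree() -> pd.DataFrame:
    """Packaged three-generation laboratory pedigree with Y-marker PCR,
    infection status and qPCR dose ratios."""
    return read_pedigree_table(_fixture("pedigree_threegen.tsv"))
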