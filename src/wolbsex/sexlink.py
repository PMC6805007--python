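"""Detection of Y-specific contigs from male/female sequencing data.

Two complementary per-contig scores identify Y-specific sequence in a male
(XY) genome assembly:

* **CQ** (chromosome quotient): the ratio of female to male normalized
  sequencing depth.  Y-specific contigs receive no female coverage (CQ ~ 0),
  autosomal contigs equal coverage (CQ ~ 1), X-specific contigs twice the
  female coverage (CQ ~ 2).
* **YGS** (Y-chromosome genome scan): the percentage of a contig's
  single-copy k-mers (k-mers occurring exactly once in the whole assembly,
  canonical form) that are absent from the female read set.  Y-specific
  contigs approach 100%, autosomal and X-linked contigs 0%.

Candidates are contigs passing both thresholds (defaults CQ <= 0.35 and
YGS >= 35%).  Depth is measured by exact canonical k-mer matching rather
than read alignment, which is deterministic and library-free; externally
computed depth tables can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rank_stats import RankTestResult, mann_whitney_u

__all__ = [
    "KmerSet",
    "count_kmers",
    "canonical_kmers",
    "depth_table",
    "cq_scores",
    "ygs_scores",
    "call_candidates",
    "snp_density",
    "group_compare",
    "DEFAULT_CQ_MAX",
    "DEFAULT_YGS_MIN",
]

DEFAULT_CQ_MAX = 0.35
DEFAULT_YGS_MIN = 35.0

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward and reverse-complement) k-mers of ``seq`` as
    uint64 codes; windows containing ambiguous bases are dropped."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    codes = _encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (codes == 255).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    valid = (csum[k:] - csum[:-k]) == 0
    safe = np.where(codes == 255, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd |= safe[i : i + n] << np.uint64(2 * (k - 1 - i))
        rev |= (np.uint64(3) - safe[i : i + n]) << np.uint64(2 * i)
    out = np.minimum(fwd, rev)[valid]
    return out


@dataclass(frozen=True)
class KmerSet:
    """Sorted canonical k-mers with counts."""

    k: int
    kmers: np.ndarray  # sorted uint64
    counts: np.ndarray  # same length, >= 1
    source: str = ""

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        """Count of each query k-mer in this set (0 when absent)."""
        idx = np.searchsorted(self.kmers, queries)
        idx_c = np.clip(idx, 0, self.kmers.size - 1) if self.kmers.size else idx
        if self.kmers.size == 0:
            return np.zeros(queries.size, dtype=np.int64)
        hit = self.kmers[idx_c] == queries
        out = np.where(hit, self.counts[idx_c], 0)
        return out

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def count_kmers(seqs: Iterable[str], k: int, source: str = "") -> KmerSet:
    """Count canonical k-mers over a collection of sequences.

    Sequences are joined with an ambiguous separator so no window spans two
    inputs; one vectorized pass encodes everything.
    """
    joined = "N".join(seqs)
    km = canonical_kmers(joined, k)
    if km.size == 0:
        return KmerSet(k=k, kmers=np.empty(0, np.uint64), counts=np.empty(0, np.int64), source=source)
    uniq, counts = np.unique(km, return_counts=True)
    return KmerSet(k=k, kmers=uniq, counts=counts.astype(np.int64), source=source)


def depth_table(
    contigs: Mapping[str, str],
    male_reads: Sequence[str],
    female_reads: Sequence[str],
    k: int = 21,
) -> pd.DataFrame:
    """Per-contig male/female k-mer depths, normalized by library size.

    Depth of a contig is the mean, over its k-mer positions, of the number of
    occurrences of that k-mer in the read set, scaled to matches per million
    read bases so libraries of unequal size are comparable.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    if not male_reads or not female_reads:
        raise ValueError("empty read set")
    male_set = count_kmers(male_reads, k, source="male_reads")
    female_set = count_kmers(female_reads, k, source="female_reads")
    male_bases = sum(len(r) for r in male_reads)
    female_bases = sum(len(r) for r in female_reads)
    rows = []
    for cid, seq in contigs.items():
        km = canonical_kmers(seq, k)
        if km.size == 0:
            rows.append(dict(contig_id=cid, length=len(seq), male_depth=np.nan,
                             female_depth=np.nan, n_kmers=0))
            continue
        m = male_set.lookup(km).mean() * 1e6 / male_bases
        f = female_set.lookup(km).mean() * 1e6 / female_bases
        rows.append(dict(contig_id=cid, length=len(seq), male_depth=m,
                         female_depth=f, n_kmers=int(km.size)))
    return pd.DataFrame(rows)


def cq_scores(depths: pd.DataFrame, male_floor_frac: float = 0.1) -> pd.DataFrame:
    """CQ = female_depth / male_depth per contig.

    Contigs whose male depth is below ``male_floor_frac`` times the
    genome-wide median male depth get an undefined CQ (NaN) and are excluded
    from candidate calling; this avoids ratio blow-ups on barely covered
    contigs.
    """
    out = depths.copy()
    med = np.nanmedian(out["male_depth"].to_numpy(dtype=float))
    floor = male_floor_frac * med if np.isfinite(med) else 0.0
    male = out["male_depth"].to_numpy(dtype=float)
    female = out["female_depth"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cq = female / male
    cq = np.where((male <= 0) | (male < floor) | ~np.isfinite(cq), np.nan, cq)
    out["cq"] = cq
    return out


def ygs_scores(
    contigs: Mapping[str, str],
    assembly_kmers: KmerSet,
    female_kmers: KmerSet,
    min_count: int = 2,
) -> pd.DataFrame:
    """YGS percentage per contig.

    A contig k-mer is *single-copy* when it occurs exactly once in the whole
    assembly (canonical counting); it is *matched* when present in the female
    read set with count >= ``min_count`` (absorbing sequencing errors).
    YGS = 100 * unmatched single-copy k-mers / single-copy k-mers.
    """
    if assembly_kmers.k != female_kmers.k:
        raise ValueError("k-mer sizes differ between assembly and female sets")
    rows = []
    for cid, seq in contigs.items():
        km = np.unique(canonical_kmers(seq, assembly_kmers.k))
        if km.size == 0:
            rows.append(dict(contig_id=cid, ygs=np.nan, n_single_copy=0))
            continue
        single = km[assembly_kmers.lookup(km) == 1]
        if single.size == 0:
            rows.append(dict(contig_id=cid, ygs=np.nan, n_single_copy=0))
            continue
        matched = female_kmers.lookup(single) >= min_count
        ygs = 100.0 * float(np.mean(~matched))
        rows.append(dict(contig_id=cid, ygs=ygs, n_single_copy=int(single.size)))
    return pd.DataFrame(rows)


def call_candidates(
    records: pd.DataFrame,
    cq_max: float = DEFAULT_CQ_MAX,
    ygs_min: float = DEFAULT_YGS_MIN,
) -> pd.DataFrame:
    """Flag Y-specific candidates: CQ <= cq_max AND YGS >= ygs_min.

    Contigs with undefined CQ or YGS are never candidates.
    """
    out = records.copy()
    cq = out["cq"].to_numpy(dtype=float)
    ygs = out["ygs"].to_numpy(dtype=float)
    out["candidate"] = np.isfinite(cq) & np.isfinite(ygs) & (cq <= cq_max) & (ygs >= ygs_min)
    return out


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def snp_density(
    variants: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Heterozygous SNPs per kb of unmasked sequence, per contig.

    ``variants`` needs columns chrom, pos (1-based), ref, alt and optionally
    ``het`` (missing genotype information is treated as heterozygous).  Only
    biallelic single-nucleotide records count.  ``mask`` is a BED-style table
    (chrom, start, end; 0-based half-open) of regions excluded from both the
    SNP count and the length denominator.  A fully masked contig has
    undefined (NaN) density.
    """
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    unknown = set(variants["chrom"]) - set(contig_lengths)
    if unknown:
        bad = variants[variants["chrom"].isin(unknown)]
        raise ValueError(
            f"variants on unknown contigs: {sorted(unknown)} "
            f"({len(bad)} offending records)"
        )
    het = variants["het"] if "het" in variants.columns else pd.Series(True, index=variants.index)
    is_snp = (
        het.astype(bool)
        & (variants["ref"].str.len() == 1)
        & (variants["alt"].str.len() == 1)
        & ~variants["alt"].str.contains(",")
    )
    snps = variants[is_snp]
    mask_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if mask is not None and len(mask):
        for chrom, sub in mask.groupby("chrom"):
            mask_by_chrom[chrom] = _merge_intervals(
                sub["start"].to_numpy(int), sub["end"].to_numpy(int)
            )
    rows = []
    for cid, length in contig_lengths.items():
        sub = snps[snps["chrom"] == cid]
        pos0 = sub["pos"].to_numpy(int) - 1  # to 0-based
        if cid in mask_by_chrom:
            ms, me = mask_by_chrom[cid]
            masked_len = int(np.sum(np.minimum(me, length) - np.minimum(ms, length)))
            idx = np.searchsorted(ms, pos0, side="right") - 1
            in_mask = (idx >= 0) & (pos0 < me[np.clip(idx, 0, len(me) - 1)])
            n_snp = int(np.sum(~in_mask))
        else:
            masked_len = 0
            n_snp = len(pos0)
        unmasked = length - masked_len
        density = (n_snp / unmasked * 1000.0) if unmasked > 0 else np.nan
        rows.append(dict(contig_id=cid, length=length, unmasked_length=unmasked,
                         n_het_snps=n_snp, snp_density=density))
    return pd.DataFrame(rows)


def group_compare(
    values: pd.Series | Sequence[float],
    in_group: Sequence[bool],
) -> dict:
    """Compare a focal contig group against the rest: per-group medians and a
    two-sided Mann-Whitney U test (both orientations reported)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(in_group, dtype=bool)
    if g.sum() < 1 or (~g).sum() < 1:
        raise ValueError("both groups need at least one member")
    a, b = v[g], v[~g]
    res: RankTestResult = mann_whitney_u(a, b)
    return dict(
        median_group=float(np.median(a)),
        median_rest=float(np.median(b)),
        n_group=int(a.size),
        n_rest=int(b.size),
        u1=res.u1,
        u2=res.u2,
        u_min=res.u_min,
        p_two_sided=res.p_two_sided,
        result=res,
    )
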