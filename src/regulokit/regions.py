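"""Candidate-region selection and regulatory-window construction.

Accessible peaks are restricted to the sequence supported by prior regulatory
evidence: the clip-to-overlap intersection with conserved elements (minus any
exonic base) unioned with the intersection with an external cCRE catalogue.
Interval algebra runs on pyranges; the result is verified elsewhere against a
per-base boolean-mask oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .core_io import GeneAnnotation, RegionSet

PROVENANCE = ("conserved", "cCRE", "both")


@dataclass
class CandidateRegions:
    """Candidate regions with a provenance flag per row.

    ``df`` carries the RegionSet columns plus ``provenance`` in
    {"conserved", "cCRE", "both"}.
    """

    df: pd.DataFrame

    @property
    def region_set(self) -> RegionSet:
        return RegionSet(self.df[["chrom", "start", "end", "region_id"]])

    def __len__(self) -> int:
        return len(self.df)


def _to_pr(rs: RegionSet) -> pr.PyRanges:
    df = rs.df
    return pr.PyRanges(
        pd.DataFrame(
            {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
        )
    )


def _pr_df(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df
    if df.empty:
        return pd.DataFrame({"Chromosome": [], "Start": [], "End": []})
    return df.sort_values(["Chromosome", "Start", "End"]).reset_index(drop=True)


def _merged(rs: RegionSet) -> pr.PyRanges:
    g = _to_pr(rs)
    return g.merge() if len(g) else g


def _overlaps_any(df: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per row of ``df``: overlaps any interval of ``other`` by >= 1 bp."""
    out = np.zeros(len(df), dtype=bool)
    by_chrom = {str(c): g for c, g in other.groupby("Chromosome", observed=True)}
    for i, row in enumerate(df.itertuples(index=False)):
        g = by_chrom.get(str(row.Chromosome))
        if g is None:
            continue
        out[i] = bool(((g["Start"] < row.End) & (g["End"] > row.Start)).any())
    return out


def filter_peaks_by_width(
    peaks: RegionSet, min_bp: int = 21, max_bp: int = 9999
) -> RegionSet:
    """Retain peaks with min_bp <= width <= max_bp, preserving input order.

    The defaults implement the strict bounds "> 20 bp" and "< 10,000 bp".
    """
    w = peaks.widths()
    keep = (w >= min_bp) & (w <= max_bp)
    if len(peaks) == 0:
        return RegionSet.empty()
    kept = peaks.df.loc[keep]
    return RegionSet(kept) if len(kept) else RegionSet.empty()


def select_candidate_regions(
    peaks: RegionSet,
    conserved: RegionSet,
    exons: RegionSet,
    ccres: RegionSet,
) -> CandidateRegions:
    """Clip peaks to conserved (non-exonic) and cCRE evidence and take the union.

    A = (peaks ∩ conserved) with exon-overlapping bases subtracted (intervals may
    split); B = peaks ∩ cCREs.  The result is the merged interval union of A and
    B; each merged row is flagged by which branch(es) contributed sequence.
    """
    peaks_m = _merged(peaks)
    if len(peaks) == 0:
        return CandidateRegions(_flagged_frame(pd.DataFrame(), pd.DataFrame(), pd.DataFrame()))

    a = peaks_m.intersect(_merged(conserved)) if len(conserved) else pr.PyRanges()
    if len(a) and len(exons):
        a = a.subtract(_merged(exons))
    b = peaks_m.intersect(_merged(ccres)) if len(ccres) else pr.PyRanges()

    a_df, b_df = _pr_df(a), _pr_df(b)
    parts = [d for d in (a_df, b_df) if not d.empty]
    if not parts:
        return CandidateRegions(_flagged_frame(pd.DataFrame(), a_df, b_df))
    union = pd.concat(parts, ignore_index=True)
    merged = _pr_df(pr.PyRanges(union).merge())
    return CandidateRegions(_flagged_frame(merged, a_df, b_df))


def _flagged_frame(
    merged: pd.DataFrame, a_df: pd.DataFrame, b_df: pd.DataFrame
) -> pd.DataFrame:
    if merged.empty:
        return pd.DataFrame(
            {
                "chrom": pd.Series([], dtype=str),
                "start": pd.Series([], dtype=np.int64),
                "end": pd.Series([], dtype=np.int64),
                "region_id": pd.Series([], dtype=str),
                "provenance": pd.Series([], dtype=str),
            }
        )
    from_a = _overlaps_any(merged, a_df)
    from_b = _overlaps_any(merged, b_df)
    flags = np.where(from_a & from_b, "both", np.where(from_a, "conserved", "cCRE"))
    return pd.DataFrame(
        {
            "chrom": merged["Chromosome"].astype(str),
            "start": merged["Start"].astype(np.int64),
            "end": merged["End"].astype(np.int64),
            "region_id": [
                f"{c}:{s}-{e}"
                for c, s, e in zip(merged["Chromosome"], merged["Start"], merged["End"])
            ],
            "provenance": flags,
        }
    )


def regulatory_window(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    upstream_bp: int = 100_000,
) -> tuple[str, int, int]:
    """The gene body extended ``upstream_bp`` upstream of the TSS (strand-aware).

    Plus strand: [max(0, start - upstream_bp), end); minus strand:
    [start, end + upstream_bp).  Chromosome-end overflow is not clipped here;
    sequence lookups clamp later.
    """
    if strand == "+":
        return chrom, max(0, start - upstream_bp), end
    return chrom, start, end + upstream_bp


def regulatory_windows(
    genes: GeneAnnotation, upstream_bp: int = 100_000
) -> pd.DataFrame:
    """Per-gene regulatory windows as a (gene_id, chrom, start, end) frame."""
    rows = [
        (g.gene_id, *regulatory_window(g.gene_id, g.chrom, g.start, g.end, g.strand, upstream_bp))
        for g in genes.df.itertuples(index=False)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def assign_regions_to_genes(
    candidates: CandidateRegions | RegionSet,
    genes: GeneAnnotation,
    upstream_bp: int = 100_000,
) -> pd.DataFrame:
    """Emit one (gene_id, region_id) pair per >= 1 bp window overlap.

    A region overlapping several genes' windows maps to each of them.
    """
    cdf = candidates.df
    windows = regulatory_windows(genes, upstream_bp)
    pairs = []
    by_chrom = {c: g for c, g in cdf.groupby("chrom")}
    for w in windows.itertuples(index=False):
        g = by_chrom.get(w.chrom)
        if g is None:
            continue
        hit = g.loc[(g["start"] < w.end) & (g["end"] > w.start), "region_id"]
        pairs.extend((w.gene_id, rid) for rid in hit)
    return pd.DataFrame(pairs, columns=["gene_id", "region_id"])
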