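"""Shared data model and readers/writers for the standard formats the toolkit touches.

All genomic coordinates are 0-based, half-open (BED convention) everywhere inside
the package.  GTF import converts 1-based inclusive coordinates at the boundary.
Chromosome names are taken verbatim; cross-file naming mismatches are surfaced as
warnings, never silently "fixed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy.io import mmread, mmwrite
from scipy import sparse

BASES = ("A", "C", "G", "T")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """A set of genomic intervals with unique ids — the currency of region algebra.

    ``df`` holds columns ``chrom`` (str), ``start``/``end`` (int, 0-based
    half-open) and ``region_id`` (str, unique within the set).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = ["chrom", "start", "end", "region_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"RegionSet missing columns: {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["region_id"] = df["region_id"].astype(str)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"region {row.region_id!r}: start {row.start} >= end {row.end}"
            )
        if df["region_id"].duplicated().any():
            dupes = df.loc[df["region_id"].duplicated(), "region_id"].unique()
            raise ValidationError(f"duplicate region ids: {list(dupes)[:5]}")
        self.df = df[required]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]] | Iterable[tuple[str, int, int, str]]
    ) -> "RegionSet":
        rows = []
        for rec in records:
            if len(rec) == 3:
                chrom, start, end = rec
                rid = f"{chrom}:{start}-{end}"
            else:
                chrom, start, end, rid = rec
            rows.append((chrom, int(start), int(end), rid))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series([], dtype=str),
                    "start": pd.Series([], dtype=np.int64),
                    "end": pd.Series([], dtype=np.int64),
                    "region_id": pd.Series([], dtype=str),
                }
            )
        )

    def sorted(self) -> "RegionSet":
        """Canonical ordering by (chrom, start, end)."""
        return RegionSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        )

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.sorted().df.reset_index(drop=True).equals(
            other.sorted().df.reset_index(drop=True)
        )


@dataclass
class GeneAnnotation:
    """Gene bodies: ``df`` with gene_id, chrom, start, end (0-based half-open), strand."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"GeneAnnotation missing columns: {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("gene with start >= end")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValidationError(
                f"invalid strand values: {df.loc[bad_strand, 'strand'].unique()}"
            )
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids")
        self.df = df[required]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PairedMatrix:
    """Aligned expression and accessibility matrices over shared observations.

    ``expression``: genes x observations of log-normalized values, >= 0.
    ``accessibility``: peaks x observations of probabilities in [0, 1].
    ``obs_meta``: per-observation metadata (branch, pseudotime, organoid, ...),
    indexed by observation id in the shared column order.
    """

    expression: pd.DataFrame
    accessibility: pd.DataFrame
    obs_meta: pd.DataFrame

    def __post_init__(self) -> None:
        e, a, m = self.expression, self.accessibility, self.obs_meta
        if not (list(e.columns) == list(a.columns) == list(m.index)):
            raise ValidationError(
                "expression / accessibility / obs_meta observation order differs"
            )
        if (e.to_numpy() < 0).any():
            raise ValidationError("expression contains negative values")
        av = a.to_numpy()
        if (av < 0).any() or (av > 1).any():
            raise ValidationError("accessibility values outside [0, 1]")

    @property
    def n_obs(self) -> int:
        return self.expression.shape[1]


@dataclass
class MotifPFM:
    """A position frequency matrix over (A, C, G, T), rows in that fixed order."""

    motif_id: str
    tf_names: list[str]
    matrix: np.ndarray  # 4 x L, nonnegative counts or frequencies

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValidationError(f"motif {self.motif_id}: matrix must have 4 rows")
        if self.matrix.shape[1] < 4:
            raise ValidationError(f"motif {self.motif_id}: length must be >= 4")
        if (self.matrix < 0).any():
            raise ValidationError(f"motif {self.motif_id}: negative entries")
        if not self.tf_names:
            raise ValidationError(f"motif {self.motif_id}: no TF name")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> RegionSet:
    """Read BED3/BED4 into a RegionSet, coordinates taken verbatim.

    A missing name column is replaced by auto ids ``chrom:start-end``.  Malformed
    lines raise :class:`ParseError` naming the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            rid = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, rid))
    if not rows:
        return RegionSet.empty()
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))


def write_bed(regions: RegionSet, path: str | Path, extra: pd.DataFrame | None = None) -> None:
    """Write a RegionSet as BED4 in canonical (chrom, start, end) order."""
    df = regions.sorted().df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.region_id}\n")


def read_jaspar_pfm(path: str | Path) -> list[MotifPFM]:
    """Read a JASPAR-format PFM file; rows normalized to A, C, G, T order."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            out = []
            for rec in records:
                try:
                    mat = np.array([rec.counts[b] for b in BASES], dtype=float)
                except KeyError as exc:
                    raise ParseError(f"{path}: motif missing base row {exc}") from exc
                tf_names = [rec.name] if rec.name else [rec.matrix_id]
                out.append(MotifPFM(rec.matrix_id or rec.name, tf_names, mat))
        except ParseError:
            raise
        except Exception as exc:  # malformed records surface as ParseError
            raise ParseError(f"{path}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: no motif records found")
    return out


def write_jaspar_pfm(pfms: Sequence[MotifPFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.tf_names[0]}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in pfm.matrix[i])
                fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    """Read genes from a BED6-like TSV: chrom, start, end, gene_id, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    return GeneAnnotation(df[["gene_id", "chrom", "start", "end", "strand"]])


def write_gene_bed(genes: GeneAnnotation, path: str | Path) -> None:
    df = genes.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_gtf_genes(path: str | Path) -> GeneAnnotation:
    """Read ``gene`` features from a GTF subset; 1-based inclusive -> 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: fewer than 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            rows.append(
                (gene_id, fields[0], int(fields[3]) - 1, int(fields[4]), fields[6])
            )
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def load_paired_matrix(
    expr_mtx: str | Path,
    access_mtx: str | Path,
    genes: str | Path,
    peaks: str | Path,
    obs: str | Path,
) -> PairedMatrix:
    """Assemble a PairedMatrix from MatrixMarket matrices plus TSV sidecars.

    ``genes`` / ``peaks`` are one-id-per-line row sidecars; ``obs`` is a TSV whose
    first column holds observation ids (remaining columns become metadata).
    Accessibility values outside [0, 1] are an error, never clipped.
    """
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
    peak_ids = pd.read_csv(peaks, sep="\t", header=None)[0].astype(str).tolist()
    obs_meta = pd.read_csv(obs, sep="\t", index_col=0)
    obs_meta.index = obs_meta.index.astype(str)

    e = np.asarray(mmread(str(expr_mtx)).todense() if sparse.issparse(mmread(str(expr_mtx))) else mmread(str(expr_mtx)))
    a_raw = mmread(str(access_mtx))
    a = np.asarray(a_raw.todense() if sparse.issparse(a_raw) else a_raw)
    if e.shape != (len(gene_ids), len(obs_meta)):
        raise ValidationError(
            f"expression matrix {e.shape} does not match sidecars "
            f"({len(gene_ids)} genes x {len(obs_meta)} obs)"
        )
    if a.shape != (len(peak_ids), len(obs_meta)):
        raise ValidationError(
            f"accessibility matrix {a.shape} does not match sidecars "
            f"({len(peak_ids)} peaks x {len(obs_meta)} obs)"
        )
    return PairedMatrix(
        expression=pd.DataFrame(e, index=gene_ids, columns=obs_meta.index),
        accessibility=pd.DataFrame(a, index=peak_ids, columns=obs_meta.index),
        obs_meta=obs_meta,
    )


def save_paired_matrix(data: PairedMatrix, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / f"{prefix}expression.mtx"), sparse.csr_matrix(data.expression.to_numpy()))
    mmwrite(str(outdir / f"{prefix}accessibility.mtx"), sparse.csr_matrix(data.accessibility.to_numpy()))
    pd.Series(data.expression.index).to_csv(outdir / f"{prefix}genes.tsv", sep="\t", header=False, index=False)
    pd.Series(data.accessibility.index).to_csv(outdir / f"{prefix}peaks.tsv", sep="\t", header=False, index=False)
    data.obs_meta.to_csv(outdir / f"{prefix}obs.tsv", sep="\t")


def check_chrom_naming(*region_sets: RegionSet | GeneAnnotation) -> None:
    """Warn if inputs have disjoint chromosome naming (e.g. 'chr1' vs '1')."""
    sets = [set(rs.df["chrom"].unique()) for rs in region_sets if len(rs.df)]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] and sets[j] and not (sets[i] & sets[j]):
                warnings.warn(
                    "inputs share no chromosome names: "
                    f"{sorted(sets[i])[:3]} vs {sorted(sets[j])[:3]}",
                    stacklevel=2,
                )
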