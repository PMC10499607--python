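"""TF-binding-site prediction in candidate regions and family-similarity motif transfer.

Position frequency matrices are converted to log2-odds scores against a
background model (uniform by default, GC-matched as a config option).  The
score threshold for a given p-value is computed by exact dynamic programming
over the discretized score distribution (0.01-bit bins), so a scan is fully
deterministic and agrees with an exhaustive per-window scorer.

TFs without a known motif inherit motifs from the most similar members of
their family, measured by global Needleman-Wunsch protein alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import BASES, MotifPFM, ValidationError
from .regions import CandidateRegions

UNIFORM_BG = np.full(4, 0.25)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

SITE_COLUMNS = ["region_id", "motif_id", "tf", "strand", "offset", "logodds_score"]


def pfm_to_logodds(
    pfm: MotifPFM,
    background: np.ndarray = UNIFORM_BG,
    pseudocount: float = 0.8,
) -> np.ndarray:
    """log2 odds matrix: column-normalize (counts + pseudocount * background)."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-9:
        raise ValidationError("background must be 4 positive probabilities summing to 1")
    counts = pfm.matrix
    colsum = counts.sum(axis=0) + pseudocount
    if (colsum == 0).any():
        raise ValidationError(
            f"motif {pfm.motif_id}: zero column with zero pseudocount"
        )
    probs = (counts + pseudocount * bg[:, None]) / colsum
    return np.log2(probs / bg[:, None])


def score_threshold(
    logodds: np.ndarray,
    background: np.ndarray = UNIFORM_BG,
    p_threshold: float = 5e-5,
    bin_bits: float = 0.01,
) -> float:
    """Smallest score t with P(score >= t) <= p under the background model.

    Exact DP: each column contributes one of 4 scores with background
    probabilities; scores are discretized to ``bin_bits`` bins and convolved.
    Returns -inf for the vacuous threshold p >= 1.
    """
    if p_threshold >= 1.0:
        return -np.inf
    bg = np.asarray(background, dtype=float)
    q = np.rint(logodds / bin_bits).astype(np.int64)  # 4 x L integer bins
    cur = np.ones(1)  # distribution over the running support [cur_min, ...]
    cur_min = 0
    for col in range(q.shape[1]):
        col_min = q[:, col].min()
        col_max = q[:, col].max()
        new = np.zeros(len(cur) + (col_max - col_min))
        for b in range(4):
            shift = q[b, col] - col_min
            new[shift : shift + len(cur)] += bg[b] * cur
        cur = new
        cur_min += col_min
    # survival function over discretized scores
    sf = np.cumsum(cur[::-1])[::-1]
    ok = np.nonzero(sf <= p_threshold)[0]
    if len(ok) == 0:
        return np.inf  # no attainable score is that rare
    return (cur_min + ok[0]) * bin_bits


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0, C=1, G=2, T=3, other=-1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window of length L on the coded strand; NaN where N present."""
    L = lo.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        idx = win[valid]
        scores[valid] = lo[idx, np.arange(L)].sum(axis=1)
    return scores


def scan_regions(
    candidates: CandidateRegions,
    genome: Mapping[str, str],
    motifs: Sequence[MotifPFM],
    p_threshold: float = 5e-5,
    background: np.ndarray = UNIFORM_BG,
    pseudocount: float = 0.8,
) -> pd.DataFrame:
    """Scan candidate regions for motif hits on both strands.

    Returns a BindingSiteTable frame (region_id, motif_id, tf, strand, offset,
    logodds_score); offsets are region-relative, on the forward strand, for both
    orientations.  Windows containing non-ACGT bases are skipped.  Regions
    extending past their chromosome end are clamped; unknown chromosomes raise.
    """
    rows: list[tuple] = []
    prepped = []
    for pfm in motifs:
        lo = pfm_to_logodds(pfm, background, pseudocount)
        thr = score_threshold(lo, background, p_threshold)
        lo_rc = lo[::-1, ::-1]  # reverse complement: flip bases and positions
        prepped.append((pfm, lo, lo_rc, thr))

    for region in candidates.df.itertuples(index=False):
        if region.chrom not in genome:
            raise ValidationError(f"unknown chromosome {region.chrom!r} in scan")
        chrom_seq = genome[region.chrom]
        start = min(region.start, len(chrom_seq))
        end = min(region.end, len(chrom_seq))
        if end <= start:
            continue
        codes = encode_sequence(chrom_seq[start:end].upper())
        for pfm, lo, lo_rc, thr in prepped:
            for strand, mat in (("+", lo), ("-", lo_rc)):
                scores = _window_scores(codes, mat)
                hits = np.nonzero(~np.isnan(scores) & (scores >= thr))[0]
                for off in hits:
                    for tf in pfm.tf_names:
                        rows.append(
                            (region.region_id, pfm.motif_id, tf, strand,
                             int(off), float(scores[off]))
                        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# Family-similarity motif assignment
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def family_similarity(tf_query_seq: str, tf_other_seq: str) -> float:
    """Global NW alignment identity: identical columns / alignment length."""
    if not tf_query_seq or not tf_other_seq:
        raise ValidationError("empty protein sequence")
    aln = _aligner().align(tf_query_seq.upper(), tf_other_seq.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(s1, s2) if a == b and a != "-")
    return matches / len(s1)


def assign_motifs_by_similarity(
    tf: str,
    tf_seq: str,
    family_members: Mapping[str, tuple[str, Sequence[str]]],
    min_similarity: float = 0.20,
    top_k: int = 3,
) -> pd.DataFrame:
    """Transfer motifs from the ``top_k`` most similar same-family TFs.

    ``family_members`` maps member name -> (protein sequence, motif ids).  Only
    members with identity >= ``min_similarity`` qualify; ties in similarity are
    broken lexicographically by member name.  Returns MotifAssignment rows
    (tf, motif_id, source, similarity); empty when nothing qualifies.
    """
    sims = []
    for name, (seq, motif_ids) in family_members.items():
        if name == tf:
            continue
        sim = family_similarity(tf_seq, seq)
        if sim >= min_similarity:
            sims.append((name, sim, list(motif_ids)))
    sims.sort(key=lambda x: (-x[1], x[0]))
    rows = []
    for name, sim, motif_ids in sims[:top_k]:
        for mid in motif_ids:
            rows.append((tf, mid, "family-inferred", sim))
    return pd.DataFrame(rows, columns=["tf", "motif_id", "source", "similarity"])


def build_motif_assignment(
    direct: Mapping[str, Sequence[str]],
    sequences: Mapping[str, str],
    families: Mapping[str, str],
    min_similarity: float = 0.20,
    top_k: int = 3,
) -> pd.DataFrame:
    """Combine direct motif evidence with family-inferred transfer.

    TFs present in ``direct`` keep their own motifs (source "direct"); the rest
    inherit from same-family members that do have direct motifs.  Deduplication
    keeps the best-ranked row per (tf, motif_id), direct before inferred.
    """
    rows = [
        (tf, mid, "direct", np.nan) for tf, mids in direct.items() for mid in mids
    ]
    out = pd.DataFrame(rows, columns=["tf", "motif_id", "source", "similarity"])
    for tf, seq in sequences.items():
        if tf in direct:
            continue
        fam = families.get(tf)
        members = {
            name: (sequences[name], direct[name])
            for name in direct
            if name in sequences and families.get(name) == fam
        }
        inferred = assign_motifs_by_similarity(tf, seq, members, min_similarity, top_k)
        out = pd.concat([out, inferred], ignore_index=True)
    rank = out["source"].map({"direct": 0, "family-inferred": 1})
    out = (
        out.assign(_rank=rank)
        .sort_values(["tf", "motif_id", "_rank"], kind="mergesort")
        .drop_duplicates(["tf", "motif_id"], keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return out
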