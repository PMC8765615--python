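"""Adjacent-pair enumeration, expression filtering, coverage windows and
Kruskal-Wallis featurization.

The signal exploited here is read-through: two genes transcribed on one mRNA
show similar coverage over the 3' end of the upstream gene, the intergenic
region and the 5' end of the downstream gene, so a k-group rank test across
those three windows stays insignificant, whereas independently transcribed
neighbors show a sharp drop over the intergenic region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    FEATURE_COLUMNS,
    CoverageTrack,
    GeneRecord,
    pair_id,
)

logger = logging.getLogger(__name__)

#: Terminal/central window size in bp.
DEFAULT_WINDOW = 50
#: Mean-coverage expression filter threshold.
DEFAULT_MIN_MEAN = 10.0
#: Floor applied to p-values before the log10 transform.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class AdjacentPair:
    """An ordered adjacent gene pair.

    ``geneA`` is the 5'-most gene in transcription order for same-strand
    pairs (so for a minus-strand pair it is the genomically *right* gene);
    for opposite-strand pairs it is the genomically left gene.
    ``intergenic_length`` is signed: zero or negative when the genes abut or
    overlap.
    """

    geneA: GeneRecord
    geneB: GeneRecord
    intergenic_start: int
    intergenic_end: int
    intergenic_length: int
    strand_match: int

    @property
    def pair_id(self) -> str:
        return pair_id(self.geneA.gene_id, self.geneB.gene_id)

    @property
    def seqid(self) -> str:
        return self.geneA.seqid

    @property
    def left_gene(self) -> GeneRecord:
        return self.geneA if self.geneA.start <= self.geneB.start else self.geneB

    @property
    def right_gene(self) -> GeneRecord:
        return self.geneB if self.geneA.start <= self.geneB.start else self.geneA


@dataclass(frozen=True)
class WindowSample:
    """Depth vectors for the three coverage windows of one pair."""

    covA: np.ndarray
    covI: np.ndarray
    covB: np.ndarray


@dataclass(frozen=True)
class KWResult:
    H: float
    p: float
    k: int
    n: int


def enumerate_adjacent_pairs(
    genes: Sequence[GeneRecord], same_strand_only: bool = False
) -> List[AdjacentPair]:
    """Pair every two consecutive genes on each seqid.

    Genes must be sorted by (seqid, start). Each seqid is treated
    independently: no pair spans a replicon boundary.
    """
    genes = sorted(genes, key=lambda g: (g.seqid, g.start))
    pairs: List[AdjacentPair] = []
    for left, right in zip(genes, genes[1:]):
        if left.seqid != right.seqid:
            continue
        strand_match = int(left.strand == right.strand)
        if same_strand_only and not strand_match:
            continue
        # 5'-most gene in transcription order: for minus/minus pairs
        # transcription runs right-to-left, so the right gene is upstream.
        if strand_match and left.strand == "-":
            geneA, geneB = right, left
        else:
            geneA, geneB = left, right
        ig_len = right.start - left.end - 1
        pairs.append(
            AdjacentPair(
                geneA=geneA,
                geneB=geneB,
                intergenic_start=left.end + 1,
                intergenic_end=right.start - 1,
                intergenic_length=ig_len,
                strand_match=strand_match,
            )
        )
    return pairs


def _gene_mean_depth(gene: GeneRecord, track: CoverageTrack) -> float:
    return float(track.depth(gene.seqid, gene.start, gene.end).mean())


def filter_expressed(
    pairs: Iterable[AdjacentPair],
    track: CoverageTrack,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> List[AdjacentPair]:
    """Keep pairs where at least one gene's full-span mean depth >= min_mean.

    Unexpressed pairs carry no read-through evidence either way and would
    only teach the classifiers to call silence; they are removed up front.
    """
    kept = []
    for pair in pairs:
        if (
            _gene_mean_depth(pair.geneA, track) >= min_mean
            or _gene_mean_depth(pair.geneB, track) >= min_mean
        ):
            kept.append(pair)
    return kept


def _three_prime_window(
    gene: GeneRecord, window: int, offset: int
) -> tuple:
    """1-based inclusive bounds of the window at the gene's 3' end."""
    if gene.strand == "+":
        hi = max(gene.start, gene.end - offset)
        lo = max(gene.start, hi - window + 1)
    else:
        lo = min(gene.end, gene.start + offset)
        hi = min(gene.end, lo + window - 1)
    return lo, hi


def _five_prime_window(gene: GeneRecord, window: int, offset: int) -> tuple:
    if gene.strand == "+":
        lo = min(gene.end, gene.start + offset)
        hi = min(gene.end, lo + window - 1)
    else:
        hi = max(gene.start, gene.end - offset)
        lo = max(gene.start, hi - window + 1)
    return lo, hi


def extract_windows(
    pair: AdjacentPair,
    track: CoverageTrack,
    window: int = DEFAULT_WINDOW,
    offset: int = 0,
) -> WindowSample:
    """Extract the three coverage windows for a pair.

    covA: the ``window`` bases of gene A nearest its 3' end (whole gene if
    shorter); covB: the bases of gene B nearest its 5' end; covI: the central
    ``window`` bases of the intergenic region — the whole region when it is
    shorter, and the single base at the left gene's end when the genes abut
    or overlap. ``offset`` shifts the gene windows away from the intergenic
    region (0 keeps them terminal).
    """
    try:
        a_lo, a_hi = _three_prime_window(pair.geneA, window, offset)
        covA = track.depth(pair.geneA.seqid, a_lo, a_hi)
        b_lo, b_hi = _five_prime_window(pair.geneB, window, offset)
        covB = track.depth(pair.geneB.seqid, b_lo, b_hi)
        L = pair.intergenic_length
        if L <= 0:
            left_end = pair.left_gene.end
            covI = track.depth(pair.seqid, left_end, left_end)
        elif L <= window:
            covI = track.depth(pair.seqid, pair.intergenic_start, pair.intergenic_end)
        else:
            lo = pair.intergenic_start + (L - window) // 2
            covI = track.depth(pair.seqid, lo, lo + window - 1)
    except (IndexError, KeyError) as exc:
        raise IndexError(f"pair {pair.pair_id}: {exc}") from exc
    return WindowSample(covA=covA, covI=covI, covB=covB)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis H test with midranks and tie correction.

    p is the chi-square upper tail at H with k-1 degrees of freedom. When
    every observation across all groups is identical the test carries no
    information and (H=0, p=1) is returned.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size == 0:
            raise ValueError(f"kruskal_wallis: group {i} is empty")
    pooled = np.concatenate(arrays)
    k, n = len(arrays), pooled.size
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, p=1.0, k=k, n=n)
    H, _ = stats.kruskal(*arrays)
    # tie correction can round H to a tiny negative; clamp before the tail
    H = max(float(H), 0.0)
    p = float(stats.chi2.sf(H, k - 1))
    return KWResult(H=H, p=min(max(p, 0.0), 1.0), k=k, n=n)


def compute_features(
    pair: AdjacentPair,
    windows: WindowSample,
    sample_id: str,
    label: Optional[int] = None,
) -> dict:
    """Assemble the 12-feature row for one (pair, sample).

    Four Kruskal-Wallis comparisons are run — (A,I), (B,I), (A,B) and the
    three-way (A,I,B) — giving eight statistic/log10-p dimensions; gene
    lengths, signed intergenic length and strand match complete the vector.
    """
    comparisons = {
        "AI": (windows.covA, windows.covI),
        "BI": (windows.covB, windows.covI),
        "AB": (windows.covA, windows.covB),
        "AIB": (windows.covA, windows.covI, windows.covB),
    }
    row = {
        "pair_id": pair.pair_id,
        "sample_id": sample_id,
        "lenA": pair.geneA.length,
        "lenB": pair.geneB.length,
        "intergenic_length": pair.intergenic_length,
        "strand_match": pair.strand_match,
    }
    for name, grp in comparisons.items():
        res = kruskal_wallis(grp)
        row[f"kw_{name}_H"] = res.H
        row[f"kw_{name}_logp"] = float(np.log10(max(res.p, P_FLOOR)))
    if label is not None:
        row["label"] = int(label)
    return row


def features_for_track(
    genes: Sequence[GeneRecord],
    track: CoverageTrack,
    min_mean: float = DEFAULT_MIN_MEAN,
    same_strand_only: bool = False,
    window: int = DEFAULT_WINDOW,
    offset: int = 0,
    labels: Optional[dict] = None,
) -> pd.DataFrame:
    """End-to-end featurization of one coverage sample.

    ``labels`` maps (geneA_id, geneB_id) — in either gene order — to 0/1.
    Returns one row per filtered adjacent pair, columns as in the feature
    table format.
    """
    pairs = enumerate_adjacent_pairs(genes, same_strand_only=same_strand_only)
    pairs = filter_expressed(pairs, track, min_mean=min_mean)
    rows = []
    for pair in pairs:
        windows = extract_windows(pair, track, window=window, offset=offset)
        label = None
        if labels is not None:
            label = labels.get((pair.geneA.gene_id, pair.geneB.gene_id))
            if label is None:
                label = labels.get((pair.geneB.gene_id, pair.geneA.gene_id))
        rows.append(compute_features(pair, windows, track.sample_id, label=label))
    cols = ["pair_id", "sample_id"] + list(FEATURE_COLUMNS)
    if labels is not None:
        cols.append("label")
    df = pd.DataFrame(rows, columns=cols)
    if labels is not None:
        df = df.dropna(subset=["label"]).reset_index(drop=True)
        df["label"] = df["label"].astype(int)
    return df
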