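"""Vote tallying across the six algorithms, replicate consensus, and
stringing of consecutive positive pairs into multi-gene operons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ALGORITHM_KEYS, GeneRecord, split_pair_id

N_ALGORITHMS = len(ALGORITHM_KEYS)
DEFAULT_VOTE_THRESHOLD = 3

_CALL_COLS = [f"call_{k}" for k in ALGORITHM_KEYS]


@dataclass(frozen=True)
class OperonChain:
    """A maximal run of genes merged from consecutive positive pairs."""

    gene_ids: tuple
    seqid: str
    strand: str

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("an operon chain needs at least 2 genes")


def tally_votes(predictions: pd.DataFrame) -> pd.DataFrame:
    """Count positive algorithm calls per prediction row.

    Returns pair_id, sample_id (when present), ``votes`` in 0..6 and the
    thresholded calls ``call_at_k`` for k = 1..6 (call_at_k = 1 iff
    votes >= k).
    """
    missing = [c for c in _CALL_COLS if c not in predictions.columns]
    if missing:
        raise ValueError(f"predictions missing algorithm call columns {missing}")
    keep = [c for c in ("pair_id", "sample_id") if c in predictions.columns]
    out = predictions[keep].copy()
    votes = predictions[_CALL_COLS].to_numpy(dtype=int).sum(axis=1)
    out["votes"] = votes
    for k in range(1, N_ALGORITHMS + 1):
        out[f"call_at_{k}"] = (votes >= k).astype(int)
    return out


def replicate_consensus(
    predictions: pd.DataFrame, min_replicates: int = 2, mode: str = "unanimous"
) -> pd.DataFrame:
    """Collapse per-sample predictions into per-pair consensus calls.

    Pairs observed in fewer than ``min_replicates`` samples are dropped.
    Within each algorithm a consensus exists only when the replicate calls
    agree ("unanimous", default) or when one class holds a strict majority
    ("majority"); otherwise the algorithm abstains and contributes no vote.
    ``votes`` counts positive consensus calls only, so consensus can never
    increase an algorithm's contribution.
    """
    if mode not in ("unanimous", "majority"):
        raise ValueError("mode must be 'unanimous' or 'majority'")
    rows = []
    for pid, grp in predictions.groupby("pair_id", sort=True):
        if len(grp) < min_replicates:
            continue
        row: Dict[str, object] = {"pair_id": pid, "n_replicates": len(grp)}
        votes = 0
        for key in ALGORITHM_KEYS:
            calls = grp[f"call_{key}"].to_numpy(dtype=int)
            consensus: Optional[int]
            if mode == "unanimous":
                consensus = int(calls[0]) if np.all(calls == calls[0]) else None
            else:
                pos = int(calls.sum())
                neg = len(calls) - pos
                consensus = 1 if pos > neg else (0 if neg > pos else None)
            row[f"call_{key}"] = consensus
            if consensus == 1:
                votes += 1
        row["votes"] = votes
        rows.append(row)
    cols = ["pair_id", "n_replicates"] + _CALL_COLS + ["votes"]
    out = pd.DataFrame(rows, columns=cols)
    for k in range(1, N_ALGORITHMS + 1):
        out[f"call_at_{k}"] = (out["votes"].to_numpy(dtype=int) >= k).astype(int)
    return out


def string_operons(
    calls: pd.DataFrame,
    genes: Sequence[GeneRecord],
    threshold: int = DEFAULT_VOTE_THRESHOLD,
) -> List[OperonChain]:
    """Merge consecutive positive same-strand pairs into maximal chains.

    ``calls`` needs pair_id plus either ``votes`` (thresholded at
    ``threshold``) or a binary ``call`` column. A negative pair, an
    opposite-strand pair, or a pair missing from the table breaks a chain;
    an isolated positive pair becomes a 2-gene chain.
    """
    if "call" in calls.columns:
        positive = set(calls.loc[calls["call"].astype(int) == 1, "pair_id"])
    elif "votes" in calls.columns:
        positive = set(
            calls.loc[calls["votes"].astype(int) >= threshold, "pair_id"]
        )
    else:
        raise ValueError("calls table needs a 'call' or 'votes' column")
    # accept either gene order inside the pair id
    positive_pairs = set()
    for pid in positive:
        a, b = split_pair_id(pid)
        positive_pairs.add(frozenset((a, b)))

    ordered = sorted(genes, key=lambda g: (g.seqid, g.start))
    chains: List[OperonChain] = []
    current: List[GeneRecord] = []

    def flush() -> None:
        if len(current) >= 2:
            chains.append(
                OperonChain(
                    gene_ids=tuple(g.gene_id for g in current),
                    seqid=current[0].seqid,
                    strand=current[0].strand,
                )
            )
        current.clear()

    for left, right in zip(ordered, ordered[1:]):
        linked = (
            left.seqid == right.seqid
            and left.strand == right.strand
            and frozenset((left.gene_id, right.gene_id)) in positive_pairs
        )
        if linked:
            if not current:
                current.append(left)
            current.append(right)
        else:
            flush()
    flush()
    return chains


def chains_to_frame(chains: Iterable[OperonChain]) -> pd.DataFrame:
    rows = [
        {
            "chain_id": f"operon_{i + 1}",
            "seqid": c.seqid,
            "strand": c.strand,
            "n_genes": len(c.gene_ids),
            "gene_ids": ",".join(c.gene_ids),
        }
        for i, c in enumerate(chains)
    ]
    return pd.DataFrame(
        rows, columns=["chain_id", "seqid", "strand", "n_genes", "gene_ids"]
    )
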