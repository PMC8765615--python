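"""Seeded synthetic genomes, operon structures and per-base coverage tracks.

The generator lays out genes left to right, groups consecutive genes into
transcription units with geometrically distributed sizes, and emits coverage
in which all bases of a unit — genes and the intergenic gaps inside the unit
— share one expression level (up to a read-through attenuation factor and
negative-binomial noise), while gaps between units sit at background. That
is exactly the premise the classifier suite is trained to exploit:
co-transcribed neighbors look like one coverage distribution, independent
neighbors do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import (
    CoverageTrack,
    GeneRecord,
    PairLabel,
    write_coverage,
    write_gff3_genes,
    write_pair_labels,
)
from .features import features_for_track


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome and coverage model.

    Unit sizes are geometric: after each gene the unit ends with probability
    ``p_stop`` (mean size 1/p_stop). ``readthrough`` is the ratio of
    within-operon intergenic mean depth to the unit's gene depth;
    ``dispersion`` is the negative-binomial size parameter (variance
    m + m^2/dispersion), so smaller values mean noisier coverage.
    """

    n_genes: int = 4000
    p_stop: float = 0.5
    gene_length_range: Tuple[int, int] = (200, 1500)
    within_gap_range: Tuple[int, int] = (1, 30)
    between_gap_range: Tuple[int, int] = (50, 400)
    minus_strand_fraction: float = 0.5
    log_mean_depth: float = float(np.log(50.0))
    log_sd_depth: float = 1.0
    readthrough: float = 0.9
    background_depth: float = 1.0
    dispersion: float = 5.0
    n_replicates: int = 2
    redraw_unit_depths: bool = False
    seqid: str = "chr1"
    seed: int = 0


@dataclass
class SyntheticTruth:
    genes: List[GeneRecord]
    labels: List[PairLabel]
    unit_of_gene: Dict[str, int]
    unit_depths: Dict[int, float] = field(default_factory=dict)
    genome_length: int = 0


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Draw gene layout, transcription-unit membership and pair labels.

    Every adjacent pair is labeled: 1 when both genes share a transcription
    unit, 0 otherwise (including opposite-strand neighbors).
    """
    if not (0.0 < config.p_stop <= 1.0):
        raise ValueError("p_stop must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    genes: List[GeneRecord] = []
    unit_of_gene: Dict[str, int] = {}
    unit = 0
    unit_strand = "+" if rng.random() >= config.minus_strand_fraction else "-"
    pos = 1 + int(rng.integers(*config.between_gap_range))
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        gid = f"g{i + 1:05d}"
        genes.append(GeneRecord(config.seqid, pos, pos + length - 1, gid, unit_strand))
        unit_of_gene[gid] = unit
        end = pos + length - 1
        if rng.random() < config.p_stop:  # unit terminates after this gene
            unit += 1
            unit_strand = "+" if rng.random() >= config.minus_strand_fraction else "-"
            gap = int(rng.integers(config.between_gap_range[0], config.between_gap_range[1] + 1))
        else:
            gap = int(rng.integers(config.within_gap_range[0], config.within_gap_range[1] + 1))
        pos = end + gap + 1
    labels = [
        PairLabel(a.gene_id, b.gene_id, int(unit_of_gene[a.gene_id] == unit_of_gene[b.gene_id]))
        for a, b in zip(genes, genes[1:])
    ]
    genome_length = genes[-1].end + int(np.mean(config.between_gap_range))
    return SyntheticTruth(
        genes=genes,
        labels=labels,
        unit_of_gene=unit_of_gene,
        genome_length=genome_length,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size ``dispersion``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_coverage(
    truth: SyntheticTruth, config: SimulationConfig
) -> List[CoverageTrack]:
    """Generate one per-base coverage track per replicate.

    Gene bases get negative-binomial noise around their unit's depth;
    within-unit intergenic bases get readthrough * unit depth; everything
    else sits at the background depth. Replicates share the unit layout and
    (by default) the unit depths, redrawing only the per-base noise.
    """
    master = np.random.default_rng(config.seed + 1)
    n_units = max(truth.unit_of_gene.values()) + 1
    base_depths = np.exp(
        master.normal(config.log_mean_depth, config.log_sd_depth, size=n_units)
    )
    truth.unit_depths = {u: float(d) for u, d in enumerate(base_depths)}
    tracks = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + 1000 * (rep + 1))
        if config.redraw_unit_depths:
            depths_u = np.exp(
                rng.normal(config.log_mean_depth, config.log_sd_depth, size=n_units)
            )
        else:
            depths_u = base_depths
        # background is an additive floor: gene bases sit at background +
        # unit depth, within-unit gaps at background + readthrough * depth,
        # between-unit gaps at background alone
        mean = np.full(truth.genome_length, config.background_depth, dtype=float)
        for gene in truth.genes:
            mean[gene.start - 1 : gene.end] = (
                config.background_depth + depths_u[truth.unit_of_gene[gene.gene_id]]
            )
        for a, b in zip(truth.genes, truth.genes[1:]):
            ua, ub = truth.unit_of_gene[a.gene_id], truth.unit_of_gene[b.gene_id]
            if ua == ub and b.start > a.end + 1:
                mean[a.end : b.start - 1] = (
                    config.background_depth + config.readthrough * depths_u[ua]
                )
        depth = _nb_draw(rng, mean, config.dispersion).astype(np.int64)
        tracks.append(CoverageTrack(f"rep{rep + 1}", {config.seqid: depth}))
    return tracks


def label_map(truth: SyntheticTruth) -> Dict[Tuple[str, str], int]:
    return {(l.geneA_id, l.geneB_id): l.label for l in truth.labels}


def default_benchmark(
    seed: int = 0, config: Optional[SimulationConfig] = None
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate, featurize and split the standard synthetic benchmark.

    Returns (features, labels, train_index, test_index) where the split is a
    stratified 75/25 partition of the (pair, sample) rows. This is the
    fixture behind the classifier-level checks.
    """
    from sklearn.model_selection import train_test_split

    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config.seed = seed
    truth = simulate_genome(config)
    tracks = simulate_coverage(truth, config)
    lmap = label_map(truth)
    frames = [features_for_track(truth.genes, t, labels=lmap) for t in tracks]
    features = pd.concat(frames, ignore_index=True)
    labels = features["label"].to_numpy(dtype=int)
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.25, stratify=labels, random_state=seed
    )
    return features, labels, np.sort(train_idx), np.sort(test_idx)


def write_simulation(truth: SyntheticTruth, tracks: List[CoverageTrack], outdir) -> Dict[str, str]:
    """Write GFF3, per-replicate depth files and the label TSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gff = outdir / "genes.gff3"
    write_gff3_genes(truth.genes, gff)
    paths["gff"] = str(gff)
    for track in tracks:
        p = outdir / f"coverage_{track.sample_id}.txt"
        write_coverage(track, p)
        paths[f"coverage_{track.sample_id}"] = str(p)
    lab = outdir / "labels.tsv"
    write_pair_labels(truth.labels, lab)
    paths["labels"] = str(lab)
    return paths
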