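"""Synthetic benchmark data with known planted motifs.

Generates two-class gene sets (expressed vs low expressed) as 1000-nt
windows over {A,C,G,T,N}, with PWM motifs planted class-conditionally at
configurable insertion rates and positional distributions, plus a
matching synthetic FPKM table. Every downstream stage of the pipeline is
testable against the generator's recorded ground truth.

A single global integer seed drives all sampling; per-gene sub-streams
are derived from (seed, gene index) so individual records are
reproducible independently of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LABEL_EXPRESSED, LABEL_LOW, NUCLEOTIDES, Pwm, SequenceRecord

_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass
class PlantSpec:
    """One motif to plant: which PWM, how often per class, and where.

    position_distribution is ("uniform",) for a uniform start over all
    in-bounds offsets, or ("gaussian", center, sd) for a truncated
    normal draw of the start offset. Orientation is forward-only.
    """

    motif: Pwm
    insertion_rate_expressed: float
    insertion_rate_low: float
    position_distribution: tuple = ("uniform",)

    def __post_init__(self) -> None:
        for r in (self.insertion_rate_expressed, self.insertion_rate_low):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"insertion rate {r} outside [0, 1]")
        kind = self.position_distribution[0]
        if kind not in ("uniform", "gaussian"):
            raise ValueError(f"unknown position distribution {kind!r}")
        if kind == "gaussian":
            center = self.position_distribution[1]
            if not 0 <= center <= 999:
                raise ValueError("gaussian center must lie in [0, 999]")

    def rate(self, label: str) -> float:
        return (
            self.insertion_rate_expressed
            if label == LABEL_EXPRESSED
            else self.insertion_rate_low
        )


@dataclass
class SyntheticDatasetConfig:
    n_expressed: int = 1000
    n_low: int = 1000
    window_length: int = 1000
    background: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    n_char_rate: float = 0.0
    plants: list = field(default_factory=list)
    conflict_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array([self.background[c] for c in "ACGT"], dtype=float)
        if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if np.any(freqs < 0):
            raise ValueError("background frequencies must be non-negative")
        if not 0.0 <= self.n_char_rate <= 0.2:
            raise ValueError("n_char_rate must lie in [0, 0.2]")
        for plant in self.plants:
            if plant.motif.width > self.window_length:
                raise ValueError("motif wider than window")
        if not 0.0 <= self.conflict_fraction <= 1.0:
            raise ValueError("conflict_fraction must lie in [0, 1]")

    def background_array(self) -> np.ndarray:
        """Background frequencies in internal A,T,C,G channel order."""
        return np.array([self.background[c] for c in NUCLEOTIDES], dtype=float)


def _gene_rng(cfg: SyntheticDatasetConfig, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, gene_index)))


def _draw_offset(
    plant: PlantSpec, window_length: int, rng: np.random.Generator
) -> int:
    max_start = window_length - plant.motif.width
    kind = plant.position_distribution[0]
    if kind == "uniform":
        return int(rng.integers(0, max_start + 1))
    _, center, sd = plant.position_distribution
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        start = int(round(rng.normal(center, sd)))
        if 0 <= start <= max_start:
            return start
    raise RuntimeError(
        f"could not place motif with gaussian(center={center}, sd={sd}) "
        f"inside [0, {max_start}] after {_MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def _sample_motif_instance(motif: Pwm, rng: np.random.Generator) -> str:
    letters = []
    for j in range(motif.width):
        letters.append(rng.choice(list(NUCLEOTIDES), p=motif.column(j)))
    return "".join(letters)


def sample_sequence(
    cfg: SyntheticDatasetConfig,
    label: str,
    gene_index: int = 0,
    gene_id: str | None = None,
    stage: str = "synthetic",
) -> tuple[SequenceRecord, list[dict]]:
    """Draw one labeled window; returns the record and its plant truth.

    Background positions are i.i.d. from cfg.background; each PlantSpec
    independently fires with its class rate, sampling an instance
    letter-by-letter from its PWM. Plants never straddle the window edge
    and never overlap each other (bounded retries, then error). N
    characters are injected i.i.d. after placement, sparing planted
    positions.
    """
    if label not in (LABEL_EXPRESSED, LABEL_LOW):
        raise ValueError(f"label must be expressed/low, got {label!r}")
    rng = _gene_rng(cfg, gene_index)
    if gene_id is None:
        gene_id = f"gene{gene_index:06d}"

    bg = np.array([cfg.background[c] for c in "ACGT"], dtype=float)
    seq = rng.choice(list("ACGT"), size=cfg.window_length, p=bg)

    occupied: list[tuple[int, int]] = []
    truth: list[dict] = []
    for plant in cfg.plants:
        if rng.random() >= plant.rate(label):
            continue
        width = plant.motif.width
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            start = _draw_offset(plant, cfg.window_length, rng)
            if all(start + width <= s or start >= e for s, e in occupied):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place motif {plant.motif.name!r} without overlap "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        instance = _sample_motif_instance(plant.motif, rng)
        seq[start : start + width] = list(instance)
        occupied.append((start, start + width))
        truth.append(
            {"motif": plant.motif.name, "start": start, "instance": instance}
        )

    if cfg.n_char_rate > 0:
        mask = rng.random(cfg.window_length) < cfg.n_char_rate
        for s, e in occupied:
            mask[s:e] = False
        seq[mask] = "N"

    record = SequenceRecord(gene_id, "".join(seq), label, stage)
    return record, truth


def sample_dataset(
    cfg: SyntheticDatasetConfig, stage: str = "synthetic"
) -> tuple[list[SequenceRecord], dict[str, list[dict]]]:
    """Draw the full two-class dataset plus a gene -> plant-truth map."""
    records: list[SequenceRecord] = []
    truth: dict[str, list[dict]] = {}
    labels = [LABEL_EXPRESSED] * cfg.n_expressed + [LABEL_LOW] * cfg.n_low
    for idx, label in enumerate(labels):
        rec, plants = sample_sequence(cfg, label, gene_index=idx, stage=stage)
        records.append(rec)
        truth[rec.gene_id] = plants
    return records, truth


def sample_fpkm_table(
    cfg: SyntheticDatasetConfig, timepoints: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic gene x timepoint FPKM table consistent with the labels.

    Expressed genes receive FPKM > 1 at every timepoint, low genes
    FPKM <= 1 at every timepoint. A cfg.conflict_fraction of genes is
    instead given mixed values (some above, some at/below 1) so the
    downstream conflict-trimming rule has something to trim; the second
    return value records the generating status of every gene
    ("expressed" / "low" / "conflict").
    """
    if not timepoints:
        raise ValueError("need at least one timepoint")
    # sub-stream tag keeps the FPKM draw independent of sequence draws
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x46504B)))
    n = cfg.n_expressed + cfg.n_low
    labels = [LABEL_EXPRESSED] * cfg.n_expressed + [LABEL_LOW] * cfg.n_low
    genes = [f"gene{idx:06d}" for idx in range(n)]

    rows = []
    status: dict[str, str] = {}
    for gene, label in zip(genes, labels):
        conflicted = len(timepoints) >= 2 and rng.random() < cfg.conflict_fraction
        if conflicted:
            values = 1.0 + rng.exponential(5.0, size=len(timepoints))
            k = int(rng.integers(1, len(timepoints)))  # at least one of each side
            low_at = rng.choice(len(timepoints), size=k, replace=False)
            values[low_at] = rng.uniform(0.0, 1.0, size=k)
            status[gene] = "conflict"
        elif label == LABEL_EXPRESSED:
            values = 1.0 + rng.exponential(5.0, size=len(timepoints))
            status[gene] = LABEL_EXPRESSED
        else:
            values = rng.uniform(0.0, 1.0, size=len(timepoints))
            status[gene] = LABEL_LOW
        rows.append(values)

    table = pd.DataFrame(rows, index=genes, columns=timepoints)
    table.index.name = "gene"
    return table, status


def write_dataset(
    outdir: str | Path,
    records: list[SequenceRecord],
    truth: dict[str, list[dict]] | None = None,
    fpkm: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write FASTA windows, a gene/label/stage TSV, and optional extras."""
    from . import prep

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "windows.fasta",
        "labels": outdir / "labels.tsv",
    }
    prep.write_fasta(paths["fasta"], records)
    pd.DataFrame(
        [(r.gene_id, r.label, r.stage) for r in records],
        columns=["gene", "label", "stage"],
    ).to_csv(paths["labels"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1))
    if fpkm is not None:
        paths["fpkm"] = outdir / "fpkm.tsv"
        fpkm.to_csv(paths["fpkm"], sep="\t")
    return paths
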