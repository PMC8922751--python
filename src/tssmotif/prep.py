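"""Preprocessing: FPKM thresholding, TSS window extraction, one-hot encoding.

Genes are labeled per developmental stage from an FPKM table: expressed
if FPKM > threshold (default 1) at every timepoint of the stage, low if
FPKM <= threshold at every timepoint, and trimmed (excluded, with the
reason recorded) when the status conflicts across timepoints or a value
is missing.

Windows are 500 nt either side of the TSS, length 1000, in transcription
orientation; the TSS base sits at window offset 500. Input TSS tables
are 1-based; internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import (
    ALPHABET,
    CHANNEL_INDEX,
    LABEL_EXPRESSED,
    LABEL_LOW,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 1000
FLANK = 500

# IUPAC ambiguity codes (everything that is not a plain base) map to N.
_IUPAC_TO_N = set("RYSWKMBDHVU")


@dataclass
class FpkmTable:
    """Gene x timepoint FPKM values plus a timepoint -> stage mapping."""

    values: pd.DataFrame  # index: gene, columns: timepoints
    stage_map: dict = field(default_factory=dict)  # timepoint -> stage

    def __post_init__(self) -> None:
        numeric = self.values.to_numpy(dtype=float, na_value=np.nan)
        finite = numeric[np.isfinite(numeric)]
        if np.any(finite < 0):
            raise ValueError("FPKM values must be non-negative")

    def stage_timepoints(self, stage: str) -> list[str]:
        cols = [t for t in self.values.columns if self.stage_map.get(t) == stage]
        if not cols:
            raise KeyError(f"stage {stage!r} has no timepoints in the table")
        return cols


def label_stage(
    table: FpkmTable, stage: str, threshold: float = 1.0
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Label every gene for one stage; returns (labels, trimmed).

    A gene is expressed iff FPKM > threshold at ALL of the stage's
    timepoints and low iff FPKM <= threshold at all of them; genes with
    conflicting status across timepoints, or missing values, are trimmed
    and reported as (gene, reason) pairs.
    """
    cols = table.stage_timepoints(stage)
    sub = table.values[cols]
    labels: dict[str, str] = {}
    trimmed: list[tuple[str, str]] = []
    arr = sub.to_numpy(dtype=float, na_value=np.nan)
    for gene, row in zip(sub.index, arr):
        if np.any(~np.isfinite(row)):
            trimmed.append((gene, "missing value"))
            continue
        above = row > threshold
        if above.all():
            labels[gene] = LABEL_EXPRESSED
        elif (~above).all():
            labels[gene] = LABEL_LOW
        else:
            trimmed.append((gene, "conflicting status across timepoints"))
    return labels, trimmed


def extract_window(
    genome: dict[str, str],
    chrom: str,
    tss: int,
    strand: str,
    flank: int = FLANK,
) -> str:
    """Extract flank nt either side of a 1-based TSS, oriented with
    transcription; positions beyond the contig edge are padded with N.

    The window covers [tss-flank, tss+flank) on the plus strand before
    orientation, so after reverse-complementing minus-strand genes the
    TSS base is always at offset ``flank``.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    contig = genome[chrom]
    tss0 = tss - 1  # to 0-based
    if not 0 <= tss0 < len(contig):
        raise ValueError(f"TSS {tss} outside chromosome {chrom!r} bounds")
    if strand == "+":
        start, end = tss0 - flank, tss0 + flank
    elif strand == "-":
        # mirror image so the TSS base remains the first downstream base
        start, end = tss0 - flank + 1, tss0 + flank + 1
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    left_pad = max(0, -start)
    right_pad = max(0, end - len(contig))
    window = (
        "N" * left_pad
        + contig[max(0, start) : min(end, len(contig))]
        + "N" * right_pad
    )
    if strand == "-":
        window = reverse_complement(window)
    return window


def clean_sequence(seq: str) -> str:
    """Uppercase; map IUPAC ambiguity codes (not plain A,C,G,T,N) to N."""
    seq = seq.upper()
    if any(c in _IUPAC_TO_N for c in seq):
        seq = "".join("N" if c in _IUPAC_TO_N else c for c in seq)
    return seq


def one_hot(seq: str) -> np.ndarray:
    """Encode a sequence as a (length, 5) indicator matrix, channel
    order A, T, C, G, N."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    seq = clean_sequence(seq)
    idx = np.fromiter(
        (CHANNEL_INDEX[c] for c in seq), dtype=np.int64, count=len(seq)
    )
    out = np.zeros((len(seq), 5), dtype=np.float32)
    out[np.arange(len(seq)), idx] = 1.0
    return out


def decode(window: np.ndarray) -> str:
    """Inverse of one_hot."""
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[1] != 5:
        raise ValueError("expected a (length, 5) one-hot matrix")
    if not np.all(window.sum(axis=1) == 1):
        raise ValueError("each row must have exactly one active channel")
    return "".join(ALPHABET[i] for i in window.argmax(axis=1))


def encode_records(records: list[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into X (n, length, 5) float32 and y (n,) int labels."""
    X = np.stack([one_hot(r.sequence) for r in records])
    y = np.array([r.label_code for r in records], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------- I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: list[SequenceRecord]) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.gene_id, description=r.label)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fpkm_tsv(path: str | Path, stage_map: dict | None = None) -> FpkmTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FpkmTable(df, stage_map or {})


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS table: gene, chrom, tss (1-based), strand columns (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df


def build_stage_dataset(
    genome: dict[str, str],
    tss_table: pd.DataFrame,
    fpkm: FpkmTable,
    stage: str,
    threshold: float = 1.0,
) -> list[SequenceRecord]:
    """Labeled windows for one stage: label, extract, clean."""
    labels, trimmed = label_stage(fpkm, stage, threshold)
    if trimmed:
        logger.info("stage %s: trimmed %d genes", stage, len(trimmed))
    records = []
    for row in tss_table.itertuples(index=False):
        label = labels.get(row.gene)
        if label is None:
            continue
        seq = clean_sequence(
            extract_window(genome, row.chrom, int(row.tss), row.strand)
        )
        records.append(SequenceRecord(row.gene, seq, label, stage))
    return records
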