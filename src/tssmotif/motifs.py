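"""Motif I/O, comparison, calling, and scanning.

Covers the motif-handling half of the pipeline: minimal MEME motif
format read/write, an offset-aligned Pearson PWM similarity (the
in-core stand-in for tomtom alignment), the common/specific motif call
across cross-validation folds ("present in at least 2 models"), greedy
novel-motif deduplication, FIMO-style forward-strand log-odds scanning
with exact dynamic-programming p-values and Benjamini-Hochberg
q-values, and class-conditional occurrence profiles.

Scanning is forward-strand only — reverse-complement instances are
deliberately not found. N bases score 0 bits (background-neutral), so
N-padded window edges neither create nor destroy hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import NUCLEOTIDES, Pwm, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.1
DEFAULT_SIM_THRESHOLD = 0.8
PSEUDOCOUNT = 1e-3
N_BINS = 1000

# MEME files use A,C,G,T column order; internal row order is A,T,C,G.
_MEME_ORDER = [NUCLEOTIDES.index(c) for c in "ACGT"]  # internal -> ACGT
_FROM_MEME = [list("ACGT").index(c) for c in NUCLEOTIDES]  # ACGT -> internal


@dataclass
class MotifLibrary:
    motifs: list
    background: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    source: str = "transformed"  # "transformed" | "external"

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def names(self) -> list[str]:
        return [m.name for m in self.motifs]

    def background_array(self) -> np.ndarray:
        return np.array([self.background[c] for c in NUCLEOTIDES])


@dataclass
class MotifHit:
    gene_id: str
    motif: str
    offset: int  # 0-based, forward strand
    width: int
    score: float  # log-odds, bits
    p_value: float
    q_value: float = np.nan
    matched: str = ""


# ----------------------------------------------------------- MEME I/O


def write_meme(lib: MotifLibrary, path: str | Path) -> None:
    """Minimal MEME motif format, 6-decimal letter probabilities."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: +", ""]
    bg = lib.background
    lines.append("Background letter frequencies")
    lines.append(
        "A {:.6f} C {:.6f} G {:.6f} T {:.6f}".format(
            bg["A"], bg["C"], bg["G"], bg["T"]
        )
    )
    lines.append("")
    for m in lib.motifs:
        lines.append(f"MOTIF {m.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.width} "
            f"nsites= {m.nsites} E= 0"
        )
        for j in range(m.width):
            col = m.matrix[_MEME_ORDER, j]
            lines.append(" ".join(f"{v:.6f}" for v in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


class MemeParseError(ValueError):
    pass


def read_meme(path: str | Path) -> MotifLibrary:
    """Parse a minimal MEME motif file; errors carry the line number."""
    lines = Path(path).read_text().splitlines()
    background = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    motifs: list[Pwm] = []
    i = 0
    saw_version = False
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("Background letter frequencies"):
            i += 1
            if i >= n:
                raise MemeParseError(f"line {i + 1}: missing background values")
            toks = lines[i].split()
            try:
                background = {
                    toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)
                }
            except (IndexError, ValueError) as exc:
                raise MemeParseError(f"line {i + 1}: bad background line") from exc
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise MemeParseError(f"line {i + 1}: MOTIF line missing a name")
            name = toks[1]
            i += 1
            while i < n and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MemeParseError(
                        f"line {i + 1}: motif {name!r} has no probability matrix"
                    )
                i += 1
            if i >= n:
                raise MemeParseError(
                    f"line {n}: motif {name!r} has no probability matrix"
                )
            toks = lines[i].split()
            w = nsites = None
            for k, t in enumerate(toks):
                if t == "w=" and k + 1 < len(toks):
                    w = int(toks[k + 1])
                if t == "nsites=" and k + 1 < len(toks):
                    nsites = int(float(toks[k + 1]))
            if w is None:
                raise MemeParseError(f"line {i + 1}: matrix header missing w=")
            rows = []
            for r in range(w):
                i += 1
                if i >= n:
                    raise MemeParseError(
                        f"line {n}: motif {name!r} matrix truncated"
                    )
                vals = lines[i].split()
                if len(vals) != 4:
                    raise MemeParseError(
                        f"line {i + 1}: expected 4 probabilities, got "
                        f"{len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise MemeParseError(
                        f"line {i + 1}: non-numeric probability"
                    ) from exc
            meme_mat = np.array(rows).T  # 4 x w in ACGT order
            mat = meme_mat[_FROM_MEME]  # to internal A,T,C,G
            mat = mat / mat.sum(axis=0)  # absorb 6-decimal rounding
            motifs.append(Pwm(mat, name=name, nsites=nsites or 20))
        i += 1
    if not saw_version:
        raise MemeParseError("line 1: missing 'MEME version' header")
    return MotifLibrary(motifs, background=background, source="external")


# ------------------------------------------------------- similarity


def pwm_similarity(a: Pwm, b: Pwm, min_overlap: int = 4):
    """Best Pearson correlation between flattened overlapping columns
    over all relative offsets with >= min_overlap columns.

    Returns (score, offset, degenerate): offset is b's start relative
    to a's start; degenerate is True when every candidate overlap has
    zero variance (e.g. two uniform motifs), in which case score 0 is
    returned. Symmetric in its arguments.
    """
    if min(a.width, b.width) < min_overlap:
        raise ValueError(
            f"motifs must be at least {min_overlap} columns wide"
        )
    best = (-np.inf, 0)
    any_valid = False
    for offset in range(-(b.width - min_overlap), a.width - min_overlap + 1):
        a_lo = max(0, offset)
        a_hi = min(a.width, offset + b.width)
        if a_hi - a_lo < min_overlap:
            continue
        sub_a = a.matrix[:, a_lo:a_hi].ravel()
        sub_b = b.matrix[:, a_lo - offset : a_hi - offset].ravel()
        if np.std(sub_a) == 0 or np.std(sub_b) == 0:
            continue
        r = float(np.corrcoef(sub_a, sub_b)[0, 1])
        any_valid = True
        if r > best[0]:
            best = (r, offset)
    if not any_valid:
        return 0.0, 0, True
    return best[0], best[1], False


def match_library(
    pwms: list[Pwm],
    library: MotifLibrary,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> dict[str, str | None]:
    """Best library match per PWM at the similarity threshold, else None."""
    out: dict[str, str | None] = {}
    for pwm in pwms:
        best_name, best_score = None, sim_threshold
        for ref in library:
            score, _, degenerate = pwm_similarity(pwm, ref)
            if not degenerate and score >= best_score:
                best_name, best_score = ref.name, score
        out[pwm.name] = best_name
    return out


def call_common(
    per_fold_matches: list[set], min_models: int = 2
) -> tuple[set, set]:
    """Common motifs appear in >= min_models cross-validation models;
    specific motifs in exactly one."""
    counts: dict[str, int] = {}
    for fold_set in per_fold_matches:
        for name in fold_set:
            counts[name] = counts.get(name, 0) + 1
    common = {n for n, c in counts.items() if c >= min_models}
    specific = {n for n, c in counts.items() if c == 1}
    return common, specific


def dedup_novel(
    unmatched: list[Pwm], sim_threshold: float = DEFAULT_SIM_THRESHOLD
) -> list[Pwm]:
    """Greedy non-redundant set: in input order, keep a motif unless it
    matches an already-kept one at the threshold."""
    kept: list[Pwm] = []
    for pwm in unmatched:
        redundant = False
        for rep in kept:
            score, _, degenerate = pwm_similarity(pwm, rep)
            if not degenerate and score >= sim_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(pwm)
    return kept


# ---------------------------------------------------------- scanning


@dataclass
class _ScoredMotif:
    """Integer-discretized log-odds scores plus the exact null tail."""

    name: str
    width: int
    int_scores: np.ndarray  # (4, w) integers, rows A,T,C,G
    delta: float  # bin width in bits
    tail: np.ndarray  # tail[k - offset] = P(score >= k) under background
    min_total: int


def _discretize_motif(
    motif: Pwm,
    background: np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
    n_bins: int = N_BINS,
) -> _ScoredMotif:
    probs = motif.matrix + pseudocount
    probs = probs / probs.sum(axis=0)
    lods = np.log2(probs / background[:, None])  # (4, w) bits
    # bins span the motif's full score range, N's 0 included
    col_min = np.minimum(lods.min(axis=0), 0.0)
    col_max = np.maximum(lods.max(axis=0), 0.0)
    span = float((col_max - col_min).sum())
    delta = span / n_bins if span > 0 else 1.0
    int_scores = np.rint(lods / delta).astype(np.int64)
    min_col = np.minimum(int_scores.min(axis=0), 0)
    max_col = np.maximum(int_scores.max(axis=0), 0)
    min_total = int(min_col.sum())
    max_total = int(max_col.sum())
    size = max_total - min_total + 1
    # DP over columns: pmf of the integer total under the background
    pmf = np.zeros(size)
    pmf[-min_total] = 1.0  # score 0 before any column
    for j in range(motif.width):
        nxt = np.zeros(size)
        for i in range(4):
            s = int_scores[i, j]
            w = background[i]
            if s >= 0:
                nxt[s:] += w * pmf[: size - s] if s > 0 else w * pmf
            else:
                nxt[:s] += w * pmf[-s:]
        pmf = nxt
    tail = np.minimum(1.0, pmf[::-1].cumsum()[::-1])
    return _ScoredMotif(
        motif.name, motif.width, int_scores, delta, tail, min_total
    )


def _windows_as_indices(seq: str) -> np.ndarray:
    """Sequence to channel indices 0..3 (A,T,C,G) with N (and anything
    else) as 4."""
    lut = np.full(256, 4, dtype=np.int64)
    for i, c in enumerate(NUCLEOTIDES):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan(
    lib: MotifLibrary,
    windows: list[SequenceRecord],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
    n_bins: int = N_BINS,
) -> list[MotifHit]:
    """FIMO-style forward-strand scan of every motif over every window.

    Per (motif, gene, offset): integer-discretized log-odds score
    against the library background (N scores 0 bits), exact p-value
    from the dynamic-programming null tail, then per-motif
    Benjamini-Hochberg q-values over all (gene, offset) tests; hits
    with q <= q_threshold are returned.
    """
    background = lib.background_array()
    hits: list[MotifHit] = []
    seq_idx = {rec.gene_id: _windows_as_indices(rec.sequence) for rec in windows}
    for motif in lib:
        too_wide = [
            r.gene_id for r in windows if len(r.sequence) < motif.width
        ]
        if too_wide:
            logger.warning(
                "motif %s wider than %d windows; skipped there",
                motif.name,
                len(too_wide),
            )
        sm = _discretize_motif(motif, background, pseudocount, n_bins)
        # per-letter integer scores with an explicit 0 row for N
        scores5 = np.vstack([sm.int_scores, np.zeros(sm.width, dtype=np.int64)])
        motif_hits: list[MotifHit] = []
        pvals: list[float] = []
        for rec in windows:
            idx = seq_idx[rec.gene_id]
            if len(idx) < motif.width:
                continue
            win = sliding_window_view(idx, sm.width)  # (n_off, w)
            totals = scores5[win, np.arange(sm.width)].sum(axis=1)
            p = sm.tail[
                np.clip(totals - sm.min_total, 0, len(sm.tail) - 1)
            ]
            p = np.where(totals - sm.min_total >= len(sm.tail), 0.0, p)
            for off in range(len(totals)):
                motif_hits.append(
                    MotifHit(
                        gene_id=rec.gene_id,
                        motif=motif.name,
                        offset=off,
                        width=sm.width,
                        score=float(totals[off] * sm.delta),
                        p_value=float(p[off]),
                        matched=rec.sequence[off : off + sm.width],
                    )
                )
                pvals.append(float(p[off]))
        if not motif_hits:
            continue
        q = benjamini_hochberg(np.array(pvals))
        for h, qv in zip(motif_hits, q):
            h.q_value = float(qv)
        hits.extend(h for h in motif_hits if h.q_value <= q_threshold)
    return hits


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def exact_scan_pvalue(
    motif: Pwm,
    observed_int_score: int,
    background: np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
    n_bins: int = N_BINS,
) -> float:
    """p-value of an integer score from the same DP null used by scan."""
    sm = _discretize_motif(motif, background, pseudocount, n_bins)
    k = observed_int_score - sm.min_total
    if k < 0:
        return 1.0
    if k >= len(sm.tail):
        return 0.0
    return float(sm.tail[k])


# ----------------------------------------------------------- profiles


def occurrence_profile(
    hits: list[MotifHit],
    labels: dict[str, str],
    window_length: int = 1000,
    smooth: int = 0,
) -> dict[str, np.ndarray]:
    """Per-class fraction of genes with a hit starting at each offset.

    Multiple hits of one gene at the same offset count once; an
    optional centered moving-average window smooths the profile
    (default none).
    """
    classes = sorted(set(labels.values()))
    class_n = {c: sum(1 for v in labels.values() if v == c) for c in classes}
    seen: set[tuple[str, int]] = set()
    counts = {c: np.zeros(window_length) for c in classes}
    for h in hits:
        label = labels.get(h.gene_id)
        if label is None or (h.gene_id, h.offset) in seen:
            continue
        seen.add((h.gene_id, h.offset))
        counts[label][h.offset] += 1
    profiles = {}
    for c in classes:
        prof = counts[c] / max(class_n[c], 1)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            prof = np.convolve(prof, kernel, mode="same")
        profiles[c] = prof
    return profiles


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """FIMO-style hit table (1-based inclusive start/stop, strand '+')."""
    return pd.DataFrame(
        [
            {
                "motif_id": h.motif,
                "sequence_name": h.gene_id,
                "start": h.offset + 1,
                "stop": h.offset + h.width,
                "strand": "+",
                "score": h.score,
                "p-value": h.p_value,
                "q-value": h.q_value,
                "matched_sequence": h.matched,
            }
            for h in hits
        ]
    )
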