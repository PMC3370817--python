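"""Subgroup-specific conserved-block discovery and log-odds scanning.

Most members of an R2R3-MYB subgroup share one or more ungapped conserved
motifs in the otherwise divergent C-terminal region (downstream of the
DNA-binding domain).  Discovery here is deterministic conserved-block
extraction over a center-star alignment of a subgroup's C-terminal
sequences: a block is a maximal run of alignment columns that are

* gapless in at least ``min_member_fraction`` of the members,
* dominated by one residue (majority fraction >= ``conservation_min``,
  the conventional >=75% shading rule for alignment conservation), and
* informative (plug-in information content >= ``min_ic_per_col`` bits),

with width inside the configured bounds (6-300 by default), at most one
occurrence per member sequence, ranked by total information content and
capped at 100 blocks.  The majority-fraction rule guards against the small-
sample upward bias of plug-in information content on a handful of random
sequences.  Discovered blocks can be written in MEME minimal text format
and rediscovered in arbitrary sequences by a MAST-like log-odds scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import center_star_align

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MAX_IC = math.log2(20.0)

DEFAULT_MIN_WIDTH = 6
DEFAULT_MAX_WIDTH = 300
DEFAULT_MIN_IC = 1.5
DEFAULT_CONSERVATION_MIN = 0.75
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_MAX_BLOCKS = 100


@dataclass
class MotifBlock:
    subgroup: str
    consensus: str
    width: int
    frequencies: np.ndarray          # (width, 20) column frequencies
    information_content: np.ndarray  # (width,) bits per column
    occurrences: tuple[tuple[str, int], ...] = ()  # (sequence id, 1-based start)

    @property
    def total_ic(self) -> float:
        return float(self.information_content.sum())

    def max_score(self, background: np.ndarray | None = None,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
        return float(self.pssm(background, pseudocount).max(axis=1).sum())

    def pssm(self, background: np.ndarray | None = None,
             pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        bg = _background(background)
        f = self.frequencies + pseudocount
        f = f / f.sum(axis=1, keepdims=True)
        return np.log2(f / bg)


def _background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(20, 1.0 / 20.0)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")
    return bg


def _column_stats(column: list[str]) -> tuple[float, float, float, np.ndarray]:
    """(gapless fraction, majority fraction, IC bits, frequencies) of a column."""
    residues = [c for c in column if c != GAP]
    counts = np.zeros(20)
    for c in residues:
        counts[AMINO_ACIDS.index(c)] += 1
    if not residues:
        return 0.0, 0.0, 0.0, counts
    freqs = counts / counts.sum()
    nz = freqs[freqs > 0]
    ic = MAX_IC + float((nz * np.log2(nz)).sum())
    return len(residues) / len(column), float(freqs.max()), ic, freqs


def discover_blocks(sequences: dict[str, str], subgroup: str = "",
                    min_width: int = DEFAULT_MIN_WIDTH,
                    max_width: int = DEFAULT_MAX_WIDTH,
                    min_member_fraction: float = 1.0,
                    min_ic_per_col: float = DEFAULT_MIN_IC,
                    conservation_min: float = DEFAULT_CONSERVATION_MIN,
                    max_blocks: int = DEFAULT_MAX_BLOCKS) -> list[MotifBlock]:
    """Conserved ungapped blocks shared by one subgroup's C-terminal regions."""
    if len(sequences) < 2:
        raise ValueError("block discovery needs at least 2 member sequences")
    for sid, seq in sequences.items():
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid characters in {sid!r}: {sorted(bad)!r}")
    msa = center_star_align(sequences)
    ids = sorted(msa)
    rows = [msa[i] for i in ids]
    width_cols = len(rows[0])
    qualifying = []
    for c in range(width_cols):
        column = [r[c] for r in rows]
        gapless, majority, ic, _ = _column_stats(column)
        qualifying.append(gapless >= min_member_fraction
                          and majority >= conservation_min
                          and ic >= min_ic_per_col)
    blocks: list[MotifBlock] = []
    c = 0
    while c < width_cols:
        if not qualifying[c]:
            c += 1
            continue
        run_start = c
        while c < width_cols and qualifying[c]:
            c += 1
        run = list(range(run_start, c))
        if len(run) > max_width:
            run = _best_subwindow(rows, run, max_width)
        if len(run) < min_width:
            continue
        block = _build_block(ids, rows, run, subgroup, min_member_fraction)
        if block is not None:
            blocks.append(block)
    blocks.sort(key=lambda b: (-b.total_ic, b.consensus))
    return blocks[:max_blocks]


def _best_subwindow(rows: list[str], run: list[int], max_width: int) -> list[int]:
    """Highest-IC contiguous sub-window when a run exceeds the width cap."""
    ics = [_column_stats([r[c] for r in rows])[2] for c in run]
    best_start, best_total = 0, -1.0
    window = sum(ics[:max_width])
    for s in range(len(run) - max_width + 1):
        if s > 0:
            window += ics[s + max_width - 1] - ics[s - 1]
        if window > best_total:
            best_total, best_start = window, s
    return run[best_start:best_start + max_width]


def _build_block(ids: list[str], rows: list[str], run: list[int],
                 subgroup: str, min_member_fraction: float) -> MotifBlock | None:
    occurrences = []
    for sid, row in zip(ids, rows):
        if any(row[c] == GAP for c in run):
            continue
        start = sum(1 for c in range(run[0]) if row[c] != GAP) + 1
        occurrences.append((sid, start))
    if len(occurrences) / len(ids) < min_member_fraction:
        return None
    freqs = np.zeros((len(run), 20))
    consensus = []
    ics = np.zeros(len(run))
    occ_rows = [rows[ids.index(sid)] for sid, _ in occurrences]
    for k, c in enumerate(run):
        _, _, ic, f = _column_stats([r[c] for r in occ_rows])
        freqs[k] = f
        ics[k] = ic
        consensus.append(AMINO_ACIDS[int(f.argmax())])
    return MotifBlock(subgroup, "".join(consensus), len(run), freqs, ics,
                      tuple(occurrences))


def default_threshold(block: MotifBlock, background: np.ndarray | None = None) -> float:
    """Half of the block's maximum attainable log-odds score."""
    return 0.5 * block.max_score(background)


def scan_block(sequence: str, block: MotifBlock,
               score_threshold: float | None = None,
               background: np.ndarray | None = None,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[tuple[int, float]]:
    """All windows scoring >= threshold against the block's log-odds matrix.

    Returns (1-based start, score) sorted by descending score (ties by
    start).  Sequences shorter than the block width yield ``[]``.
    """
    if score_threshold is None:
        score_threshold = default_threshold(block, background)
    pssm = block.pssm(background, pseudocount)
    w = block.width
    if len(sequence) < w:
        return []
    idx = np.array([AMINO_ACIDS.index(c) for c in sequence])
    hits = []
    for s in range(len(sequence) - w + 1):
        score = float(pssm[np.arange(w), idx[s:s + w]].sum())
        if score >= score_threshold:
            hits.append((s + 1, score))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def write_meme(blocks: list[MotifBlock], handle) -> None:
    """Write blocks in MEME minimal text format (consumable by MAST etc.)."""
    handle.write("MEME version 4\n\n")
    handle.write("ALPHABET= " + AMINO_ACIDS + "\n\n")
    handle.write("Background letter frequencies\n")
    handle.write(" ".join(f"{a} {1/20:.5f}" for a in AMINO_ACIDS) + "\n\n")
    for i, block in enumerate(blocks, start=1):
        name = f"{block.subgroup or 'block'}-{i}"
        handle.write(f"MOTIF {name} {block.consensus}\n")
        handle.write(
            f"letter-probability matrix: alength= 20 w= {block.width} "
            f"nsites= {len(block.occurrences)} E= 0\n")
        for row in block.frequencies:
            handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        handle.write("\n")
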