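"""Progressive center-star multiple alignment over pairwise global alignments.

A deliberately simple aligner used for whole-protein trees and C-terminal
motif discovery: the center sequence (the one with the highest summed
pairwise alignment score against all others, ties to the smallest id) is
aligned pairwise against every other sequence with BLOSUM62 and needle-like
gap costs, and the pairwise gap patterns are merged into one master
alignment.  Center-star alignments are a documented simplification of a
full progressive aligner; for the low-divergence inputs this package
targets they are equivalent in practice.
"""

from __future__ import annotations

from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"


def make_protein_aligner() -> Align.PairwiseAligner:
    """Global protein aligner with EMBOSS-needle-like parameters."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_aligned_strings(a: str, b: str,
                             aligner: Align.PairwiseAligner | None = None) -> tuple[str, str]:
    """Aligned (gapped) strings of the best global alignment of ``a`` and ``b``."""
    aligner = aligner or make_protein_aligner()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _merge(master_rows: dict[str, str], center_id: str,
           c_aln: str, s_aln: str, new_id: str) -> dict[str, str]:
    """Merge one pairwise (center, new) alignment into the master alignment."""
    master_center = master_rows[center_id]
    out = {rid: [] for rid in master_rows}
    new_row: list[str] = []
    i = j = 0  # i over master columns, j over pairwise columns
    while i < len(master_center) or j < len(c_aln):
        m_gap = i < len(master_center) and master_center[i] == GAP
        p_gap = j < len(c_aln) and c_aln[j] == GAP
        if i < len(master_center) and m_gap:
            # master-only gap column: new sequence gets a gap here
            for rid in master_rows:
                out[rid].append(master_rows[rid][i])
            new_row.append(GAP)
            i += 1
        elif j < len(c_aln) and p_gap:
            # pairwise-only gap column: insert a gap column into the master
            for rid in master_rows:
                out[rid].append(GAP)
            new_row.append(s_aln[j])
            j += 1
        else:
            for rid in master_rows:
                out[rid].append(master_rows[rid][i])
            new_row.append(s_aln[j])
            i += 1
            j += 1
    merged = {rid: "".join(cols) for rid, cols in out.items()}
    merged[new_id] = "".join(new_row)
    return merged


def center_star_align(sequences: dict[str, str],
                      aligner: Align.PairwiseAligner | None = None) -> dict[str, str]:
    """Multiple alignment of ``sequences`` (id -> sequence), id -> gapped row."""
    ids = sorted(sequences)
    if not ids:
        return {}
    if len(ids) == 1:
        return {ids[0]: sequences[ids[0]]}
    aligner = aligner or make_protein_aligner()
    totals = {i: 0.0 for i in ids}
    for a, b in combinations(ids, 2):
        s = aligner.score(sequences[a], sequences[b])
        totals[a] += s
        totals[b] += s
    center = min(ids, key=lambda i: (-totals[i], i))
    rows = {center: sequences[center]}
    for other in ids:
        if other == center:
            continue
        c_aln, s_aln = pairwise_aligned_strings(rows[center].replace(GAP, ""),
                                                sequences[other], aligner)
        # re-express the pairwise center against the current master gaps
        rows = _merge(rows, center, c_aln, s_aln, other)
    return rows
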