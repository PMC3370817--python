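"""Tissue expression categorization and plant miRNA target prediction.

Expression input is an ordinal band-intensity table (genes x tissues, RT-PCR
style calls 0-3 by default).  Each gene falls into exactly one category:

* ``none`` — every tissue below the presence floor;
* ``preferential:<tissue>`` — a unique maximum at least ``preference_ratio``
  times the runner-up;
* ``balanced:<t1+t2+...>`` — the top tissues within the ratio of each other
  but not all tissues (e.g. approximately equal male/female catkins);
* ``ubiquitous`` — expressed everywhere with no preferred subset.

miRNA targets are predicted with the standard plant complementarity-penalty
convention: the reverse complement of the mature miRNA is slid along each
transcript; each position contributes 0 for a Watson-Crick pair, 0.5 for a
G:U wobble and 1.0 for a mismatch, doubled within the 5' core (miRNA
positions 2-13); windows with total penalty <= 4.0 (default) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_TISSUES = ("root", "stem", "leaf", "female_catkins", "male_catkins", "seed")

CATEGORY_NONE = "none"
CATEGORY_UBIQUITOUS = "ubiquitous"

DEFAULT_PRESENCE_FLOOR = 1.0
DEFAULT_PREFERENCE_RATIO = 2.0
DEFAULT_MAX_PENALTY = 4.0
CORE_SPAN = (2, 13)  # miRNA positions (1-based, 5' end) where penalties double

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def classify_expression(table: pd.DataFrame,
                        presence_floor: float = DEFAULT_PRESENCE_FLOOR,
                        preference_ratio: float = DEFAULT_PREFERENCE_RATIO) -> pd.Series:
    """Per-gene expression category from a genes x tissues intensity table."""
    if table.empty:
        raise ValueError("empty expression table")
    if (table.values < 0).any():
        raise ValueError("negative intensity in expression table")
    categories = {}
    for gene, row in table.iterrows():
        values = row.sort_values(ascending=False)
        top = values.iloc[0]
        if top < presence_floor:
            categories[gene] = CATEGORY_NONE
            continue
        second = values.iloc[1] if len(values) > 1 else 0.0
        if top >= preference_ratio * second and (len(values) < 2 or top > second):
            categories[gene] = f"preferential:{values.index[0]}"
            continue
        top_set = sorted(t for t, v in row.items()
                         if v >= presence_floor and v * preference_ratio >= top)
        if len(top_set) == len(row):
            categories[gene] = CATEGORY_UBIQUITOUS
        else:
            categories[gene] = "balanced:" + "+".join(top_set)
    return pd.Series(categories, name="category")


@dataclass(frozen=True)
class MirnaHit:
    mirna_id: str
    transcript_id: str
    start: int           # 1-based on the transcript
    penalty: float
    match_string: str    # per miRNA position 5'->3': '|' pair, 'o' wobble, '.' mismatch

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")


def _normalize_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters in {what}: {sorted(bad)!r}")
    return seq


def pair_penalty(mirna_base: str, transcript_base: str) -> float:
    """0 for Watson-Crick, 0.5 for G:U wobble, 1.0 for a mismatch."""
    if _COMPLEMENT[mirna_base] == transcript_base:
        return 0.0
    if {mirna_base, transcript_base} == {"G", "U"}:
        return 0.5
    return 1.0


def score_window(mirna: str, window: str) -> tuple[float, str]:
    """Penalty and match string of one miRNA/transcript window (antiparallel)."""
    m = len(mirna)
    penalty = 0.0
    marks = []
    for i in range(1, m + 1):  # miRNA position, 5'->3'
        mb = mirna[i - 1]
        tb = window[m - i]  # antiparallel pairing
        p = pair_penalty(mb, tb)
        if CORE_SPAN[0] <= i <= CORE_SPAN[1]:
            p *= 2.0
        penalty += p
        marks.append("|" if p == 0 else ("o" if pair_penalty(mb, tb) == 0.5 else "."))
    return penalty, "".join(marks)


def predict_targets(mirna: str, transcripts: dict[str, str],
                    max_penalty: float = DEFAULT_MAX_PENALTY,
                    mirna_id: str = "miRNA") -> list[MirnaHit]:
    """Complementarity-scored miRNA target sites across transcripts."""
    mirna = _normalize_rna(mirna, "miRNA")
    if not 19 <= len(mirna) <= 24:
        raise ValueError("mature miRNA length must be within 19-24 nt")
    m = len(mirna)
    hits = []
    for tid in sorted(transcripts):
        seq = _normalize_rna(transcripts[tid], f"transcript {tid!r}")
        for s in range(len(seq) - m + 1):
            penalty, marks = score_window(mirna, seq[s:s + m])
            if penalty <= max_penalty:
                hits.append(MirnaHit(mirna_id, tid, s + 1, penalty, marks))
    hits.sort(key=lambda h: (h.penalty, h.transcript_id, h.start))
    return hits
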