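"""Landmark-based detection and profiling of the R2R3-MYB DNA-binding domain.

The plant R2R3-MYB DNA-binding domain (DBD) is a ~108-residue region made of
two imperfect MYB repeats (R2, R3), each folding into three alpha-helices.
A small set of structurally critical residues is nearly invariant across
plant families and can be used as *landmarks* to recognize the domain
without any external database:

* tryptophans at domain positions 9, 29 and 49 (R2) and 62, 81 and 100 (R3),
  which pack into the hydrophobic core.  Position 62 is the one tolerant
  landmark: when substituted the replacement is almost always hydrophobic
  (F, less often I, L or Y), so the scanner accepts {W, F, I, L, Y} there;
* a completely conserved cysteine at position 45 in the DNA-recognition
  helix of R2.  A second cysteine at position 41 is frequent but substituted
  in a sizable minority of family members, so it is tracked but not scored;
* an L-R-P-[DN] linker motif at positions 53-56 between the repeats;
* a single-residue insertion (Leu in most members, Gly otherwise) between
  the second and third helices of R2, fixed at one model position.

A candidate window scores one point per matched landmark (six tryptophan
positions plus Cys-45, hence 0-7) and is reported when the score reaches a
configurable threshold.  This landmark score replaces similarity-search
E-values as the acceptance statistic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Canonical plant R2R3-MYB domain consensus, 108 residues, with the
#: tryptophan/cysteine landmarks, LRPD linker and R2 Leu insertion at the
#: model positions documented in :class:`DomainModel`.
CONSENSUS = (
    "SRKGLATD" "W"                      # 1-9
    "TEEEDKLLVDYITAHGEGN" "W"           # 10-29
    "RSLPKRAGL" "NR"                    # 30-40 (insertion Leu at 38)
    "C" "GKS" "C" "RLR"                 # 41-48
    "W" "TNY"                           # 49-52
    "LRPD"                              # 53-56 linker
    "IKRGN" "W"                         # 57-62
    "TKEEEDRIIELHAKLGNK" "W"            # 63-81
    "AEIAKRLPGRTDNEIKNY" "W"            # 82-100
    "NTHLRKKL"                          # 101-108
)


@dataclass(frozen=True)
class DomainModel:
    """Landmark specification of the ~108-residue R2R3 domain.

    All positions are 1-based domain coordinates.  ``helices`` are
    descriptive defaults (the precise helix boundaries vary slightly among
    members) and are not used for scoring.
    """

    length: int = 108
    trp_landmarks: tuple[int, ...] = (9, 29, 49, 62, 81, 100)
    position62: int = 62
    position62_classes: frozenset[str] = frozenset("WFILY")
    cys_landmarks: tuple[int, ...] = (41, 45)
    scoring_cys: int = 45
    linker_span: tuple[int, int] = (53, 56)
    linker_consensus: tuple[str, ...] = ("L", "R", "P", "DN")
    r2_span: tuple[int, int] = (1, 52)
    r3_span: tuple[int, int] = (57, 108)
    insertion_position: int = 38
    insertion_classes: frozenset[str] = frozenset("LG")
    helices: tuple[tuple[str, int, int], ...] = (
        ("R2-helix1", 10, 22),
        ("R2-helix2", 26, 37),
        ("R2-helix3", 39, 50),
        ("R3-helix1", 63, 74),
        ("R3-helix2", 77, 88),
        ("R3-helix3", 90, 102),
    )
    consensus: str = CONSENSUS

    def __post_init__(self) -> None:
        marks = self.scored_landmarks()
        positions = [p for p, _ in marks]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("landmark positions must be strictly increasing")
        if positions[-1] > self.length:
            raise ValueError("landmark position beyond domain length")
        if not self.r2_span[1] < self.r3_span[0]:
            raise ValueError("R2 and R3 spans must be disjoint and ordered")
        if not (self.r2_span[1] < self.linker_span[0] <= self.linker_span[1] < self.r3_span[0]):
            raise ValueError("linker must lie between the repeat spans")
        if len(self.consensus) != self.length:
            raise ValueError("consensus length does not match model length")

    def scored_landmarks(self) -> list[tuple[int, frozenset[str]]]:
        """The seven scoring positions and their accepted residue sets."""
        marks = []
        for p in self.trp_landmarks:
            allowed = self.position62_classes if p == self.position62 else frozenset("W")
            marks.append((p, allowed))
        marks.append((self.scoring_cys, frozenset("C")))
        return sorted(marks)

    def protected_positions(self) -> frozenset[int]:
        """Positions the synthetic generator never mutates by default."""
        pos = set(self.trp_landmarks) | set(self.cys_landmarks)
        pos.update(range(self.linker_span[0], self.linker_span[1] + 1))
        pos.add(self.insertion_position)
        return frozenset(pos)


@dataclass
class DomainHit:
    """One detected R2R3 domain window on a protein (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    landmark_score: int
    matched: tuple[int, ...]
    missed: tuple[int, ...]
    position62_residue: str
    insertion_residue: str | None = None
    cys41_residue: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class ResidueProfile:
    """Per-position residue frequencies over a set of mapped domains."""

    model: DomainModel
    n_sequences: int
    frequencies: np.ndarray  # (length, 21): 20 amino acids + gap
    majority: str
    conservation: np.ndarray  # (length,) fraction of majority residue
    excluded: tuple[str, ...] = ()

    ALPHABET = AMINO_ACIDS + GAP


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)!r}")


def _score_window(sequence: str, start0: int, model: DomainModel,
                  delta: int, pivot_index: int) -> tuple[int, list[int], list[int]] | None:
    """Score one window interpretation.

    ``delta``/``pivot_index`` implement the single-indel tolerance: scored
    landmarks at or after ``pivot_index`` are shifted by ``delta`` (+1 models
    an insertion upstream of them, -1 a deletion).  ``delta == 0`` is the
    plain ungapped interpretation.
    """
    marks = model.scored_landmarks()
    end0 = start0 + model.length + delta
    if end0 > len(sequence):
        return None
    matched, missed = [], []
    for idx, (pos, allowed) in enumerate(marks):
        offset = delta if idx >= pivot_index else 0
        i = start0 + pos - 1 + offset
        if i < start0 or i >= end0:
            missed.append(pos)
            continue
        (matched if sequence[i] in allowed else missed).append(pos)
    return len(matched), matched, missed


def scan_protein(sequence: str, model: DomainModel | None = None,
                 min_score: int = 5) -> list[DomainHit]:
    """Scan a protein for R2R3 domain windows with landmark score >= ``min_score``.

    Every start position is evaluated ungapped and under every single-indel
    interpretation (window width 107-109); the best-scoring interpretation
    defines the window.  Overlapping qualifying windows are resolved by
    keeping the higher score, ties going to the leftmost window.  Sequences
    shorter than the model return an empty list.
    """
    model = model or DomainModel()
    if not 1 <= min_score <= 7:
        raise ValueError("min_score must be within [1, 7]")
    _validate_sequence(sequence)
    n_marks = len(model.scored_landmarks())
    candidates: list[DomainHit] = []
    # a single-deletion window is one residue narrower than the model
    max_start = len(sequence) - (model.length - 2)
    for s in range(max(0, max_start)):
        best = None  # (score, |delta|, pivot, delta, matched, missed)
        for delta, pivots in ((0, (0,)), (1, range(1, n_marks)), (-1, range(1, n_marks))):
            for pivot in pivots:
                scored = _score_window(sequence, s, model, delta, pivot)
                if scored is None:
                    continue
                score, matched, missed = scored
                key = (-score, abs(delta), pivot)
                if best is None or key < best[0]:
                    best = (key, delta, matched, missed)
        if best is None:
            continue
        (negscore, _, pivot), delta, matched, missed = best
        score = -negscore
        if score < min_score:
            continue
        marks = model.scored_landmarks()
        pivot_pos = marks[pivot][0] if 0 < pivot < len(marks) else 10**9

        def residue_at(pos: int) -> str | None:
            i = s + pos - 1 + (delta if pos >= pivot_pos else 0)
            return sequence[i] if 0 <= i < len(sequence) else None

        hit = DomainHit(
            protein_id="",
            start=s + 1,
            end=s + model.length + delta,
            landmark_score=score,
            matched=tuple(matched),
            missed=tuple(missed),
            position62_residue=residue_at(model.position62),
            insertion_residue=residue_at(model.insertion_position),
            cys41_residue=residue_at(model.cys_landmarks[0]),
        )
        candidates.append(hit)
    # overlap resolution: higher score wins; at equal score prefer the
    # ungapped (model-width) interpretation, then the leftmost window
    kept: list[DomainHit] = []
    for hit in sorted(candidates,
                      key=lambda h: (-h.landmark_score,
                                     abs(h.width - model.length), h.start)):
        if all(hit.end < k.start or hit.start > k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


@dataclass
class FilterResult:
    """Outcome of family-membership filtering."""

    accepted: tuple[str, ...]
    atypical: tuple[str, ...]  # >1 domain window (3-repeat-like variants)
    rejected: dict[str, str] = field(default_factory=dict)


def filter_candidates(hits: dict[str, list[DomainHit]],
                      proteins: dict[str, str],
                      loci: dict[str, tuple[str, int, int]]) -> FilterResult:
    """Apply the family-membership rules to scanned proteins.

    A protein is accepted when it encodes a complete ORF (leading Met, no
    internal stop), carries exactly one R2R3 domain window, and maps to a
    locus not overlapping a higher-scoring accepted locus.  Proteins with
    two or more windows (three-repeat-like variants) are flagged separately.
    """
    accepted: list[tuple[str, int]] = []
    atypical: list[str] = []
    rejected: dict[str, str] = {}
    for pid in sorted(proteins):
        if pid not in loci:
            raise KeyError(f"no locus registered for protein {pid!r}")
        seq = proteins[pid].rstrip("*")
        phits = hits.get(pid, [])
        if not seq.startswith("M") or "*" in seq:
            rejected[pid] = "incomplete_orf"
            continue
        if len(phits) == 0:
            rejected[pid] = "no_domain"
            continue
        if len(phits) > 1:
            atypical.append(pid)
            continue
        accepted.append((pid, phits[0].landmark_score))
    # locus redundancy: keep the best-scoring representative per overlapping locus
    accepted.sort(key=lambda t: (-t[1], t[0]))
    kept: list[tuple[str, int]] = []
    for pid, score in accepted:
        chrom, start, end = loci[pid]
        clash = None
        for kpid, _ in kept:
            kchrom, kstart, kend = loci[kpid]
            if chrom == kchrom and start <= kend and kstart <= end:
                clash = kpid
                break
        if clash is None:
            kept.append((pid, score))
        else:
            rejected[pid] = f"redundant_locus:{clash}"
    return FilterResult(
        accepted=tuple(sorted(pid for pid, _ in kept)),
        atypical=tuple(sorted(atypical)),
        rejected=rejected,
    )


def profile_alignment(domains: dict[str, str],
                      model: DomainModel | None = None,
                      length_tolerance: int = 0) -> tuple[ResidueProfile, dict]:
    """Column-wise residue profile plus conservation summary statistics.

    Sequences whose length deviates from the model by more than
    ``length_tolerance`` cannot be mapped position-for-position and are
    reported in ``profile.excluded`` (and the stats) rather than aborting.

    The summary reports the position-62 residue distribution (the one
    routinely substituted tryptophan landmark), conservation fractions of
    the two R2 cysteines, the linker-motif match fraction, and the
    insertion-site residue counts (Leu vs Gly vs other).
    """
    model = model or DomainModel()
    usable = {k: v for k, v in sorted(domains.items())
              if abs(len(v) - model.length) <= length_tolerance and len(v) == model.length}
    excluded = tuple(k for k in sorted(domains) if k not in usable)
    if len(usable) < 2:
        raise ValueError("profiling needs at least 2 mappable domain sequences")
    alpha = ResidueProfile.ALPHABET
    index = {a: i for i, a in enumerate(alpha)}
    counts = np.zeros((model.length, len(alpha)))
    for seq in usable.values():
        for i, aa in enumerate(seq):
            counts[i, index.get(aa, index[GAP])] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    maj_idx = freqs.argmax(axis=1)
    majority = "".join(alpha[i] for i in maj_idx)
    conservation = freqs[np.arange(model.length), maj_idx]
    profile = ResidueProfile(model, len(usable), freqs, majority, conservation, excluded)

    n = len(usable)
    p62 = Counter(seq[model.position62 - 1] for seq in usable.values())
    c41, c45 = model.cys_landmarks
    lspan = range(model.linker_span[0] - 1, model.linker_span[1])
    linker_ok = sum(
        all(seq[i] in cons for i, cons in zip(lspan, model.linker_consensus))
        for seq in usable.values()
    )
    ins = Counter(seq[model.insertion_position - 1] for seq in usable.values())
    stats = {
        "n_sequences": n,
        "excluded": excluded,
        "position62_counts": dict(p62),
        "position62_substitution_fraction": 1.0 - p62.get("W", 0) / n,
        "cys41_conserved_fraction": sum(
            1 for s in usable.values() if s[c41 - 1] == "C") / n,
        "cys45_conserved_fraction": sum(
            1 for s in usable.values() if s[c45 - 1] == "C") / n,
        "linker_match_fraction": linker_ok / n,
        "insertion_counts": {
            "L": ins.get("L", 0),
            "G": ins.get("G", 0),
            "other": n - ins.get("L", 0) - ins.get("G", 0),
        },
    }
    return profile, stats


# ---------------------------------------------------------------------------
# Named motif patterns in the field's class/wildcard notation, e.g. the
# bHLH-interaction motif "[DE]Lx2[RK]x3Lx6Lx3R" and the MIXTA-like motif
# "AQWESARxxAExRLxRES".  "x" is a single-position wildcard; a letter or a
# bracketed class may be followed by a repeat count.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NamedMotifPattern:
    name: str
    text: str
    positions: tuple[frozenset[str] | None, ...]  # None = wildcard

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def n_specified(self) -> int:
        return sum(1 for p in self.positions if p is not None)


_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Zx])|(\d+)|(.)")


def parse_motif_pattern(text: str, name: str = "") -> NamedMotifPattern:
    """Compile a class/wildcard pattern string into per-position residue sets."""
    if not text:
        raise ValueError("empty motif pattern")
    if text.count("[") != text.count("]"):
        raise ValueError(f"unbalanced bracket in pattern {text!r}")
    positions: list[frozenset[str] | None] = []
    last: frozenset[str] | None | str = "NONE"
    for m in _TOKEN.finditer(text):
        cls, letter, digits, bad = m.groups()
        if bad is not None:
            raise ValueError(f"unexpected token {bad!r} in pattern {text!r}")
        if digits is not None:
            if last == "NONE":
                raise ValueError(f"repeat count {digits!r} without a preceding position")
            positions.extend([last] * (int(digits) - 1))  # type: ignore[list-item]
            last = "NONE"
            continue
        if cls is not None:
            if not set(cls) <= set(AMINO_ACIDS):
                raise ValueError(f"invalid residue class [{cls}] in pattern {text!r}")
            last = frozenset(cls)
        elif letter == "x":
            last = None
        else:
            if letter not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {letter!r} in pattern {text!r}")
            last = frozenset(letter)
        positions.append(last)  # type: ignore[arg-type]
    pattern = NamedMotifPattern(name or text, text, tuple(positions))
    if pattern.n_specified == 0:
        raise ValueError(f"pattern {text!r} has no specified position")
    return pattern


#: Named consensus motifs scanned alongside the domain model.
BHLH_INTERACTION = parse_motif_pattern("[DE]Lx2[RK]x3Lx6Lx3R", name="bHLH-interaction")
MIXTA = parse_motif_pattern("AQWESARxxAExRLxRES", name="MIXTA")


def scan_named_motif(sequence: str, pattern: NamedMotifPattern) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences of ``pattern``, 1-based inclusive."""
    _validate_sequence(sequence)
    regex = "".join(
        "." if p is None else "[" + "".join(sorted(p)) + "]" for p in pattern.positions
    )
    return [
        (m.start() + 1, m.start() + pattern.length)
        for m in re.finditer(f"(?=({regex}))", sequence)
    ]
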