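"""Intron extraction, splicing phases, and intron-pattern classification.

Plant R2R3-MYB genes show a strikingly conserved exon/intron organization
inside the DNA-binding domain (DBD): most members carry one or two introns
at fixed domain sites with fixed splicing phases, and the family can be
partitioned into a small taxonomy of intron patterns (labeled ``a``-``l``).
The most common pattern (``a``) has three exons and two introns, the R2-site
intron splicing in phase 1 and the R3-site intron in phase 2; pattern ``d``
has no intron in the DBD at all.

Conventions
-----------
* All genomic coordinates are GFF3-style 1-based inclusive.
* The splicing *phase* of an intron is the number of coding nucleotides 5'
  of it modulo 3 (0 = between codons, 1/2 = after the first/second base of
  a codon).  Note this is the codon-interruption convention; the GFF3 CDS
  ``phase`` column instead gives the offset to the next codon start, and
  the two are related by ``intron_phase = (3 - cds_phase) % 3`` for the CDS
  segment following the intron (see :func:`intron_phase_from_gff3_phase`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]

OUTSIDE = "outside-domain"
UNCLASSIFIED = "unclassified"


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    """One locus: chromosome, strand and its transcript structures."""

    gene_id: str
    chrom: str
    strand: str
    start: int = 0
    end: int = 0
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def representative_transcript(self) -> Transcript:
        """Longest-CDS transcript (ties broken by transcript id)."""
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return min(self.transcripts.values(),
                   key=lambda t: (-t.cds_length(), t.transcript_id))


@dataclass(frozen=True)
class IntronAnnotation:
    """An intron located in coding orientation, 5'->3'."""

    index: int                 # 1-based, coding order
    start: int                 # genomic, 1-based inclusive
    end: int
    upstream_cds_nt: int       # coding nucleotides 5' of the splice
    phase: int                 # upstream_cds_nt % 3

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")


def extract_introns(gene: GeneModel, transcript_id: str | None = None) -> list[IntronAnnotation]:
    """Introns of a transcript as gaps between consecutive CDS intervals.

    Returned in coding (5'->3') order with the cumulative upstream CDS
    length and phase precomputed.  A single-interval CDS yields ``[]``.
    """
    tx = (gene.transcripts[transcript_id] if transcript_id is not None
          else gene.representative_transcript())
    if not tx.cds:
        raise ValueError(f"transcript {tx.transcript_id} has no CDS")
    cds = sorted(tx.cds)
    for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
        if s2 <= e1:
            raise ValueError(
                f"overlapping CDS intervals in {tx.transcript_id}: "
                f"({s1},{e1}) and ({s2},{e2})")
    gaps = [(e1 + 1, s2 - 1) for (s1, e1), (s2, e2) in zip(cds, cds[1:])]
    lengths = [e - s + 1 for s, e in cds]
    if gene.strand == "-":
        gaps = gaps[::-1]
        lengths = lengths[::-1]
    introns = []
    upstream = 0
    for i, (g, ln) in enumerate(zip(gaps, lengths[:-1]), start=1):
        upstream += ln
        introns.append(IntronAnnotation(
            index=i, start=g[0], end=g[1],
            upstream_cds_nt=upstream, phase=upstream % 3))
    return introns


def compute_intron_phase(upstream_cds_nt: int) -> int:
    """Splicing phase: coding nucleotides 5' of the intron, modulo 3."""
    if upstream_cds_nt < 0:
        raise ValueError("upstream CDS nucleotide count must be non-negative")
    return upstream_cds_nt % 3


def intron_phase_from_gff3_phase(cds_phase: int) -> int:
    """Convert the GFF3 ``phase`` column of the CDS segment *after* an intron."""
    if cds_phase not in (0, 1, 2):
        raise ValueError("GFF3 phase must be 0, 1 or 2")
    return (3 - cds_phase) % 3


def map_intron_to_domain(upstream_cds_nt: int, domain_start: int,
                         domain_end: int, protein_length: int | None = None) -> int | str:
    """Domain-relative amino-acid position of an intron, or ``outside-domain``.

    The position is the 1-based index (relative to the domain start) of the
    codon the intron interrupts, or of the preceding codon for phase-0
    introns.  ``domain_start``/``domain_end`` are 1-based protein coordinates.
    """
    if protein_length is not None and upstream_cds_nt > 3 * protein_length + 3:
        raise ValueError("intron position beyond the protein's CDS length")
    phase = compute_intron_phase(upstream_cds_nt)
    aa = upstream_cds_nt // 3 if phase == 0 else upstream_cds_nt // 3 + 1
    if domain_start <= aa <= domain_end:
        return aa - domain_start + 1
    return OUTSIDE


# ---------------------------------------------------------------------------
# Pattern taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSite:
    """A domain-site window (1-based, inclusive, tolerance included) + phase."""

    name: str
    lo: int
    hi: int
    phase: int


@dataclass
class PatternTaxonomy:
    """Ordered intron-pattern labels with their required site/phase sets.

    A gene matches a label when its domain-internal introns can be put in
    one-to-one correspondence with the label's sites (position inside the
    window, equal phase) with nothing left over.  The empty requirement set
    is the no-intron pattern.  Validation rejects taxonomies in which one
    intron configuration could satisfy two labels.
    """

    labels: tuple[str, ...]
    requirements: dict[str, tuple[PatternSite, ...]]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxonomy labels")
        if set(self.labels) != set(self.requirements):
            raise ValueError("labels and requirements out of sync")
        for a in self.labels:
            for b in self.labels:
                if a < b and self._compatible(self.requirements[a], self.requirements[b]):
                    raise ValueError(f"ambiguous taxonomy: labels {a!r} and {b!r} "
                                     "can match the same intron configuration")

    @staticmethod
    def _compatible(sa: tuple[PatternSite, ...], sb: tuple[PatternSite, ...]) -> bool:
        """True if one intron set could satisfy both requirement lists."""
        if len(sa) != len(sb):
            return False
        return _has_perfect_matching(
            [[j for j, b in enumerate(sb)
              if a.phase == b.phase and a.lo <= b.hi and b.lo <= a.hi]
             for a in sa], len(sb))

    def sites(self) -> dict[str, PatternSite]:
        out: dict[str, PatternSite] = {}
        for req in self.requirements.values():
            for s in req:
                out.setdefault(s.name, s)
        return out


def _has_perfect_matching(adjacency: list[list[int]], n_right: int) -> bool:
    """Bipartite perfect matching (tiny instances; Hungarian is overkill)."""
    match_right: dict[int, int] = {}

    def augment(i: int, seen: set[int]) -> bool:
        for j in adjacency[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_right or augment(match_right[j], seen):
                match_right[j] = i
                return True
        return False

    return all(augment(i, set()) for i in range(len(adjacency)))


#: Default taxonomy config (editable plain-text table).  Columns:
#: label <TAB> comma-separated site requirements "name:lo-hi:phase", or "-"
#: for the no-intron pattern.  Windows already include the +-2 tolerance.
#: The R2 and R3 sites carry the canonical phases (1 and 2); the remaining
#: patterns encode qualitative presence/position/phase combinations.
DEFAULT_TAXONOMY_TEXT = """\
a\tR2:45-50:1,R3:93-100:2
b\tR3:93-100:2
c\tR2:45-50:1
d\t-
e\tE1:12-18:0,R2:45-50:1,R3:93-100:2
f\tE1:12-18:0
g\tE2:30-36:1
h\tE3:66-72:0
i\tE1:12-18:0,R3:93-100:2
j\tE2:30-36:1,R3:93-100:2
k\tR2:45-50:1,E3:66-72:0
l\tE2:30-36:1,R2:45-50:1,R3:93-100:2,E3:66-72:0
"""


def load_taxonomy(text: str | None = None) -> PatternTaxonomy:
    """Parse a taxonomy config table (defaults to the shipped 12-pattern one)."""
    text = DEFAULT_TAXONOMY_TEXT if text is None else text
    labels: list[str] = []
    requirements: dict[str, tuple[PatternSite, ...]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            label, spec = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"malformed taxonomy line {line!r}") from exc
        sites: list[PatternSite] = []
        if spec != "-":
            for token in spec.split(","):
                name, window, phase = token.split(":")
                lo, hi = window.split("-")
                sites.append(PatternSite(name, int(lo), int(hi), int(phase)))
        labels.append(label)
        requirements[label] = tuple(sites)
    return PatternTaxonomy(tuple(labels), requirements)


def default_taxonomy() -> PatternTaxonomy:
    return load_taxonomy()


def classify_pattern(domain_introns: list[tuple[int, int]],
                     taxonomy: PatternTaxonomy | None = None) -> str:
    """Pattern label for a gene's domain-internal introns.

    ``domain_introns`` are (domain_position, phase) pairs; introns outside
    the domain must already be excluded.  Returns ``unclassified`` when no
    label's requirements are met.
    """
    taxonomy = taxonomy or default_taxonomy()
    for label in taxonomy.labels:
        sites = taxonomy.requirements[label]
        if len(sites) != len(domain_introns):
            continue
        adjacency = [
            [j for j, s in enumerate(sites) if s.lo <= pos <= s.hi and s.phase == phase]
            for pos, phase in domain_introns
        ]
        if _has_perfect_matching(adjacency, len(sites)):
            return label
    return UNCLASSIFIED


def classify_gene(gene: GeneModel, domain_start: int, domain_end: int,
                  taxonomy: PatternTaxonomy | None = None,
                  transcript_id: str | None = None) -> tuple[str, list[tuple[int, int]]]:
    """Extract, map and classify a gene's domain introns in one step."""
    introns = extract_introns(gene, transcript_id)
    mapped = []
    for intr in introns:
        pos = map_intron_to_domain(intr.upstream_cds_nt, domain_start, domain_end)
        if pos != OUTSIDE:
            mapped.append((pos, intr.phase))
    return classify_pattern(mapped, taxonomy), mapped


def count_transcript_variants(genes: dict[str, GeneModel]) -> dict[str, int]:
    """Distinct transcript structures (ordered exon interval lists) per gene."""
    counts = {}
    for gid, gene in genes.items():
        structures = {tuple(sorted(tx.exons)) for tx in gene.transcripts.values()}
        counts[gid] = len(structures)
    return counts
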