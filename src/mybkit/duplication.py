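"""Paralog clustering and tandem/segmental duplication classification.

Paralog clusters are single-linkage components over gene pairs whose
global-alignment identity passes *both* thresholds: >= 90% within the
DNA-binding domain and >= 60% over the whole protein (the family's
conventional cluster criterion; "similarity" is operationalized as
global-alignment identity, which is reproducible and parameter-light).

A threshold-passing pair is *tandem* when the two genes sit on the same
chromosome either within two intervening gene ranks or within a configurable
physical separation (250 kb by default); it is *segmental* when not tandem
and either on different chromosomes or, when a duplicated-block file is
supplied, both inside a paired block; otherwise it is *unclassified*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .align import make_protein_aligner, pairwise_aligned_strings

TANDEM = "tandem"
SEGMENTAL = "segmental"
UNCLASSIFIED = "unclassified"

DEFAULT_DBD_THRESHOLD = 90.0
DEFAULT_FULL_THRESHOLD = 60.0
DEFAULT_TANDEM_MAX_SEPARATION = 250_000
DEFAULT_MAX_INTERVENING = 2


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    rank: int  # 0-based index among genes on its chromosome, by start

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus {self.gene_id}: start > end")


def build_loci(positions: dict[str, tuple[str, int, int]]) -> dict[str, GeneLocus]:
    """Rank genes per chromosome by start coordinate and build loci."""
    by_chrom: dict[str, list[str]] = {}
    for gid, (chrom, _, _) in positions.items():
        by_chrom.setdefault(chrom, []).append(gid)
    loci = {}
    for chrom, gids in by_chrom.items():
        gids.sort(key=lambda g: (positions[g][1], g))
        for rank, gid in enumerate(gids):
            _, start, end = positions[gid]
            loci[gid] = GeneLocus(gid, chrom, start, end, rank)
    return loci


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Global-alignment identity in percent: matches / alignment columns,
    gap columns included."""
    aligner = aligner or make_protein_aligner()
    ra, rb = pairwise_aligned_strings(a, b, aligner)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return 100.0 * matches / len(ra)


@dataclass
class ParalogCluster:
    members: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]  # threshold-passing linked pairs
    classifications: dict[tuple[str, str], str] = field(default_factory=dict)


def cluster_paralogs(dbd_identity: dict[tuple[str, str], float],
                     full_identity: dict[tuple[str, str], float],
                     dbd_threshold: float = DEFAULT_DBD_THRESHOLD,
                     full_threshold: float = DEFAULT_FULL_THRESHOLD) -> list[ParalogCluster]:
    """Single-linkage clusters over pairs passing both identity thresholds.

    Identity mappings are keyed by sorted gene-id pairs.  Singletons are not
    reported.
    """
    passing = []
    for pair in sorted(dbd_identity):
        if pair not in full_identity:
            continue
        if dbd_identity[pair] >= dbd_threshold and full_identity[pair] >= full_threshold:
            passing.append(tuple(sorted(pair)))
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in passing:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    components: dict[str, set[str]] = {}
    for a, b in passing:
        components.setdefault(find(a), set()).update((a, b))
    clusters = []
    for root in sorted(components):
        members = tuple(sorted(components[root]))
        pairs = tuple(p for p in passing if p[0] in members)
        clusters.append(ParalogCluster(members, pairs))
    return clusters


def classify_pair(a: GeneLocus, b: GeneLocus,
                  tandem_max_separation: int = DEFAULT_TANDEM_MAX_SEPARATION,
                  max_intervening: int = DEFAULT_MAX_INTERVENING,
                  block_pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]] | None = None,
                  known_chroms: set[str] | None = None) -> str:
    """Tandem / segmental / unclassified call for one linked gene pair."""
    if known_chroms is not None:
        for locus in (a, b):
            if locus.chrom not in known_chroms:
                raise ValueError(f"locus {locus.gene_id} on unknown chromosome {locus.chrom}")
    if a.chrom == b.chrom:
        intervening = abs(a.rank - b.rank) - 1
        separation = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
        if intervening <= max_intervening or separation <= tandem_max_separation:
            return TANDEM
        if block_pairs and _in_paired_blocks(a, b, block_pairs):
            return SEGMENTAL
        return UNCLASSIFIED
    if block_pairs:
        return SEGMENTAL if _in_paired_blocks(a, b, block_pairs) else UNCLASSIFIED
    return SEGMENTAL


def _within(locus: GeneLocus, block: tuple[str, int, int]) -> bool:
    chrom, s, e = block
    return locus.chrom == chrom and s <= locus.start and locus.end <= e


def _in_paired_blocks(a: GeneLocus, b: GeneLocus, block_pairs) -> bool:
    return any(
        (_within(a, p) and _within(b, q)) or (_within(a, q) and _within(b, p))
        for p, q in block_pairs
    )


def classify_clusters(clusters: list[ParalogCluster], loci: dict[str, GeneLocus],
                      **kwargs) -> list[ParalogCluster]:
    """Fill per-pair classifications in place (and return the clusters)."""
    known = {l.chrom for l in loci.values()}
    for cluster in clusters:
        for a, b in cluster.pairs:
            cluster.classifications[(a, b)] = classify_pair(
                loci[a], loci[b], known_chroms=known, **kwargs)
    return clusters


def summarize_events(clusters: list[ParalogCluster]) -> dict[str, int]:
    """Event census: cluster count, tandem genes/arrays, segmental pairs.

    A tandem array is a maximal set of genes connected by tandem-classified
    pairs; ``n_segmental_pairs`` counts segmental-classified linked pairs.
    """
    tandem_adj: dict[str, set[str]] = {}
    n_segmental = 0
    for cluster in clusters:
        for (a, b), call in cluster.classifications.items():
            if call == TANDEM:
                tandem_adj.setdefault(a, set()).add(b)
                tandem_adj.setdefault(b, set()).add(a)
            elif call == SEGMENTAL:
                n_segmental += 1
    seen: set[str] = set()
    arrays = []
    for start in sorted(tandem_adj):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            g = stack.pop()
            if g in comp:
                continue
            comp.add(g)
            stack.extend(tandem_adj[g] - comp)
        seen |= comp
        arrays.append(comp)
    return {
        "n_clusters": len(clusters),
        "n_tandem_genes": sum(len(a) for a in arrays),
        "n_tandem_arrays": len(arrays),
        "n_segmental_pairs": n_segmental,
    }


def identity_matrices(proteins: dict[str, str],
                      domains: dict[str, tuple[int, int]],
                      aligner=None) -> tuple[dict, dict]:
    """Full-length and DBD identity mappings for all protein pairs.

    ``domains`` maps gene id -> (start, end) of its domain hit (1-based,
    inclusive); a missing domain raises, since DBD identity is undefined.
    """
    aligner = aligner or make_protein_aligner()
    full: dict[tuple[str, str], float] = {}
    dbd: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(proteins), 2):
        for gid in (a, b):
            if gid not in domains:
                raise KeyError(f"no domain hit for protein {gid!r}: DBD identity undefined")
        full[(a, b)] = pairwise_identity(proteins[a], proteins[b], aligner)
        da = proteins[a][domains[a][0] - 1: domains[a][1]]
        db = proteins[b][domains[b][0] - 1: domains[b][1]]
        dbd[(a, b)] = pairwise_identity(da, db, aligner)
    return full, dbd
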