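"""Synthetic gene families with planted, machine-checkable ground truth.

The generator emulates the features of a plant R2R3-MYB family that the
analysis stages measure, without attempting sequence realism: every gene's
protein carries one R2R3 domain derived from the canonical consensus
(landmark residues never mutated unless explicitly overridden), introns are
inserted at the taxonomy-configured domain sites with the configured
phases, subgroups diverge by disjoint sets of marker substitutions so that
between-subgroup distance dominates within-subgroup noise, tandem arrays
are near-identical copies placed 2-50 kb apart on one chromosome, segmental
pairs are near-identical copies on different chromosomes, each subgroup
appends its own C-terminal motif, and each gene is assigned a tissue
expression category realized later by :func:`generate_expression`.

Everything is driven by a single integer seed; a fixed spec and seed
reproduce byte-identical FASTA/GFF3 outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .domain import CONSENSUS, AMINO_ACIDS, DomainModel
from .genestruct import GeneModel, PatternTaxonomy, Transcript, default_taxonomy
from .profiles import DEFAULT_TISSUES

#: Family-scale mixture of intron patterns: the canonical two-intron pattern
#: dominates (~44%), the two single-intron derivatives and the intron-less
#: pattern are the other major classes, the rest are rare.
DEFAULT_PATTERN_MIX = {
    "a": 0.44, "b": 0.12, "c": 0.11, "d": 0.13,
    "e": 0.04, "f": 0.03, "g": 0.03, "h": 0.02,
    "i": 0.02, "j": 0.02, "k": 0.02, "l": 0.02,
}

DEFAULT_EXPRESSION_MIX = {
    "ubiquitous": 0.35,
    "none": 0.05,
    "preferential:root": 0.08,
    "preferential:stem": 0.10,
    "preferential:leaf": 0.09,
    "preferential:seed": 0.10,
    "preferential:female_catkins": 0.07,
    "preferential:male_catkins": 0.06,
    "balanced:female_catkins+male_catkins": 0.10,
}

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass
class FamilySpec:
    """Study conditions for one synthetic family."""

    n_subgroups: int = 3
    genes_per_subgroup: int = 6
    mutation_rate: float = 0.02
    intron_pattern_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    n_tandem_arrays: int = 2
    n_segmental_pairs: int = 2
    n_chromosomes: int = 5
    cterm_motif_length: int = 18
    seed: int = 0
    # secondary knobs (defaults are part of the study conditions)
    subgroup_divergence: float | None = None  # fraction of free positions; 3x rate if None
    tandem_array_size: int = 3
    nterm_len_range: tuple[int, int] = (8, 20)
    cterm_pre_range: tuple[int, int] = (60, 110)
    cterm_tail_range: tuple[int, int] = (60, 110)
    intron_len_range: tuple[int, int] = (80, 400)
    tandem_gap_range: tuple[int, int] = (2_000, 50_000)
    intergenic_gap: int = 300_000
    expression_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_MIX))
    protect_landmarks: bool = True

    def __post_init__(self):
        if self.n_subgroups < 1 or self.genes_per_subgroup < 1:
            raise ValueError("n_subgroups and genes_per_subgroup must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be within [0, 1]")
        if not 6 <= self.cterm_motif_length <= 300:
            raise ValueError("cterm_motif_length must be within [6, 300]")
        total = sum(self.intron_pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"intron pattern fractions sum to {total}, not 1")
        total = sum(self.expression_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expression fractions sum to {total}, not 1")
        if self.n_tandem_arrays < 0 or self.n_segmental_pairs < 0:
            raise ValueError("duplication counts must be non-negative")
        if self.tandem_array_size < 2:
            raise ValueError("a tandem array needs at least 2 members")
        n_founders = self.n_tandem_arrays + self.n_segmental_pairs
        if n_founders > self.n_subgroups * self.genes_per_subgroup:
            raise ValueError("more duplication events than available genes")
        if self.n_segmental_pairs > 0 and self.n_chromosomes < 2:
            raise ValueError("segmental pairs need at least 2 chromosomes")

    @property
    def divergence(self) -> float:
        return (3.0 * self.mutation_rate if self.subgroup_divergence is None
                else self.subgroup_divergence)


@dataclass
class TruthRecord:
    gene_id: str
    subgroup: str
    pattern: str
    domain_start: int            # 1-based protein coordinate
    duplication_role: str        # "singleton" | "tandem:<i>" | "segmental:<i>"
    motif_start: int             # 1-based protein coordinates of the planted motif
    motif_end: int
    expression: str


@dataclass
class PlantedTruth:
    records: dict[str, TruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records.values()]).set_index("gene_id")

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(r) for k, r in sorted(self.records.items())},
                      fh, indent=1, sort_keys=True)


@dataclass
class SyntheticFamily:
    spec: FamilySpec
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    proteins: dict[str, str]
    truth: PlantedTruth


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(seq: str, rate: float, protected: frozenset[int],
            rng: np.random.Generator) -> str:
    """Substitute residues at ``rate`` per position, sparing 1-based
    ``protected`` positions."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(seq)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
        for aa in protein
    ]
    codons.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    return "".join(codons)


def _site_positions(taxonomy: PatternTaxonomy, label: str) -> list[tuple[int, int]]:
    """(domain position, phase) for each required site, at window midpoints."""
    sites = taxonomy.requirements[label]
    return sorted(((s.lo + s.hi) // 2, s.phase) for s in sites)


@dataclass
class _GeneDraft:
    gene_id: str
    subgroup: str
    pattern: str
    protein: str
    domain_start: int
    motif_span: tuple[int, int]
    role: str
    expression: str


def _intron_split_points(draft: _GeneDraft, taxonomy: PatternTaxonomy) -> list[int]:
    """Coding-nucleotide offsets at which the CDS is interrupted."""
    points = []
    for dpos, phase in _site_positions(taxonomy, draft.pattern):
        codon = draft.domain_start + dpos - 1
        upstream = 3 * codon if phase == 0 else 3 * (codon - 1) + phase
        points.append(upstream)
    return sorted(points)


def generate_family(spec: FamilySpec,
                    model: DomainModel | None = None,
                    taxonomy: PatternTaxonomy | None = None) -> SyntheticFamily:
    """Generate genome, gene models, proteins and planted truth for a family."""
    model = model or DomainModel()
    taxonomy = taxonomy or default_taxonomy()
    unknown = set(spec.intron_pattern_mix) - set(taxonomy.labels)
    if unknown:
        raise ValueError(f"pattern labels not in taxonomy: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)

    protected = model.protected_positions() if spec.protect_landmarks else frozenset()
    free = [p for p in range(1, model.length + 1) if p not in protected]
    n_marker = int(round(spec.divergence * len(free)))
    if n_marker * spec.n_subgroups > len(free):
        raise ValueError("subgroup divergence too high for disjoint marker sets")
    shuffled = list(rng.permutation(free))
    subgroup_domains: dict[str, str] = {}
    subgroup_motifs: dict[str, str] = {}
    for g in range(spec.n_subgroups):
        name = f"SG{g + 1}"
        dom = list(CONSENSUS)
        for p in shuffled[g * n_marker:(g + 1) * n_marker]:
            choices = AMINO_ACIDS.replace(dom[p - 1], "")
            dom[p - 1] = choices[rng.integers(0, len(choices))]
        subgroup_domains[name] = "".join(dom)
        subgroup_motifs[name] = _random_aa(rng, spec.cterm_motif_length)

    labels = sorted(spec.intron_pattern_mix)
    label_p = np.array([spec.intron_pattern_mix[l] for l in labels])
    expr_labels = sorted(spec.expression_mix)
    expr_p = np.array([spec.expression_mix[l] for l in expr_labels])

    total = spec.n_subgroups * spec.genes_per_subgroup
    n_events = spec.n_tandem_arrays + spec.n_segmental_pairs
    founder_idx = set(rng.choice(total, size=n_events, replace=False)) if n_events else set()
    founder_roles = {}
    for i, idx in enumerate(sorted(founder_idx)):
        if i < spec.n_tandem_arrays:
            founder_roles[idx] = f"tandem:{i + 1}"
        else:
            founder_roles[idx] = f"segmental:{i - spec.n_tandem_arrays + 1}"

    def build_protein(subgroup: str) -> tuple[str, int, tuple[int, int], str]:
        nterm_len = int(rng.integers(*spec.nterm_len_range))
        nterm = "M" + _random_aa(rng, nterm_len - 1)
        dom = _mutate(subgroup_domains[subgroup], spec.mutation_rate, protected, rng)
        pre = _random_aa(rng, int(rng.integers(*spec.cterm_pre_range)))
        motif = subgroup_motifs[subgroup]
        tail = _random_aa(rng, int(rng.integers(*spec.cterm_tail_range)))
        protein = nterm + dom + pre + motif + tail
        domain_start = len(nterm) + 1
        mstart = len(nterm) + len(dom) + len(pre) + 1
        return protein, domain_start, (mstart, mstart + len(motif) - 1), motif

    drafts: list[_GeneDraft] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"MYB{counter:03d}"

    copy_protect = protected  # domain-relative; offset below per protein

    for idx in range(total):
        subgroup = f"SG{idx // spec.genes_per_subgroup + 1}"
        pattern = labels[rng.choice(len(labels), p=label_p)]
        expression = expr_labels[rng.choice(len(expr_labels), p=expr_p)]
        protein, dstart, mspan, _ = build_protein(subgroup)
        role = founder_roles.get(idx, "singleton")
        drafts.append(_GeneDraft(next_id(), subgroup, pattern, protein,
                                 dstart, mspan, role, expression))
        if role == "singleton":
            continue
        n_copies = (spec.tandem_array_size - 1 if role.startswith("tandem") else 1)
        for _ in range(n_copies):
            offset_protected = frozenset({1} | {dstart + p - 1 for p in copy_protect})
            copy_prot = _mutate(protein, spec.mutation_rate, offset_protected, rng)
            expr = expr_labels[rng.choice(len(expr_labels), p=expr_p)]
            drafts.append(_GeneDraft(next_id(), subgroup, pattern, copy_prot,
                                     dstart, mspan, role, expr))

    # --- nucleotide structures -------------------------------------------
    gene_seqs: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for draft in drafts:
        cds = _reverse_translate(draft.protein, rng)
        points = _intron_split_points(draft, taxonomy)
        pieces = []
        prev = 0
        for p in points:
            pieces.append(cds[prev:p])
            prev = p
        pieces.append(cds[prev:])
        seq_parts = []
        intervals = []
        cursor = 0
        for i, piece in enumerate(pieces):
            intervals.append((cursor + 1, cursor + len(piece)))
            seq_parts.append(piece)
            cursor += len(piece)
            if i < len(pieces) - 1:
                ilen = int(rng.integers(*spec.intron_len_range))
                seq_parts.append("GT" + _random_nt(rng, ilen - 4) + "AG")
                cursor += ilen
        gene_seqs[draft.gene_id] = ("".join(seq_parts), intervals)

    # --- placement --------------------------------------------------------
    units: list[list[_GeneDraft]] = []
    arrays: dict[str, list[_GeneDraft]] = {}
    seg_pairs: dict[str, list[_GeneDraft]] = {}
    for draft in drafts:
        if draft.role.startswith("tandem"):
            arrays.setdefault(draft.role, []).append(draft)
        elif draft.role.startswith("segmental"):
            seg_pairs.setdefault(draft.role, []).append(draft)
        else:
            units.append([draft])
    units.extend(arrays.values())
    seg_placements: list[tuple[_GeneDraft, _GeneDraft]] = [
        (pair[0], pair[1]) for pair in seg_pairs.values()]
    for founder, _ in seg_placements:
        units.append([founder])

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chrom_units: dict[str, list[list[_GeneDraft]]] = {c: [] for c in chrom_names}
    for i, unit in enumerate(units):
        chrom_units[chrom_names[i % spec.n_chromosomes]].append(unit)
    founder_chrom = {}
    for unit_list, chrom in ((ul, c) for c, uls in chrom_units.items() for ul in uls):
        for draft in unit_list:
            founder_chrom[draft.gene_id] = chrom
    for founder, copy in seg_placements:
        options = [c for c in chrom_names if c != founder_chrom[founder.gene_id]]
        chrom_units[options[int(rng.integers(0, len(options)))]].append([copy])

    genome: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    for chrom in chrom_names:
        parts = []
        cursor = 0
        pad = 5_000 + int(rng.integers(0, 5_000))
        for unit in chrom_units[chrom]:
            for j, draft in enumerate(unit):
                gap = (int(rng.integers(*spec.tandem_gap_range)) if j > 0
                       else pad if cursor == 0
                       else spec.intergenic_gap + int(rng.integers(0, 50_000)))
                parts.append(_random_nt(rng, gap))
                cursor += gap
                seq, intervals = gene_seqs[draft.gene_id]
                strand = "+" if rng.random() < 0.5 else "-"
                glen = len(seq)
                if strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                    intervals = sorted((glen - e + 1, glen - s + 1) for s, e in intervals)
                offset = cursor
                abs_intervals = [(offset + s, offset + e) for s, e in intervals]
                parts.append(seq)
                gene = GeneModel(draft.gene_id, chrom, strand,
                                 offset + 1, offset + glen)
                tid = draft.gene_id + ".t1"
                gene.transcripts[tid] = Transcript(
                    tid, exons=list(abs_intervals), cds=list(abs_intervals))
                genes[draft.gene_id] = gene
                cursor += glen
        parts.append(_random_nt(rng, 2_000))
        genome[chrom] = "".join(parts)

    truth = PlantedTruth({
        d.gene_id: TruthRecord(d.gene_id, d.subgroup, d.pattern, d.domain_start,
                               d.role, d.motif_span[0], d.motif_span[1], d.expression)
        for d in drafts
    })
    proteins = {d.gene_id: d.protein for d in drafts}
    return SyntheticFamily(spec, genome, genes, proteins, truth)


def generate_expression(truth: PlantedTruth,
                        tissues: tuple[str, ...] = DEFAULT_TISSUES,
                        seed: int = 0, dropout: float = 0.0) -> pd.DataFrame:
    """Realize each gene's planted category as ordinal band intensities (0-3).

    ``dropout`` optionally zeroes non-category-defining cells with the given
    probability, for robustness experiments; the default is noise-free.
    """
    if not tissues:
        raise ValueError("tissue list must be non-empty")
    rng = np.random.default_rng(seed)
    rows = {}
    for gid in sorted(truth.records):
        category = truth.records[gid].expression
        kind, _, detail = category.partition(":")
        if kind == "none":
            values = {t: 0 for t in tissues}
        elif kind == "ubiquitous":
            values = {t: int(rng.integers(2, 4)) for t in tissues}
        elif kind == "preferential":
            if detail not in tissues:
                raise ValueError(f"unknown tissue {detail!r} in category {category!r}")
            values = {t: int(rng.integers(0, 2)) for t in tissues}
            values[detail] = 3
        elif kind == "balanced":
            members = detail.split("+")
            bad = set(members) - set(tissues)
            if bad:
                raise ValueError(f"unknown tissues {sorted(bad)} in category {category!r}")
            values = {t: int(rng.integers(0, 2)) for t in tissues}
            for t in members:
                values[t] = 3
        else:
            raise ValueError(f"unknown expression category {category!r}")
        if dropout > 0 and kind not in ("none",):
            for t in tissues:
                if rng.random() < dropout:
                    values[t] = 0
        rows[gid] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
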