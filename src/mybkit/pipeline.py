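"""End-to-end family characterization: scan -> filter -> gene structure ->
phylogeny -> duplication -> motifs -> expression/miRNA profiles.

All stage products are written as plain-text tables with a provenance
header (tool version, configuration hash, seed); a run manifest JSON
carries the same provenance for formats that cannot hold comments (FASTA,
Newick).  Stages degrade gracefully: an empty candidate set short-circuits
downstream stages and still produces a complete report of zeros.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, domain, duplication, genestruct, io, motifs, phylogeny, profiles


@dataclass
class PipelineConfig:
    proteins: str = ""
    gff3: str = ""
    genome: str = ""
    expression: str = ""
    mirnas: str = ""
    blocks: str = ""
    min_landmark_score: int = 5
    bootstrap_replicates: int = 200
    min_support: float = 50.0
    min_subgroup_size: int = 2
    dbd_threshold: float = duplication.DEFAULT_DBD_THRESHOLD
    full_threshold: float = duplication.DEFAULT_FULL_THRESHOLD
    tandem_max_separation: int = duplication.DEFAULT_TANDEM_MAX_SEPARATION
    motif_min_width: int = motifs.DEFAULT_MIN_WIDTH
    motif_max_width: int = motifs.DEFAULT_MAX_WIDTH
    motif_min_ic: float = motifs.DEFAULT_MIN_IC
    presence_floor: float = profiles.DEFAULT_PRESENCE_FLOOR
    preference_ratio: float = profiles.DEFAULT_PREFERENCE_RATIO
    mirna_max_penalty: float = profiles.DEFAULT_MAX_PENALTY
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"mybkit {__version__}",
                f"config={self.config_hash()}",
                f"seed={self.seed}"]


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _log(stage: str, t0: float) -> None:
    print(f"[mybkit] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and write the consolidated report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.config_hash(),
                    "seed": config.seed}
    model = domain.DomainModel()

    t0 = time.perf_counter()
    prots = io.read_fasta(config.proteins) if config.proteins else {}
    genes = io.read_gff3(config.gff3) if config.gff3 else {}
    genome = io.read_fasta(config.genome) if config.genome else {}
    _log("load", t0)

    # --- scan + filter ----------------------------------------------------
    t0 = time.perf_counter()
    hits = {pid: domain.scan_protein(seq.rstrip("*"), model, config.min_landmark_score)
            for pid, seq in prots.items()}
    positions = {gid: (g.chrom, g.start, g.end) for gid, g in genes.items()}
    if positions:
        filt = domain.filter_candidates(hits, prots, positions)
        accepted = list(filt.accepted)
        report["n_atypical"] = len(filt.atypical)
    else:
        accepted = sorted(pid for pid, h in hits.items() if len(h) == 1)
        report["n_atypical"] = sum(1 for h in hits.values() if len(h) > 1)
    report["n_input_proteins"] = len(prots)
    report["n_genes"] = len(accepted)
    hit_rows = [
        {"protein_id": pid, "start": h.start, "end": h.end,
         "score": h.landmark_score,
         "missed_landmarks": ",".join(map(str, h.missed)) or "-"}
        for pid in sorted(hits) for h in hits[pid]
    ]
    _write_tsv(pd.DataFrame(hit_rows), outdir / "domain_hits.tsv", config, index=False)
    _log("scan", t0)

    domains = {pid: (hits[pid][0].start, hits[pid][0].end) for pid in accepted}
    domain_seqs = {pid: prots[pid][s - 1:e] for pid, (s, e) in domains.items()}

    if len(accepted) >= 2:
        profile, stats = domain.profile_alignment(
            {p: s for p, s in domain_seqs.items() if len(s) == model.length},
            model) if sum(len(s) == model.length for s in domain_seqs.values()) >= 2 \
            else (None, {})
        if profile is not None:
            prof_frame = pd.DataFrame(
                profile.frequencies, columns=list(profile.ALPHABET),
                index=pd.RangeIndex(1, model.length + 1, name="position"))
            prof_frame["majority"] = list(profile.majority)
            prof_frame["conservation"] = profile.conservation
            _write_tsv(prof_frame, outdir / "residue_profile.tsv", config)
            report["residue_stats"] = {
                k: v for k, v in stats.items()
                if k in ("position62_substitution_fraction",
                         "cys41_conserved_fraction", "cys45_conserved_fraction",
                         "linker_match_fraction")}

    # --- gene structure ---------------------------------------------------
    t0 = time.perf_counter()
    taxonomy = genestruct.default_taxonomy()
    pattern_rows = []
    pattern_hist: dict[str, int] = {}
    for gid in accepted:
        if gid not in genes:
            continue
        label, mapped = genestruct.classify_gene(
            genes[gid], domains[gid][0], domains[gid][1], taxonomy)
        pattern_hist[label] = pattern_hist.get(label, 0) + 1
        pattern_rows.append({
            "gene_id": gid, "n_domain_introns": len(mapped),
            "positions": ",".join(str(p) for p, _ in mapped) or "-",
            "phases": ",".join(str(ph) for _, ph in mapped) or "-",
            "pattern": label,
        })
    if pattern_rows:
        _write_tsv(pd.DataFrame(pattern_rows), outdir / "gene_structure.tsv",
                   config, index=False)
    report["intron_patterns"] = dict(sorted(pattern_hist.items()))
    if genes:
        variants = genestruct.count_transcript_variants(
            {g: genes[g] for g in accepted if g in genes})
        report["n_multi_transcript_genes"] = sum(1 for v in variants.values() if v > 1)
    _log("structure", t0)

    # --- phylogeny + subgroups -------------------------------------------
    t0 = time.perf_counter()
    assignment = None
    aligned = {p: s for p, s in domain_seqs.items() if len(s) == model.length}
    if len(aligned) >= 3:
        aln = phylogeny.Alignment.from_dict(aligned)
        boot = phylogeny.bootstrap_support(
            aln, config.bootstrap_replicates, seed=config.seed)
        (outdir / "tree.nwk").write_text(boot.tree.newick() + "\n")
        assignment = phylogeny.assign_subgroups(
            boot.tree, config.min_support, config.min_subgroup_size, reroot=True)
        sub_frame = pd.DataFrame(
            [{"gene_id": g, "subgroup": s} for g, s in sorted(assignment.mapping.items())])
        _write_tsv(sub_frame, outdir / "subgroups.tsv", config, index=False)
        report["n_subgroups"] = len(assignment.subgroups)
        report["n_unassigned"] = sum(
            1 for s in assignment.mapping.values()
            if s == phylogeny.SubgroupAssignment.UNASSIGNED)
    else:
        report["n_subgroups"] = 0
    _log("phylogeny", t0)

    # --- duplication ------------------------------------------------------
    t0 = time.perf_counter()
    summary = {"n_clusters": 0, "n_tandem_genes": 0, "n_tandem_arrays": 0,
               "n_segmental_pairs": 0}
    if len(accepted) >= 2 and genes:
        full_id, dbd_id = duplication.identity_matrices(
            {p: prots[p] for p in accepted}, domains)
        clusters = duplication.cluster_paralogs(
            dbd_id, full_id, config.dbd_threshold, config.full_threshold)
        loci = duplication.build_loci(
            {gid: positions[gid] for gid in accepted if gid in positions})
        blocks = _read_block_pairs(config.blocks) if config.blocks else None
        duplication.classify_clusters(
            clusters, loci, tandem_max_separation=config.tandem_max_separation,
            block_pairs=blocks)
        summary = duplication.summarize_events(clusters)
        rows = [{"cluster": i + 1, "members": ",".join(c.members),
                 "pair": f"{a}-{b}", "classification": c.classifications[(a, b)]}
                for i, c in enumerate(clusters) for a, b in c.pairs]
        if rows:
            _write_tsv(pd.DataFrame(rows), outdir / "clusters.tsv", config, index=False)
    report["duplication"] = summary
    _log("duplication", t0)

    # --- motifs -----------------------------------------------------------
    t0 = time.perf_counter()
    all_blocks: list[motifs.MotifBlock] = []
    if assignment is not None:
        for label, info in sorted(assignment.subgroups.items()):
            cterms = {m: prots[m][domains[m][1]:] for m in info["members"]
                      if len(prots[m]) > domains[m][1]}
            if len(cterms) < 2:
                continue
            all_blocks.extend(motifs.discover_blocks(
                cterms, subgroup=label, min_width=config.motif_min_width,
                max_width=config.motif_max_width, min_ic_per_col=config.motif_min_ic))
        if all_blocks:
            with open(outdir / "motifs.meme.txt", "w") as fh:
                motifs.write_meme(all_blocks, fh)
            occ = [{"subgroup": b.subgroup, "consensus": b.consensus,
                    "width": b.width, "sequence": sid, "start": start}
                   for b in all_blocks for sid, start in b.occurrences]
            _write_tsv(pd.DataFrame(occ), outdir / "motif_occurrences.tsv",
                       config, index=False)
    report["n_motifs"] = len(all_blocks)
    _log("motifs", t0)

    # --- profiles ---------------------------------------------------------
    t0 = time.perf_counter()
    if config.expression:
        table = pd.read_csv(config.expression, sep="\t", index_col=0, comment="#")
        table = table.loc[[g for g in table.index if g in set(accepted)]] \
            if accepted else table.iloc[0:0]
        if not table.empty:
            categories = profiles.classify_expression(
                table, config.presence_floor, config.preference_ratio)
            _write_tsv(categories.to_frame(), outdir / "expression_categories.tsv",
                       config)
            counts: dict[str, int] = {}
            for c in categories:
                counts[c] = counts.get(c, 0) + 1
            report["expression_categories"] = dict(sorted(counts.items()))
    if config.mirnas and genome and genes:
        mirnas = io.read_fasta(config.mirnas)
        transcripts = {gid: io.extract_cds(genome, genes[gid])
                       for gid in accepted if gid in genes}
        rows = []
        for mid in sorted(mirnas):
            for hit in profiles.predict_targets(
                    mirnas[mid], transcripts, config.mirna_max_penalty, mirna_id=mid):
                rows.append({"mirna": mid, "transcript": hit.transcript_id,
                             "start": hit.start, "penalty": hit.penalty,
                             "match": hit.match_string})
        if rows:
            _write_tsv(pd.DataFrame(rows), outdir / "mirna_targets.tsv",
                       config, index=False)
        report["n_mirna_hits"] = len(rows)
    _log("profiles", t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest = {"tool": f"mybkit {__version__}", "config": config.config_hash(),
                "seed": config.seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def _read_block_pairs(path: str):
    """Duplicated-block pairs from a 6-column BED-like file:
    chromA startA endA chromB startB endB (0-based half-open starts)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            pairs.append(((f[0], int(f[1]) + 1, int(f[2])),
                          (f[3], int(f[4]) + 1, int(f[5]))))
    return pairs
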