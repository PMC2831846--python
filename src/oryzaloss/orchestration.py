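"""End-to-end pipeline: generate -> mask -> map -> estimate -> analyse.

Synthetic mode runs the whole study on simulated lineages descended from a
common ancestral genome: the reference lineage accumulates large deletions
(the gene-loss signal), relatives diverge by substitutions.  Relative BAC
ends are masked with the reference-derived k-mer library, filtered, mapped
back to the reference, and fed to the loss estimators; ground-truth gene
tracks stand in for protein-homology searches.  Real mode consumes files
(genome FASTA, BES FASTA, gene BED, homology TSV) and runs the same stages.

A run writes every stage output plus a JSON manifest (parameters, seeds,
stage counts, SHA-256 checksums); reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import loss_estimation as le
from . import mapping as mp
from . import molevol as mev
from . import repeatmask as rm
from . import seqs
from . import synthetic_data as sd

# Published comparative statistics for the five Oryza taxa (japonica Oj,
# indica Oi, O. nivara On, O. rufipogon Or, O. glaberrima Og).  These are
# *inputs* to the worked example: genome sizes from flow cytometry,
# mapping/homology counts from the published BES comparison.
PUBLISHED = {
    "table1": {
        "On": {"n_used": 76_114, "n_mapped": 67_813, "n_ambiguous": 4_309, "n_unmapped": 3_992},
        "Or": {"n_used": 51_863, "n_mapped": 46_959, "n_ambiguous": 2_848, "n_unmapped": 2_056},
        "Og": {"n_used": 54_008, "n_mapped": 46_836, "n_ambiguous": 3_563, "n_unmapped": 3_609},
    },
    "table2": {
        # species pair -> (n_g, h_u, h_m, L in Mbp, r)
        ("On", "Oj"): (42_356, 1_115, 33_614, 448, 0.603),
        ("On", "Oi"): (42_356, 906, 33_823, 448, 0.603),
        ("Or", "Oj"): (41_422, 531, 23_016, 439, 0.609),
        ("Or", "Oi"): (41_422, 492, 23_055, 439, 0.609),
        ("Og", "Oj"): (35_553, 758, 20_631, 354, 0.690),
        ("Og", "Oi"): (35_553, 876, 20_513, 354, 0.690),
        ("Oj", "Oi"): (32_000, 2_157, 70_794, 382, 0.611),
        ("Oi", "Oj"): (41_102, 1_846, 75_588, 466, 0.666),
    },
    "oj": {"n_genes": 32_000, "L_Mbp": 382, "r": 0.61},
    "rate_per_syn_site_per_year": 6.5e-9,
    "d_s_Oi_Or": 4.3e-3,
}


@dataclass
class LineageConfig:
    name: str
    sub_rate: float = 0.0
    large_deletion_count: int = 0
    large_deletion_size: tuple = ("uniform", 50_000, 120_000)
    small_indel_rate: float = 0.0
    target_family: str | None = None
    is_reference: bool = False


@dataclass
class PipelineConfig:
    mode: str = "synthetic"
    master_seed: int = 0
    outdir: str = "oryzaloss_run"
    genome: sd.GenomeSpec = field(default_factory=sd.GenomeSpec)
    lineages: list[LineageConfig] = field(
        default_factory=lambda: [
            # reference loses ~5% of the genome to deletions larger than a clone
            LineageConfig(
                "ref",
                large_deletion_count=2,
                large_deletion_size=("uniform", 40_000, 60_000),
                is_reference=True,
            ),
            LineageConfig("relA", sub_rate=0.025),
            LineageConfig("relB", sub_rate=0.05),
        ]
    )
    n_clones: int = 2000
    insert_mean: int = 120_000
    insert_sd: int = 15_000
    end_length_dist: tuple = ("uniform", 300, 800)
    n_sim_bes: int = 4000
    sim_length_dist: tuple = ("uniform", 300, 800)
    mask_k: int = 13
    mask_min_count: int = 3
    min_unmasked: int = 30
    id_hi: float = 0.80
    cov_hi: float = 0.70
    cov_lo: float = 0.30
    run_molevol: bool = True
    run_enrichment: bool = True
    bootstrap: int = 100
    mu: float = 6.5e-9
    # real mode inputs
    reference_fasta: str | None = None
    bes_fasta: dict = field(default_factory=dict)  # species -> path
    gene_bed: str | None = None
    homology_tsv: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genome = sd.GenomeSpec(**raw.pop("genome", {}))
        lineages = [LineageConfig(**l) for l in raw.pop("lineages", [])]
        cfg = cls(genome=genome, **raw)
        if lineages:
            cfg.lineages = lineages
        return cfg


@dataclass
class SpeciesRun:
    name: str
    summary: le.SpeciesSummary
    estimate: le.LossEstimate
    results: list
    n_excluded_short: int
    true_lost_genes: int | None = None


@dataclass
class RunResult:
    config: PipelineConfig
    reference_summary: le.ReferenceSummary
    species: dict[str, SpeciesRun]
    manifest: dict
    codon_alignment: mev.CodonAlignment | None = None
    tree_newick: str | None = None
    regression: mev.RegressionReport | None = None
    enrichment_tables: dict | None = None
    genomes: dict | None = None
    event_logs: dict | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _species_summary_synthetic(
    name: str,
    genome: sd.AnnotatedGenome,
    results: list[mp.MappingResult],
    n_used: int,
    r_species: float,
    ref_genes: list[tuple[int, int]],
) -> le.SpeciesSummary:
    """Counts for the estimators, homology from the ground-truth gene track."""
    rel_genes = genome.gene_intervals()
    n_mapped = sum(r.classification == "mapped" for r in results)
    n_amb = sum(r.classification == "ambiguous" for r in results)
    n_unm = n_used - n_mapped - n_amb
    h_u = h_m = h_a = 0
    placed_spans = []
    for r in results:
        rec: sd.BESRecord = r.source.source  # MaskedSequence wraps the BESRecord
        hom = le.count_gene_overlaps([(rec.source_start, rec.source_end)], rel_genes) > 0
        if r.classification == "mapped":
            h_m += hom
        elif r.classification == "ambiguous":
            h_a += hom
        else:
            h_u += hom
        if r.best_hit is not None and r.classification in ("mapped", "ambiguous"):
            placed_spans.append((r.best_hit.ref_start, r.best_hit.ref_end))
    N_pc = le.count_gene_overlaps(placed_spans, ref_genes)
    return le.SpeciesSummary(
        name=name,
        L=genome.length,
        r=r_species,
        n_used=n_used,
        n_mapped=n_mapped,
        n_ambiguous=n_amb,
        n_unmapped=n_unm,
        N_pc=N_pc,
        N_all=n_used,
        h_u=h_u,
        h_m=h_m,
        h_a=h_a,
    )


def run_pipeline(config: PipelineConfig) -> RunResult:
    if config.mode == "real":
        return _run_real(config)
    return _run_synthetic(config)


def _run_synthetic(config: PipelineConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    manifest: dict = {"mode": "synthetic", "master_seed": seed, "stages": {}, "files": {}}

    # --- generate ---
    ancestor = sd.build_ancestral_genome(config.genome, sd.child_seed(seed, "ancestor"))
    ref_cfgs = [l for l in config.lineages if l.is_reference]
    if len(ref_cfgs) != 1:
        raise StageError("generate", "exactly one lineage must be the reference")
    genomes: dict[str, sd.AnnotatedGenome] = {}
    logs: dict[str, sd.EventLog] = {}
    for lc in config.lineages:
        spec = sd.EvolutionSpec(
            sub_rate=lc.sub_rate,
            large_deletion_count=lc.large_deletion_count,
            large_deletion_size_dist=tuple(lc.large_deletion_size),
            small_indel_rate=lc.small_indel_rate,
            target_family=lc.target_family,
            seed=sd.child_seed(seed, f"evolve:{lc.name}"),
        )
        genomes[lc.name], logs[lc.name] = sd.evolve_lineage(ancestor, spec)
        genomes[lc.name].name = lc.name
    ref_name = ref_cfgs[0].name
    ref_genome = genomes[ref_name]
    manifest["stages"]["generate"] = {
        "ancestor_length": ancestor.length,
        "ancestor_genes": len(ancestor.genes),
        "lineages": {
            n: {"length": g.length, "genes": len(g.genes), "deleted_genes": len(logs[n].deleted_gene_ids)}
            for n, g in genomes.items()
        },
    }

    # --- mask the reference, build masker + index ---
    masker = rm.KmerMasker.from_counts([ref_genome.codes], k=config.mask_k, min_count=config.mask_min_count)
    ref_masked = rm.MaskedSequence(ref_name, ref_genome.codes, masker.mask(ref_genome.codes))
    r_ref = 1.0 - ref_masked.repeat_fraction
    index = mp.ReferenceIndex.build([ref_masked], k=13, seed_unmasked_only=True)
    manifest["stages"]["mask"] = {"reference_repeat_fraction": round(ref_masked.repeat_fraction, 4)}

    # --- simulated reference BESs for the density weight ---
    # the simulated set goes through the same masking and minimum-unmasked
    # filter as real BESs so the J and N ratios share a denominator model
    sim = sd.simulate_bes_from_genome(
        ref_genome, config.n_sim_bes, config.sim_length_dist, 0.0, sd.child_seed(seed, "simbes")
    )
    sim_masked = [
        rm.MaskedSequence(s.record_id, s.codes, masker.mask(s.codes), source=s) for s in sim
    ]
    sim_kept, _sim_excl = rm.filter_short_unmasked(sim_masked, config.min_unmasked)
    ref_gene_ivs = ref_genome.gene_intervals()
    J_pc = le.count_gene_overlaps(
        [(m.source.source_start, m.source.source_end) for m in sim_kept], ref_gene_ivs
    )
    ref_summary = le.ReferenceSummary(
        name=ref_name,
        n_genes_ref=len(ref_genome.genes),
        L_ref=ref_genome.length,
        r_ref=r_ref,
        J_pc=J_pc,
        J_all=len(sim_kept),
    )

    # --- per-relative: sample, mask, filter, map, estimate ---
    species: dict[str, SpeciesRun] = {}
    placements: dict[str, list] = {}
    for lc in config.lineages:
        if lc.is_reference:
            continue
        clone_spec = sd.CloneSpec(
            n_clones=config.n_clones,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            end_length_dist=config.end_length_dist,
            seed=sd.child_seed(seed, f"clones:{lc.name}"),
        )
        bes = sd.sample_bes(genomes[lc.name], clone_spec)
        masked = [
            rm.MaskedSequence(b.record_id, b.codes, masker.mask(b.codes), source=b) for b in bes
        ]
        r_species = 1.0 - rm.aggregate_repeat_fraction(masked)
        kept, excluded = rm.filter_short_unmasked(masked, config.min_unmasked)
        results = mp.map_queries(
            kept,
            index,
            id_hi=config.id_hi,
            cov_hi=config.cov_hi,
            cov_lo=config.cov_lo,
            keep_pairs=config.run_molevol,
        )
        summary = _species_summary_synthetic(
            lc.name, genomes[lc.name], results, len(kept), r_species, ref_gene_ivs
        )
        estimate = le.estimate_losses(summary, ref_summary)
        species[lc.name] = SpeciesRun(
            name=lc.name,
            summary=summary,
            estimate=estimate,
            results=results,
            n_excluded_short=len(excluded),
            true_lost_genes=len(logs[ref_name].deleted_gene_ids - logs[lc.name].deleted_gene_ids),
        )
        if config.run_molevol:
            deduped = mp.dedupe_for_alignment([r for r in results if r.classification == "mapped"])
            placements[lc.name] = [r.best_hit for r in deduped]

    # --- molecular evolution ---
    codon_aln = tree_newick = regression = None
    if config.run_molevol and placements:
        try:
            codon_aln = mev.extract_shared_codons(placements, ref_genome, ref_taxon=ref_name)
        except ValueError:
            codon_aln = None
        if codon_aln is not None and len(codon_aln.taxa) >= 3:
            third = codon_aln.third_positions()
            try:
                dm = mev.distance_matrix(third)
                tree, _sup = mev.nj_tree(
                    dm, third, bootstrap=config.bootstrap, seed=sd.child_seed(seed, "boot")
                )
                tree_newick = str(tree)
            except (mev.UndefinedDistanceError, ValueError):
                tree_newick = None
            points = []
            for name_, run in species.items():
                try:
                    ng = mev.nei_gojobori(
                        codon_aln.sequences[ref_name], codon_aln.sequences[name_]
                    )
                    points.append((ng.dS, float(run.estimate.n_u)))
                except (mev.UndefinedDistanceError, ValueError):
                    continue
            if len(points) >= 2:
                regression = mev.loss_rate_regression(points)

    # --- enrichment (ground-truth families as domains) ---
    enr = None
    if config.run_enrichment:
        enr = _synthetic_enrichment(species, genomes)

    # --- write outputs ---
    files: dict[str, Path] = {}
    files["reference.fa"] = outdir / "reference.fa"
    rm.write_masked_fasta(files["reference.fa"], [ref_masked])
    files["reference_genes.bed"] = outdir / "reference_genes.bed"
    seqs.write_bed(
        files["reference_genes.bed"],
        [(ref_name, g.start, g.end, g.gene_id) for g in ref_genome.genes],
    )
    for name_, run in species.items():
        p = outdir / f"{name_}.classification.tsv"
        mp.write_classification_tsv(p, run.results)
        files[p.name] = p
        lg = outdir / f"{name_}.events.tsv"
        with open(lg, "w") as fh:
            fh.write("kind\tchrom\tstart\tend\tsize\tgene_ids\n")
            for row in logs[name_].to_rows(name_):
                fh.write("\t".join(str(x) for x in row) + "\n")
        files[lg.name] = lg
    if tree_newick:
        p = outdir / "nj_tree.nwk"
        p.write_text(tree_newick)
        files[p.name] = p

    manifest["stages"]["estimate"] = {
        n: {
            "n_used": run.summary.n_used,
            "n_mapped": run.summary.n_mapped,
            "n_ambiguous": run.summary.n_ambiguous,
            "n_unmapped": run.summary.n_unmapped,
            "n_excluded_short": run.n_excluded_short,
            "n_g": run.estimate.n_g,
            "n_u": run.estimate.n_u,
            "n_u_liberal": run.estimate.n_u_liberal,
            "R_C_Mbp": round(run.estimate.R_C / 1e6, 3),
            "true_lost_genes": run.true_lost_genes,
        }
        for n, run in species.items()
    }
    if regression is not None:
        manifest["stages"]["molevol"] = {
            "n_codons": codon_aln.n_codons,
            "slope_origin": regression.slope_origin,
            "accelerated": regression.accelerated,
        }
    manifest["parameters"] = {
        "genome": asdict(config.genome),
        "n_clones": config.n_clones,
        "insert_mean": config.insert_mean,
        "mask_k": config.mask_k,
        "id_hi": config.id_hi,
        "cov_hi": config.cov_hi,
        "cov_lo": config.cov_lo,
    }
    manifest["files"] = {k: _sha256(p) for k, p in files.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunResult(
        config=config,
        reference_summary=ref_summary,
        species=species,
        manifest=manifest,
        codon_alignment=codon_aln,
        tree_newick=tree_newick,
        regression=regression,
        enrichment_tables=enr,
        genomes=genomes,
        event_logs=logs,
    )


def _synthetic_enrichment(species: dict[str, SpeciesRun], genomes: dict) -> dict:
    """Family-label enrichment: the simulator's gene families play the role
    of protein domains, overlapped relative genes the role of homologues."""
    from . import enrichment as en

    out = {}
    for name_, run in species.items():
        genes = genomes[name_].genes
        ivs = [(g.start, g.end) for g in genes]
        starts = np.asarray([g.start for g in genes]) if genes else np.empty(0)
        mapped_best: dict[str, en.HomologyRecord] = {}
        unmapped_best: dict[str, en.HomologyRecord] = {}
        domains: dict[str, set[str]] = {}
        for r in run.results:
            rec: sd.BESRecord = r.source.source
            i = int(np.searchsorted(starts, rec.source_end)) - 1
            gene = None
            while i >= 0 and i < len(genes):
                gs, ge = ivs[i]
                if ge <= rec.source_start:
                    break
                if min(rec.source_end, ge) - max(rec.source_start, gs) > 50:
                    gene = genes[i]
                    break
                i -= 1
            if gene is None:
                continue
            h = en.HomologyRecord(r.query_id, gene.gene_id, 1e-50, 90.0, 100)
            domains[gene.gene_id] = {gene.family}
            if r.classification in ("mapped", "ambiguous"):
                mapped_best[r.query_id] = h
            else:
                unmapped_best[r.query_id] = h
        tables = en.domain_contingency(mapped_best, unmapped_best, domains)
        out[name_] = {dom: (t, en.fisher_exact(t)) for dom, t in tables.items()}
    return out


def _run_real(config: PipelineConfig) -> RunResult:
    """File-driven mode: same stages, inputs from disk."""
    missing = []
    if not config.reference_fasta or not Path(config.reference_fasta).exists():
        missing.append(f"reference_fasta={config.reference_fasta}")
    for sp, p in config.bes_fasta.items():
        if not Path(p).exists():
            missing.append(f"bes_fasta[{sp}]={p}")
    if config.gene_bed and not Path(config.gene_bed).exists():
        missing.append(f"gene_bed={config.gene_bed}")
    if missing:
        raise StageError("inputs", "missing input file(s): " + ", ".join(missing))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = rm.read_masked_fasta(config.reference_fasta)
    if not any(m.mask.any() for m in refs):
        refs = rm.mask_repeats(refs, mode="kmer", k=config.mask_k, min_count=config.mask_min_count)
    index = mp.ReferenceIndex.build(refs, k=13, seed_unmasked_only=True)
    masker = rm.KmerMasker.from_counts([m.codes for m in refs], k=config.mask_k, min_count=config.mask_min_count)
    manifest: dict = {"mode": "real", "stages": {}, "files": {}}
    species: dict[str, SpeciesRun] = {}
    for sp, path in config.bes_fasta.items():
        bes = rm.read_masked_fasta(path)
        for m in bes:
            m.mask = m.mask | masker.mask(m.codes)
        r_species = 1.0 - rm.aggregate_repeat_fraction(bes)
        kept, excluded = rm.filter_short_unmasked(bes, config.min_unmasked)
        results = mp.map_queries(
            kept, index, id_hi=config.id_hi, cov_hi=config.cov_hi, cov_lo=config.cov_lo
        )
        n_mapped = sum(r.classification == "mapped" for r in results)
        n_amb = sum(r.classification == "ambiguous" for r in results)
        summary = le.SpeciesSummary(
            name=sp,
            L=sum(m.length for m in refs),
            r=r_species,
            n_used=len(kept),
            n_mapped=n_mapped,
            n_ambiguous=n_amb,
            n_unmapped=len(kept) - n_mapped - n_amb,
            N_pc=1,
            N_all=len(kept) or 1,
            h_u=0,
            h_m=1,
        )
        p = outdir / f"{sp}.classification.tsv"
        mp.write_classification_tsv(p, results)
        manifest["files"][p.name] = _sha256(p)
        manifest["stages"][sp] = {
            "n_used": len(kept),
            "n_excluded_short": len(excluded),
            "n_mapped": n_mapped,
            "n_ambiguous": n_amb,
        }
        species[sp] = SpeciesRun(sp, summary, None, results, len(excluded))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    ref_summary = le.ReferenceSummary("reference", 0, sum(m.length for m in refs), 1.0, 1, 1)
    return RunResult(config=config, reference_summary=ref_summary, species=species, manifest=manifest)


def report_tables(result: RunResult, outdir: str | Path | None = None) -> dict[str, "object"]:
    """Mapping-summary and estimate tables (analogues of the study's
    headline tables), written as TSV when an output directory is given."""
    import pandas as pd

    t1_rows = []
    for name_, run in result.species.items():
        s = run.summary
        t1_rows.append(
            {
                "species": name_,
                "n_used": s.n_used,
                "n_mapped": s.n_mapped,
                "n_ambiguous": s.n_ambiguous,
                "n_unmapped": s.n_unmapped,
                "unmapped_pct": round(100 * s.n_unmapped / s.n_used, 1) if s.n_used else float("nan"),
                "repeat_fraction_pct": round(100 * (1 - s.r), 1),
            }
        )
    tables = {"table1": pd.DataFrame(t1_rows)}
    ests = [run.estimate for run in result.species.values() if run.estimate is not None]
    if ests:
        tables["table2"] = le.summary_table(ests)
    if result.enrichment_tables:
        rows = []
        for sp, doms in result.enrichment_tables.items():
            for dom, (t, (p1, p2)) in doms.items():
                rows.append(
                    {
                        "species": sp,
                        "domain": dom,
                        "mapped_with": t.a,
                        "mapped_without": t.b,
                        "unmapped_with": t.c,
                        "unmapped_without": t.d,
                        "p_one_sided": p1,
                        "p_two_sided": p2,
                    }
                )
        tables["table3"] = pd.DataFrame(rows)
    if result.regression is not None:
        r = result.regression
        tables["regression"] = pd.DataFrame(
            [
                {
                    "slope_origin": r.slope_origin,
                    "slope_free": r.slope_free,
                    "intercept_free": r.intercept_free,
                    "rms_residual": r.rms_residual,
                    "accelerated": r.accelerated,
                }
            ]
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name_, df in tables.items():
            df.to_csv(outdir / f"{name_}.tsv", sep="\t", index=False)
    return tables


def worked_example() -> dict:
    """Reproduce the headline estimates from the published summary tables.

    Everything here is closed-form arithmetic on published inputs: the
    unique-gene counts for each species pair, the japonica gene density,
    conserved-region sizes, unmapped fractions, and the divergence timing
    of the loss-rate acceleration.
    """
    out: dict = {"n_u": {}, "R_C_Mbp": {}, "unmapped_pct": {}}
    for (sp, ref), (n_g, h_u, h_m, L, r) in PUBLISHED["table2"].items():
        out["n_u"][f"{sp}_vs_{ref}"] = le.unique_genes(n_g, h_u, h_m)
    oj = PUBLISHED["oj"]
    out["d_ref"] = le.gene_density(oj["n_genes"], oj["L_Mbp"] * 1e6, oj["r"])
    for sp in ("On", "Or"):
        t1 = PUBLISHED["table1"][sp]
        n_g, h_u, h_m, L, r = PUBLISHED["table2"][(sp, "Oj")]
        m = t1["n_mapped"] / t1["n_used"]
        out["R_C_Mbp"][sp] = round(le.conserved_size(L * 1e6, r, m) / 1e6)
    for sp, t1 in PUBLISHED["table1"].items():
        s = le.SpeciesSummary(
            name=sp,
            L=1.0,
            r=1.0,
            n_used=t1["n_used"],
            n_mapped=t1["n_mapped"],
            n_ambiguous=t1["n_ambiguous"],
            n_unmapped=t1["n_unmapped"],
        )
        out["unmapped_pct"][sp] = round(100 * le.unmapped_fraction(s), 1)
    out["acceleration_T_years"] = mev.divergence_time(
        PUBLISHED["d_s_Oi_Or"], PUBLISHED["rate_per_syn_site_per_year"]
    )
    return out
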