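"""End-to-end orchestration: simulate/ingest -> demultiplex -> genotype ->
population, peptide, phylogenetic and selection analyses, in one immutable,
seed-determined run directory with a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon, genotyping, peptide, phylo, popgen, selection
from .synthdata import (Cohort, SimConfig, make_tag_scheme,
                        simulate_allele_pool, simulate_cohort, simulate_reads)

log = logging.getLogger("amp_typer")

GENE_CODES = {"Temporin": "Temp", "Brevinin": "Brev", "Palustrin": "Palu"}


@dataclass
class RunConfig:
    """Global pipeline configuration; defaults match the study thresholds
    (3% allele frequency, 300-read amplicon minimum, 1000 bootstrap
    replicates)."""

    out_dir: str = "run"
    seed: int = 0
    sim: SimConfig | None = None           # simulate mode when set
    reads_fastq: str | None = None         # ingest mode: merged reads
    tags_tsv: str | None = None
    primers_yaml: str | None = None
    min_reads: int = 300
    min_frac: float = 0.03
    use_doc: bool = True
    bootstrap_reps: int = 1000
    n_permutations: int = 9999
    grouping: str = "region"
    selection_models: tuple[str, ...] = ("M0", "M1a", "M2a")
    stages: tuple[str, ...] = ("simulate", "demux", "genotype", "popgen",
                               "peptide", "phylo", "selection")

    def require(self, stage: str, dependency: str, present: bool):
        if stage in self.stages and not present:
            raise ValueError(
                f"stage '{stage}' requires output of '{dependency}', which is "
                "neither enabled nor provided as input")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order.

    Identical config (including seed) yields a byte-identical run directory,
    apart from timestamps in the log file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "log.txt")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {"parameters": _config_dict(config), "stages": {}}

    try:
        pool = cohort = truth = None
        tags = None
        replicate_of: dict[str, str] = {}
        reads = None

        if "simulate" in config.stages:
            if config.sim is None:
                config.sim = SimConfig(seed=config.seed)
            log.info("simulating cohort and reads")
            pool = simulate_allele_pool(config.sim)
            cohort = simulate_cohort(pool, config.sim)
            tags, replicate_of = make_tag_scheme(cohort, pool, config.sim)
            sim_dir = out / "sim"
            reads, truth = simulate_reads(cohort, pool, tags, config.sim,
                                          out_dir=sim_dir,
                                          replicate_of=replicate_of)
            tags.write(sim_dir / "tags.tsv", sim_dir / "primers.yaml")
            config.sim.to_yaml(sim_dir / "sim_config.yaml")
            manifest["stages"]["simulate"] = {
                "n_reads": len(reads), "n_amplicons": len(tags.assignments)}
        elif config.reads_fastq:
            reads = amplicon.read_fastq(config.reads_fastq)
            tags = amplicon.TagScheme.read(config.tags_tsv, config.primers_yaml)
            manifest["inputs"] = {
                p: _checksum(Path(p)) for p in
                (config.reads_fastq, config.tags_tsv, config.primers_yaml)}

        config.require("demux", "simulate/ingest", reads is not None)
        tables = None
        if "demux" in config.stages:
            log.info("demultiplexing %d reads", len(reads))
            bins, counters = amplicon.demultiplex(reads, tags)
            tables = [amplicon.tally_variants(b)
                      for _, b in sorted(bins.items())]
            demux_dir = out / "demux"
            demux_dir.mkdir(exist_ok=True)
            amplicon.write_variant_tables(tables, demux_dir / "variants.tsv")
            (demux_dir / "counters.json").write_text(
                json.dumps(counters, sort_keys=True, indent=1))
            manifest["stages"]["demux"] = counters

        config.require("genotype", "demux", tables is not None)
        calls = None
        registries = None
        species_of = {}
        if "genotype" in config.stages:
            log.info("validating alleles on %d amplicons", len(tables))
            calls = [genotyping.validate_alleles(
                t, min_reads=config.min_reads, min_frac=config.min_frac,
                use_doc=config.use_doc) for t in tables]
            if cohort is not None:
                species_of = {ind.id: ind.species for ind in cohort.individuals}
            else:
                species_of = {c.individual: c.individual.split("_")[0]
                              for c in calls}
            primary = [c for c in calls if not c.amplicon_id.endswith("|rep")]
            registries = genotyping.name_alleles(primary, species_of, GENE_CODES)
            # replicate calls get names too (for reporting)
            genotyping.name_alleles([c for c in calls
                                     if c.amplicon_id.endswith("|rep")],
                                    species_of, GENE_CODES, registries)
            gdir = out / "genotype"
            gdir.mkdir(exist_ok=True)
            genotyping.calls_frame(calls).to_csv(gdir / "calls.tsv", sep="\t",
                                                 index=False)
            for gene, reg in sorted(registries.items()):
                (gdir / f"registry_{gene}.fasta").write_text(reg.as_fasta())
                reg.sidecar_frame().to_csv(gdir / f"registry_{gene}.tsv",
                                           sep="\t", index=False)
            summary = genotyping.copy_number_summary(primary, species_of)
            summary.to_csv(gdir / "copy_number.tsv", sep="\t", index=False)
            call_map = {c.amplicon_id: c for c in calls}
            if replicate_of:
                report = genotyping.replicate_concordance(call_map, replicate_of)
                pd.DataFrame([{
                    "replicate": p.amplicon_id, "original": p.partner_id,
                    "concordant": p.concordant,
                    "difference": ";".join(sorted(p.difference)),
                } for p in report.pairs]).to_csv(
                    gdir / "replicates.tsv", sep="\t", index=False)
                manifest["stages"]["genotype"] = {
                    "replicate_concordance": report.fraction_concordant}

        config.require("popgen", "genotype", calls is not None)
        obs_by_gene = None
        if calls is not None:
            obs_by_gene = _observations(calls, cohort)
        aligned_sets = {}
        if obs_by_gene is not None and registries is not None:
            for gene, obs in obs_by_gene.items():
                seqs = {registries[gene].name_of(s): s
                        for s in registries[gene].sequences}
                domains = (pool.genes[gene].domains if pool is not None else None)
                aligned_sets[gene] = popgen.AlignedAlleleSet(
                    gene=gene, sequences=seqs, observations=obs,
                    domains=domains)

        if "popgen" in config.stages:
            log.info("population-genetic summaries")
            pdir = out / "popgen"
            pdir.mkdir(exist_ok=True)
            all_div = []
            freq_frames = []
            tests = {}
            for gene, aset in sorted(aligned_sets.items()):
                intervals = ["whole"]
                if aset.domains:
                    intervals += ["propiece", "mature"]
                for interval in intervals:
                    for s in popgen.diversity_by_group(
                            aset, grouping=config.grouping, interval=interval):
                        s.group = f"{gene}:{s.group}"
                        all_div.append(s)
                ft = popgen.allele_frequencies(aset.observations,
                                               grouping=config.grouping)
                f = ft.frame()
                f.insert(0, "gene", gene)
                freq_frames.append(f)
                counts, regions = _allele_counts(aset.observations)
                if len(set(regions)) >= 2:
                    stat, p = popgen.region_allele_count_test(
                        counts, regions, n_perm=config.n_permutations,
                        seed=config.seed)
                    tests[gene] = {"statistic": stat, "p_value": p}
            popgen.summaries_frame(all_div).to_csv(
                pdir / "diversity.tsv", sep="\t", index=False,
                float_format="%.6g")
            pd.concat(freq_frames).to_csv(pdir / "frequencies.tsv", sep="\t",
                                          index=False, float_format="%.6g")
            (pdir / "region_tests.json").write_text(
                json.dumps(tests, sort_keys=True, indent=1))
            manifest["stages"]["popgen"] = tests

        if "peptide" in config.stages:
            log.info("peptide domains and charge regression")
            pepdir = out / "peptide"
            pepdir.mkdir(exist_ok=True)
            charge_rows = []
            regressions = {}
            for gene, aset in sorted(aligned_sets.items()):
                dmap = peptide.DomainMap(
                    gene=gene, frame_offset=0,
                    intervals={k: v for k, v in (aset.domains or {}).items()
                               if k in ("propiece", "mature")} or None)
                variants = peptide.collapse_synonymous(
                    aset.sequences, GENE_CODES.get(gene, gene[:4]), dmap)
                with open(pepdir / f"variants_{gene}.fasta", "w") as fh:
                    for v in variants:
                        fh.write(f">{v.name} members={','.join(v.members)}\n"
                                 f"{v.aa_seq}\n")
                pairs = []
                for name in sorted(aset.sequences):
                    _, prop, mat = peptide.translate_and_partition(
                        aset.sequences[name], dmap)
                    mc = peptide.net_charge(mat)
                    pc = peptide.net_charge(prop)
                    charge_rows.append({"gene": gene, "allele": name,
                                        "mature_charge": mc,
                                        "propiece_charge": pc})
                    pairs.append((mc, pc))
                try:
                    r = peptide.charge_regression(pairs)
                    regressions[gene] = {"slope": r.slope, "stderr": r.stderr,
                                         "intercept": r.intercept, "n": r.n}
                except ValueError as exc:
                    regressions[gene] = {"error": str(exc)}
            pd.DataFrame(charge_rows).to_csv(pepdir / "charges.tsv", sep="\t",
                                             index=False)
            (pepdir / "charge_regression.json").write_text(
                json.dumps(regressions, sort_keys=True, indent=1))
            manifest["stages"]["peptide"] = regressions

        trees = {}
        if "phylo" in config.stages:
            log.info("NJ trees, bootstrap, networks")
            phydir = out / "phylo"
            phydir.mkdir(exist_ok=True)
            mixtures = {}
            for gene, aset in sorted(aligned_sets.items()):
                if len(aset.sequences) < 3:
                    continue
                tree = phylo.bootstrap_support(
                    aset.sequences, n_reps=config.bootstrap_reps,
                    seed=config.seed)
                trees[gene] = tree
                (phydir / f"tree_{gene}.nwk").write_text(tree.newick() + "\n")
                species_map = {name: name.split("_")[0]
                               for name in aset.sequences}
                report = phylo.clade_species_mixture(tree, species_map)
                mixtures[gene] = {"fraction_mixed": report.fraction_mixed,
                                  "n_clades": len(report.rows)}
                dm = phylo.hamming_distance_matrix(
                    {n: s for n, s in aset.sequences.items()})
                edges = phylo.mst_network(dm)
                pd.DataFrame(edges, columns=["a", "b", "weight"]).to_csv(
                    phydir / f"mst_{gene}.tsv", sep="\t", index=False)
            (phydir / "clade_mixture.json").write_text(
                json.dumps(mixtures, sort_keys=True, indent=1))
            manifest["stages"]["phylo"] = mixtures

        if "selection" in config.stages:
            log.info("codon-model selection analyses")
            seldir = out / "selection"
            seldir.mkdir(exist_ok=True)
            results = {}
            for gene, aset in sorted(aligned_sets.items()):
                if len(aset.sequences) < 3:
                    continue
                aln = selection.CodonAlignment.from_nucleotide(aset.sequences)
                if aln.n_sites < 10:
                    continue
                tree = trees.get(gene) or phylo.nj_tree(
                    phylo.p_distance_matrix(aset.sequences))
                m0 = selection.fit_site_model(aln, tree, "M0",
                                              seed=config.seed)
                entry = {"M0": {"kappa": m0.spec.kappa, "omega": m0.spec.omega,
                                "lnL": m0.lnl}}
                for null, alt in (("M1a", "M2a"), ("M7", "M8")):
                    if null in config.selection_models and \
                            alt in config.selection_models:
                        _, nf, af = selection.fit_nested_pair(
                            aln, tree, null, alt, seed=config.seed, m0=m0)
                        stat, df, p = selection.lrt(nf, af)
                        sites, _ = selection.neb_positive_sites(af, aln, tree)
                        entry[f"{null}_vs_{alt}"] = {
                            "lnL_null": nf.lnl, "lnL_alt": af.lnl,
                            "stat": stat, "df": df, "p_value": p,
                            "positive_sites": sites}
                scan = selection.slac_site_scan(aln, tree)
                entry["slac_mean_omega"] = scan.mean_omega
                pd.DataFrame(scan.sites).to_csv(
                    seldir / f"slac_{gene}.tsv", sep="\t", index=False,
                    float_format="%.6g")
                results[gene] = entry
            (seldir / "fits.json").write_text(
                json.dumps(results, sort_keys=True, indent=1))
            manifest["stages"]["selection"] = {
                g: {k: v for k, v in e.items() if k != "slac_mean_omega"}
                for g, e in results.items()}

        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1, default=str))
        return out
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _observations(calls, cohort: Cohort | None) -> dict[str, pd.DataFrame]:
    """Per-gene observation table (one row per individual x validated allele),
    using cohort metadata when available."""
    meta = {}
    if cohort is not None:
        meta = {ind.id: (ind.population, ind.region, ind.species)
                for ind in cohort.individuals}
    rows: dict[str, list[dict]] = {}
    for c in calls:
        if c.status != "ok" or c.amplicon_id.endswith("|rep"):
            continue
        pop, region, species = meta.get(
            c.individual, (c.individual.rsplit("_", 1)[0], "all",
                           c.individual.split("_")[0]))
        for seq, *_ in c.alleles:
            rows.setdefault(c.gene, []).append({
                "individual": c.individual, "population": pop,
                "region": region, "species": species,
                "allele_name": c.names.get(seq, seq)})
    return {g: pd.DataFrame(r) for g, r in rows.items()}


def _allele_counts(obs: pd.DataFrame):
    per_ind = obs.groupby("individual").agg(
        count=("allele_name", "nunique"), region=("region", "first"))
    return per_ind["count"].to_numpy(), per_ind["region"].to_numpy()
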