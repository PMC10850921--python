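"""End-to-end orchestration: simulate -> discover -> design -> genotype ->
type -> tree -> size -> morphometry, driven by an INI-style config.

Every stage writes its outputs under the run's output directory and logs
record counts after each filter; the consolidated report lists per-stage
provenance (inputs, parameters, counts). A stage failure halts the run
with the failing stage named; partial outputs are retained.
"""

from __future__ import annotations

import configparser
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("cplineage.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


#: defaults mirror the study conditions: the read screen at >200x coverage
#: and >60% allele fraction, and the rice internal standard size
DEFAULT_CONFIG = {
    "run": {"seed": "1", "out_dir": "cplineage_run",
            "stages": "simulate,scan,markers,genotype,plastidtype,tree,"
                      "cytometry,morphometry"},
    "simulate": {"region_lengths": "20000,5000,4000,5000",
                 "tree_scale": "6", "indels_per_branch": "2",
                 "margin": "200", "min_indel_spacing": "300"},
    "scan": {"min_coverage": "200", "min_fraction": "0.60",
             "coverage_mean": "300", "frac_noise": "0.05",
             "fp_rate": "0.001"},
    "markers": {"amplicon_min": "100", "amplicon_max": "300",
                "primer_len": "20", "max_product": "2000"},
    "cytometry": {"internal_size": "373245519",
                  "baseline": "diploid-median"},
    "morphometry": {"n_per_taxon": "8"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (sections of key/value pairs)."""

    sections: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")
        return cls._from_parser(parser)

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        cfg = cls({s: dict(kv) for s, kv in DEFAULT_CONFIG.items()})
        for dotted, value in overrides.items():
            section, key = dotted.split(".", 1)
            cfg.sections.setdefault(section, {})[key] = str(value)
        cfg.validate()
        return cfg

    @classmethod
    def _from_parser(cls, parser) -> "RunConfig":
        sections = {s: dict(DEFAULT_CONFIG.get(s, {})) for s in DEFAULT_CONFIG}
        for s in parser.sections():
            sections.setdefault(s, {}).update(dict(parser[s]))
        cfg = cls(sections)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        known = set(DEFAULT_CONFIG)
        unknown = set(self.sections) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, defaults in DEFAULT_CONFIG.items():
            extra = set(self.sections.get(section, {})) - set(defaults)
            if extra:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(extra)}")
        self.get_int("run", "seed")
        lengths = self.get_ints("simulate", "region_lengths")
        if len(lengths) != 4:
            raise ValueError("simulate.region_lengths needs four integers")

    def get(self, section: str, key: str) -> str:
        return self.sections[section][key]

    def get_int(self, section: str, key: str) -> int:
        return int(self.get(section, key))

    def get_float(self, section: str, key: str) -> float:
        return float(self.get(section, key))

    def get_ints(self, section: str, key: str) -> tuple[int, ...]:
        return tuple(int(x) for x in self.get(section, key).split(","))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run the configured stages; returns a provenance report dict and
    writes a report bundle (tables, newick, VCF, log) under out_dir."""
    seed = config.get_int("run", "seed")
    out = Path(out_dir or config.get("run", "out_dir"))
    out.mkdir(parents=True, exist_ok=True)
    stages = [s.strip() for s in config.get("run", "stages").split(",")]
    report: dict = {"seed": seed, "stages": {}, "outputs": {}}
    state: dict = {}

    handlers = [logging.FileHandler(out / "run.log", mode="w")]
    for h in handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(logging.INFO)

    try:
        for stage in stages:
            logger.info("stage %s: start", stage)
            try:
                _STAGES[stage](config, seed, out, state, report)
            except Exception as exc:
                logger.error("stage %s: FAILED (%s)", stage, exc)
                raise PipelineError(stage, exc) from exc
            logger.info("stage %s: done", stage)
        report["outputs"] = {p.name: _sha256(p)
                            for p in sorted(out.iterdir()) if p.is_file()
                            and p.name != "run.log"}
        (out / "report.txt").write_text(_format_report(report))
    finally:
        for h in handlers:
            logger.removeHandler(h)
            h.close()
    return report


def _stage_simulate(config, seed, out, state, report):
    from . import synthdata

    lengths = config.get_ints("simulate", "region_lengths")
    ref = synthdata.simulate_reference_genome(seed, lengths)
    tree = synthdata.fig_tree(config.get_int("simulate", "tree_scale"),
                              config.get_int("simulate", "indels_per_branch"))
    genomes, truth = synthdata.simulate_lineages(
        ref, tree, seed=seed + 1,
        margin=config.get_int("simulate", "margin"),
        min_indel_spacing=config.get_int("simulate", "min_indel_spacing"))
    synthdata.write_fasta(out / "genomes.fasta",
                          {ref.id: ref.sequence, **genomes})
    synthdata.write_truth(out / "truth.txt", truth)
    state.update(reference=ref, genomes=genomes, truth=truth)
    report["stages"]["simulate"] = {
        "region_lengths": lengths, "genome_length": len(ref.sequence),
        "n_leaves": len(genomes),
        "n_planted_snps": sum(v.kind == "snp"
                              for vs in truth.variants.values() for v in vs),
        "n_planted_indels": sum(v.kind == "indel"
                                for vs in truth.variants.values() for v in vs)}


def _stage_scan(config, seed, out, state, report):
    from . import indelscan, synthdata

    truth = state["truth"]
    cand = synthdata.simulate_pileup_candidates(
        truth, seed=seed + 2,
        coverage_mean=config.get_int("scan", "coverage_mean"),
        frac_noise=config.get_float("scan", "frac_noise"),
        fp_rate=config.get_float("scan", "fp_rate"))
    spec = indelscan.FilterSpec(config.get_int("scan", "min_coverage"),
                                config.get_float("scan", "min_fraction"))
    kept = indelscan.filter_candidates(cand, spec)
    logger.info("scan: %d candidates, %d pass coverage>%d and fraction>%.2f",
                len(cand), len(kept), spec.min_coverage, spec.min_fraction)
    cand.to_csv(out / "candidates.tsv", sep="\t", index=False)
    kept.to_csv(out / "candidates_filtered.tsv", sep="\t", index=False)

    # discover indels from the first non-reference genome by alignment
    ref = state["reference"]
    leaf = sorted(state["genomes"])[0]
    aln = indelscan.align_pair(ref.sequence, state["genomes"][leaf],
                               ref_id=ref.id, qry_id=leaf)
    found = [indelscan.classify_motif(v, ref.sequence)
             for v in indelscan.extract_indels(aln)]
    (out / "indels.vcf").write_text(indelscan.indels_to_vcf(found, ref.id))
    state.update(candidates=cand, kept=kept, discovered=found)
    report["stages"]["scan"] = {
        "n_candidates": len(cand), "n_retained": len(kept),
        "aligned_leaf": leaf, "n_discovered_indels": len(found),
        "census": indelscan.motif_census(found).to_dict()}


def _stage_markers(config, seed, out, state, report):
    from . import markers as mk

    ref = state["reference"]
    designed, failed = [], 0
    for i, v in enumerate(state["discovered"], start=1):
        try:
            designed.append(mk.design_primers(
                ref, v, locus=f"synINDEL{i}",
                primer_len=config.get_int("markers", "primer_len"),
                amplicon_range=(config.get_int("markers", "amplicon_min"),
                                config.get_int("markers", "amplicon_max"))))
        except mk.UndesignableError:
            failed += 1
    logger.info("markers: %d designed, %d undesignable", len(designed), failed)
    pd.DataFrame([{"locus": m.locus, "forward": m.fwd_primer,
                   "reverse": m.rev_primer, "start": m.ref_start,
                   "end": m.ref_end, "length": m.expected_length}
                  for m in designed]).to_csv(out / "markers.tsv", sep="\t",
                                             index=False)
    state["markers"] = designed
    report["stages"]["markers"] = {"n_designed": len(designed),
                                   "n_undesignable": failed}


def _stage_genotype(config, seed, out, state, report):
    from . import markers as mk

    genomes = {state["reference"].id: state["reference"].sequence,
               **state["genomes"]}
    lengths = mk.genotype_accessions(genomes, state["markers"],
                                     config.get_int("markers", "max_product"))
    codes = mk.call_genotypes(lengths)
    (out / "genotypes.tsv").write_text(mk.genotype_table_text(codes))
    state["codes"] = codes
    report["stages"]["genotype"] = {
        "n_accessions": len(codes), "n_loci": codes.shape[1],
        "n_missing_calls": int(codes.isna().sum().sum())}


def _stage_plastidtype(config, seed, out, state, report):
    from .plastidtype import assign_plastid_types, type_report_text

    codes = state["codes"]
    panel = list(codes.columns)
    assignment = assign_plastid_types(codes.reset_index(), panel)
    (out / "plastid_types.tsv").write_text(type_report_text(assignment))
    state["assignment"] = assignment
    report["stages"]["plastidtype"] = {
        "n_types": len(assignment), "n_excluded": len(assignment.excluded)}


def _stage_tree(config, seed, out, state, report):
    from . import phylo, synthdata

    taxa, rows = synthdata.true_alignment(state["reference"], state["truth"])
    aln = phylo.MultiAlignment(taxa, rows)
    dm = phylo.mcl_distances(aln)
    tree = phylo.nj_tree(dm)
    rooted = phylo.root_with_outgroup(tree, "outgroup")
    (out / "distances.phylip").write_text(dm.to_phylip())
    (out / "tree.nwk").write_text(str(rooted).strip() + "\n")
    state["tree"] = rooted
    report["stages"]["tree"] = {
        "n_taxa": aln.n_taxa, "alignment_length": len(aln),
        "variable_sites": phylo.count_variable_sites(aln),
        "informative_sites": phylo.count_variable_sites(
            aln, "parsimony-informative")}


def _stage_cytometry(config, seed, out, state, report):
    from . import cytometry, synthdata

    internal = config.get_float("cytometry", "internal_size")
    params = synthdata.PeakSimParams(
        true_1c_sizes={"T. incisa": 406_826_068, "T. natans": 438_297_965,
                       "T. bispinosa": 481_616_741, "T. japonica": 883_068_853},
        internal_size=internal, noise_sd=0.01, seed=seed + 3)
    peaks = synthdata.simulate_flow_peaks(params, n_reps=3)
    peaks["diploid_flag"] = peaks["site"].isin(
        ["T. incisa", "T. natans"]).astype(int)
    rep = cytometry.batch_report(peaks, config.get("cytometry", "baseline"))
    rep.to_csv(out / "genome_sizes.csv", index=False)
    state["cytometry"] = rep
    report["stages"]["cytometry"] = {
        "n_samples": len(rep),
        "ploidy_by_taxon": rep.groupby("site")["ploidy"].first().to_dict()}


def _stage_morphometry(config, seed, out, state, report):
    from . import morphometry, synthdata

    n = config.get_int("morphometry", "n_per_taxon")
    seeds, vols = synthdata.simulate_morphometry(
        {t: n for t in synthdata.DEFAULT_MORPHO_PRESETS}, seed=seed + 4)
    summary = morphometry.summarize_dims(seeds)
    summary.to_csv(out / "seed_summary.csv")
    vols.to_csv(out / "volumes.csv", index=False)
    ratio_t = morphometry.interspecific_ratio(
        vols[vols.taxon == "T. bispinosa"], vols[vols.taxon == "T. japonica"],
        "total")
    ratio_e = morphometry.interspecific_ratio(
        vols[vols.taxon == "T. bispinosa"], vols[vols.taxon == "T. japonica"],
        "endosperm")
    report["stages"]["morphometry"] = {
        "n_per_taxon": n,
        "total_volume_ratio": round(ratio_t["ratio"], 3),
        "endosperm_volume_ratio": round(ratio_e["ratio"], 3)}


_STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "markers": _stage_markers,
    "genotype": _stage_genotype,
    "plastidtype": _stage_plastidtype,
    "tree": _stage_tree,
    "cytometry": _stage_cytometry,
    "morphometry": _stage_morphometry,
}


def _format_report(report: dict) -> str:
    lines = [f"seed: {report['seed']}", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k} = {v}")
        lines.append("")
    lines.append("[output checksums]")
    for name, digest in report["outputs"].items():
        lines.append(f"  {name} sha256={digest}")
    return "\n".join(lines) + "\n"
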