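"""End-to-end orchestration: one config in, the analysis tables out.

A run consumes either a :class:`cpgmut.synth.SynthConfig` (self-generated
inputs with ground truth) or a set of file paths, executes the stages in
method order — parse/generate, reference-context filtering, methylation
levels and classes, CpG islands, region index, then each statistic — and
writes seven TSV/JSON products:

    class_rates.tsv        SNP density per methylation class
    region_rates.tsv       the same, stratified by primary region label
    chrom_rates.tsv        the same, per chromosome
    divergence_by_class.tsv  outgroup divergence per methylation class
    allele_report.tsv      level-frequency correlations + binned regression
    noncpg_rates.tsv       SNP density per class at CHG/CHH cytosines
    run_log.json           every filter's kept/removed accounting

Outputs are deterministic for a fixed config (and seed, for synthetic
runs). Plots are deliberately not produced; the TSVs are the contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alleles as _alleles
from . import methylome as _methylome
from . import rates as _rates
from . import regions as _regions
from . import synth as _synth
from .core import genome_lengths, load_genome

log = logging.getLogger("cpgmut")


@dataclass
class InputPaths:
    genome: Path
    annotation: Path
    methylome: Path
    snps: Path
    alignment: Path
    freqs: Path


@dataclass
class RunConfig:
    """Exactly one of `synth` / `inputs` drives the run."""
    outdir: Path
    synth: _synth.SynthConfig | None = None
    inputs: InputPaths | None = None
    coverage_cutoffs: tuple[int, ...] = (1, 5, 10)
    n_freq_bins: int = 5
    min_coverage: int = 1
    cgi_merge_gap: int = 0
    group_test: str = "welch"
    bin_scheme: str = "width"

    def __post_init__(self):
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("provide exactly one of synth config / input paths")
        self.outdir = Path(self.outdir)


@dataclass
class RunResult:
    tables: dict[str, pd.DataFrame]
    report: dict
    log: dict
    paths: dict[str, Path] = field(default_factory=dict)
    bundle: "_synth.SynthBundle | None" = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis; see the module docstring for products."""
    runlog: dict = {"filters": {}, "stages": []}
    bundle = None

    if config.synth is not None:
        bundle = _synth.generate_bundle(config.synth)
        genome, annotation = bundle.genome, bundle.annotation
        calls_raw = bundle.calls
        snps, snp_counts = bundle.snps, {
            "total": len(bundle.snps), "kept": len(bundle.snps),
            "not_validated": 0, "not_biallelic": 0, "not_unique": 0,
        }
        pairs = _stage("alignment")(
            lambda: _pairs_from_outgroup(bundle))()
        freqs = bundle.freqs
    else:
        ip = config.inputs
        genome = _stage("genome")(load_genome)(ip.genome)
        annotation = _stage("annotation")(_regions.read_annotation)(ip.annotation)
        calls_raw = _stage("methylome")(_methylome.read_methylome)(ip.methylome)
        snps, snp_counts = _stage("snps")(_rates.read_snps)(ip.snps)
        pairs = _stage("alignment")(_rates.read_alignment)(ip.alignment)
        freqs = _stage("freqs")(_alleles.read_allele_freqs)(ip.freqs)
    runlog["filters"]["snps"] = snp_counts
    lengths = genome_lengths(genome)

    # methylome processing: reference-context restriction, coverage, classes
    cg_calls, n_bad_cg = _methylome.filter_reference_context(calls_raw, genome, "CG")
    chg_calls, _ = _methylome.filter_reference_context(calls_raw, genome, "CHG")
    chh_calls, _ = _methylome.filter_reference_context(calls_raw, genome, "CHH")
    noncpg_calls = pd.concat([chg_calls, chh_calls], ignore_index=True)
    runlog["filters"]["methylome"] = {
        "calls_total": int(len(calls_raw)),
        "cg_reference": int(len(cg_calls)),
        "chg_reference": int(len(chg_calls)),
        "chh_reference": int(len(chh_calls)),
        "non_reference_cg": n_bad_cg,
    }
    cg_calls, n_lowcov = _methylome.filter_coverage(cg_calls, config.min_coverage)
    runlog["filters"]["methylome"]["below_min_coverage"] = n_lowcov
    cg_calls = _methylome.add_level_and_class(cg_calls)
    noncpg_calls = _methylome.add_level_and_class(noncpg_calls)

    # regions
    cgis = _stage("cgi")(_regions.find_cgis_genome)(
        genome, merge_gap=config.cgi_merge_gap)
    index = _stage("regions")(_regions.build_region_index)(
        annotation, cgis, lengths)
    runlog["stages"].append({"cgi": len(cgis),
                             "promoters_clipped": index.n_promoters_clipped})

    tables: dict[str, pd.DataFrame] = {}
    tables["class_rates"] = _stage("class_rates")(_rates.stratified_rates)(
        cg_calls, snps)
    tables["region_rates"] = _stage("region_rates")(_rates.stratified_rates)(
        cg_calls, snps, index, by=("region",))
    tables["chrom_rates"] = _stage("chrom_rates")(_rates.stratified_rates)(
        cg_calls, snps, by=("chrom",))
    tables["coverage_rates"] = _stage("coverage_rates")(
        _rates.coverage_stratified_rates)(cg_calls, snps,
                                          config.coverage_cutoffs)
    tables["divergence_by_class"] = _stage("divergence")(
        _rates.divergence_rate_table)(cg_calls, pairs)
    tables["noncpg_rates"] = _stage("noncpg_rates")(_rates.rate_table)(
        _rates.attach_snp_events(noncpg_calls, snps), "snp", by=("context",))

    report = _stage("alleles")(_allele_report)(freqs, cg_calls, config)
    tables["allele_report"] = report["table"]

    result = RunResult(tables=tables, report=report, log=runlog, bundle=bundle)
    result.paths = _write_outputs(config.outdir, tables, report, runlog)
    return result


def _pairs_from_outgroup(bundle: "_synth.SynthBundle") -> pd.DataFrame:
    rows = []
    for chrom, seq in bundle.genome.items():
        o = bundle.outgroup[chrom]
        df = pd.DataFrame({
            "chrom": chrom,
            "pos": range(len(seq)),
            "human": list(seq),
            "outgroup": list(o),
        })
        rows.append(df[(df["human"] != "N") & (df["outgroup"] != "N")])
    return pd.concat(rows, ignore_index=True)


def _allele_report(freqs: pd.DataFrame, cg_calls: pd.DataFrame,
                   config: RunConfig) -> dict:
    sites = _alleles.annotate_sites(freqs, cg_calls)
    report: dict = {"join_stats": sites.attrs.get("join_stats", {})}
    rows = []
    for which in ("cytosine", "major", "ancestral"):
        try:
            r, p, n = _alleles.correlate_level_frequency(sites, which)
            rows.append((f"pearson_{which}", r, p, n))
        except (ValueError, KeyError) as exc:
            rows.append((f"pearson_{which}", float("nan"), float("nan"), 0))
            report[f"pearson_{which}_error"] = str(exc)
    try:
        bins, fit_r = _alleles.binned_regression(
            sites, config.n_freq_bins, scheme=config.bin_scheme)
        rows.append(("binned_fit_r", fit_r, float("nan"), int(bins["n"].sum())))
        report["bins"] = bins
    except (ValueError, _alleles.UndefinedStatisticError) as exc:
        report["bins_error"] = str(exc)
    for grouping in ("major", "ancestral", "ancestral_c_major"):
        try:
            ma, mb, p = _alleles.compare_groups(sites, grouping,
                                                test=config.group_test)
            rows.append((f"group_{grouping}_meanC", ma, p, len(sites)))
            rows.append((f"group_{grouping}_meanOther", mb, p, len(sites)))
        except ValueError as exc:
            report[f"group_{grouping}_error"] = str(exc)
    report["table"] = pd.DataFrame(
        rows, columns=["statistic", "value", "p_value", "n"])
    report["n_sites"] = int(len(sites))
    return report


def _write_outputs(outdir: Path, tables, report, runlog) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, tab in tables.items():
        paths[name] = outdir / f"{name}.tsv"
        tab.to_csv(paths[name], sep="\t", index=False, float_format="%.6g")
    if "bins" in report:
        paths["allele_bins"] = outdir / "allele_bins.tsv"
        report["bins"].to_csv(paths["allele_bins"], sep="\t", index=False,
                              float_format="%.6g")
    paths["run_log"] = outdir / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump(runlog, fh, indent=2)
    return paths
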