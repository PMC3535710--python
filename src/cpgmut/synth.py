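"""Synthetic input bundles with recorded ground truth.

Generates the five inputs the analysis consumes — genome FASTA + transcript
annotation, Lister-style methylome, SNP VCF, outgroup alignment and an
allele-frequency table — from a single :class:`SynthConfig`, together with
a truth table aligned row-for-row with the emitted methylome calls. The
statistical structure planted is the one the analysis assumes:

* every reference-CpG cytosine (both strands of a dinucleotide share one
  true level, mirroring the strand symmetry of real methylomes) draws its
  true methylation level from a discrete mixture with a point mass at 0;
* read totals are shifted Poisson (minimum one read, mean
  ``coverage_mean``) and methylated-read counts are binomial at the true
  level, so observed levels are noisy versions of planted ones;
* each CpG cytosine carries a SNP with a probability set by its *true*
  methylation class (optionally overridden per region label), CHG/CHH
  cytosines with a flat rate; alternative alleles are transition-weighted;
* the outgroup sequence differs at CpG cytosines with class-dependent
  probabilities and elsewhere at a background rate;
* the C-allele frequency of each SNP is a linear function of the true
  level plus Gaussian noise, clipped to [0, 1].

All randomness flows from ``SynthConfig.seed`` through fixed per-stage
substreams, so adding or rerunning one stage never perturbs another and a
fixed config reproduces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import methylome as _methylome
from . import rates as _rates
from . import regions as _regions
from .core import (
    A,
    C,
    G,
    METH_CLASSES,
    N,
    T,
    array_to_seq,
    classify_level,
    seq_to_array,
    write_fasta,
)

_STAGES = {"genome": 0, "methylome": 1, "snps": 2, "outgroup": 3, "freqs": 4}

# Fig-1-patterned SNP densities per true methylation class: unmethylated
# lowest, a low-intermediate/intermediate peak, decline toward high.
DEFAULT_CLASS_SNP_RATE = {
    "unmethylated": 0.011, "low": 0.063, "low_int": 0.118,
    "int": 0.110, "high_int": 0.050, "high": 0.029,
}
# Fig-4-patterned human-outgroup divergence per class (the high-intermediate
# value is not printed anywhere; 0.10 interpolates its neighbours).
DEFAULT_CLASS_DIV_RATE = {
    "unmethylated": 0.040, "low": 0.0723, "low_int": 0.1066,
    "int": 0.1049, "high_int": 0.100, "high": 0.0994,
}
# Balanced design: 30% unmethylated + equal mass at the five class
# midpoints, so every class is recoverable with comparable precision.
DEFAULT_LEVEL_MIXTURE = (
    (0.30, 0.0), (0.14, 0.1), (0.14, 0.3), (0.14, 0.5), (0.14, 0.7), (0.14, 0.9),
)


@dataclass(frozen=True)
class CGIBlock:
    """A planted CpG-island-like segment: elevated GC and CpG density."""
    start: int
    length: int
    gc: float = 0.6
    cpg_enrichment: float = 0.25  # per-step probability of emitting a CG pair


@dataclass(frozen=True)
class GeneModel:
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class FreqCoupling:
    """Linear link from true methylation level to C-allele frequency."""
    slope: float = 0.3
    intercept: float = 0.4
    noise_sd: float = 0.15


@dataclass
class SynthConfig:
    chrom: str = "chr1"
    genome_length: int = 1_000_000
    gc_background: float = 0.41
    cgi_blocks: tuple[CGIBlock, ...] = ()
    gene_models: tuple[GeneModel, ...] = ()
    level_mixture: tuple[tuple[float, float], ...] = DEFAULT_LEVEL_MIXTURE
    coverage_mean: float = 20.0
    class_snp_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SNP_RATE))
    class_div_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DIV_RATE))
    background_div_rate: float = 0.012
    noncpg_rate: float = 0.004
    noncpg_call_fraction: float = 0.05
    transition_weight: float = 0.8
    freq_coupling: FreqCoupling = field(default_factory=FreqCoupling)
    outgroup_c_prob: float = 0.80
    outgroup_alt_prob: float = 0.15
    region_snp_rate: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "gc_background": self.gc_background,
            "background_div_rate": self.background_div_rate,
            "noncpg_rate": self.noncpg_rate,
            "noncpg_call_fraction": self.noncpg_call_fraction,
            "transition_weight": self.transition_weight,
            "outgroup_c_prob": self.outgroup_c_prob,
            "outgroup_alt_prob": self.outgroup_alt_prob,
            **{f"class_snp_rate[{k}]": v for k, v in self.class_snp_rate.items()},
            **{f"class_div_rate[{k}]": v for k, v in self.class_div_rate.items()},
        }
        if self.region_snp_rate:
            probs.update({f"region_snp_rate[{k}]": v
                          for k, v in self.region_snp_rate.items()})
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.outgroup_c_prob + self.outgroup_alt_prob > 1.0 + 1e-9:
            raise ValueError("outgroup allele probabilities exceed 1")
        weights = [w for w, _ in self.level_mixture]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("level_mixture weights must be >= 0 and sum to 1")
        if any(not 0 <= lv <= 1 for _, lv in self.level_mixture):
            raise ValueError("level_mixture levels must lie in [0, 1]")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        for blk in self.cgi_blocks:
            if not (0 <= blk.start and blk.start + blk.length <= self.genome_length):
                raise ValueError("cgi_block outside genome")
        for gm in self.gene_models:
            if not (0 <= gm.tx_start < gm.tx_end <= self.genome_length):
                raise ValueError("gene model outside genome")
            for es, ee in gm.exons:
                if not (gm.tx_start <= es < ee <= gm.tx_end):
                    raise ValueError("exon outside its transcript")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible substream for one pipeline stage."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _cgi_block_seq(length: int, gc: float, enrich: float,
                   rng: np.random.Generator) -> np.ndarray:
    """CpG-enriched segment: at each step emit a CG dinucleotide with
    probability `enrich`, otherwise one base whose composition is chosen so
    the segment's overall GC stays near the requested value."""
    p = min(enrich, 0.999)
    gc_single = float(np.clip(((1 + p) * gc - 2 * p) / (1 - p), 0.0, 1.0))
    pair = rng.random(length) < p
    singles = rng.choice(np.array([A, C, G, T], dtype=np.uint8), size=length,
                         p=_background_probs(gc_single))
    out = np.empty(length + 1, dtype=np.uint8)
    i = k = 0
    while i < length:
        if pair[k] and i + 1 < length + 1:
            out[i] = C
            out[i + 1] = G
            i += 2
        else:
            out[i] = singles[k]
            i += 1
        k += 1
    return out[:length]


def generate_genome(config: SynthConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Background-composition sequence with CpG-enriched blocks overlaid,
    plus the transcript annotation table. Same-strand overlapping gene
    models are rejected."""
    config.validate()
    for strand in ("+", "-"):
        gms = sorted((g for g in config.gene_models if g.strand == strand),
                     key=lambda g: g.tx_start)
        for g1, g2 in zip(gms, gms[1:]):
            if g2.tx_start < g1.tx_end:
                raise ValueError(
                    f"overlapping gene models on strand {strand}: "
                    f"[{g1.tx_start},{g1.tx_end}) and [{g2.tx_start},{g2.tx_end})"
                )
    rng = config.rng("genome")
    arr = rng.choice(np.array([A, C, G, T], dtype=np.uint8),
                     size=config.genome_length,
                     p=_background_probs(config.gc_background))
    for blk in config.cgi_blocks:
        arr[blk.start:blk.start + blk.length] = _cgi_block_seq(
            blk.length, blk.gc, blk.cpg_enrichment, rng)
    genome = {config.chrom: array_to_seq(arr)}
    ann = pd.DataFrame(
        [(config.chrom, g.tx_start, g.tx_end, f"gene{i}", g.strand,
          [es for es, _ in g.exons], [ee for _, ee in g.exons])
         for i, g in enumerate(config.gene_models)],
        columns=_regions.ANNOTATION_COLUMNS,
    )
    return genome, ann


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _noncpg_cytosines(arr: np.ndarray):
    """Plus- and minus-strand cytosines outside CpG context, with their
    CHG/CHH context; positions whose trinucleotide leaves the chromosome or
    touches an N are skipped."""
    L = len(arr)
    out = []
    plus = np.flatnonzero(arr[:-2] == C)
    plus = plus[(arr[plus + 1] != G)]
    ctx_ok = (arr[plus + 1] != N) & (arr[plus + 2] != N)
    plus = plus[ctx_ok]
    chg = arr[plus + 2] == G
    out.append((plus, "+", chg))
    minus = np.flatnonzero(arr[2:] == G) + 2
    minus = minus[arr[minus - 1] != C]
    ctx_ok = (arr[minus - 1] != N) & (arr[minus - 2] != N)
    minus = minus[ctx_ok]
    chg = arr[minus - 2] == C
    out.append((minus, "-", chg))
    return out


def generate_methylome(
    genome: dict[str, str], config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit calls for every reference-CpG cytosine (both strands, shared
    true level per dinucleotide) and a sampled fraction of CHG/CHH
    cytosines. Returns (calls, truth) aligned row for row."""
    config.validate()
    rng = config.rng("methylome")
    weights = np.array([w for w, _ in config.level_mixture])
    levels = np.array([lv for _, lv in config.level_mixture])
    mu = config.coverage_mean - 1.0

    chroms, poss, strands, ctxs, true_lvls = [], [], [], [], []
    for chrom, seq in genome.items():
        arr = seq_to_array(seq)
        di = np.flatnonzero((arr[:-1] == C) & (arr[1:] == G))
        comp = rng.choice(len(levels), size=len(di), p=weights)
        lvl_di = levels[comp]
        # interleave plus (the C) and minus (the G) site of each dinucleotide
        pos = np.column_stack([di, di + 1]).ravel()
        strand = np.tile(["+", "-"], len(di))
        lvl = np.repeat(lvl_di, 2)
        ctx = np.full(len(pos), "CG", dtype=object)

        extra_pos, extra_strand, extra_ctx = [], [], []
        for npos, nstrand, chg in _noncpg_cytosines(arr):
            keep = rng.random(len(npos)) < config.noncpg_call_fraction
            npos, chg = npos[keep], chg[keep]
            extra_pos.append(npos)
            extra_strand.append(np.full(len(npos), nstrand, dtype=object))
            extra_ctx.append(np.where(chg, "CHG", "CHH"))
        e_pos = np.concatenate(extra_pos) if extra_pos else np.array([], int)
        e_lvl = levels[rng.choice(len(levels), size=len(e_pos), p=weights)]

        pos = np.concatenate([pos, e_pos]).astype(np.int64)
        strand = np.concatenate([strand, np.concatenate(extra_strand)])
        ctx = np.concatenate([ctx, np.concatenate(extra_ctx)])
        lvl = np.concatenate([lvl, e_lvl])
        order = np.argsort(pos, kind="stable")
        chroms.append(np.full(len(pos), chrom, dtype=object))
        poss.append(pos[order])
        strands.append(strand[order])
        ctxs.append(ctx[order])
        true_lvls.append(lvl[order])

    pos = np.concatenate(poss)
    true_lvl = np.concatenate(true_lvls)
    totals = 1 + rng.poisson(mu, size=len(pos))
    mc = rng.binomial(totals, true_lvl)
    calls = pd.DataFrame({
        "chrom": np.concatenate(chroms), "pos": pos,
        "strand": np.concatenate(strands), "context": np.concatenate(ctxs),
        "mc_reads": mc.astype(np.int64), "total_reads": totals.astype(np.int64),
    })
    truth = calls[["chrom", "pos", "strand", "context"]].copy()
    truth["true_level"] = true_lvl
    truth["true_class"] = classify_level(true_lvl)
    return calls, truth


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def _alt_alleles(ref: np.ndarray, rng: np.random.Generator,
                 transition_weight: float) -> np.ndarray:
    """Alternative allele per site: the transition partner (C->T on a
    plus-strand cytosine, G->A on the complemented one) with probability
    `transition_weight`, else one of the two transversions."""
    u = rng.random(len(ref))
    v = rng.random(len(ref)) < 0.5
    alt = np.empty(len(ref), dtype=object)
    is_c = ref == "C"
    alt[is_c] = np.where(u[is_c] < transition_weight, "T",
                         np.where(v[is_c], "A", "G"))
    alt[~is_c] = np.where(u[~is_c] < transition_weight, "A",
                          np.where(v[~is_c], "C", "T"))
    return alt


def generate_snps(
    genome: dict[str, str],
    truth: pd.DataFrame,
    config: SynthConfig,
    region_index: "_regions.RegionIndex | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant SNPs on called cytosines: CpG sites by true-class rate (or by
    region label when ``region_snp_rate`` is set), CHG/CHH sites at the flat
    non-CpG rate. Returns (VCF-ready SNP table, truth with 'snp')."""
    config.validate()
    rng = config.rng("snps")
    truth = truth.copy()
    is_cpg = (truth["context"] == "CG").to_numpy()
    p = np.full(len(truth), config.noncpg_rate)
    per_class = np.array([config.class_snp_rate[c] for c in METH_CLASSES])
    p[is_cpg] = per_class[np.asarray(truth["true_class"].cat.codes)][is_cpg]
    if config.region_snp_rate is not None:
        # region-planted rates override the class rates at CpG sites whose
        # label appears in the mapping
        if region_index is None:
            raise ValueError("region_snp_rate requires a region index")
        labels = _regions.region_labels_at(region_index, truth["chrom"],
                                           truth["pos"])
        for code, lab in enumerate(_regions.REGION_LABELS):
            if lab in config.region_snp_rate:
                sel = is_cpg & (np.asarray(labels.codes) == code)
                p[sel] = config.region_snp_rate[lab]
    hit = rng.random(len(truth)) < p
    truth["snp"] = hit

    sub = truth.loc[hit]
    refs = np.array(
        [genome[c][q] for c, q in zip(sub["chrom"], sub["pos"])], dtype=object
    )
    alts = _alt_alleles(refs, rng, config.transition_weight)
    snps = pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "id": [f"rs{i}" for i in range(len(sub))],
        "ref": refs, "alt": alts,
        "validated": True, "unique_map": True,
    })
    return snps, truth


# ---------------------------------------------------------------------------
# outgroup
# ---------------------------------------------------------------------------

_SUBS = {A: (G, C, T), C: (T, A, G), G: (A, C, T), T: (C, A, G)}


def generate_outgroup(
    genome: dict[str, str], truth: pd.DataFrame, config: SynthConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Outgroup genome: CpG cytosine call sites flip with their true-class
    divergence rate (transition-weighted substitutions), every other
    position with the background rate. Returns (outgroup, truth with
    'divergent')."""
    config.validate()
    rng = config.rng("outgroup")
    truth = truth.copy()
    per_class = np.array([config.class_div_rate[c] for c in METH_CLASSES])
    outgroup: dict[str, str] = {}
    truth["divergent"] = False
    for chrom, seq in genome.items():
        arr = seq_to_array(seq)
        L = len(arr)
        rows = truth["chrom"] == chrom
        cpg_rows = rows & (truth["context"] == "CG")
        cpg_pos = truth.loc[cpg_rows, "pos"].to_numpy()
        cls = np.asarray(truth.loc[cpg_rows, "true_class"].cat.codes)

        flip_bg = rng.random(L) < config.background_div_rate
        flip_bg[arr == N] = False
        flip_bg[cpg_pos] = False  # class-governed sites are not background
        flip_cpg = rng.random(len(cpg_pos)) < per_class[cls]

        out = arr.copy()
        bg_idx = np.flatnonzero(flip_bg)
        if len(bg_idx):
            choice = rng.integers(0, 3, size=len(bg_idx))
            subs = np.array([[_SUBS[b][k] for k in range(3)] for b in
                             (A, C, G, T)], dtype=np.uint8)
            # map base byte -> row of subs
            lut = np.zeros(256, dtype=np.uint8)
            for row, b in enumerate((A, C, G, T)):
                lut[b] = row
            out[bg_idx] = subs[lut[arr[bg_idx]], choice]
        hit_pos = cpg_pos[flip_cpg]
        if len(hit_pos):
            u = rng.random(len(hit_pos))
            v = rng.random(len(hit_pos)) < 0.5
            orig = arr[hit_pos]
            is_c = orig == C
            new = np.where(
                u < config.transition_weight,
                np.where(is_c, T, A),
                np.where(v, np.where(is_c, A, C), np.where(is_c, G, T)),
            ).astype(np.uint8)
            out[hit_pos] = new
        outgroup[chrom] = array_to_seq(out)

        pos_all = truth.loc[rows, "pos"].to_numpy()
        div = out[pos_all] != arr[pos_all]
        truth.loc[rows, "divergent"] = div
    return outgroup, truth


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def generate_allele_freqs(
    snps: pd.DataFrame, truth: pd.DataFrame, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """C-allele frequency per SNP from the planted linear coupling to the
    true level; outgroup allele = cytosine allele / alternative / missing
    with configured probabilities. Returns (frequency table, truth with
    'c_freq')."""
    config.validate()
    rng = config.rng("freqs")
    truth = truth.copy()
    cp = config.freq_coupling
    merged = snps.merge(truth[["chrom", "pos", "true_level"]],
                        on=["chrom", "pos"], how="left")
    lvl = merged["true_level"].to_numpy()
    fc = np.clip(cp.intercept + cp.slope * lvl +
                 rng.normal(0.0, cp.noise_sd, size=len(merged)), 0.0, 1.0)
    u = rng.random(len(merged))
    og = np.where(u < config.outgroup_c_prob, merged["ref"],
                  np.where(u < config.outgroup_c_prob + config.outgroup_alt_prob,
                           merged["alt"], "."))
    freqs = pd.DataFrame({
        "chrom": merged["chrom"], "pos": merged["pos"],
        "alleleA": merged["ref"], "freqA": fc,
        "alleleB": merged["alt"], "freqB": 1.0 - fc,
        "outgroup_allele": og,
    })
    truth["c_freq"] = np.nan
    key = truth.set_index(["chrom", "pos"]).index
    fmap = pd.Series(fc, index=pd.MultiIndex.from_frame(merged[["chrom", "pos"]]))
    truth["c_freq"] = fmap.reindex(key).to_numpy()
    return freqs, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SynthBundle:
    config: SynthConfig
    genome: dict[str, str]
    annotation: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    snps: pd.DataFrame
    outgroup: dict[str, str]
    freqs: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def generate_bundle(config: SynthConfig,
                    outdir: str | Path | None = None,
                    region_index: "_regions.RegionIndex | None" = None
                    ) -> SynthBundle:
    """Run every generator stage; optionally serialize the whole bundle."""
    genome, ann = generate_genome(config)
    if config.region_snp_rate is not None and region_index is None:
        cgis = _regions.find_cgis_genome(genome)
        region_index = _regions.build_region_index(
            ann, cgis, {c: len(s) for c, s in genome.items()})
    calls, truth = generate_methylome(genome, config)
    snps, truth = generate_snps(genome, truth, config, region_index)
    outgroup, truth = generate_outgroup(genome, truth, config)
    freqs, truth = generate_allele_freqs(snps, truth, config)
    bundle = SynthBundle(config, genome, ann, calls, truth, snps, outgroup, freqs)
    if outdir is not None:
        bundle.paths = write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.tsv",
        "methylome": outdir / "methylome.tsv",
        "snps": outdir / "snps.vcf",
        "alignment": outdir / "alignment.axt",
        "freqs": outdir / "allele_freqs.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_fasta(bundle.genome, paths["genome"])
    _regions.write_annotation(bundle.annotation, paths["annotation"])
    _methylome.write_methylome(bundle.calls, paths["methylome"])
    _rates.write_snps(bundle.snps, paths["snps"],
                      {c: len(s) for c, s in bundle.genome.items()})
    _rates.write_alignment(bundle.genome, bundle.outgroup, paths["alignment"])
    from .alleles import write_allele_freqs
    write_allele_freqs(bundle.freqs, paths["freqs"])
    truth = bundle.truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=2, default=str)
    return paths


# ---------------------------------------------------------------------------
# closed-form accounting for the level <-> frequency coupling
# ---------------------------------------------------------------------------

def mixture_moments(level_mixture, methylated_only: bool = True
                    ) -> tuple[float, float]:
    """(mean, variance) of the level mixture, optionally conditioned on
    level > 0 — the conditioning the methylated-only analysis set applies."""
    pairs = [(w, lv) for w, lv in level_mixture
             if not (methylated_only and lv == 0)]
    wsum = sum(w for w, _ in pairs)
    if wsum == 0:
        raise ValueError("mixture has no methylated mass")
    mean = sum(w * lv for w, lv in pairs) / wsum
    var = sum(w * (lv - mean) ** 2 for w, lv in pairs) / wsum
    return mean, var


def expected_read_noise_var(level_mixture, coverage_mean: float,
                            methylated_only: bool = True) -> float:
    """E[level(1-level)/reads]: the binomial sampling variance an observed
    level adds on top of the planted one. For shifted-Poisson totals
    n = 1 + K, K ~ Poisson(mu), E[1/n] = (1 - e^-mu)/mu."""
    mu = coverage_mean - 1.0
    e_inv_n = 1.0 if mu <= 0 else (1.0 - math.exp(-mu)) / mu
    pairs = [(w, lv) for w, lv in level_mixture
             if not (methylated_only and lv == 0)]
    wsum = sum(w for w, _ in pairs)
    e_pq = sum(w * lv * (1 - lv) for w, lv in pairs) / wsum
    return e_pq * e_inv_n


def slope_for_target_r(target_r: float, level_mixture, noise_sd: float,
                       coverage_mean: float | None = None) -> float:
    """Coupling slope that yields Pearson r = target_r between *observed*
    methylation level and C-allele frequency (ignoring [0,1] clipping).

    With planted-level variance a, observed-level variance v = a + read
    noise, and frequency noise sd sigma, r = s*a / (sqrt(v)*sqrt(s^2 a +
    sigma^2)); solving gives s = r*sigma*sqrt(v / (a*(a - r^2 v))).
    """
    _, a = mixture_moments(level_mixture, methylated_only=True)
    v = a
    if coverage_mean is not None:
        v = a + expected_read_noise_var(level_mixture, coverage_mean)
    if target_r == 0:
        return 0.0
    denom = a * (a - target_r ** 2 * v)
    if denom <= 0:
        raise ValueError("target r unattainable for this mixture/coverage")
    return float(target_r * noise_sd * math.sqrt(v / denom))
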