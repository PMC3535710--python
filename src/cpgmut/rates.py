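"""Mutation-rate proxies at cytosine sites, stratified by methylation class.

Two proxies are supported, mirroring a recent-vs-ancient contrast:

* SNP density — the fraction of cytosine analysis sites carrying a
  validated, bi-allelic, uniquely mapped polymorphism whose allele pair
  contains the site's cytosine (C on plus-strand sites; G on minus-strand
  sites, i.e. the strand-complemented C SNP, since variant tables report
  plus-strand alleles).
* Divergence — among sites alignable to an outgroup genome, the fraction
  whose human and outgroup bases differ; gap and N columns never enter the
  denominator.

Both are tabulated per methylation class within arbitrary composable strata
(region label, chromosome, context, strand, coverage cutoff) as a RateTable
DataFrame: stratum columns + meth_class, n_sites, n_events, density.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core import (
    METH_CLASSES,
    METHYLATED_CLASSES,
    MalformedInputError,
    UndefinedStatisticError,
)
from . import regions as _regions

SNP_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "validated", "unique_map"]


# ---------------------------------------------------------------------------
# SNP input
# ---------------------------------------------------------------------------

def read_snps(path: str | Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a minimal VCF and apply the analysis filters.

    Keeps records that are validated (INFO flag VLD), bi-allelic SNPs
    (single one-base REF and ALT) and uniquely mapped (INFO flag UNIQ).
    Returns (records kept, counts removed per filter); positions 0-based.
    """
    counts = {"total": 0, "not_validated": 0, "not_biallelic": 0,
              "not_unique": 0, "kept": 0}
    rows = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise MalformedInputError(f"{path}: {exc}") from exc
    with vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            counts["total"] += 1
            alts = rec.alts or ()
            biallelic = (
                len(alts) == 1
                and rec.ref is not None
                and len(rec.ref) == 1
                and len(alts[0]) == 1
                and rec.ref != alts[0]
            )
            if not biallelic:
                counts["not_biallelic"] += 1
                continue
            if "VLD" not in rec.info:
                counts["not_validated"] += 1
                continue
            if "UNIQ" not in rec.info:
                counts["not_unique"] += 1
                continue
            rows.append((rec.chrom, rec.start, rec.id or ".", rec.ref.upper(),
                         alts[0].upper(), True, True))
    counts["kept"] = len(rows)
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    if df.empty:
        df = df.astype({"pos": np.int64})
    return df, counts


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=VLD,Number=0,Type=Flag,Description="Validated">
##INFO=<ID=UNIQ,Number=0,Type=Flag,Description="Uniquely mapped">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snps(snps: pd.DataFrame, path: str | Path,
               chrom_lengths: dict[str, int] | None = None) -> None:
    """Write the minimal VCF dialect (1-based positions, VLD/UNIQ flags)."""
    contigs = ""
    if chrom_lengths:
        contigs = "".join(f"##contig=<ID={c},length={n}>\n"
                          for c, n in chrom_lengths.items())
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs))
        for row in snps.itertuples(index=False):
            info = ";".join(
                flag for flag, on in
                [("VLD", row.validated), ("UNIQ", row.unique_map)] if on
            ) or "."
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t{info}\n")


def cytosine_snps(snps: pd.DataFrame, strand: str) -> pd.DataFrame:
    """SNPs relevant to cytosine mutation on one strand: allele pair contains
    C (plus-strand sites) or G (minus-strand sites, complemented C)."""
    base = "C" if strand == "+" else "G"
    keep = (snps["ref"] == base) | (snps["alt"] == base)
    return snps.loc[keep].reset_index(drop=True)


def attach_snp_events(calls: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Mark each call with whether a qualifying SNP sits on its cytosine.

    A site counts at most one event regardless of how many records share the
    position. Returns a copy with a boolean 'snp' column.
    """
    out = calls.copy()
    if snps.empty or calls.empty:
        out["snp"] = False
        return out
    plus_pos = {
        (r.chrom, r.pos) for r in cytosine_snps(snps, "+").itertuples()
    }
    minus_pos = {
        (r.chrom, r.pos) for r in cytosine_snps(snps, "-").itertuples()
    }
    keys = list(zip(out["chrom"], out["pos"]))
    is_minus = (out["strand"] == "-").to_numpy()
    out["snp"] = [
        (k in minus_pos) if m else (k in plus_pos)
        for k, m in zip(keys, is_minus)
    ]
    return out


def snp_density(calls: pd.DataFrame, snps: pd.DataFrame | None = None) -> float:
    """Fraction of cytosine sites carrying a qualifying SNP."""
    if len(calls) == 0:
        raise UndefinedStatisticError("SNP density undefined over zero sites")
    if "snp" not in calls.columns:
        if snps is None:
            raise ValueError("need either a 'snp' column or a SNP table")
        calls = attach_snp_events(calls, snps)
    return float(calls["snp"].mean())


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

def rate_table(calls: pd.DataFrame, event_col: str = "snp",
               by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Stratified counts and densities per methylation class.

    `by` names extra stratum columns already present on `calls` (e.g.
    'region', 'chrom', 'context', 'strand'). Rows with zero sites keep
    density = NaN (undefined flag) so empty strata stay visible.
    """
    cols = [*by, "meth_class"]
    grouped = calls.groupby(cols, observed=False, dropna=False)
    tab = grouped.agg(
        n_sites=(event_col, "size"), n_events=(event_col, "sum")
    ).reset_index()
    tab["n_events"] = tab["n_events"].astype(np.int64)
    tab["density"] = np.where(
        tab["n_sites"] > 0, tab["n_events"] / tab["n_sites"].clip(lower=1),
        np.nan,
    )
    return tab


def stratified_rates(
    calls: pd.DataFrame,
    snps: pd.DataFrame,
    index: "_regions.RegionIndex | None" = None,
    by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One SNP density per (stratum, methylation class).

    Strata are composable: any subset of {'region', 'chrom', 'context',
    'strand'}; 'region' requires a RegionIndex and labels each call by its
    precedence-resolved primary region (CGI overlay added as 'cgi')."""
    work = attach_snp_events(calls, snps)
    if "region" in by:
        if index is None:
            raise ValueError("'region' stratification requires a RegionIndex")
        work["region"] = _regions.region_labels_at(index, work["chrom"], work["pos"])
        work["cgi"] = _regions.cgi_flags_at(index, work["chrom"], work["pos"])
    return rate_table(work, "snp", by)


def coverage_stratified_rates(
    calls: pd.DataFrame, snps: pd.DataFrame, cutoffs: tuple[int, ...] = (1, 5, 10)
) -> pd.DataFrame:
    """Class rate table at each minimum-coverage cutoff (sensitivity slice)."""
    from .methylome import filter_coverage

    parts = []
    work = attach_snp_events(calls, snps)
    for cut in cutoffs:
        kept, _ = filter_coverage(work, cut)
        tab = rate_table(kept, "snp")
        tab.insert(0, "min_coverage", cut)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# outgroup alignment and divergence
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> pd.DataFrame:
    """Read AXT-style blocks into per-position aligned pairs.

    Returns a DataFrame (chrom, pos, human, outgroup) covering alignment
    columns where both bases are A/C/G/T; gap ('-') and N columns are
    dropped so they can never enter a divergence denominator. Positions are
    0-based reference coordinates.
    """
    rows_chrom, rows_pos, rows_h, rows_o = [], [], [], []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) < 9:
            raise MalformedInputError(f"{path}: line {i + 1}: bad AXT header")
        chrom, start = header[1], int(header[2]) - 1
        if i + 2 >= n:
            raise MalformedInputError(f"{path}: line {i + 1}: truncated block")
        human, outg = lines[i + 1].upper(), lines[i + 2].upper()
        if len(human) != len(outg):
            raise MalformedInputError(
                f"{path}: line {i + 1}: block length mismatch"
            )
        h = np.frombuffer(human.encode(), dtype=np.uint8)
        o = np.frombuffer(outg.encode(), dtype=np.uint8)
        ref_pos = np.cumsum(h != ord("-")) - 1 + start
        good = np.isin(h, np.frombuffer(b"ACGT", np.uint8)) & np.isin(
            o, np.frombuffer(b"ACGT", np.uint8)
        )
        rows_chrom.append(np.full(int(good.sum()), chrom, dtype=object))
        rows_pos.append(ref_pos[good])
        rows_h.append(h[good])
        rows_o.append(o[good])
        i += 3
    if not rows_pos:
        return pd.DataFrame({"chrom": [], "pos": [], "human": [], "outgroup": []}
                            ).astype({"pos": np.int64})
    df = pd.DataFrame({
        "chrom": np.concatenate(rows_chrom),
        "pos": np.concatenate(rows_pos).astype(np.int64),
        "human": [chr(b) for b in np.concatenate(rows_h)],
        "outgroup": [chr(b) for b in np.concatenate(rows_o)],
    })
    return df


def write_alignment(genome: dict[str, str], outgroup: dict[str, str],
                    path: str | Path) -> None:
    """One gap-free AXT block per chromosome (both sequences full length)."""
    with open(path, "w") as fh:
        for k, (chrom, seq) in enumerate(genome.items()):
            oseq = outgroup[chrom]
            fh.write(f"{k} {chrom} 1 {len(seq)} {chrom} 1 {len(oseq)} + 0\n")
            fh.write(seq + "\n")
            fh.write(oseq + "\n\n")


def attach_divergence_events(calls: pd.DataFrame,
                             pairs: pd.DataFrame) -> pd.DataFrame:
    """Mark calls with alignment status and human/outgroup disagreement."""
    out = calls.copy()
    if pairs.empty or out.empty:
        out["aligned"] = False
        out["divergent"] = False
        return out
    key = pairs.set_index(["chrom", "pos"])
    diff = (key["human"] != key["outgroup"])
    idx = pd.MultiIndex.from_arrays([out["chrom"], out["pos"]])
    out["aligned"] = idx.isin(key.index)
    d = diff.reindex(idx).to_numpy()
    out["divergent"] = np.where(pd.isna(d), False, d).astype(bool)
    return out


def divergence(calls: pd.DataFrame, pairs: pd.DataFrame | None = None) -> float:
    """Proportion of aligned sites whose human and outgroup bases differ."""
    work = calls
    if "aligned" not in work.columns:
        if pairs is None:
            raise ValueError("need aligned/divergent columns or an alignment")
        work = attach_divergence_events(work, pairs)
    aligned = work.loc[work["aligned"]]
    if len(aligned) == 0:
        raise UndefinedStatisticError("divergence undefined with no aligned sites")
    return float(aligned["divergent"].mean())


def divergence_rate_table(calls: pd.DataFrame, pairs: pd.DataFrame,
                          by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Divergence per methylation class (denominator = aligned sites only)."""
    work = attach_divergence_events(calls, pairs)
    work = work.loc[work["aligned"]].reset_index(drop=True)
    return rate_table(work, "divergent", by)


# ---------------------------------------------------------------------------
# gene density vs rate
# ---------------------------------------------------------------------------

def gene_density_rate_correlation(
    chrom_rates: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int],
) -> tuple[float, float]:
    """Pearson r between per-chromosome gene density (genes/Mb) and SNP
    density at methylated CpG sites.

    `chrom_rates` is a rate table stratified by 'chrom'; methylated classes
    are pooled per chromosome. Needs >= 3 chromosomes; zero variance in
    either variable is signalled as undefined.
    """
    meth = chrom_rates[chrom_rates["meth_class"].isin(METHYLATED_CLASSES)]
    agg = meth.groupby("chrom", observed=True).agg(
        n_sites=("n_sites", "sum"), n_events=("n_events", "sum")
    )
    agg = agg[agg["n_sites"] > 0]
    if len(agg) < 3:
        raise ValueError("need at least 3 chromosomes with methylated sites")
    dens = agg["n_events"] / agg["n_sites"]
    genes = annotation.groupby("chrom")["name"].count()
    gene_density = pd.Series(
        {c: genes.get(c, 0) / (chrom_lengths[c] / 1e6) for c in agg.index}
    )
    if dens.std() == 0 or gene_density.std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = stats.pearsonr(gene_density.loc[agg.index], dens)
    return float(r), float(p)
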