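"""Allele frequencies at methylated CpG SNPs and their link to methylation.

The ancestral allele of a polymorphism is inferred from an outgroup base:
when the outgroup allele equals exactly one of the two human alleles it is
taken as ancestral, otherwise the ancestral state is left missing. The
cytosine-allele frequency of a site is the frequency of C (of G for a
minus-strand cytosine, which is the complemented C). The analysis set is
methylated (level > 0) reference-CpG cytosines carrying a qualifying SNP.

Quantitative summaries: Pearson correlation of methylation level against
the cytosine / major / ancestral allele frequency; a binned regression of
mean methylation level on cytosine-allele-frequency bins; and two-group
mean comparisons (Welch by default, rank-sum optionally).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import UndefinedStatisticError

FREQ_COLUMNS = ["chrom", "pos", "alleleA", "freqA", "alleleB", "freqB",
                "outgroup_allele"]

_FREQ_TOL = 1e-6


def read_allele_freqs(path: str | Path) -> pd.DataFrame:
    """TSV dialect: chrom, 1-based pos, alleleA, freqA, alleleB, freqB,
    outgroup allele ('.' = missing). Positions converted to 0-based."""
    df = pd.read_csv(path, sep="\t", header=None, names=FREQ_COLUMNS,
                     dtype={"chrom": str, "alleleA": str, "alleleB": str,
                            "outgroup_allele": str})
    df["pos"] = df["pos"].astype(np.int64) - 1
    bad = (df["freqA"] + df["freqB"] - 1).abs() > _FREQ_TOL
    if bad.any():
        raise ValueError(f"{path}: line {bad.idxmax() + 1}: freqA + freqB != 1")
    if (df["alleleA"] == df["alleleB"]).any():
        raise ValueError(f"{path}: identical alleles in a record")
    return df


def write_allele_freqs(freqs: pd.DataFrame, path: str | Path) -> None:
    out = freqs[FREQ_COLUMNS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", header=False, index=False)


def infer_ancestral(freqs: pd.DataFrame) -> pd.Series:
    """Ancestral allele per record, or NaN when the outgroup base is missing
    or matches neither human allele. Always one of the record's alleles."""
    og = freqs["outgroup_allele"]
    out = pd.Series(np.nan, index=freqs.index, dtype=object)
    out[og == freqs["alleleA"]] = og
    out[og == freqs["alleleB"]] = og
    return out


def cytosine_frequency(freqs: pd.DataFrame, strand) -> pd.Series:
    """Frequency of the strand-appropriate cytosine allele (C on '+', G on
    '-'); NaN where neither allele is that base."""
    strand = pd.Series(np.asarray(strand), index=freqs.index)
    target = np.where(strand == "-", "G", "C")
    out = pd.Series(np.nan, index=freqs.index, dtype=float)
    a = freqs["alleleA"] == target
    b = freqs["alleleB"] == target
    out[a] = freqs.loc[a, "freqA"]
    out[b] = freqs.loc[b, "freqB"]
    return out


def major_allele(freqs: pd.DataFrame, strand) -> pd.Series:
    """Allele with frequency >= 0.5; exact ties go to the cytosine allele
    when one of the pair is the strand-appropriate cytosine."""
    strand = pd.Series(np.asarray(strand), index=freqs.index)
    target = pd.Series(np.where(strand == "-", "G", "C"), index=freqs.index)
    major = pd.Series(
        np.where(freqs["freqA"] >= freqs["freqB"], freqs["alleleA"], freqs["alleleB"]),
        index=freqs.index, dtype=object,
    )
    tie = (freqs["freqA"] - freqs["freqB"]).abs() <= _FREQ_TOL
    has_c = (freqs["alleleA"] == target) | (freqs["alleleB"] == target)
    major[tie & has_c] = target[tie & has_c]
    return major


def annotate_sites(freqs: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Join frequency records onto methylated reference-CpG cytosine calls.

    `calls` must already be context-filtered to CG and carry 'level' (and
    'meth_class'); only level > 0 sites enter the analysis set. Returns the
    joined table with cytosine/major/ancestral annotations; join statistics
    land in ``df.attrs['join_stats']``.
    """
    meth = calls.loc[calls["level"] > 0] if len(calls) else calls
    merged = freqs.merge(
        meth, on=["chrom", "pos"], how="inner", suffixes=("", "_call")
    )
    stats_ = {
        "n_freq_records": int(len(freqs)),
        "n_methylated_calls": int(len(meth)),
        "n_joined": int(len(merged)),
    }
    if len(merged):
        merged["c_freq"] = cytosine_frequency(merged, merged["strand"])
        merged["ancestral"] = infer_ancestral(merged)
        merged["major"] = major_allele(merged, merged["strand"])
        target = pd.Series(np.where(merged["strand"] == "-", "G", "C"),
                           index=merged.index)
        merged["major_is_c"] = merged["major"] == target
        merged["ancestral_is_c"] = merged["ancestral"] == target
        anc = merged["ancestral"]
        freq = pd.Series(np.nan, index=merged.index, dtype=float)
        a = anc == merged["alleleA"]
        b = anc == merged["alleleB"]
        freq[a] = merged.loc[a, "freqA"]
        freq[b] = merged.loc[b, "freqB"]
        merged["ancestral_freq"] = freq
        merged["major_freq"] = merged[["freqA", "freqB"]].max(axis=1)
    else:
        for col in ("c_freq", "ancestral", "major", "major_is_c",
                    "ancestral_is_c", "ancestral_freq", "major_freq"):
            merged[col] = []
    merged.attrs["join_stats"] = stats_
    return merged


_FREQ_CHOICES = {"cytosine": "c_freq", "major": "major_freq",
                 "ancestral": "ancestral_freq"}


def correlate_level_frequency(
    sites: pd.DataFrame, which: str = "cytosine"
) -> tuple[float, float, int]:
    """Pearson r (with p-value and n) between methylation level and the
    chosen allele frequency, over sites where both are defined."""
    col = _FREQ_CHOICES[which]
    work = sites[["level", col]].dropna()
    n = len(work)
    if n < 3:
        raise ValueError("need at least 3 sites for a correlation")
    if work["level"].std() == 0 or work[col].std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = stats.pearsonr(work["level"], work[col])
    return float(r), float(p), n


def binned_regression(
    sites: pd.DataFrame,
    n_bins: int = 5,
    which: str = "cytosine",
    scheme: str = "width",
) -> tuple[pd.DataFrame, float]:
    """Bin sites by allele frequency; regress per-bin mean level on the bin
    midpoint.

    scheme='width': equal-width bins over [0, 1] (midpoint = bin centre);
    scheme='count': equal-count (quantile) bins, midpoint = median frequency
    in the bin. Empty bins are flagged and excluded from the fit. Returns
    (per-bin table, correlation coefficient of the fit).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    col = _FREQ_CHOICES[which]
    work = sites[["level", col]].dropna()
    if scheme == "width":
        edges = np.linspace(0, 1, n_bins + 1)
        idx = np.clip(np.digitize(work[col], edges[1:-1]), 0, n_bins - 1)
        mids = (edges[:-1] + edges[1:]) / 2
    elif scheme == "count":
        ranks = work[col].rank(method="first") - 1
        idx = np.floor(ranks / len(work) * n_bins).astype(int).clip(0, n_bins - 1)
        mids = np.full(n_bins, np.nan)
    else:
        raise ValueError("scheme must be 'width' or 'count'")
    rows = []
    for b in range(n_bins):
        sel = work.loc[np.asarray(idx) == b]
        mid = float(np.median(sel[col])) if (scheme == "count" and len(sel)) \
            else float(mids[b]) if scheme == "width" else np.nan
        rows.append((b, mid, len(sel),
                     float(sel["level"].mean()) if len(sel) else np.nan))
    table = pd.DataFrame(rows, columns=["bin", "midpoint", "n", "mean_level"])
    fit = table.dropna(subset=["mean_level", "midpoint"])
    if len(fit) < 2:
        raise UndefinedStatisticError("fewer than 2 non-empty bins: no fit")
    if fit["mean_level"].std() == 0 or fit["midpoint"].std() == 0:
        raise UndefinedStatisticError("zero variance across bins: fit undefined")
    res = stats.linregress(fit["midpoint"], fit["mean_level"])
    return table, float(res.rvalue)


_GROUPINGS = ("major", "ancestral", "ancestral_c_major")


def compare_groups(
    sites: pd.DataFrame, grouping: str = "major", test: str = "welch"
) -> tuple[float, float, float]:
    """Compare mean methylation level between two allele-defined groups.

    grouping='major': major allele is the cytosine vs not;
    'ancestral': ancestral allele is the cytosine vs not (inferred only);
    'ancestral_c_major': among ancestral-is-C sites, major C vs major not-C.
    Returns (mean A, mean B, two-sided p) from a Welch location test
    (test='ranksum' switches to Mann-Whitney U).
    """
    if grouping == "major":
        work = sites
        mask = work["major_is_c"].astype(bool)
    elif grouping == "ancestral":
        work = sites.dropna(subset=["ancestral"])
        mask = work["ancestral_is_c"].astype(bool)
    elif grouping == "ancestral_c_major":
        work = sites.dropna(subset=["ancestral"])
        work = work.loc[work["ancestral_is_c"].astype(bool)]
        mask = work["major_is_c"].astype(bool)
    else:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    a = work.loc[mask, "level"]
    b = work.loc[~mask, "level"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 sites")
    if test == "welch":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "ranksum":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError("test must be 'welch' or 'ranksum'")
    return float(a.mean()), float(b.mean()), float(p)
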