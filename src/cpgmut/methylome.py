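"""Per-cytosine methylation calls: parsing, context filtering, levels, classes.

A methylome is a pandas DataFrame with one row per called cytosine:

    chrom, pos (0-based plus-strand coordinate of the cytosine base),
    strand ('+'/'-'), context ('CG'/'CHG'/'CHH'), mc_reads, total_reads

The methylation level ("deepness") of a call is mc_reads / total_reads; a
site is methylated iff its level is > 0, i.e. at least one read reported a
methylated cytosine. Methylated sites split further into five 20%-wide
classes (see :func:`cpgmut.core.classify_level`). The two cytosines of one
CpG dinucleotide are distinct analysis units; nothing here merges strands.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import C, G, METH_CLASSES, MalformedInputError, classify_level, seq_to_array

CONTEXTS = ("CG", "CHG", "CHH")
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "mc_reads", "total_reads"]

_DTYPES = {"chrom": str, "strand": str, "context": str}


def read_methylome(path: str | Path) -> pd.DataFrame:
    """Parse a Lister-style TSV (chrom, 1-based pos, strand, context, mc, total).

    Positions are converted to 0-based. Rows with total_reads == 0,
    mc_reads > total_reads, an unknown context token or a non-numeric count
    are rejected with the offending line number.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CALL_COLUMNS, dtype=_DTYPES
        )
    except pd.errors.EmptyDataError:
        return empty_methylome()
    for col in ("pos", "mc_reads", "total_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            raise MalformedInputError(
                f"{path}: line {bad.idxmax() + 1}: non-integer {col!r} field"
            )
        df[col] = vals.astype(np.int64)
    for cond, msg in [
        (~df["context"].isin(CONTEXTS), "unknown context token"),
        (~df["strand"].isin(["+", "-"]), "strand must be '+' or '-'"),
        (df["total_reads"] < 1, "total_reads must be >= 1"),
        ((df["mc_reads"] < 0) | (df["mc_reads"] > df["total_reads"]),
         "mc_reads must satisfy 0 <= mc_reads <= total_reads"),
        (df["pos"] < 1, "1-based position must be >= 1"),
    ]:
        if cond.any():
            raise MalformedInputError(f"{path}: line {cond.idxmax() + 1}: {msg}")
    df["pos"] -= 1
    return df.reset_index(drop=True)


def write_methylome(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls[CALL_COLUMNS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", header=False, index=False)


def empty_methylome() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in CALL_COLUMNS})
    return df.astype({"pos": np.int64, "mc_reads": np.int64, "total_reads": np.int64,
                      **_DTYPES})


def methylation_level(calls: pd.DataFrame) -> pd.Series:
    """Methylation deepness: methylated reads over total mapped reads."""
    return calls["mc_reads"] / calls["total_reads"]


def add_level_and_class(calls: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with 'level' and ordered-categorical 'meth_class' columns."""
    out = calls.copy()
    out["level"] = methylation_level(out)
    if len(out):
        out["meth_class"] = classify_level(out["level"].to_numpy())
    else:
        out["meth_class"] = pd.Categorical([], categories=METH_CLASSES, ordered=True)
    return out


def _context_mask(arr: np.ndarray, pos: np.ndarray, minus: np.ndarray,
                  context: str) -> np.ndarray:
    """Boolean mask: call at (pos, strand) sits in `context` on the reference.

    Contexts are read 5'->3' on the call's own strand; out-of-range
    neighbours fail the match rather than erroring.
    """
    L = len(arr)
    n1 = np.full(len(pos), -1)  # +1 position in reading direction
    n2 = np.full(len(pos), -1)
    plus = ~minus
    n1[plus] = pos[plus] + 1
    n2[plus] = pos[plus] + 2
    n1[minus] = pos[minus] - 1
    n2[minus] = pos[minus] - 2
    ok1 = (n1 >= 0) & (n1 < L)
    ok2 = (n2 >= 0) & (n2 < L)
    b0 = arr[pos]
    b1 = np.where(ok1, arr[np.clip(n1, 0, L - 1)], 0)
    b2 = np.where(ok2, arr[np.clip(n2, 0, L - 1)], 0)
    is_c = np.where(minus, b0 == G, b0 == C)  # cytosine on own strand
    # next base on own strand is G  <=>  plus: b1==G ; minus: complement(b1)==G i.e. b1==C
    nxt_g = np.where(minus, b1 == C, b1 == G) & ok1
    nn_g = np.where(minus, b2 == C, b2 == G) & ok2
    nxt_acgt = ok1 & np.isin(b1, (ord("A"), ord("C"), ord("G"), ord("T")))
    nn_acgt = ok2 & np.isin(b2, (ord("A"), ord("C"), ord("G"), ord("T")))
    if context == "CG":
        return is_c & nxt_g
    if context == "CHG":
        return is_c & nxt_acgt & ~nxt_g & nn_g
    if context == "CHH":
        return is_c & nxt_acgt & ~nxt_g & nn_acgt & ~nn_g
    raise ValueError(f"unknown context {context!r}")


def filter_reference_context(
    calls: pd.DataFrame, genome: dict[str, str], context: str = "CG"
) -> tuple[pd.DataFrame, int]:
    """Keep calls whose position matches `context` on the reference.

    A plus-strand CG call at p survives iff genome[p:p+2] == "CG"; a
    minus-strand one iff genome[p-1:p+1] == "CG" (the call sits on the G).
    A call whose own context token differs from `context` is dropped too:
    it cannot be mapped to a reference site of its declared context.
    Returns (kept calls, number dropped). Idempotent. Positions outside the
    genome raise.
    """
    if calls.empty:
        return calls.copy(), 0
    calls = calls.reset_index(drop=True)
    keep = (calls["context"] == context).to_numpy()
    for chrom, grp in calls.groupby("chrom", sort=False):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        arr = seq_to_array(genome[chrom])
        pos = grp["pos"].to_numpy()
        if np.any((pos < 0) | (pos >= len(arr))):
            raise IndexError(f"call position outside chromosome {chrom}")
        minus = (grp["strand"] == "-").to_numpy()
        keep[grp.index] &= _context_mask(arr, pos, minus, context)
    kept = calls.loc[keep].reset_index(drop=True)
    return kept, int(len(calls) - len(kept))


def filter_coverage(calls: pd.DataFrame, min_total: int) -> tuple[pd.DataFrame, int]:
    """Keep calls with total_reads >= min_total; returns (kept, n_removed)."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    keep = calls["total_reads"] >= min_total
    return calls.loc[keep].reset_index(drop=True), int((~keep).sum())


def split_by_strand(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    plus = calls.loc[calls["strand"] == "+"].reset_index(drop=True)
    minus = calls.loc[calls["strand"] == "-"].reset_index(drop=True)
    return plus, minus
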