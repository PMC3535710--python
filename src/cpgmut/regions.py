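"""Genomic stratification: CpG-island detection and region labelling.

CpG islands are found with the Takai–Jones criteria — length >= 500 bp,
GC content >= 55% and CpG observed/expected ratio >= 0.65, where

    O/E = (#CpG dinucleotides * L) / (#C * #G)

— using the canonical seed/extend/trim scan: slide a 200-bp window base by
base until it meets the GC and O/E thresholds, extend rightward in 200-bp
jumps while the trailing 200-bp window still qualifies, then trim one base
from each end at a time until the whole candidate qualifies; candidates
shorter than 500 bp are discarded and scanning resumes one base after the
seed. Accepted islands that overlap or abut (configurable gap, default 0)
are merged and the merged interval re-verified.

The primary region labels form a partition of each chromosome: every base
is exactly one of promoter, exonic, intronic or intergenic, resolved with
precedence promoter > exonic > intronic > intergenic. The promoter of a
transcript is the interval −1500/+500 around its TSS in the direction of
transcription. CpG islands are an independent overlay flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    C,
    G,
    N,
    REGION_LABELS,
    UndefinedStatisticError,
    seq_to_array,
)

PROMOTER, EXONIC, INTRONIC, INTERGENIC = range(4)

MIN_LENGTH = 500
MIN_GC = 0.55
MIN_OE = 0.65
SEED_WINDOW = 200
MAX_N_FRAC = 0.1  # windows with more ambiguous bases than this never qualify


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def gc_content(window: str) -> float:
    """(#G + #C) / (non-N length); raises on an all-N window."""
    arr = seq_to_array(window)
    n_n = int((arr == N).sum())
    denom = len(arr) - n_n
    if denom == 0:
        raise UndefinedStatisticError("GC content undefined on an all-N window")
    return float(((arr == C).sum() + (arr == G).sum()) / denom)


def cpg_oe(window: str) -> float:
    """CpG observed/expected ratio, (#CpG * L) / (#C * #G), L = non-N length.

    Returns 0.0 when there are no C's or no G's (then #CpG is necessarily 0).
    """
    arr = seq_to_array(window)
    if len(arr) == 0:
        raise UndefinedStatisticError("O/E undefined on an empty window")
    n_c = int((arr == C).sum())
    n_g = int((arr == G).sum())
    n_cpg = int(((arr[:-1] == C) & (arr[1:] == G)).sum())
    length = len(arr) - int((arr == N).sum())
    if length == 0:
        raise UndefinedStatisticError("O/E undefined on an all-N window")
    if n_c * n_g == 0:
        return 0.0
    return float(n_cpg * length / (n_c * n_g))


class _SeqProfile:
    """Prefix sums over one chromosome so any window's GC / O/E is O(1)."""

    def __init__(self, seq: str):
        arr = seq_to_array(seq)
        self.length = len(arr)
        is_c = arr == C
        is_g = arr == G
        is_n = arr == N
        is_cpg = np.zeros(self.length, dtype=bool)
        if self.length > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate([z, np.cumsum(is_c)])
        self.cum_g = np.concatenate([z, np.cumsum(is_g)])
        self.cum_n = np.concatenate([z, np.cumsum(is_n)])
        self.cum_cpg = np.concatenate([z, np.cumsum(is_cpg)])

    def counts(self, start, end):
        """(#C, #G, #N, #CpG-fully-inside) for [start, end) — vectorised."""
        n_c = self.cum_c[end] - self.cum_c[start]
        n_g = self.cum_g[end] - self.cum_g[start]
        n_n = self.cum_n[end] - self.cum_n[start]
        # a CpG counts when both bases are inside the window
        n_cpg = self.cum_cpg[np.maximum(end - 1, start)] - self.cum_cpg[start]
        return n_c, n_g, n_n, n_cpg

    def window_ok(self, start, end, min_gc=MIN_GC, min_oe=MIN_OE,
                  max_n_frac=MAX_N_FRAC):
        """Vectorised three-criterion check (GC, O/E, N fraction) on windows."""
        start = np.asarray(start)
        end = np.asarray(end)
        n_c, n_g, n_n, n_cpg = self.counts(start, end)
        length = end - start
        nn_len = length - n_n
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(nn_len > 0, (n_c + n_g) / np.maximum(nn_len, 1), 0.0)
            oe = np.where(n_c * n_g > 0,
                          n_cpg * nn_len / np.maximum(n_c * n_g, 1), 0.0)
        return (
            (n_n <= max_n_frac * length)
            & (nn_len > 0)
            & (gc >= min_gc)
            & (oe >= min_oe)
        )

    def stats(self, start: int, end: int) -> tuple[float, float]:
        n_c, n_g, n_n, n_cpg = self.counts(start, end)
        nn_len = int(end - start - n_n)
        gc = (n_c + n_g) / nn_len if nn_len else float("nan")
        oe = n_cpg * nn_len / (n_c * n_g) if n_c * n_g else 0.0
        return float(gc), float(oe)


# ---------------------------------------------------------------------------
# Takai–Jones scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc: float
    oe: float

    @property
    def length(self) -> int:
        return self.end - self.start


def find_cgis(
    seq: str,
    chrom: str = "chr1",
    min_length: int = MIN_LENGTH,
    min_gc: float = MIN_GC,
    min_oe: float = MIN_OE,
    merge_gap: int = 0,
    window: int = SEED_WINDOW,
) -> list[CpGIsland]:
    """Takai–Jones CpG-island scan over one chromosome sequence."""
    L = len(seq)
    if L < min_length:
        return []
    prof = _SeqProfile(seq)
    starts = np.arange(0, L - window + 1)
    ok = prof.window_ok(starts, starts + window, min_gc, min_oe)

    cum_c, cum_g = prof.cum_c, prof.cum_g
    cum_n, cum_cpg = prof.cum_n, prof.cum_cpg

    def meets(s: int, e: int) -> bool:
        # scalar fast path of _SeqProfile.window_ok (the trim loops hit this)
        n_n = int(cum_n[e] - cum_n[s])
        length = e - s
        nn_len = length - n_n
        if n_n > MAX_N_FRAC * length or nn_len == 0:
            return False
        n_c = int(cum_c[e] - cum_c[s])
        n_g = int(cum_g[e] - cum_g[s])
        # keep the float expressions identical to window_ok's vectorised ones
        if (n_c + n_g) / nn_len < min_gc:
            return False
        if n_c * n_g == 0:
            return False
        n_cpg = int(cum_cpg[max(e - 1, s)] - cum_cpg[s])
        return n_cpg * nn_len / (n_c * n_g) >= min_oe

    ok_starts = np.flatnonzero(ok)  # for rollback queries

    def _extend(seed: int) -> int:
        """Grow the candidate end: 200-bp jumps while the trailing window
        qualifies; on a failed jump, roll the window back 1 bp at a time to
        the nearest qualifying start (the original algorithm's rollback),
        which also bridges sub-window gaps; stop when the end stops moving."""
        e = seed + window
        while True:
            if e + window <= L and ok[e]:
                e += window
                continue
            lo = np.searchsorted(ok_starts, e - window + 1)
            hi = np.searchsorted(ok_starts, min(e, L - window), side="right")
            if hi > lo and ok_starts[hi - 1] + window > e:
                e = int(ok_starts[hi - 1]) + window
                continue
            return e

    def _trim(s: int, e: int) -> tuple[int, int] | None:
        """Shrink until the whole candidate qualifies: symmetric 1 bp from
        both ends first, then left-only and right-only passes so a
        qualifying stretch at either edge of a failing candidate can still
        be isolated."""
        ts, te = s, e
        while te - ts >= min_length and not meets(ts, te):
            ts += 1
            te -= 1
        if te - ts >= min_length and meets(ts, te):
            return ts, te
        for step_l, step_r in ((1, 0), (0, 1)):
            ts, te = s, e
            while te - ts >= min_length and not meets(ts, te):
                ts += step_l
                te -= step_r
            if te - ts >= min_length and meets(ts, te):
                return ts, te
        if e - s < min_length:
            # short candidate: its neighbourhood may still qualify in
            # aggregate once padded to the minimum length
            mid = (s + e) // 2
            for ts in (e - min_length, s, mid - min_length // 2):
                ts = min(max(ts, 0), L - min_length)
                if ts >= 0 and meets(ts, ts + min_length):
                    return ts, ts + min_length
        return None

    raw: list[tuple[int, int]] = []
    i = 0
    n_seeds = len(starts)
    while i < n_seeds:
        if not ok[i]:
            nxt = np.argmax(ok[i:])
            if not ok[i + nxt]:
                break
            i += int(nxt)
        seed = i
        e = _extend(seed)
        trimmed = _trim(seed, e)
        if trimmed is not None:
            raw.append(trimmed)
            i = trimmed[1]
        else:
            i = seed + 1

    merged = _merge_islands(raw, prof, min_length, min_gc, min_oe, merge_gap)
    out = []
    for s, e in merged:
        gc, oe = prof.stats(s, e)
        out.append(CpGIsland(chrom, int(s), int(e), gc, oe))
    return out


def _merge_islands(raw, prof, min_length, min_gc, min_oe, merge_gap):
    """Merge overlapping/abutting accepted islands; keep a merge only if the
    merged interval still satisfies all three criteria."""
    if not raw:
        return []
    raw = sorted(raw)
    out = [raw[0]]
    for s, e in raw[1:]:
        ps, pe = out[-1]
        if s <= pe + merge_gap:
            cand = (ps, max(pe, e))
            if cand[1] - cand[0] >= min_length and bool(
                prof.window_ok(np.array([cand[0]]), np.array([cand[1]]),
                               min_gc, min_oe)[0]
            ):
                out[-1] = cand
                continue
        out.append((s, e))
    return out


def find_cgis_genome(genome: dict[str, str], **kwargs) -> list[CpGIsland]:
    islands: list[CpGIsland] = []
    for chrom, seq in genome.items():
        islands.extend(find_cgis(seq, chrom=chrom, **kwargs))
    return islands


def cgis_to_frame(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.chrom, c.start, c.end, c.gc, c.oe) for c in islands],
        columns=["chrom", "start", "end", "gc", "oe"],
    )


# ---------------------------------------------------------------------------
# annotation and region index
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["chrom", "tx_start", "tx_end", "name", "strand",
                      "exon_starts", "exon_ends"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """BED12-like transcript table: chrom, txStart, txEnd, name, strand,
    exonStarts, exonEnds (comma-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str})
    for col in ("exon_starts", "exon_ends"):
        df[col] = df[col].apply(
            lambda s: [int(x) for x in str(s).rstrip(",").split(",") if x != ""]
        )
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    for col in ("exon_starts", "exon_ends"):
        out[col] = out[col].apply(lambda xs: ",".join(str(x) for x in xs) + ",")
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegionIndex:
    """Dense per-chromosome primary labels plus a CpG-island overlay."""

    labels: dict[str, np.ndarray]  # uint8 arrays over REGION_LABELS codes
    cgi: dict[str, np.ndarray]  # bool arrays
    n_promoters_clipped: int = 0
    islands: list[CpGIsland] = field(default_factory=list)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in REGION_LABELS}
        for arr in self.labels.values():
            for code, lab in enumerate(REGION_LABELS):
                counts[lab] += int((arr == code).sum())
        return counts


def build_region_index(
    annotation: pd.DataFrame,
    cgis: list[CpGIsland],
    chrom_lengths: dict[str, int],
    promoter_upstream: int = 1500,
    promoter_downstream: int = 500,
) -> RegionIndex:
    """Paint the partition: intergenic by default, then genic spans as
    intronic, exons on top, promoters last (highest precedence). Promoters
    run [TSS − 1500, TSS + 500) in the direction of transcription; for a
    minus-strand transcript the TSS is tx_end and the genomic interval is
    [tx_end − 500, tx_end + 1500). Promoters poking past a chromosome edge
    are clipped (counted)."""
    labels = {c: np.full(n, INTERGENIC, dtype=np.uint8)
              for c, n in chrom_lengths.items()}
    clipped = 0

    def _paint(chrom, start, end, code):
        arr = labels[chrom]
        s, e = max(0, start), min(len(arr), end)
        if s < e:
            arr[s:e] = code

    for _, tx in annotation.iterrows():
        if tx.chrom not in labels:
            raise KeyError(f"annotation chromosome {tx.chrom!r} not in genome")
        if not (0 <= tx.tx_start < tx.tx_end <= len(labels[tx.chrom])):
            raise ValueError(f"transcript {tx['name']} outside chromosome")
        _paint(tx.chrom, tx.tx_start, tx.tx_end, INTRONIC)
    for _, tx in annotation.iterrows():
        for es, ee in zip(tx.exon_starts, tx.exon_ends):
            _paint(tx.chrom, es, ee, EXONIC)
    for _, tx in annotation.iterrows():
        if tx.strand == "+":
            p_start, p_end = tx.tx_start - promoter_upstream, tx.tx_start + promoter_downstream
        else:
            p_start, p_end = tx.tx_end - promoter_downstream, tx.tx_end + promoter_upstream
        if p_start < 0 or p_end > len(labels[tx.chrom]):
            clipped += 1
        _paint(tx.chrom, p_start, p_end, PROMOTER)

    cgi = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for isl in cgis:
        if isl.chrom in cgi:
            cgi[isl.chrom][isl.start:isl.end] = True

    return RegionIndex(labels=labels, cgi=cgi, n_promoters_clipped=clipped,
                       islands=list(cgis))


def classify_position(index: RegionIndex, chrom: str, pos: int) -> tuple[str, bool]:
    """Primary label and CGI-overlay flag for one genome position."""
    arr = index.labels[chrom]
    if not 0 <= pos < len(arr):
        raise IndexError(f"position {pos} outside chromosome {chrom}")
    return REGION_LABELS[arr[pos]], bool(index.cgi[chrom][pos])


def region_labels_at(index: RegionIndex, chroms: pd.Series,
                     positions: pd.Series) -> pd.Categorical:
    """Vectorised primary labels for many (chrom, pos) pairs."""
    codes = np.empty(len(chroms), dtype=np.int64)
    chroms = pd.Series(np.asarray(chroms), name="chrom")
    positions = np.asarray(positions)
    for chrom, idx in chroms.groupby(chroms).groups.items():
        idx = np.asarray(idx)
        codes[idx] = index.labels[chrom][positions[idx]]
    return pd.Categorical.from_codes(codes, categories=REGION_LABELS)


def cgi_flags_at(index: RegionIndex, chroms: pd.Series,
                 positions: pd.Series) -> np.ndarray:
    flags = np.empty(len(chroms), dtype=bool)
    chroms = pd.Series(np.asarray(chroms), name="chrom")
    positions = np.asarray(positions)
    for chrom, idx in chroms.groupby(chroms).groups.items():
        idx = np.asarray(idx)
        flags[idx] = index.cgi[chrom][positions[idx]]
    return flags
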