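"""Shared vocabulary: methylation classes, region labels, genome I/O helpers.

Coordinates are 0-based half-open everywhere inside the package; readers and
writers convert at the boundary (methylome TSV, VCF and AXT are 1-based on
disk, the annotation table and FASTA are not).
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

# Six-way methylation category: unmethylated (level == 0) plus five
# 20-percentage-point bins of positive levels, half-open on the left.
METH_CLASSES = ["unmethylated", "low", "low_int", "int", "high_int", "high"]
METHYLATED_CLASSES = METH_CLASSES[1:]

# Mutually exclusive primary region labels (precedence-resolved); CpG islands
# are an independent overlay, not a fifth primary label.
REGION_LABELS = ["promoter", "exonic", "intronic", "intergenic"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
A, C, G, T, N = (ord(x) for x in "ACGTN")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class MalformedInputError(ValueError):
    """An input file violates its dialect (reported with line number)."""


class UndefinedStatisticError(ValueError):
    """A statistic has an empty or degenerate denominator (zero variance,
    zero aligned sites, all-N window, ...)."""


def seq_to_array(seq: str) -> np.ndarray:
    """Uppercase sequence as a uint8 byte array (A/C/G/T/N)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a {chrom: uppercase sequence} dict."""
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)))
            fh.write("\n")


def genome_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def classify_level(level):
    """Map methylation level(s) in [0, 1] to the six-way class.

    0 -> unmethylated; then half-open bins (0,.2] low, (.2,.4] low_int,
    (.4,.6] int, (.6,.8] high_int, (.8,1] high, so 20% is "low" and 80%
    is "high_int" while anything above 80% is "high".
    """
    arr = np.asarray(level, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("methylation level must lie in [0, 1]")
    idx = np.where(arr == 0, 0, 1 + np.digitize(arr, [0.2, 0.4, 0.6, 0.8], right=True))
    out = pd.Categorical.from_codes(
        np.atleast_1d(idx), categories=METH_CLASSES, ordered=True
    )
    if np.isscalar(level) or (isinstance(level, np.ndarray) and level.ndim == 0):
        return out[0]
    return out


def class_categorical(values) -> pd.Categorical:
    """Coerce class labels into the ordered categorical used throughout."""
    return pd.Categorical(values, categories=METH_CLASSES, ordered=True)
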