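"""Per-position allele counting from aligned reads, with base-quality filtering.

The unit of all downstream statistics is a per-position count vector over
A/C/G/T plus an "other" bucket (low-quality calls, Ns, deleted bases).  In
bulk the pileup is carried as a pandas DataFrame with one row per covered
position (columns ``chrom, pos, ref, A, C, G, T, other, depth``); the
:class:`PositionCounts` dataclass wraps single rows for scalar operations.

By default low-quality and non-ACGT bases still count toward depth, so VAF
denominators match the total coverage at the position; ``lowq_in_depth=False``
selects the alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from . import reference as ref_mod
from .errors import UndefinedFrequencyError
from .reference import BASES, CHROM, MiniReference, TargetRegion

#: Default phred cutoff; amplicon QC shows read qualities rarely dip below 30.
DEFAULT_MIN_BASE_QUALITY = 30
#: Design depth of the amplicon assay.
DEFAULT_MIN_DEPTH = 5000

PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "other", "depth"]

#: hg19 chr2 length, for SAM headers.
_CHR2_LENGTH = 243_199_373


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read: leftmost 1-based position, bases, per-base phred scores."""

    chrom: str
    pos: int
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")
        if len(self.seq) == 0:
            raise ValueError("empty read")
        if self.pos < 1:
            raise ValueError(f"read position {self.pos} is not 1-based positive")


@dataclass(frozen=True)
class PositionCounts:
    chrom: str
    pos: int
    ref: str
    A: int
    C: int
    G: int
    T: int
    other: int = 0

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValueError(f"reference base {self.ref!r} not in ACGT")
        if min(self.A, self.C, self.G, self.T, self.other) < 0:
            raise ValueError("negative count")

    @property
    def depth(self) -> int:
        return self.A + self.C + self.G + self.T + self.other

    def count(self, base: str) -> int:
        return getattr(self, base) if base in BASES else self.other


@dataclass(frozen=True)
class FrequencyVector:
    """Per-base fractions of depth; components sum to 1 exactly."""

    A: float
    C: float
    G: float
    T: float
    other: float

    def fraction(self, base: str) -> float:
        return getattr(self, base) if base in BASES else self.other


def frequencies(pc: PositionCounts) -> FrequencyVector:
    """Exact per-base fractions; undefined (raises) at zero depth."""
    d = pc.depth
    if d == 0:
        raise UndefinedFrequencyError(f"{pc.chrom}:{pc.pos} has zero depth")
    return FrequencyVector(pc.A / d, pc.C / d, pc.G / d, pc.T / d, pc.other / d)


# ---------------------------------------------------------------------------
# DataFrame container helpers


def counts_frame(
    positions: Sequence[int],
    ref_bases: Sequence[str],
    counts: np.ndarray,
    other: Sequence[int] | None = None,
    chrom: str = CHROM,
) -> pd.DataFrame:
    """Assemble the canonical pileup DataFrame from a (n, 4) count matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    other_arr = (
        np.zeros(len(positions), dtype=np.int64)
        if other is None
        else np.asarray(other, dtype=np.int64)
    )
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": list(ref_bases),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
            "other": other_arr,
        }
    )
    df["depth"] = df[["A", "C", "G", "T", "other"]].sum(axis=1)
    return df.sort_values("pos", ignore_index=True)


def row_counts(row: pd.Series) -> PositionCounts:
    return PositionCounts(
        row["chrom"], int(row["pos"]), row["ref"],
        int(row["A"]), int(row["C"]), int(row["G"]), int(row["T"]),
        int(row["other"]),
    )


# ---------------------------------------------------------------------------
# Pileup construction


def build_pileup(
    reads: Iterable[ReadRecord],
    regions: Sequence[TargetRegion] | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    reference: MiniReference | None = None,
    lowq_in_depth: bool = True,
) -> pd.DataFrame:
    """Count bases per position, routing sub-threshold calls to "other".

    Positions outside ``regions`` are dropped.  Non-ACGT bases always count
    as "other"; with ``lowq_in_depth=False`` low-quality bases are excluded
    from depth entirely instead of bucketed.
    """
    regions = ref_mod.default_target_regions() if regions is None else list(regions)
    reference = ref_mod.default_reference() if reference is None else reference
    in_target = {p for r in regions for p in range(r.start, r.end + 1)}
    chroms = {r.chrom for r in regions}

    per_pos: dict[int, np.ndarray] = {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    for i, read in enumerate(reads):
        if not isinstance(read, ReadRecord):
            raise ValueError(f"malformed read record at index {i}: {read!r}")
        if read.chrom not in chroms:
            continue
        for k, (base, q) in enumerate(zip(read.seq, read.quals)):
            pos = read.pos + k
            if pos not in in_target:
                continue
            vec = per_pos.setdefault(pos, np.zeros(5, dtype=np.int64))
            base = base.upper()
            if q < min_base_quality or base not in base_idx:
                if lowq_in_depth or base not in base_idx:
                    vec[4] += 1
            else:
                vec[base_idx[base]] += 1

    positions = sorted(per_pos)
    mat = np.array([per_pos[p][:4] for p in positions], dtype=np.int64).reshape(-1, 4)
    other = [int(per_pos[p][4]) for p in positions]
    refs = [reference.base(p) for p in positions]
    chrom = next(iter(chroms)) if chroms else CHROM
    return counts_frame(positions, refs, mat, other, chrom=chrom)


def validate_coverage(
    pileup: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """Per-position pass/fail against the assay's minimum depth."""
    report = pileup[["chrom", "pos", "depth"]].copy()
    report["callable"] = report["depth"] >= min_depth
    return report


# ---------------------------------------------------------------------------
# Interchange: pileup TSV and minimal SAM


def write_pileup_tsv(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV {path} lacks columns: {sorted(missing)}")
    return df[PILEUP_COLUMNS]


def _sam_header(chrom: str = CHROM) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": chrom, "LN": _CHR2_LENGTH}]}
    )


def write_sam(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as minimal mapped SAM records (full-match CIGAR)."""
    header = _sam_header()
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{i}"
            a.query_sequence = read.seq
            a.reference_id = 0
            a.reference_start = read.pos - 1  # SAM API is 0-based
            a.mapping_quality = 60
            a.cigartuples = [(0, len(read.seq))]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            out.write(a)


def read_sam(path: str | Path) -> list[ReadRecord]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            quals = tuple(int(q) for q in (a.query_qualities or ()))
            reads.append(
                ReadRecord(a.reference_name, a.reference_start + 1,
                           a.query_sequence, quals)
            )
    return reads
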