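"""The k-standard-deviation mutation caller and downstream classification.

A nucleotide frequency is classified as a mutation when it exceeds the
control-derived background mean by more than ``k`` standard deviations
(default k=5).  Every alternate base is tested separately at every position,
so two subclones mutating the same codon position to different bases yield
two calls.  No multiple-testing correction is applied — k=5 is itself
stringent — but the number of tests performed is reported.

Calls are further classified as clonal/subclonal (VAF < 0.20 is subclonal)
and as detectable or not by capillary (Sanger) sequencing (VAF > 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from . import reference as ref_mod
from .errors import FrameUnknownError, ModelCoverageError
from .noise import NoiseModel, zscores
from .pileup import DEFAULT_MIN_DEPTH
from .reference import HOTSPOT_RESIDUES, MiniReference

DEFAULT_K = 5.0
DEFAULT_CLONAL_THRESHOLD = 0.20
DEFAULT_SANGER_THRESHOLD = 0.15


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float
    z: float
    aa_change: str
    residue: int
    synonymous: bool
    hotspot: str  # e.g. "F1174", or "non-hotspot"
    clonality: str  # "clonal" | "subclonal"
    sanger_detectable: bool
    sample_id: str


@dataclass(frozen=True)
class CallResult:
    calls: tuple[VariantCall, ...]
    n_tests: int  # number of (position, alt) hypotheses examined
    n_not_assessable: int  # positions failing the depth requirement
    coverage_gaps: tuple[tuple[int, str], ...]  # (pos, alt) without model entry


def classify_clonality(
    call_or_vaf, clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD
) -> str:
    """"subclonal" iff VAF < threshold (strict), else "clonal"."""
    vaf = getattr(call_or_vaf, "vaf", call_or_vaf)
    return "subclonal" if vaf < clonal_threshold else "clonal"


def flag_sanger_detectable(
    call_or_vaf, sanger_threshold: float = DEFAULT_SANGER_THRESHOLD
) -> bool:
    """True iff VAF > threshold (strict): capillary sequencing would see it."""
    vaf = getattr(call_or_vaf, "vaf", call_or_vaf)
    return vaf > sanger_threshold


def call_variants(
    pileup: pd.DataFrame,
    model: NoiseModel,
    reference: MiniReference | None = None,
    k: float = DEFAULT_K,
    min_depth: int = DEFAULT_MIN_DEPTH,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    sanger_threshold: float = DEFAULT_SANGER_THRESHOLD,
    sample_id: str = "sample",
    on_gap: str = "report",  # "report" | "error"
) -> CallResult:
    """Emit one call per (position, alt) with z > k at assessable depth.

    Positions with depth below ``min_depth`` are "not assessable" (counted,
    not tested); (position, alt) pairs the model does not cover are returned
    as coverage gaps (or raised with ``on_gap="error"``).
    """
    reference = ref_mod.default_reference() if reference is None else reference
    assessable = pileup[pileup["depth"] >= min_depth]
    n_not_assessable = int((pileup["depth"] < min_depth).sum())
    if not len(assessable):
        return CallResult((), 0, n_not_assessable, ())
    scored = zscores(assessable, model)
    gaps = tuple(
        (int(r.pos), r.alt) for r in scored[scored["z"].isna()].itertuples()
    )
    if gaps and on_gap == "error":
        raise ModelCoverageError(f"{len(gaps)} (position, alt) pairs uncovered")
    tested = scored.dropna(subset=["z"])
    hits = tested[tested["z"] > k]
    calls = []
    for r in hits.itertuples():
        try:
            change = ref_mod.annotate_substitution(
                int(r.pos), r.ref, r.alt, reference
            )
            aa_change, residue, synonymous = (
                change.label, change.residue_number, change.synonymous
            )
        except FrameUnknownError:
            # codon truncated at the target boundary: call stands, unannotated
            residue, _ = ref_mod.codon_for_position(int(r.pos))
            aa_change, synonymous = f"?{residue}?", False
        hotspot = (
            f"{aa_change[0]}{residue}"
            if residue in HOTSPOT_RESIDUES and not aa_change.startswith("?")
            else "non-hotspot"
        )
        vaf = float(r.fraction)
        calls.append(
            VariantCall(
                chrom=r.chrom,
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                alt_count=int(r.count),
                depth=int(r.depth),
                vaf=vaf,
                z=float(r.z),
                aa_change=aa_change,
                residue=residue,
                synonymous=synonymous,
                hotspot=hotspot,
                clonality=classify_clonality(vaf, clonal_threshold),
                sanger_detectable=flag_sanger_detectable(vaf, sanger_threshold),
                sample_id=sample_id,
            )
        )
    calls.sort(key=lambda c: (c.pos, c.alt))
    return CallResult(tuple(calls), int(len(tested)), n_not_assessable, gaps)


# ---------------------------------------------------------------------------
# Dilution-series evaluation


def evaluate_dilution_series(
    calls_per_dilution: Sequence[CallResult | Sequence[VariantCall]],
    expected_vafs: Sequence[float],
    site: tuple[int, str] | None = None,
) -> pd.DataFrame:
    """Detection report for a serial dilution.

    One row per dilution step: whether the spike was detected, the observed
    vs expected VAF and their relative error.  The frame carries the overall
    detection limit (smallest detected expected VAF) in ``.attrs``.
    """
    rows = []
    for step, (result, expected) in enumerate(
        zip(calls_per_dilution, expected_vafs)
    ):
        calls = result.calls if isinstance(result, CallResult) else tuple(result)
        if site is not None:
            calls = tuple(c for c in calls if (c.pos, c.alt) == site)
        detected = len(calls) > 0
        observed = max((c.vaf for c in calls), default=np.nan)
        rows.append(
            {
                "step": step,
                "expected_vaf": expected,
                "detected": detected,
                "observed_vaf": observed,
                "relative_error": (
                    abs(observed - expected) / expected if detected else np.nan
                ),
            }
        )
    report = pd.DataFrame(
        rows, columns=["step", "expected_vaf", "detected", "observed_vaf",
                       "relative_error"],
    )
    detected_vafs = report.loc[report["detected"], "expected_vaf"]
    report.attrs["detection_limit"] = (
        float(detected_vafs.min()) if len(detected_vafs) else np.nan
    )
    return report


# ---------------------------------------------------------------------------
# VCF interchange (one sample per file)


_VCF_INFO = [
    ('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">'),
    ('##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alternate base count">'),
    ('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">'),
    ('##INFO=<ID=Z,Number=1,Type=Float,Description="Background z-statistic">'),
    ('##INFO=<ID=AA,Number=1,Type=String,Description="Amino-acid change">'),
    ('##INFO=<ID=RES,Number=1,Type=Integer,Description="Protein residue">'),
    ('##INFO=<ID=SYN,Number=0,Type=Flag,Description="Synonymous change">'),
    ('##INFO=<ID=HOTSPOT,Number=1,Type=String,Description="Hotspot codon">'),
    ('##INFO=<ID=CLONALITY,Number=1,Type=String,Description="clonal/subclonal">'),
    ('##INFO=<ID=SANGER,Number=1,Type=String,'
     'Description="Detectable by Sanger sequencing (yes/no)">'),
]


def write_vcf(calls: Sequence[VariantCall], path: str | Path,
              sample_id: str | None = None) -> None:
    header = pysam.VariantHeader()
    header.add_line("##source=alkdeep")
    if sample_id is None and calls:
        sample_id = calls[0].sample_id
    header.add_line(f"##sample={sample_id or 'unknown'}")
    header.contigs.add("chr2", length=243_199_373)
    for line in _VCF_INFO:
        header.add_line(line)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.pos, c.alt)):
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt), id=c.aa_change, qual=None,
            )
            rec.info["DP"] = c.depth
            rec.info["ALTC"] = c.alt_count
            rec.info["VAF"] = c.vaf
            rec.info["Z"] = c.z
            rec.info["AA"] = c.aa_change
            rec.info["RES"] = c.residue
            rec.info["SYN"] = c.synonymous
            rec.info["HOTSPOT"] = c.hotspot
            rec.info["CLONALITY"] = c.clonality
            rec.info["SANGER"] = "yes" if c.sanger_detectable else "no"
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as fh:
        sample_id = "unknown"
        for raw in str(fh.header).splitlines():
            if raw.startswith("##sample="):
                sample_id = raw.split("=", 1)[1]
        for rec in fh:
            info = rec.info
            calls.append(
                VariantCall(
                    chrom=rec.contig, pos=rec.pos,
                    ref=rec.alleles[0], alt=rec.alleles[1],
                    alt_count=int(info["ALTC"]), depth=int(info["DP"]),
                    vaf=float(info["VAF"]), z=float(info["Z"]),
                    aa_change=str(info["AA"]), residue=int(info["RES"]),
                    synonymous=bool(info.get("SYN", False)),
                    hotspot=str(info["HOTSPOT"]),
                    clonality=str(info["CLONALITY"]),
                    sanger_detectable=str(info["SANGER"]) == "yes",
                    sample_id=sample_id,
                )
            )
    return calls
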