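"""ALK kinase-domain target geometry and minus-strand codon annotation.

The ALK gene lies on the minus strand of chromosome 2 (hg19).  The five
targeted exons (21-25) therefore carry the *start* of the kinase domain at
the highest genomic coordinates: residue numbers increase as the forward
coordinate decreases.  All per-position counts and substitutions in this
package are expressed on the FORWARD genomic strand; translation into
amino-acid space reverse-complements the codon.

The coding frame is anchored once, at the F1174 hotspot codon
(chr2:29443695-29443697, first codon base at the highest coordinate
29443697), and extended contiguously across the intron junctions.  This
single anchor reproduces every other known hotspot anchor (I1171 at
chr2:29445213, L1240 at chr2:29436875, F1245 at chr2:29436858-29436860)
exactly, and places D1160 in exon 22 and R1275 in exon 25 by the same rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FrameUnknownError, OutOfTargetError, ReferenceMismatchError

CHROM = "chr2"
BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetRegion:
    """A targeted exon interval, 1-based inclusive (UCSC style), hg19."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


#: Targeted ALK exons, hg19, in coding (5'->3' on the minus strand) order.
_EXONS = (
    TargetRegion("exon21", CHROM, 29445383, 29445473),
    TargetRegion("exon22", CHROM, 29445210, 29445274),
    TargetRegion("exon23", CHROM, 29443572, 29443701),
    TargetRegion("exon24", CHROM, 29436850, 29436947),
    TargetRegion("exon25", CHROM, 29432652, 29432744),
)

#: CDS index of the first base of the F1174 codon (chr2:29443697).
_ANCHOR_CDS = 91 + 65 + (29443701 - 29443697)
_ANCHOR_RESIDUE = 1174

#: Minus-strand reference codons at the anchored residues.  The published
#: record names residues, not bases; these codons are chosen so that every
#: hotspot substitution observed in neuroblastoma (F1174L/I/C/S, F1245I/C,
#: L1240V, I1171T, R1275Q/L and the synonymous D1160D) is reachable by a
#: single base change, matching the standard human codon usage at F1174/F1245.
HOTSPOT_MINUS_CODONS: dict[int, str] = {
    1160: "GAC",  # Asp
    1171: "ATC",  # Ile
    1174: "TTC",  # Phe
    1240: "CTG",  # Leu
    1245: "TTC",  # Phe
    1275: "CGG",  # Arg
}

#: Residues conventionally called hotspots in neuroblastoma ALK.
HOTSPOT_RESIDUES = (1170, 1171, 1174, 1240, 1245, 1275)


def default_target_regions() -> list[TargetRegion]:
    """The five targeted ALK exons with their hg19 coordinates."""
    return list(_EXONS)


def total_target_span(regions: list[TargetRegion] | None = None) -> int:
    regions = _EXONS if regions is None else regions
    return sum(len(r) for r in regions)


def locate(pos: int, chrom: str = CHROM) -> TargetRegion | None:
    """Return the target region containing ``pos``, or None if off-target."""
    if chrom == CHROM:
        for region in _EXONS:
            if pos in region:
                return region
    return None


def all_target_positions() -> list[int]:
    return [p for r in _EXONS for p in range(r.start, r.end + 1)]


# ---------------------------------------------------------------------------
# Coding frame


def _cds_index(pos: int) -> int:
    """0-based CDS index of a forward coordinate (minus-strand gene)."""
    offset = 0
    for region in _EXONS:
        if pos in region:
            return offset + (region.end - pos)
        offset += len(region)
    raise OutOfTargetError(f"{CHROM}:{pos} is outside the targeted exons")


def _pos_at(cds: int) -> int:
    """Forward coordinate of a 0-based CDS index."""
    offset = 0
    for region in _EXONS:
        if cds < offset + len(region):
            return region.end - (cds - offset)
        offset += len(region)
    raise FrameUnknownError(f"CDS index {cds} beyond the targeted exons")


def codon_for_position(pos: int) -> tuple[int, int]:
    """Residue number and within-codon offset (0, 1, 2) for a coordinate.

    Raises FrameUnknownError for positions outside the targeted exons.
    """
    try:
        i = _cds_index(pos)
    except OutOfTargetError as exc:
        raise FrameUnknownError(str(exc)) from exc
    d = i - _ANCHOR_CDS
    return _ANCHOR_RESIDUE + d // 3, d % 3


def codon_positions(residue: int) -> list[int]:
    """Forward coordinates of the three codon bases, in codon (5'->3') order.

    Codon order on a minus-strand gene runs from high to low forward
    coordinate; codons split by an intron return non-contiguous coordinates.
    """
    j0 = _ANCHOR_CDS + 3 * (residue - _ANCHOR_RESIDUE)
    if j0 < 0:
        raise FrameUnknownError(f"codon {residue} lies upstream of the targets")
    return [_pos_at(j0 + k) for k in range(3)]


def codon_span(residue: int) -> tuple[int, int]:
    """(start, end) forward span of a codon; requires a contiguous codon."""
    positions = codon_positions(residue)
    lo, hi = min(positions), max(positions)
    if hi - lo != 2:
        raise FrameUnknownError(f"codon {residue} is split across an intron")
    return lo, hi


# ---------------------------------------------------------------------------
# Bundled reference sequence


class MiniReference:
    """Forward-strand reference bases over the targeted exons only.

    The genuine article names residues, not nucleotides, so the bundled
    default is a synthetic sequence constrained to carry the canonical
    codons at every anchored hotspot residue; any sequence satisfying those
    anchors is interchangeable, and a real sequence can be supplied as FASTA.
    """

    def __init__(self, bases: dict[int, str], chrom: str = CHROM):
        self.chrom = chrom
        self._bases = dict(bases)

    def base(self, pos: int) -> str:
        try:
            return self._bases[pos]
        except KeyError:
            raise OutOfTargetError(f"{self.chrom}:{pos} not in reference") from None

    def __contains__(self, pos: int) -> bool:
        return pos in self._bases

    def region_sequence(self, region: TargetRegion) -> str:
        return "".join(self._bases[p] for p in range(region.start, region.end + 1))

    def minus_codon(self, residue: int) -> str:
        """Minus-strand (coding) codon for a residue, from forward bases."""
        return "".join(complement(self.base(p)) for p in codon_positions(residue))


def default_reference(seed: int = 1174) -> MiniReference:
    """Synthetic forward-strand reference with canonical hotspot codons."""
    rng = np.random.default_rng(seed)
    positions = all_target_positions()
    drawn = rng.choice(list(BASES), size=len(positions))
    bases = dict(zip(positions, drawn.tolist()))
    for residue, codon in HOTSPOT_MINUS_CODONS.items():
        for k, coding_base in enumerate(codon):
            bases[codon_positions(residue)[k]] = complement(coding_base)
    return MiniReference(bases)


# ---------------------------------------------------------------------------
# Hotspot codon records


@dataclass(frozen=True)
class HotspotCodon:
    residue_number: int
    codon_span: tuple[int, int]
    reference_aa: str
    reference_codon_fwd: str


def hotspot_codons(reference: MiniReference | None = None) -> list[HotspotCodon]:
    """Anchored codons (hotspots plus D1160) with their genomic spans."""
    reference = reference if reference is not None else default_reference()
    records = []
    for residue in sorted(HOTSPOT_MINUS_CODONS):
        lo, hi = codon_span(residue)
        fwd = "".join(reference.base(p) for p in range(lo, hi + 1))
        aa = str(Seq(reverse_complement(fwd)).translate())
        records.append(HotspotCodon(residue, (lo, hi), aa, fwd))
    return records


# ---------------------------------------------------------------------------
# Substitution annotation


@dataclass(frozen=True)
class AminoAcidChange:
    residue_number: int
    ref_aa: str
    alt_aa: str
    synonymous: bool

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.residue_number}{self.alt_aa}"


def annotate_substitution(
    pos: int, ref_base_fwd: str, alt_base_fwd: str, reference: MiniReference
) -> AminoAcidChange:
    """Translate a forward-strand substitution into an amino-acid change.

    The codon is read on the minus strand (reverse complement); synonymous
    changes carry the flag and a label such as ``D1160D``.
    """
    if reference.base(pos) != ref_base_fwd:
        raise ReferenceMismatchError(
            f"{reference.chrom}:{pos} reference is {reference.base(pos)}, "
            f"not {ref_base_fwd}"
        )
    residue, offset = codon_for_position(pos)
    positions = codon_positions(residue)
    if any(p not in reference for p in positions):
        raise FrameUnknownError(f"codon {residue} extends beyond the reference")
    ref_codon = "".join(complement(reference.base(p)) for p in positions)
    alt_codon = list(ref_codon)
    alt_codon[offset] = complement(alt_base_fwd)
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return AminoAcidChange(residue, ref_aa, alt_aa, synonymous=ref_aa == alt_aa)


_MUTATION_NAME = re.compile(r"^([A-Z])(\d{3,4})([A-Z*])$")


def single_base_changes(
    residue: int, reference: MiniReference
) -> dict[str, tuple[int, str, str]]:
    """All amino-acid labels reachable by one base change in a codon.

    Returns label -> (forward position, ref base, alt base); where several
    substitutions give the same label, the first in genomic order wins.
    """
    out: dict[str, tuple[int, str, str]] = {}
    for pos in sorted(codon_positions(residue)):
        ref_base = reference.base(pos)
        for alt in BASES:
            if alt == ref_base:
                continue
            change = annotate_substitution(pos, ref_base, alt, reference)
            out.setdefault(change.label, (pos, ref_base, alt))
    return out


def mutation_site(name: str, reference: MiniReference) -> tuple[int, str, str]:
    """Forward-strand (position, ref, alt) realizing a mutation name.

    ``name`` is protein notation such as ``F1174L`` or ``D1160D``; raises
    if the named change is not a single-base substitution at that codon.
    """
    m = _MUTATION_NAME.match(name.strip())
    if not m:
        raise ValueError(f"unparseable mutation name: {name!r}")
    ref_aa, residue, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    changes = single_base_changes(residue, reference)
    label = f"{ref_aa}{residue}{alt_aa}"
    if label not in changes:
        raise ValueError(f"{label} is not a single-base change in codon {residue}")
    return changes[label]


# ---------------------------------------------------------------------------
# Interchange formats


def write_regions_bed(regions: list[TargetRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open, converted on the way out)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def read_regions_bed(path: str | Path) -> list[TargetRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end, name = line.rstrip("\n").split("\t")[:4]
            regions.append(TargetRegion(name, chrom, int(start0) + 1, int(end)))
    return regions


def write_reference_fasta(reference: MiniReference, path: str | Path) -> None:
    """One record per exon; headers ``chr2:start-end:exonNN``."""
    records = []
    for region in _EXONS:
        header = f"{region.chrom}:{region.start}-{region.end}:{region.name}"
        records.append(
            SeqRecord(Seq(reference.region_sequence(region)), id=header, description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> MiniReference:
    bases: dict[int, str] = {}
    chrom = CHROM
    for record in SeqIO.parse(str(path), "fasta"):
        chrom, span, _name = record.id.split(":")
        start, end = (int(x) for x in span.split("-"))
        seq = str(record.seq).upper()
        if len(seq) != end - start + 1:
            raise ValueError(f"{record.id}: sequence length != span")
        for i, b in enumerate(seq):
            bases[start + i] = b
    return MiniReference(bases, chrom=chrom)
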