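"""Synthetic pileups and reads emulating the ultra-deep ALK amplicon assay.

The generator reproduces the structure of the study data: per-position
substitution noise around 0.1% with sample-to-sample spread, depths of
5000x and above, tumour spike-ins at allele fractions between ~1% and 60%
scaled by tumour purity, serial mutant:wild-type dilutions, and a cohort of
samples mirroring the packaged 105-case table.  Every operation takes an
explicit seed; there is no global random state.

Noise structure (tunable, defaults are the package's study conditions):

* per-(position, alternate-base) error rates are log-normal with median
  1e-3 and sigma(log10)=0.3, truncated to [0, 0.05] — a floor well below
  the lowest mutation the assay is expected to resolve (2.7%) but nonzero,
  as in real amplicon data;
* each sample additionally multiplies all its rates by one log-normal
  factor (sigma(log10)=0.1), creating the between-sample variance that
  makes a standard-deviation-based detection rule meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference as ref_mod
from .errors import InvalidConfigurationError, TooFewControlsError
from .pileup import ReadRecord, counts_frame
from .reference import BASES, CHROM, MiniReference, TargetRegion

#: Default between-sample multiplicative rate jitter, sigma in log10 units.
DEFAULT_JITTER_SIGMA_LOG10 = 0.1
#: Default per-site error-rate distribution (log-normal, median / sigma log10).
DEFAULT_RATE_MEDIAN = 1e-3
DEFAULT_RATE_SIGMA_LOG10 = 0.3
#: Hard cap on any single background rate.
MAX_RATE = 0.05

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class ErrorProfile:
    """Per-position, per-alternate background substitution rates."""

    positions: np.ndarray  # (n,) int64 forward coordinates
    ref_bases: np.ndarray  # (n,) unicode
    rates: np.ndarray  # (n, 4) float; zero at the reference column
    chrom: str = CHROM
    hyperparams: dict = field(default_factory=dict)

    def index_of(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise InvalidConfigurationError(f"{self.chrom}:{pos} not in profile")
        return i

    def rate(self, pos: int, alt: str) -> float:
        return float(self.rates[self.index_of(pos), _BASE_IDX[alt]])

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.positions):
            for b in BASES:
                if b != self.ref_bases[i]:
                    rows.append((self.chrom, int(pos), self.ref_bases[i], b,
                                 float(self.rates[i, _BASE_IDX[b]])))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "rate"])


@dataclass(frozen=True)
class SpikeIn:
    """A true variant injected into a simulated sample (forward strand)."""

    pos: int
    alt: str
    vaf: float
    germline: bool = False  # constitutional variants are not purity-scaled

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 1:
            raise InvalidConfigurationError(f"spike VAF {self.vaf} not in (0, 1]")
        if self.alt not in BASES:
            raise InvalidConfigurationError(f"spike alt {self.alt!r} not in ACGT")


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    role: str = "tumour"  # "germline control" | "tumour"
    purity: float = 1.0
    spike_ins: tuple[SpikeIn, ...] = ()
    depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise InvalidConfigurationError(f"purity {self.purity} not in (0, 1]")
        if self.depth < 1:
            raise InvalidConfigurationError("depth must be positive")
        if self.role.startswith("germline") and self.spike_ins:
            raise InvalidConfigurationError("germline controls carry no spike-ins")


def draw_error_profile(
    regions: Sequence[TargetRegion] | None = None,
    seed: int = 0,
    reference: MiniReference | None = None,
    rate_median: float = DEFAULT_RATE_MEDIAN,
    rate_sigma_log10: float = DEFAULT_RATE_SIGMA_LOG10,
    max_rate: float = MAX_RATE,
) -> ErrorProfile:
    """Draw a log-normal per-(position, alt) background error profile."""
    regions = ref_mod.default_target_regions() if regions is None else list(regions)
    reference = ref_mod.default_reference() if reference is None else reference
    rng = np.random.default_rng(seed)
    positions = np.array(
        [p for r in regions for p in range(r.start, r.end + 1)], dtype=np.int64
    )
    positions.sort()
    refs = np.array([reference.base(int(p)) for p in positions])
    if rate_median > 0:
        raw = 10 ** (np.log10(rate_median)
                     + rate_sigma_log10 * rng.standard_normal((len(positions), 4)))
    else:
        raw = np.zeros((len(positions), 4))
    rates = np.minimum(raw, max_rate)
    for i, b in enumerate(BASES):
        rates[refs == b, i] = 0.0
    # keep total alt mass strictly below 0.15 even at the truncation cap
    row_sum = rates.sum(axis=1)
    over = row_sum >= 0.15
    if over.any():
        rates[over] *= (0.15 - 1e-9) / row_sum[over, None]
    return ErrorProfile(
        positions, refs, rates,
        chrom=regions[0].chrom if regions else CHROM,
        hyperparams={
            "rate_median": rate_median,
            "rate_sigma_log10": rate_sigma_log10,
            "max_rate": max_rate,
        },
    )


def _alt_probabilities(
    sample: SimulatedSample, profile: ErrorProfile, jitter: float
) -> np.ndarray:
    """(n, 4) per-base draw probabilities: jittered noise + spikes + reference."""
    p = profile.rates * jitter
    for spike in sample.spike_ins:
        i = profile.index_of(spike.pos)
        if profile.ref_bases[i] == spike.alt:
            raise InvalidConfigurationError(
                f"spike alt {spike.alt} equals reference at {spike.pos}"
            )
        scale = 1.0 if spike.germline else sample.purity
        p[i, _BASE_IDX[spike.alt]] += spike.vaf * scale
    alt_sum = p.sum(axis=1)
    if (alt_sum > 1).any():
        bad = int(profile.positions[np.argmax(alt_sum)])
        raise InvalidConfigurationError(
            f"alternate probabilities exceed 1 at {profile.chrom}:{bad}"
        )
    for i, b in enumerate(BASES):
        mask = profile.ref_bases == b
        p[mask, i] = 1.0 - alt_sum[mask]
    return p


def simulate_pileup(
    sample: SimulatedSample,
    profile: ErrorProfile,
    jitter_sigma_log10: float = DEFAULT_JITTER_SIGMA_LOG10,
) -> pd.DataFrame:
    """Multinomial pileup draw: alt probability = jittered noise + purity x VAF."""
    rng = np.random.default_rng(sample.seed)
    jitter = 10 ** (jitter_sigma_log10 * rng.standard_normal())
    p = _alt_probabilities(sample, profile, jitter)
    counts = rng.multinomial(sample.depth, p)
    return counts_frame(
        profile.positions, profile.ref_bases, counts, chrom=profile.chrom
    )


def simulate_control_cohort(
    profile: ErrorProfile,
    n_controls: int = 8,
    depth: int = 5000,
    seed: int = 0,
    jitter_sigma_log10: float = DEFAULT_JITTER_SIGMA_LOG10,
) -> list[pd.DataFrame]:
    """Independent germline-control pileups sharing one error profile."""
    if n_controls < 2:
        raise TooFewControlsError(
            f"{n_controls} control(s): background SD needs at least 2"
        )
    seeds = np.random.default_rng(seed).integers(2**31, size=n_controls)
    out = []
    for i in range(n_controls):
        sample = SimulatedSample(
            f"control{i + 1}", role="germline control",
            depth=depth, seed=int(seeds[i]),
        )
        out.append(simulate_pileup(sample, profile, jitter_sigma_log10))
    return out


def simulate_dilution_series(
    base: SimulatedSample, ratios: Sequence[float]
) -> list[SimulatedSample]:
    """Serial mutant:wild-type mass dilutions of a spiked sample.

    A ratio ``d`` means one part mutant DNA to ``d`` parts added wild-type
    (1:0 = undiluted), so every spike VAF scales to ``vaf / (1 + d)``.
    """
    if not base.spike_ins:
        raise InvalidConfigurationError("dilution series needs a spiked base sample")
    out = []
    for j, d in enumerate(ratios):
        if d < 0:
            raise InvalidConfigurationError(f"negative dilution ratio {d}")
        spikes = tuple(
            replace(s, vaf=s.vaf / (1.0 + d)) for s in base.spike_ins
        )
        out.append(
            replace(
                base,
                sample_id=f"{base.sample_id}_1to{d:g}",
                spike_ins=spikes,
                seed=base.seed + j + 1,
            )
        )
    return out


def expected_dilution_vafs(vaf0: float, ratios: Sequence[float]) -> list[float]:
    return [vaf0 / (1.0 + d) for d in ratios]


def simulate_cohort(
    spec: pd.DataFrame,
    profile: ErrorProfile,
    reference: MiniReference | None = None,
    seed: int = 0,
    depth: int = 5000,
    jitter_sigma_log10: float = DEFAULT_JITTER_SIGMA_LOG10,
    synonymous_germline_vaf: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One pileup per cohort row, spiked according to its deep-seq entry.

    ``spec`` follows the packaged cohort schema; printed VAF percentages are
    taken as the expected allele fraction directly (tumour purity is already
    folded into an observed fraction).  Synonymous entries without a printed
    fraction are simulated as germline heterozygous variants.
    """
    from .cohort import parse_deep_seq  # local import; cohort also stands alone

    reference = ref_mod.default_reference() if reference is None else reference
    rng = np.random.default_rng(seed)
    pileups: dict[str, pd.DataFrame] = {}
    for _, row in spec.iterrows():
        result = parse_deep_seq(row["deep_seq"])
        spikes = []
        constitutional = "const" in str(row.get("sanger", "")).lower()
        for name, vaf_pct in result.mutations:
            pos, _ref_base, alt = ref_mod.mutation_site(name, reference)
            vaf = synonymous_germline_vaf if vaf_pct is None else vaf_pct / 100.0
            spikes.append(
                SpikeIn(pos, alt, vaf, germline=constitutional or vaf_pct is None)
            )
        sample = SimulatedSample(
            sample_id=str(row["case_id"]),
            role="tumour",
            spike_ins=tuple(spikes),
            depth=depth,
            seed=int(rng.integers(2**31)),
        )
        pileups[sample.sample_id] = simulate_pileup(
            sample, profile, jitter_sigma_log10
        )
    return spec.copy(), pileups


# ---------------------------------------------------------------------------
# Read-level emission (exercises the pileup builder end to end)


def emit_reads(
    pileup: pd.DataFrame,
    read_length: int = 150,
    seed: int = 0,
    low_quality_fraction: float = 0.0,
    low_quality_phred: int = 10,
    base_phred: int = 40,
) -> list[ReadRecord]:
    """Aligned reads whose pileup at quality 0 reproduces the input exactly.

    Reads are laid out as tiling rows: each covered column distributes its
    count vector (with "other" emitted as N) across rows in shuffled order,
    and each row is cut into reads of at most ``read_length`` bases.
    """
    if read_length < 1:
        raise InvalidConfigurationError("read length must be >= 1")
    rng = np.random.default_rng(seed)
    df = pileup.sort_values("pos", ignore_index=True)
    reads: list[ReadRecord] = []

    # contiguous runs of covered positions
    runs: list[pd.DataFrame] = []
    if len(df):
        breaks = np.flatnonzero(np.diff(df["pos"].to_numpy()) != 1) + 1
        runs = [chunk for chunk in np.split(df.index.to_numpy(), breaks)]
        runs = [df.loc[idx] for idx in runs]

    for run in runs:
        depths = run["depth"].to_numpy()
        n_rows = int(depths.max()) if len(depths) else 0
        width = len(run)
        grid = np.full((n_rows, width), None, dtype=object)
        for j, (_, row) in enumerate(run.iterrows()):
            col = (["A"] * int(row["A"]) + ["C"] * int(row["C"])
                   + ["G"] * int(row["G"]) + ["T"] * int(row["T"])
                   + ["N"] * int(row["other"]))
            rng.shuffle(col)
            grid[: len(col), j] = col
        start_pos = int(run["pos"].iloc[0])
        chrom = run["chrom"].iloc[0]
        for r in range(n_rows):
            j = 0
            while j < width:
                if grid[r, j] is None:
                    j += 1
                    continue
                k = j
                while k < width and grid[r, k] is not None and k - j < read_length:
                    k += 1
                seq = "".join(grid[r, j:k])
                lowq = rng.random(len(seq)) < low_quality_fraction
                quals = tuple(
                    int(low_quality_phred if lq else base_phred) for lq in lowq
                )
                reads.append(ReadRecord(chrom, start_pos + j, seq, quals))
                j = k
    return reads
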