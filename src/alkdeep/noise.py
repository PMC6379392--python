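"""Background-noise model estimated from control samples.

For every (position, alternate base) the model stores the mean and the
unbiased (n-1) sample standard deviation of the alternate-allele fraction
across germline controls.  A global noise floor (default 2e-4) replaces the
SD wherever the controls happened to agree exactly, so the downstream
k-standard-deviation rule is defined everywhere.  Mutation-positive control
tumours are detection positives only and must not enter this estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyModelError, ModelCoverageError, TooFewControlsError
from .reference import BASES

DEFAULT_NOISE_FLOOR = 2e-4

MODEL_COLUMNS = ["chrom", "pos", "ref", "alt", "mean", "sd", "n", "ctrl_depth"]


@dataclass(frozen=True)
class NoiseModel:
    """Background model: per-(position, alt) statistics + global components.

    Beyond the per-position mean/SD, the model carries two globally
    estimated pieces used to regularize the per-position SD, which with a
    handful of controls is itself a very noisy estimate:

    * ``rel_jitter_sd`` — the relative between-sample spread of overall
      error rates (each library's PCR/sequencing error level scales all of
      its rates up or down together), estimated from whole-target totals;
    * the binomial sampling variance ``m(1-m)/depth`` implied by the depth
      of the sample being tested.

    The effective SD used by the k-SD rule is the per-position sample SD,
    floored by the global noise floor and by the predictive SD these
    components imply (evaluated at a one-standard-error upper bound of the
    estimated mean, and including the mean's own sampling variance).
    Without those floors the rule's false-call rate is dominated by entries
    whose few-control SD or mean happened to come out low.
    """

    table: pd.DataFrame  # MODEL_COLUMNS, one row per (position, alt)
    floor: float = DEFAULT_NOISE_FLOOR
    rel_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        table = self.table
        if "ctrl_depth" not in table.columns:
            table = table.assign(ctrl_depth=np.nan)
            object.__setattr__(self, "table", table)
        object.__setattr__(
            self, "_lookup",
            table.set_index(["pos", "alt"])[
                ["mean", "sd", "n", "ctrl_depth"]
            ].to_dict("index"),
        )

    def covers(self, pos: int, alt: str) -> bool:
        return (pos, alt) in self._lookup

    def _jitter_eff(self, n: float) -> float:
        # one-standard-error inflation of a CV estimated from n samples
        if not np.isfinite(n) or n < 2:
            return self.rel_jitter_sd
        return self.rel_jitter_sd * (1.0 + 1.0 / np.sqrt(2.0 * (n - 1.0)))

    def model_variance(self, mean, depth=None, jitter=None):
        """Null variance of an alt fraction: binomial + sample-jitter terms."""
        jitter = self.rel_jitter_sd if jitter is None else jitter
        var = (mean * jitter) ** 2
        if depth is not None:
            with np.errstate(invalid="ignore"):
                binom = np.where(
                    np.asarray(depth, dtype=float) > 0,
                    mean * (1.0 - mean) / np.asarray(depth, dtype=float),
                    0.0,
                )
            var = var + np.nan_to_num(binom)
        return var

    def predictive_sd(self, mean, n, ctrl_depth, test_depth=None):
        """SD of (observed - estimated mean) under the null components.

        The model variance is evaluated at mean + 1 SE(mean) so that entries
        whose control mean came out low do not also get a too-small SD, and
        the SE of the mean itself enters the total.
        """
        n = np.asarray(n, dtype=float)
        jitter = self.rel_jitter_sd * (
            1.0 + 1.0 / np.sqrt(np.maximum(2.0 * (n - 1.0), 1.0))
        )
        se_mean = np.sqrt(
            self.model_variance(mean, ctrl_depth, jitter) / np.maximum(n, 1.0)
        )
        m_ub = mean + se_mean
        var = (
            self.model_variance(m_ub, test_depth, jitter)
            + self.model_variance(m_ub, ctrl_depth, jitter) / np.maximum(n, 1.0)
        )
        return np.sqrt(var)

    def entry(self, pos: int, alt: str, depth: int | None = None) -> tuple[float, float]:
        """(mean, effective SD) at a site.

        Effective SD = max(per-position sample SD, noise floor, predictive SD).
        """
        try:
            rec = self._lookup[(pos, alt)]
        except KeyError:
            raise ModelCoverageError(
                f"noise model does not cover pos {pos} alt {alt}"
            ) from None
        mean = rec["mean"]
        pred = float(
            self.predictive_sd(mean, rec["n"], rec["ctrl_depth"], depth)
        )
        return mean, max(rec["sd"], self.floor, pred)

    @property
    def partial_positions(self) -> pd.DataFrame:
        """Entries estimated from fewer controls than the maximum (flagged)."""
        return self.table[self.table["n"] < self.table["n"].max()]


def _melt_fractions(pileup: pd.DataFrame) -> pd.DataFrame:
    """(chrom, pos, ref, alt, fraction) rows for the three non-reference bases."""
    long = pileup.melt(
        id_vars=["chrom", "pos", "ref", "depth"],
        value_vars=list(BASES),
        var_name="alt",
        value_name="count",
    )
    long = long[(long["alt"] != long["ref"]) & (long["depth"] > 0)]
    long["fraction"] = long["count"] / long["depth"]
    return long


def estimate_background(
    control_pileups: Sequence[pd.DataFrame],
    floor: float = DEFAULT_NOISE_FLOOR,
) -> NoiseModel:
    """Per-(position, alt) mean/SD of alternate fractions across controls.

    Positions absent from some controls are estimated from the controls that
    cover them (their lower ``n`` flags them); entries seen in fewer than two
    controls are dropped since their SD is undefined.
    """
    if len(control_pileups) < 2:
        raise TooFewControlsError(
            f"{len(control_pileups)} control(s): need at least 2"
        )
    melted = [
        _melt_fractions(p) for p in control_pileups if len(p)
    ]
    melted = [m for m in melted if len(m)]
    if not melted:
        raise EmptyModelError("control pileups cover no target positions")
    pooled = pd.concat(melted, ignore_index=True)
    grouped = (
        pooled.groupby(["chrom", "pos", "ref", "alt"])
        .agg(
            mean=("fraction", "mean"),
            sd=("fraction", lambda s: s.std(ddof=1)),
            n=("fraction", "count"),
            ctrl_depth=("depth", "mean"),
        )
        .reset_index()
    )
    grouped = grouped[grouped["n"] >= 2].reset_index(drop=True)
    if not len(grouped):
        raise EmptyModelError("no (position, alt) entry covered by >= 2 controls")
    grouped["n"] = grouped["n"].astype(int)

    # sample-level jitter: relative spread of each control's overall error
    # rate (total alt mass), estimated across the whole target at once
    totals = np.array([
        m["count"].sum() / m.groupby("pos")["depth"].first().sum()
        for m in melted
    ])
    rel_jitter = (
        float(totals.std(ddof=1) / totals.mean()) if totals.mean() > 0 else 0.0
    )
    return NoiseModel(grouped[MODEL_COLUMNS], floor=floor,
                      rel_jitter_sd=rel_jitter)


def zscore(
    observed: float, pos: int, alt: str, model: NoiseModel,
    depth: int | None = None,
) -> float:
    """Standardized excess of an observed fraction over the background."""
    mean, sd = model.entry(pos, alt, depth=depth)
    return (observed - mean) / sd


def zscores(pileup: pd.DataFrame, model: NoiseModel) -> pd.DataFrame:
    """Vectorized z per (position, alt) of a sample pileup.

    Returns the melted pileup joined with the model; rows without model
    coverage carry NaN z (callers decide whether that is an error).
    """
    long = _melt_fractions(pileup)
    merged = long.merge(
        model.table[["pos", "alt", "mean", "sd", "n", "ctrl_depth"]],
        on=["pos", "alt"], how="left",
    )
    pred_sd = model.predictive_sd(
        merged["mean"].to_numpy(), merged["n"].to_numpy(),
        merged["ctrl_depth"].to_numpy(), merged["depth"].to_numpy(),
    )
    eff_sd = np.maximum(np.maximum(merged["sd"], model.floor), pred_sd)
    merged["z"] = (merged["fraction"] - merged["mean"]) / eff_sd
    return merged


# ---------------------------------------------------------------------------
# Serialization


def write_noise_tsv(model: NoiseModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#floor={model.floor!r}\trel_jitter_sd={model.rel_jitter_sd!r}\n")
        model.table.to_csv(fh, sep="\t", index=False)


def read_noise_tsv(path: str | Path) -> NoiseModel:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#floor="):
            raise ValueError(f"{path}: missing #floor header line")
        fields = dict(
            kv.split("=", 1) for kv in first.lstrip("#").strip().split("\t")
        )
        table = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(MODEL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"noise TSV {path} lacks columns: {sorted(missing)}")
    return NoiseModel(
        table[MODEL_COLUMNS],
        floor=float(fields["floor"]),
        rel_jitter_sd=float(fields.get("rel_jitter_sd", 0.0)),
    )
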