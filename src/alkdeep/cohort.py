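"""Cohort-level statistics over the packaged 105-case neuroblastoma table.

The packaged fixture transcribes the published per-case table verbatim
(decimal commas and all): deep-sequencing result with VAF percentages,
Sanger status, outcome, SNP-array genomic profile, age and INRG stage.
This module parses those strings, derives per-case flags (mutation-positive,
subclonal, Sanger-missed, 11q-deleted, MYCN-amplified, ...), reproduces the
published tallies, and provides the association and survival machinery.

Conventions mirroring the published tallies:

* "mutation-positive" counts cases with at least one non-synonymous point
  mutation; the synonymous D1160D case and amplification-only cases are
  tallied separately;
* "ALK-altered" = mutation-positive or amplified;
* the mutation spectrum counts each case once, by its highest-VAF
  (primary) mutation, so a dual-clone case contributes its major clone;
* a case is subclonal when its highest VAF is below 20%;
* "Sanger-missed" = deep-sequencing positive with an explicit Sanger "Neg"
  (per-case status column, not the threshold rule);
* profile-token matching: "11q-del" anywhere in the profile string marks an
  11q-deleted case; "NMA" marks a MYCN-amplified case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import UndefinedTestError

COHORT_COLUMNS = [
    "case_id", "sanger", "deep_seq", "effect", "outcome",
    "genomic_profile", "age_months", "inrg",
]

_OUTCOMES = {"NED > 5 y", "NED < 5 y", "DOD", "AWD"}
_INRG = {"L", "M", "MS"}
#: Normalized genomic-profile vocabulary ("17q gain" ~ "17q-gain" etc.).
_PROFILE_TOKENS = {
    "nma", "11q-del", "17q-gain", "num only", "other segm",
    "alk-amp", "chrom.tr",
}

_MUTATION_RE = re.compile(r"([A-Z]\d{3,4}[A-Z])(?:\s*\((\d+(?:[.,]\d+)?)\s*%?\))?")


@dataclass(frozen=True)
class DeepSeqResult:
    """Parsed deep-sequencing column: named mutations with VAF percentages."""

    mutations: tuple[tuple[str, float | None], ...] = ()
    amplified: bool = False

    @property
    def negative(self) -> bool:
        return not self.mutations and not self.amplified


def parse_deep_seq(value: str) -> DeepSeqResult:
    """Parse entries like ``F1174L (24,7%)``, ``Neg``, ``Amp.`` or dual calls."""
    text = str(value).strip()
    if not text or text.lower() in {"neg", "nan"}:
        return DeepSeqResult()
    if text.lower().startswith("amp"):
        return DeepSeqResult(amplified=True)
    mutations = []
    for name, vaf in _MUTATION_RE.findall(text):
        vaf_pct = float(vaf.replace(",", ".")) if vaf else None
        if vaf_pct is not None and not 0 < vaf_pct <= 100:
            raise ValueError(f"VAF {vaf_pct}% outside (0, 100] in {value!r}")
        mutations.append((name, vaf_pct))
    if not mutations:
        raise ValueError(f"unparseable deep-seq entry: {value!r}")
    return DeepSeqResult(mutations=tuple(mutations))


def mutation_residue(name: str) -> int:
    return int(re.search(r"\d+", name).group())


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged 105-case fixture (or a user table) and validate it."""
    if path is None:
        source = resources.files("alkdeep").joinpath("data/cohort_105.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    table = table[COHORT_COLUMNS].copy()
    table["age_months"] = table["age_months"].astype(int)
    for i, row in table.iterrows():
        if row["outcome"] not in _OUTCOMES:
            raise ValueError(f"row {i}: unknown outcome {row['outcome']!r}")
        if row["inrg"] not in _INRG:
            raise ValueError(f"row {i}: unknown INRG stage {row['inrg']!r}")
        profile = row["genomic_profile"].lower().replace("17q gain", "17q-gain")
        for token in re.split(r"[+()]", profile):
            token = token.strip().rstrip(".")
            # "chrom.tr" keeps its inner dot; trailing dots come off "segm."
            if token and token not in _PROFILE_TOKENS:
                raise ValueError(
                    f"row {i}: unknown genomic-profile token {token!r}"
                )
        parse_deep_seq(row["deep_seq"])  # raises on malformed entries
    return table


# ---------------------------------------------------------------------------
# Per-case derived flags


def annotate_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-case boolean/derived columns used by every downstream tally."""
    out = table.copy()
    parsed = out["deep_seq"].map(parse_deep_seq)
    nonsyn = parsed.map(
        lambda r: tuple((n, v) for n, v in r.mutations if n[0] != n[-1])
    )
    out["mutation_positive"] = nonsyn.map(bool).astype(bool)
    out["synonymous_only"] = parsed.map(
        lambda r: bool(r.mutations) and all(n[0] == n[-1] for n, _ in r.mutations)
    ).astype(bool)
    out["amplified"] = parsed.map(lambda r: r.amplified).astype(bool)
    out["n_mutations"] = nonsyn.map(len)
    out["max_vaf_pct"] = nonsyn.map(
        lambda ms: max((v for _, v in ms if v is not None), default=np.nan)
    )
    out["primary_mutation"] = nonsyn.map(
        lambda ms: max(ms, key=lambda m: -np.inf if m[1] is None else m[1])[0]
        if ms else None
    )
    out["all_mutations"] = nonsyn.map(lambda ms: tuple(n for n, _ in ms))
    out["subclonal"] = pd.Series(
        np.where(out["mutation_positive"], out["max_vaf_pct"] < 20.0, None),
        index=out.index, dtype=object,
    )
    out["sanger_missed"] = out["mutation_positive"] & (out["sanger"] == "Neg")
    out["alk_altered"] = out["mutation_positive"] | out["amplified"]
    profile = out["genomic_profile"].str.lower()
    out["has_11q_del"] = profile.str.contains("11q-del")
    out["mycn_amplified"] = profile.str.contains("nma")
    out["deceased"] = out["outcome"] == "DOD"
    return out


# ---------------------------------------------------------------------------
# Published-tally summary


def summarize_mutations(table: pd.DataFrame) -> dict:
    """Counts and percentages of the cohort's mutation landscape."""
    ann = annotate_cases(table)
    n = len(ann)
    mutated = ann[ann["mutation_positive"]]
    by_residue: dict[int, int] = {}
    for names in mutated["all_mutations"]:
        for res in {mutation_residue(nm) for nm in names}:
            by_residue[res] = by_residue.get(res, 0) + 1
    primary_counts = (
        mutated["primary_mutation"].value_counts().sort_index().to_dict()
    )
    vafs = mutated["max_vaf_pct"].dropna()
    all_vafs = [
        v for names in mutated["deep_seq"].map(parse_deep_seq)
        for _, v in names.mutations if v is not None
    ]
    return {
        "n_cases": n,
        "point_mutation_positive": int(len(mutated)),
        "pct_point_mutation_positive": round(100.0 * len(mutated) / n, 1) if n else 0.0,
        "synonymous_cases": int(ann["synonymous_only"].sum()),
        "amplification_cases": int(ann["amplified"].sum()),
        "alk_altered": int(ann["alk_altered"].sum()),
        "pct_alk_altered": round(100.0 * ann["alk_altered"].sum() / n, 1) if n else 0.0,
        "samples_by_residue": dict(sorted(by_residue.items())),
        "primary_substitution_counts": primary_counts,
        "clonal": int((ann["subclonal"] == False).sum()),  # noqa: E712
        "subclonal": int((ann["subclonal"] == True).sum()),  # noqa: E712
        "sanger_missed": int(ann["sanger_missed"].sum()),
        "min_vaf_pct": float(min(all_vafs)) if all_vafs else np.nan,
        "max_vaf_pct": float(max(all_vafs)) if all_vafs else np.nan,
        "n_vaf_entries": len(all_vafs),
    }


# ---------------------------------------------------------------------------
# Contingency tables and Fisher's exact test


#: Named per-case factors available to crosstab; NaN rows are excluded,
#: which is how "subclonal among mutated" restricts to mutated cases.
FACTORS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "mutation_positive": lambda a: a["mutation_positive"],
    "alk_altered": lambda a: a["alk_altered"],
    "amplified": lambda a: a["amplified"],
    "11q_del": lambda a: a["has_11q_del"],
    "mycn_amplified": lambda a: a["mycn_amplified"],
    "subclonal": lambda a: a["subclonal"],
    "deceased": lambda a: a["deceased"],
    "inrg": lambda a: a["inrg"],
    "outcome": lambda a: a["outcome"],
}


def crosstab(table: pd.DataFrame, row_factor: str, col_factor: str) -> pd.DataFrame:
    """r x c contingency counts over named per-case factors."""
    ann = annotate_cases(table)
    try:
        rows = FACTORS[row_factor](ann)
        cols = FACTORS[col_factor](ann)
    except KeyError as exc:
        raise KeyError(
            f"unknown factor {exc.args[0]!r}; available: {sorted(FACTORS)}"
        ) from None
    return pd.crosstab(rows.rename(row_factor), cols.rename(col_factor))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Survival (per-case follow-up times are user-supplied or simulated)


@dataclass(frozen=True)
class SurvivalRecord:
    time: float  # months
    event: int  # 1 = death observed, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


class KMCurve:
    """Product-limit survival estimate; callable as S(t)."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = times
        self.survival = survival

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValueError("survival is undefined at negative times")
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate honouring right-censoring; S(0) = 1."""
    if not records:
        raise ValueError("no survival records")
    if any(r.time < 0 for r in records):
        raise ValueError("negative survival time")
    fitter = KaplanMeierFitter()
    fitter.fit([r.time for r in records], [r.event for r in records])
    sf = fitter.survival_function_
    return KMCurve(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Log-rank chi-square statistic (1 df) and p-value for two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    events_a = sum(r.event for r in group_a)
    events_b = sum(r.event for r in group_b)
    if events_a == 0 and events_b == 0:
        raise UndefinedTestError("no events in either group")
    result = logrank_test(
        [r.time for r in group_a], [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(result.test_statistic), float(result.p_value)


def simulate_exponential_survival(
    n: int, median_months: float, seed: int, group: str = "",
    censor_months: float | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival times with optional administrative censoring."""
    rng = np.random.default_rng(seed)
    scale = median_months / np.log(2)
    times = rng.exponential(scale, size=n)
    records = []
    for t in times:
        if censor_months is not None and t > censor_months:
            records.append(SurvivalRecord(censor_months, 0, group))
        else:
            records.append(SurvivalRecord(float(t), 1, group))
    return records


def write_cohort_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=COHORT_COLUMNS)
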