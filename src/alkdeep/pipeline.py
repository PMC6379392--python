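"""End-to-end run configuration and orchestration.

``run_pipeline`` binds the stages together: load (or estimate from control
pileups) the background-noise model, call variants on every sample pileup,
and write the artifacts — noise TSV, one VCF per sample, a JSON report and
a JSON-lines log recording the seed and every threshold actually applied.
Identical configuration and seed produce byte-identical VCF bodies.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__, calling, noise, pileup, reference
from .errors import InvalidConfigurationError


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    sample_pileups: tuple[str, ...] = ()
    control_pileups: tuple[str, ...] = ()
    noise_path: str | None = None  # precomputed model; overrides controls
    k: float = calling.DEFAULT_K
    min_depth: int = pileup.DEFAULT_MIN_DEPTH
    min_base_quality: int = pileup.DEFAULT_MIN_BASE_QUALITY
    clonal_threshold: float = calling.DEFAULT_CLONAL_THRESHOLD
    sanger_threshold: float = calling.DEFAULT_SANGER_THRESHOLD
    noise_floor: float = noise.DEFAULT_NOISE_FLOOR
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidConfigurationError("k must be positive")
        if self.min_depth < 1:
            raise InvalidConfigurationError("min_depth must be >= 1")
        for name in ("clonal_threshold", "sanger_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidConfigurationError(f"{name} must be in (0, 1)")
        if self.noise_path is None and len(self.control_pileups) < 2:
            raise InvalidConfigurationError(
                "need a noise model or at least two control pileups"
            )

    def thresholds(self) -> dict:
        return {
            "k": self.k,
            "min_depth": self.min_depth,
            "min_base_quality": self.min_base_quality,
            "clonal_threshold": self.clonal_threshold,
            "sanger_threshold": self.sanger_threshold,
            "noise_floor": self.noise_floor,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute noise estimation + calling; return the run report (also on disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    events: list[dict] = []

    def log(event: str, **data) -> None:
        events.append({"time": datetime.now(timezone.utc).isoformat(),
                       "event": event, **data})

    log("start", version=__version__, python=platform.python_version(),
        seed=config.seed, thresholds=config.thresholds())

    reference_model = reference.default_reference()
    if config.noise_path is not None:
        model = noise.read_noise_tsv(config.noise_path)
        log("noise_loaded", path=str(config.noise_path),
            entries=int(len(model.table)))
    else:
        controls = []
        for path in config.control_pileups:
            if not Path(path).exists():
                raise FileNotFoundError(f"control pileup not found: {path}")
            controls.append(pileup.read_pileup_tsv(path))
        model = noise.estimate_background(controls, floor=config.noise_floor)
        log("noise_estimated", n_controls=len(controls),
            entries=int(len(model.table)))
    noise_out = out_dir / "noise_model.tsv"
    noise.write_noise_tsv(model, noise_out)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "noise_model": str(noise_out),
        "samples": {},
    }
    for path in config.sample_pileups:
        if not Path(path).exists():
            raise FileNotFoundError(f"sample pileup not found: {path}")
        sample_id = Path(path).stem
        sample_pileup = pileup.read_pileup_tsv(path)
        result = calling.call_variants(
            sample_pileup, model, reference_model,
            k=config.k, min_depth=config.min_depth,
            clonal_threshold=config.clonal_threshold,
            sanger_threshold=config.sanger_threshold,
            sample_id=sample_id,
        )
        vcf_path = out_dir / f"{sample_id}.vcf"
        calling.write_vcf(result.calls, vcf_path, sample_id=sample_id)
        report["samples"][sample_id] = {
            "vcf": str(vcf_path),
            "n_calls": len(result.calls),
            "n_tests": result.n_tests,
            "n_not_assessable": result.n_not_assessable,
            "n_coverage_gaps": len(result.coverage_gaps),
            "calls": [
                {"pos": c.pos, "ref": c.ref, "alt": c.alt, "vaf": c.vaf,
                 "z": c.z, "aa_change": c.aa_change, "clonality": c.clonality,
                 "sanger_detectable": c.sanger_detectable}
                for c in result.calls
            ],
        }
        log("sample_called", sample=sample_id, n_calls=len(result.calls),
            n_tests=result.n_tests)

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    log("done", report=str(report_path))
    with open(log_path, "w") as fh:
        for e in events:
            fh.write(json.dumps(e) + "\n")
    return report


def write_demo_inputs(out_dir: str | Path, seed: int = 0,
                      depth: int = 5000, n_controls: int = 8) -> dict:
    """Simulate a small demo data set (controls + two spiked tumours) on disk."""
    from . import simulate  # deferred: pipeline itself has no simulation deps

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = reference.default_reference()
    profile = simulate.draw_error_profile(seed=seed)
    control_paths = []
    for i, ctrl in enumerate(
        simulate.simulate_control_cohort(profile, n_controls, depth, seed=seed + 1)
    ):
        path = out / f"control{i + 1}.tsv"
        pileup.write_pileup_tsv(ctrl, path)
        control_paths.append(str(path))
    sample_paths = []
    for name, vaf in (("F1174L", 0.247), ("F1245I", 0.14)):
        pos, _rb, alt = reference.mutation_site(name, ref)
        sample = simulate.SimulatedSample(
            f"tumour_{name}", spike_ins=(simulate.SpikeIn(pos, alt, vaf),),
            depth=depth, seed=seed + sum(ord(ch) for ch in name),
        )
        path = out / f"{sample.sample_id}.tsv"
        pileup.write_pileup_tsv(simulate.simulate_pileup(sample, profile), path)
        sample_paths.append(str(path))
    return {"controls": control_paths, "samples": sample_paths}
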