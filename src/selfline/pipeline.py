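"""End-to-end orchestration: simulate -> filter -> correct -> trajectory ->
drift test -> diversity/LD, driven by one config with reproducible seeds.

One global seed is split deterministically per stage by hashing the stage
name, so toggling one stage never perturbs another stage's random stream.
The run manifest records the package version, a hash of the resolved config,
and per-stage input/output locus counts; identical config + seed reproduces
identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    GenotypeTable,
    PedigreeTable,
    read_pedigree,
    read_vcf,
    write_pedigree,
    write_vcf,
)
from .synthetic_data import SimulationConfig, simulate_selfing_panel
from .snp_qc import run_filter_cascade
from .selfing_lines import correct_panel, f_uni, heterozygosity_trajectory
from .drift_outliers import chi2_drift_test, tabulate_fixation
from .diversity_ld import all_pairs_within_scaffold, fit_ld_decay, pi_windows

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold defaults to the study value."""

    out_dir: str = "selfline_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    filter: bool = True
    correct: bool = True
    trajectory: bool = True
    drift_test: bool = True
    diversity: bool = True
    ld_fit: bool = False
    # inputs when not simulating
    vcf: str | None = None
    pedigree: str | None = None
    # stage parameters
    sim: dict[str, Any] = field(default_factory=dict)
    filter_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    drift_generation: str = "S4"
    drift_min_lines: int = 3
    drift_fdr: float = 0.05
    pi_window_bp: int = 10_000
    ld_maf: float = 0.05
    ld_n: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = info

    table: GenotypeTable | None = None
    depths = None
    ped: PedigreeTable | None = None

    try:
        if config.simulate:
            sim_cfg = SimulationConfig(
                seed=stage_seed(config.seed, "simulate"), **config.sim
            )
            table, depths, ped, truth = simulate_selfing_panel(sim_cfg)
            write_vcf(table, depths, out / "simulated.vcf")
            write_pedigree(ped, out / "simulated.ped.tsv")
            pd.DataFrame(
                truth.genotypes, index=truth.sample_ids
            ).to_csv(out / "simulated.truth.tsv", sep="\t")
            record("simulate", n_samples=table.n_samples, n_loci=table.n_loci)
        else:
            if config.vcf is None or config.pedigree is None:
                raise StageError("inputs: vcf and pedigree required when not simulating")
            table, depths = read_vcf(config.vcf)
            ped = read_pedigree(config.pedigree)
            record("inputs", n_samples=table.n_samples, n_loci=table.n_loci)
    except StageError:
        raise
    except Exception as exc:
        _abort(manifest, out, "simulate/inputs", exc)

    assert table is not None and ped is not None

    if config.filter:
        try:
            table, depths, report = run_filter_cascade(
                table, depths, params=config.filter_params
            )
            report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
            record(
                "filter",
                skipped=False,
                n_in=int(report.steps[0].n_in) if report.steps else table.n_loci,
                n_out=table.n_loci,
                steps=[s.name for s in report.steps],
            )
        except Exception as exc:
            _abort(manifest, out, "filter", exc)
    else:
        record("filter", skipped=True)

    corrected = None
    if config.correct:
        try:
            corrected = correct_panel(table, ped)
            kept = corrected.kept()
            write_vcf(kept.to_genotype_table(ped), None, out / "corrected.vcf")
            removed = corrected.loci.loc[~corrected.locus_kept, ["scaffold", "pos"]]
            removed.assign(reason="uncorrectable").to_csv(
                out / "removed_loci.tsv", sep="\t", index=False
            )
            record(
                "correct",
                n_in=corrected.n_loci,
                n_removed=int((~corrected.locus_kept).sum()),
                n_out=kept.n_loci,
            )
        except Exception as exc:
            _abort(manifest, out, "correct", exc)
    else:
        record("correct", skipped=True)

    if config.trajectory and corrected is not None:
        try:
            traj = heterozygosity_trajectory(corrected, ped)
            traj.to_csv(out / "trajectory.tsv", sep="\t", index=False)
            record("trajectory", n_generations=len(traj))
        except Exception as exc:
            _abort(manifest, out, "trajectory", exc)

    if config.drift_test and corrected is not None:
        try:
            fix = tabulate_fixation(
                corrected,
                ped,
                generation=config.drift_generation,
                min_lines=config.drift_min_lines,
            )
            result = chi2_drift_test(fix, fdr=config.drift_fdr)
            result.to_csv(out / "drift_outliers.tsv", sep="\t", index=False)
            record(
                "drift_test",
                n_tested=len(result),
                n_significant=int(result["significant"].sum()) if len(result) else 0,
            )
        except Exception as exc:
            _abort(manifest, out, "drift_test", exc)

    if config.diversity:
        try:
            pw = pi_windows(table, window_bp=config.pi_window_bp)
            pw.to_csv(out / "pi_windows.tsv", sep="\t", index=False)
            record("diversity", n_windows=len(pw))
        except Exception as exc:
            _abort(manifest, out, "diversity", exc)

    if config.ld_fit:
        try:
            pairs = all_pairs_within_scaffold(table, maf=config.ld_maf)
            n = config.ld_n or table.n_samples
            fit = fit_ld_decay(pairs, n=n)
            (out / "ld_fit.json").write_text(
                json.dumps(
                    {
                        "c_per_bp": fit.c_per_bp,
                        "n": fit.n,
                        "rss": fit.rss,
                        "n_pairs": fit.n_pairs,
                        "half_decay_bp": fit.half_decay_bp,
                        "d_at_r2": {str(k): v for k, v in fit.d_at_r2.items()},
                    },
                    indent=2,
                )
            )
            record("ld_fit", n_pairs=fit.n_pairs, c_per_bp=fit.c_per_bp)
        except Exception as exc:
            _abort(manifest, out, "ld_fit", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _abort(manifest: dict[str, Any], out: Path, stage: str, exc: Exception) -> None:
    manifest["failed_stage"] = stage
    manifest["error"] = str(exc)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    raise StageError(f"stage {stage!r} failed: {exc}") from exc
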