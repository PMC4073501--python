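"""End-to-end pipeline: simulate -> segment -> call -> CNVR -> annotate -> groups.

Stages are plain functions over the library modules; :func:`run_all` chains
them for a configuration and writes every intermediate table plus a run
report.  All randomness flows from the single configured seed, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import annotate, callcnv, cnvr, groups as groups_mod, io, segment as segment_mod, syndata
from .core import Cnvr, CnvCall, GenomeLayout, ProbeMap, RatioProfiles, Segment, default_genome

_KNOWN_KEYS = {
    "outdir",
    "seed",
    "n_samples_per_group",
    "group_names",
    "mean_spacing",
    "probe_len",
    "noise_sd",
    "n_shared",
    "n_group",
    "n_private",
    "min_event_len",
    "max_event_len",
    "penalty",
    "threshold",
    "min_probes",
    "min_fraction",
    "n_genes",
    "n_qtls",
    "n_perm",
    "alpha",
    "verbose",
}


@dataclass
class RunConfig:
    """Parameters for a full synthetic run; unknown keys are rejected on load."""

    outdir: str = "cnvherd_out"
    seed: int = 0
    group_names: tuple[str, ...] = ("taurine", "yak", "buffalo")
    n_samples_per_group: tuple[int, ...] = (8, 2, 3)
    mean_spacing: int = syndata.DEFAULT_MEAN_SPACING
    probe_len: int = syndata.DEFAULT_PROBE_LEN
    noise_sd: float = 0.2
    n_shared: int = 2
    n_group: int = 3
    n_private: int = 2
    min_event_len: int = 30_000
    max_event_len: int = 120_000
    penalty: float | str = "auto"
    threshold: float = 0.5
    min_probes: int = 5
    min_fraction: float = 0.5
    n_genes: int = 100
    n_qtls: int = 60
    n_perm: int = 999
    alpha: float = 0.05
    verbose: bool = False

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.n_samples_per_group):
            raise ValueError("group_names and n_samples_per_group must align")
        if self.threshold <= 0 or self.min_probes < 1:
            raise ValueError("threshold must be > 0 and min_probes >= 1")
        if not (0 <= self.min_fraction < 1):
            raise ValueError("min_fraction must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.noise_sd < 0 or self.n_perm < 1:
            raise ValueError("noise_sd must be >= 0 and n_perm >= 1")
        if self.penalty != "auto" and float(self.penalty) < 0:
            raise ValueError("penalty must be 'auto' or a non-negative number")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_names", "n_samples_per_group"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def _log(cfg: RunConfig, stage: str, msg: str) -> None:
    if cfg.verbose:
        print(f"[{stage}] {msg}", file=sys.stderr)


def sample_layout(cfg: RunConfig) -> dict[str, str]:
    """Sample -> group assignment implied by the configuration."""
    out: dict[str, str] = {}
    for g, n in zip(cfg.group_names, cfg.n_samples_per_group):
        for i in range(1, n + 1):
            out[f"{g}_{i}"] = g
    return out


def subseed(seed: int, stage: int) -> int:
    """Derive a per-stage seed below 2^31 from the master seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def simulate_stage(
    cfg: RunConfig, genome: GenomeLayout | None = None
) -> tuple[GenomeLayout, ProbeMap, list, RatioProfiles, list]:
    """Generate genome, probes, truth events, ratio profiles and features."""
    genome = genome or default_genome()
    grp = sample_layout(cfg)
    probes = syndata.make_probes(
        genome, cfg.mean_spacing, cfg.probe_len, seed=subseed(cfg.seed, 1)
    )
    design = syndata.EventDesign(
        n_shared=cfg.n_shared,
        n_group=cfg.n_group,
        n_private=cfg.n_private,
        min_len=cfg.min_event_len,
        max_len=cfg.max_event_len,
        mito_shift={g: (3 if i == 0 else 1) for i, g in enumerate(cfg.group_names)},
    )
    truth = syndata.plant_events(genome, grp, design, seed=subseed(cfg.seed, 2))
    profiles = syndata.simulate_ratios(
        probes, truth, grp, noise_sd=cfg.noise_sd, seed=subseed(cfg.seed, 3)
    )
    features = syndata.make_features(
        genome, cfg.n_genes, cfg.n_qtls, seed=subseed(cfg.seed, 4)
    )
    return genome, probes, truth, profiles, features


def segment_stage(
    profiles: RatioProfiles, probes: ProbeMap, penalty: float | str = "auto"
) -> dict[str, list[Segment]]:
    """Median-center each sample and segment every chromosome."""
    out: dict[str, list[Segment]] = {}
    for sample in profiles.samples:
        centered = segment_mod.median_center(profiles.values[sample].to_numpy())
        by_chrom = {
            c: centered[slice(*probes.span(c))] for c in probes.chromosomes
        }
        out[sample] = segment_mod.segment_sample(by_chrom, penalty=penalty)
    return out


def call_stage(
    segments: Mapping[str, Sequence[Segment]],
    probes: ProbeMap,
    threshold: float = 0.5,
    min_probes: int = 5,
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    for sample, segs in segments.items():
        calls.extend(callcnv.call_cnvs(segs, probes, sample, threshold, min_probes))
    return calls


def cnvr_stage(
    calls: Sequence[CnvCall],
    grp: Mapping[str, str],
) -> tuple[dict[str, list[Cnvr]], list[Cnvr], dict[tuple[str, ...], int]]:
    """Per-group CNVR sets plus the merged cross-group set and Venn counts."""
    by_group: dict[str, list[str]] = {}
    for s, g in grp.items():
        by_group.setdefault(g, []).append(s)
    group_cnvrs = {
        g: cnvr.build_cnvrs(
            [c for c in calls if grp[c.sample] == g],
            by_group[g],
            group_label=g,
            id_prefix=f"{g}_CNVR",
        )
        for g in by_group
    }
    merged, venn = cnvr.merge_groups(group_cnvrs, total_samples=len(grp))
    return group_cnvrs, merged, venn


def run_all(cfg: RunConfig) -> dict[str, object]:
    """Execute every stage on synthetic data and write all outputs to ``outdir``.

    Returns a run report: per-stage record counts, summaries, parameters and
    the seed.  Any stage failure aborts with the stage named.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grp = sample_layout(cfg)
    report: dict[str, object] = {"seed": cfg.seed, "parameters": asdict(cfg)}

    stage = "simulate"
    try:
        genome, probes, truth, profiles, features = simulate_stage(cfg)
        _log(cfg, stage, f"{len(probes)} probes, {len(truth)} truth events")
        io.write_genome(outdir / "genome.tsv", genome, seed=cfg.seed)
        io.write_probes(outdir / "probes.tsv", probes, seed=cfg.seed)
        io.write_truth(outdir / "truth.tsv", truth, seed=cfg.seed)
        io.write_ratios(outdir / "ratios.tsv", profiles, seed=cfg.seed, noise_sd=cfg.noise_sd)
        io.write_sample_groups(outdir / "samples.tsv", grp, seed=cfg.seed)
        io.write_features(outdir / "features.tsv", features, seed=cfg.seed)
        report[stage] = {"n_probes": len(probes), "n_truth_events": len(truth)}

        stage = "segment"
        segments = segment_stage(profiles, probes, penalty=cfg.penalty)
        io.write_segments(outdir / "segments.tsv", segments, probes, penalty=cfg.penalty)
        report[stage] = {"n_segments": sum(len(v) for v in segments.values())}

        stage = "call"
        calls = call_stage(segments, probes, cfg.threshold, cfg.min_probes)
        io.write_calls(
            outdir / "calls.tsv", calls, threshold=cfg.threshold, min_probes=cfg.min_probes
        )
        report[stage] = {"n_calls": len(calls)}

        stage = "cnvr"
        group_cnvrs, merged, venn = cnvr_stage(calls, grp)
        for g, rs in group_cnvrs.items():
            io.write_cnvrs(outdir / f"cnvrs_{g}.tsv", rs, seed=cfg.seed)
        io.write_cnvrs(outdir / "cnvrs_merged.tsv", merged, seed=cfg.seed)
        summaries = {
            g: cnvr.summarize(rs, genome.total_length, sum(1 for s in grp.values() if s == g))
            for g, rs in group_cnvrs.items()
        }
        summaries["merged"] = cnvr.summarize(merged, genome.total_length, len(grp))
        report[stage] = {
            "per_group": {g: asdict(s) for g, s in summaries.items()},
            "venn": {"+".join(k): v for k, v in venn.items()},
        }

        stage = "annotate"
        hits, ann = annotate.overlap_features(
            merged, features, cfg.min_fraction, chromosomes=genome.names
        )
        report[stage] = {
            "n_hits": len(hits),
            "n_cnvrs_with_gene": ann.n_cnvrs_with_gene,
            "n_cnvrs_with_qtl": ann.n_cnvrs_with_qtl,
            "percent_with_gene": ann.percent_with_gene,
            "qtl_class_counts": ann.qtl_class_counts,
        }

        stage = "groups"
        matrix = groups_mod.presence_matrix(merged, list(grp))
        results = groups_mod.indval(
            matrix, grp, n_perm=cfg.n_perm, seed=subseed(cfg.seed, 5)
        )
        n_sig = len(groups_mod.significant(results, cfg.alpha))
        report[stage] = {"n_cnvrs_tested": len(results), "n_indicative": n_sig}
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "run_report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
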