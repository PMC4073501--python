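"""Synthetic aCGH experiment generator.

Emulates the statistical structure the downstream analysis assumes: a
multi-chromosome probe layout with roughly even spacing, planted copy-number
events (0-4 copies) organised as shared-across-all / group-shared / private,
Gaussian probe noise on log2(test/reference), a 5-probe mitochondrial contig
with optional group-level copy shifts, gene/QTL annotation intervals, qPCR Ct
tables and phenotypes under the additive farm + genotype + breed model.

Every generator is deterministic for a fixed seed.  Ground-truth event sets
are returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    GAIN,
    LOSS,
    Chromosome,
    GenomeLayout,
    FeatureInterval,
    ProbeMap,
    RatioProfiles,
    TruthEvent,
)

# QTL trait classes used by the cattle QTL database
QTL_CLASSES = ("exterior", "health", "meat-carcass", "milk", "production", "reproduction")

# CN=0 expectation floor in log2 units: real arrays saturate rather than
# reporting -inf for homozygous deletions.
CN0_FLOOR = -3.0

DEFAULT_MEAN_SPACING = 3364  # bp, matches the commercial 720k bovine design
DEFAULT_PROBE_LEN = 60  # bp, middle of the 50-75 bp design range
MITO_N_PROBES = 5


def _expected_log2(cn: int) -> float:
    if cn == 0:
        return CN0_FLOOR
    return float(np.log2(cn / 2.0))


def make_probes(
    genome: GenomeLayout,
    mean_spacing: int = DEFAULT_MEAN_SPACING,
    probe_len: int = DEFAULT_PROBE_LEN,
    seed: int = 0,
    mito_probes: int = MITO_N_PROBES,
) -> ProbeMap:
    """Tile each chromosome with probes at jittered spacing.

    Start-to-start gaps are drawn uniformly on [0.5, 1.5] x ``mean_spacing``,
    so the realised mean spacing matches the request.  The mitochondrial
    contig gets exactly ``mito_probes`` evenly spaced probes regardless of
    spacing, mirroring the dedicated mitochondrial probe set of the array.
    """
    if mean_spacing <= probe_len:
        raise ValueError("mean_spacing must exceed probe_len")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, int, str]] = []
    for chrom in genome.chromosomes:
        if chrom.length < probe_len:
            raise ValueError(
                f"chromosome {chrom.name!r} ({chrom.length} bp) is shorter than one probe"
            )
        if chrom.is_mito:
            starts = np.linspace(0, chrom.length - probe_len, mito_probes).astype(int)
            for k, s in enumerate(starts):
                rows.append((chrom.name, int(s), int(s) + probe_len, f"{chrom.name}_P{k + 1}"))
            continue
        pos = int(rng.uniform(0, mean_spacing))
        k = 0
        while pos + probe_len <= chrom.length:
            k += 1
            rows.append((chrom.name, pos, pos + probe_len, f"{chrom.name}_P{k}"))
            gap = int(round(rng.uniform(0.5, 1.5) * mean_spacing))
            pos += max(gap, probe_len + 1)  # keep probes non-overlapping
    df = pd.DataFrame(rows, columns=list(ProbeMap.COLUMNS))
    return ProbeMap(df)


@dataclass(frozen=True)
class EventDesign:
    """How many events to plant and how big they are.

    ``n_shared`` events are placed identically in every sample; ``n_group``
    events per group are placed identically in every member of that group;
    ``n_private`` events per sample occur in exactly one sample.  Lengths are
    uniform on [min_len, max_len]; copy numbers are drawn uniformly from
    ``copy_numbers``.  ``mito_shift`` maps a group label to a whole-contig
    mitochondrial copy number for that group.
    """

    n_shared: int = 2
    n_group: int = 3
    n_private: int = 2
    min_len: int = 30_000
    max_len: int = 120_000
    copy_numbers: tuple[int, ...] = (0, 1, 1, 3, 4)
    mito_shift: Mapping[str, int] | None = None


def plant_events(
    genome: GenomeLayout,
    groups: Mapping[str, str],
    design: EventDesign,
    seed: int = 0,
    max_tries: int = 200,
) -> list[TruthEvent]:
    """Plant non-overlapping copy-number events with the requested sharing structure.

    Placement is rejection-sampled: an event overlapping an already-placed one
    (in any of its carrier samples) is retried elsewhere, so the first-placed
    event wins and the final per-sample sets are non-overlapping.
    """
    if not groups:
        raise ValueError("no samples given")
    if design.max_len > max(c.length for c in genome.autosomes):
        raise ValueError("requested event length exceeds every chromosome")
    rng = np.random.default_rng(seed)
    samples = list(groups)
    by_group: dict[str, list[str]] = {}
    for s, g in groups.items():
        by_group.setdefault(g, []).append(s)
    if any(len(v) < 1 for v in by_group.values()):
        raise ValueError("every group needs at least one sample")

    autosomes = genome.autosomes
    weights = np.array([c.length for c in autosomes], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, dict[str, IntervalTree]] = {
        s: {c.name: IntervalTree() for c in genome.chromosomes} for s in samples
    }
    events: list[TruthEvent] = []

    def place(carriers: Sequence[str], scope: str) -> None:
        for _ in range(max_tries):
            chrom = autosomes[rng.choice(len(autosomes), p=weights)]
            length = int(rng.integers(design.min_len, design.max_len + 1))
            if length > chrom.length:
                continue
            start = int(rng.integers(0, chrom.length - length + 1))
            end = start + length
            if any(occupied[s][chrom.name].overlap(start, end) for s in carriers):
                continue
            cn = int(rng.choice(design.copy_numbers))
            for s in carriers:
                occupied[s][chrom.name].addi(start, end)
                events.append(TruthEvent(s, chrom.name, start, end, cn, scope))
            return
        raise RuntimeError(f"could not place a {scope} event after {max_tries} tries")

    for _ in range(design.n_shared):
        place(samples, "shared-all")
    for g in by_group:
        for _ in range(design.n_group):
            place(by_group[g], "group")
    for s in samples:
        for _ in range(design.n_private):
            place([s], "private")

    if design.mito_shift:
        mito = [c for c in genome.chromosomes if c.is_mito]
        if not mito:
            raise ValueError("mito_shift requested but genome has no mitochondrial contig")
        (m,) = mito
        for g, cn in design.mito_shift.items():
            if g not in by_group:
                raise ValueError(f"mito_shift references unknown group {g!r}")
            if cn == 2:
                continue
            for s in by_group[g]:
                events.append(TruthEvent(s, m.name, 0, m.length, int(cn), "group"))
    return events


def simulate_ratios(
    probes: ProbeMap,
    truth: Sequence[TruthEvent],
    groups: Mapping[str, str],
    noise_sd: float = 0.2,
    seed: int = 0,
) -> RatioProfiles:
    """Per-probe log2 ratios: log2(CN/2) at the probe midpoint plus Gaussian noise.

    Background copy number is 2 (expectation 0).  CN=0 is floored at
    ``CN0_FLOOR``.  A probe belongs to an event iff its midpoint falls inside
    the event interval.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    samples = list(groups)
    n = len(probes)
    values = np.zeros((n, len(samples)))
    col = {s: k for k, s in enumerate(samples)}
    mids: dict[str, np.ndarray] = {c: probes.midpoints(c) for c in probes.chromosomes}
    for ev in truth:
        if ev.sample not in col:
            raise ValueError(f"truth event for unknown sample {ev.sample!r}")
        if ev.chrom not in mids:
            raise ValueError(f"truth event on unknown chromosome {ev.chrom!r}")
        i0, _ = probes.span(ev.chrom)
        m = mids[ev.chrom]
        lo = int(np.searchsorted(m, ev.start, side="left"))
        hi = int(np.searchsorted(m, ev.end, side="left"))
        values[i0 + lo : i0 + hi, col[ev.sample]] = _expected_log2(ev.copy_number)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=probes.df["probe_id"].to_numpy(), columns=samples)
    return RatioProfiles(df, dict(groups))


def make_features(
    genome: GenomeLayout,
    n_genes: int = 100,
    n_qtls: int = 60,
    gene_len: tuple[int, int] = (2_000, 100_000),
    qtl_len: tuple[int, int] = (20_000, 300_000),
    seed: int = 0,
) -> list[FeatureInterval]:
    """Random gene and QTL intervals (possibly overlapping), sorted genomically.

    Stand-in for genome-browser gene annotations and the animal QTL database;
    QTLs get a trait class drawn from the six classes that database uses.
    """
    if n_genes < 0 or n_qtls < 0:
        raise ValueError("feature counts must be non-negative")
    rng = np.random.default_rng(seed)
    autosomes = genome.autosomes
    weights = np.array([c.length for c in autosomes], dtype=float)
    weights /= weights.sum()
    feats: list[FeatureInterval] = []

    def draw(kind: str, idx: int, lo: int, hi: int, trait: str = "") -> FeatureInterval:
        while True:
            chrom = autosomes[rng.choice(len(autosomes), p=weights)]
            length = int(rng.integers(lo, hi + 1))
            if length < chrom.length:
                break
        start = int(rng.integers(0, chrom.length - length + 1))
        name = f"{kind.upper()}{idx}"
        return FeatureInterval(name, chrom.name, start, start + length, kind, name, trait)

    for i in range(n_genes):
        feats.append(draw("gene", i + 1, *gene_len))
    for i in range(n_qtls):
        trait = QTL_CLASSES[int(rng.integers(0, len(QTL_CLASSES)))]
        feats.append(draw("QTL", i + 1, *qtl_len, trait=trait))
    order = {c.name: k for k, c in enumerate(genome.chromosomes)}
    feats.sort(key=lambda f: (order[f.chrom], f.start, f.end))
    return feats


def score_recovery(
    calls: Sequence,
    truth: Sequence[TruthEvent],
) -> tuple[float, float]:
    """Recall and precision of CNV calls against the planted truth.

    A truth event is recovered when a call from the same sample with the
    matching state (loss for CN<2, gain for CN>2) overlaps it by at least one
    base; a call is a true positive when it overlaps such a truth event.
    Returns ``(recall, precision)``; either is 1.0 when its denominator is
    empty.
    """
    from .core import overlap_bp

    by_sample: dict[str, list] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    recovered = 0
    for ev in truth:
        hits = [
            c
            for c in by_sample.get(ev.sample, [])
            if c.chrom == ev.chrom
            and c.state == ev.state
            and overlap_bp(c.start, c.end, ev.start, ev.end) > 0
        ]
        recovered += bool(hits)
    truth_by_sample: dict[str, list[TruthEvent]] = {}
    for ev in truth:
        truth_by_sample.setdefault(ev.sample, []).append(ev)
    true_pos = 0
    for c in calls:
        hits = [
            ev
            for ev in truth_by_sample.get(c.sample, [])
            if ev.chrom == c.chrom
            and ev.state == c.state
            and overlap_bp(c.start, c.end, ev.start, ev.end) > 0
        ]
        true_pos += bool(hits)
    recall = recovered / len(truth) if truth else 1.0
    precision = true_pos / len(calls) if calls else 1.0
    return recall, precision


@dataclass(frozen=True)
class AssocModelSpec:
    """The additive fixed-effects trait model Y = mu + farm + genotype + breed + error."""

    trait: str
    mu: float
    farm_effects: Mapping[str, float]
    genotype_effects: Mapping[str, float]
    breed_effects: Mapping[str, float]
    error_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError("error_sd must be non-negative")
        for name, d in (
            ("farm", self.farm_effects),
            ("genotype", self.genotype_effects),
            ("breed", self.breed_effects),
        ):
            if not d:
                raise ValueError(f"{name} effects must be non-empty")


def simulate_phenotypes(
    model: AssocModelSpec,
    records: Mapping[str, tuple[str, str, str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one trait value per sample under the additive model.

    ``records`` maps sample id to (farm, breed, genotype).  Returns a
    DataFrame with columns sample, farm, breed, genotype and the trait.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, (farm, breed, geno) in records.items():
        for label, level, table in (
            ("farm", farm, model.farm_effects),
            ("breed", breed, model.breed_effects),
            ("genotype", geno, model.genotype_effects),
        ):
            if level not in table:
                raise ValueError(f"unknown {label} level {level!r} for sample {sample!r}")
        y = (
            model.mu
            + model.farm_effects[farm]
            + model.genotype_effects[geno]
            + model.breed_effects[breed]
        )
        if model.error_sd > 0:
            y += rng.normal(0.0, model.error_sd)
        rows.append((sample, farm, breed, geno, y))
    return pd.DataFrame(rows, columns=["sample", "farm", "breed", "genotype", model.trait])


def simulate_qpcr(
    copy_numbers: Mapping[str, int],
    calibrator: str = "reference",
    target_assay: str = "target",
    control_assay: str = "BTF3",
    base_ct: float = 26.0,
    control_ct: float = 20.0,
    rep_sd: float = 0.0,
    n_reps: int = 3,
    no_amp_ct: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table for relative quantification against a two-copy calibrator.

    Target Ct = base_ct - log2(CN/2) (+ replicate noise): each copy doubling
    saves one cycle.  The control assay is independent of copy number.  CN=0
    targets report the no-amplification ceiling.  The calibrator sample is
    added with CN=2 if absent from ``copy_numbers``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rep_sd < 0:
        raise ValueError("rep_sd must be non-negative")
    cns = dict(copy_numbers)
    cns.setdefault(calibrator, 2)
    if cns[calibrator] != 2:
        raise ValueError("calibrator must have two copies")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, cn in cns.items():
        if cn not in (0, 1, 2, 3, 4):
            raise ValueError(f"copy number {cn} for sample {sample!r} outside 0-4")
        for rep in range(1, n_reps + 1):
            if cn == 0:
                ct_t = no_amp_ct
            else:
                ct_t = base_ct - float(np.log2(cn / 2.0))
                if rep_sd > 0:
                    ct_t += rng.normal(0.0, rep_sd)
            ct_c = control_ct + (rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0)
            rows.append((sample, target_assay, "target", rep, ct_t))
            rows.append((sample, control_assay, "control", rep, ct_c))
    return pd.DataFrame(rows, columns=["sample", "assay", "role", "rep", "ct"])
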