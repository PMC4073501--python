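"""CNVR construction, cross-group merging, and summary accounting.

A CNVR (copy number variable region) is a connected component of the
interval-overlap graph over per-sample CNV calls: overlapping calls are pooled
transitively and the region spans their union.  Overlap requires at least one
shared base under half-open coordinates — bookended calls stay separate.  A
CNVR's state is "gain" or "loss" when all member calls agree and "both" when
carriers disagree; its frequency is carriers divided by group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import BOTH, GAIN, LOSS, Cnvr, CnvCall, GenomeLayout


def _components(
    items: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int, list[int]]]:
    """Sweep-line connected components of overlapping intervals.

    ``items`` are (chrom, start, end); returns per component (chrom, start,
    end, member indices).  Transitive union: a chain of pairwise overlaps is
    one component.
    """
    order = sorted(range(len(items)), key=lambda k: (items[k][0], items[k][1], items[k][2]))
    out: list[tuple[str, int, int, list[int]]] = []
    cur: list[int] = []
    cur_chrom, cur_start, cur_end = "", 0, 0
    for k in order:
        chrom, start, end = items[k]
        if cur and chrom == cur_chrom and start < cur_end:
            cur.append(k)
            cur_end = max(cur_end, end)
        else:
            if cur:
                out.append((cur_chrom, cur_start, cur_end, cur))
            cur = [k]
            cur_chrom, cur_start, cur_end = chrom, start, end
    if cur:
        out.append((cur_chrom, cur_start, cur_end, cur))
    return out


def _combined_state(states: Iterable[str]) -> str:
    s = set(states)
    if s == {GAIN}:
        return GAIN
    if s == {LOSS}:
        return LOSS
    return BOTH


def build_cnvrs(
    calls: Sequence[CnvCall],
    group_samples: Sequence[str],
    group_label: str = "",
    id_prefix: str = "CNVR",
) -> list[Cnvr]:
    """Aggregate one group's overlapping CNV calls into CNVRs.

    The frequency denominator is the number of samples in the group, not the
    number of samples carrying any CNV.  Ids are assigned in genomic order.
    """
    known = set(group_samples)
    for c in calls:
        if c.sample not in known:
            raise ValueError(f"call sample {c.sample!r} not in the group")
    comps = _components([(c.chrom, c.start, c.end) for c in calls])
    out: list[Cnvr] = []
    for i, (chrom, start, end, members) in enumerate(comps, start=1):
        member_calls = [calls[k] for k in members]
        carriers = tuple(sorted({c.sample for c in member_calls}))
        out.append(
            Cnvr(
                id=f"{id_prefix}{i}",
                chrom=chrom,
                start=start,
                end=end,
                state=_combined_state(c.state for c in member_calls),
                carriers=carriers,
                frequency=len(carriers) / len(group_samples),
                groups=(group_label,) if group_label else (),
            )
        )
    return out


def merge_groups(
    group_cnvrs: Mapping[str, Sequence[Cnvr]],
    total_samples: int | None = None,
    id_prefix: str = "CNVR",
) -> tuple[list[Cnvr], dict[tuple[str, ...], int]]:
    """Merge per-group CNVR sets into one integrated set with group provenance.

    Merged regions are again transitive overlap components, now across all
    groups' CNVRs.  A group shares a merged CNVR iff one of its CNVRs overlaps
    it.  The second return value gives Venn counts: how many merged CNVRs have
    each combination of contributing groups.
    """
    if not group_cnvrs:
        raise ValueError("need at least one group CNVR set")
    flat: list[tuple[str, Cnvr]] = [
        (g, r) for g, rs in group_cnvrs.items() for r in rs
    ]
    if total_samples is None:
        total_samples = len({s for _, r in flat for s in r.carriers}) or 1
    comps = _components([(r.chrom, r.start, r.end) for _, r in flat])
    merged: list[Cnvr] = []
    venn: dict[tuple[str, ...], int] = {}
    group_order = list(group_cnvrs)
    for i, (chrom, start, end, members) in enumerate(comps, start=1):
        rs = [flat[k] for k in members]
        provenance = tuple(g for g in group_order if any(gg == g for gg, _ in rs))
        carriers = tuple(sorted({s for _, r in rs for s in r.carriers}))
        merged.append(
            Cnvr(
                id=f"{id_prefix}{i}",
                chrom=chrom,
                start=start,
                end=end,
                state=_combined_state(r.state for _, r in rs),
                carriers=carriers,
                frequency=len(carriers) / total_samples,
                groups=provenance,
            )
        )
        venn[provenance] = venn.get(provenance, 0) + 1
    return merged, venn


@dataclass(frozen=True)
class CnvrSummary:
    """Per-group CNVR accounting: the columns of the study-style summary table."""

    n_samples: int
    n_cnvrs: int
    cnvrs_per_sample: float
    n_unique: int  # carried by exactly one sample
    n_gain: int
    n_loss: int
    n_both: int
    total_length_bp: int
    percent_genome: float

    def __post_init__(self) -> None:
        if self.n_gain + self.n_loss + self.n_both != self.n_cnvrs:
            raise ValueError("gain + loss + both must equal the CNVR count")


def summarize(
    cnvrs: Sequence[Cnvr],
    genome_length: int,
    n_samples: int,
) -> CnvrSummary:
    """Counts, per-sample average, state breakdown and genome fraction.

    CNVRs are pairwise disjoint by construction, so the total length is a
    plain sum.  ``percent_genome`` = 100 x total length / genome length.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    total = sum(r.length for r in cnvrs)
    states = [r.state for r in cnvrs]
    return CnvrSummary(
        n_samples=n_samples,
        n_cnvrs=len(cnvrs),
        cnvrs_per_sample=len(cnvrs) / n_samples,
        n_unique=sum(1 for r in cnvrs if len(r.carriers) == 1),
        n_gain=states.count(GAIN),
        n_loss=states.count(LOSS),
        n_both=states.count(BOTH),
        total_length_bp=total,
        percent_genome=100.0 * total / genome_length,
    )


def chrom_coverage(
    cnvrs: Sequence[Cnvr],
    genome: GenomeLayout,
) -> list[tuple[str, float]]:
    """Percent of each chromosome covered by CNVRs, ranked most to least covered."""
    covered: dict[str, int] = {name: 0 for name in genome.names}
    for r in cnvrs:
        if r.chrom not in covered:
            raise ValueError(f"CNVR {r.id} on unknown chromosome {r.chrom!r}")
        covered[r.chrom] += r.length
    pct = [(name, 100.0 * covered[name] / genome.length_of(name)) for name in genome.names]
    pct.sort(key=lambda t: (-t[1], t[0]))
    return pct
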