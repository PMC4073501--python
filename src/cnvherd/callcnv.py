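"""CNV calling from segmented log2-ratio profiles.

A segment qualifies as a CNV when its mean log2 ratio is at least 0.5 in
absolute value and it covers at least 5 consecutive probes; the threshold is
inclusive.  Adjacent qualifying segments of the same state are merged into a
single call (a least-squares segmentation may split one true event in two;
merging is conservative and does not change carrier frequencies).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

from .core import BOTH, GAIN, LOSS, NORMAL, CnvCall, ProbeMap, Segment, overlap_bp

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_PROBES = 5


def _state(mean: float, threshold: float) -> str | None:
    if mean >= threshold:
        return GAIN
    if mean <= -threshold:
        return LOSS
    return None


def call_cnvs(
    segments: Sequence[Segment],
    probes: ProbeMap,
    sample: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[CnvCall]:
    """Apply the CNV rule to one sample's segments and emit gain/loss calls.

    Base-pair bounds run from the start of the first member probe to the end
    of the last.  Input segment order does not affect the result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    qualifying = [
        s
        for s in sorted(segments, key=lambda s: (s.chrom, s.start_idx))
        if s.n_probes >= min_probes and _state(s.mean, threshold) is not None
    ]
    calls: list[CnvCall] = []
    run: list[Segment] = []

    def flush() -> None:
        if not run:
            return
        chrom = run[0].chrom
        i0, _ = probes.span(chrom)
        sub = probes.df
        start = int(sub.iloc[i0 + run[0].start_idx]["start"])
        end = int(sub.iloc[i0 + run[-1].end_idx - 1]["end"])
        n = sum(s.n_probes for s in run)
        mean = sum(s.mean * s.n_probes for s in run) / n
        calls.append(CnvCall(sample, chrom, start, end, _state(mean, threshold), mean, n))
        run.clear()

    for seg in qualifying:
        if run and (
            seg.chrom != run[-1].chrom
            or seg.start_idx != run[-1].end_idx
            or _state(seg.mean, threshold) != _state(run[-1].mean, threshold)
        ):
            flush()
        run.append(seg)
    flush()
    return calls


def genotype_sample_region(
    calls: Iterable[CnvCall],
    chrom: str,
    start: int,
    end: int,
    sample: str,
) -> str:
    """Type one sample over a region: gain, loss, normal, or both.

    "Normal" means no overlapping call, i.e. the same copy state as the
    two-copy reference.  If both a gain and a loss call overlap the region the
    type is "both" and a warning is raised.
    """
    states = {
        c.state
        for c in calls
        if c.sample == sample and c.chrom == chrom and overlap_bp(c.start, c.end, start, end) > 0
    }
    if states == {GAIN}:
        return GAIN
    if states == {LOSS}:
        return LOSS
    if not states:
        return NORMAL
    warnings.warn(
        f"sample {sample!r} has both gain and loss calls over {chrom}:{start}-{end}",
        stacklevel=2,
    )
    return BOTH
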