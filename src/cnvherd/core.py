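"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` — the BED
convention — both in memory and on disk.  Interval overlap everywhere in this
package means at least one shared base under that convention; bookended
intervals (one ends where the next starts) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GAIN = "gain"
LOSS = "loss"
BOTH = "both"
NORMAL = "normal"


@dataclass(frozen=True)
class Chromosome:
    """A named chromosome or contig with its length in base pairs."""

    name: str
    length: int
    is_mito: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length {self.length}")


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes, optionally including a mitochondrial contig."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if not c.is_mito]

    def length_of(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise KeyError(f"unknown chromosome {name!r}")

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, int]], mito: str | None = "M") -> "GenomeLayout":
        return GenomeLayout(tuple(Chromosome(n, l, is_mito=(n == mito)) for n, l in pairs))


def default_genome() -> GenomeLayout:
    """Desk-scale stand-in genome: 5 autosomes of 10 Mb plus a 16 kb "M" contig.

    Preserves multi-chromosome structure and a small mitochondrial contig while
    keeping probe counts in the low tens of thousands.
    """
    chroms = [Chromosome(str(i), 10_000_000) for i in range(1, 6)]
    chroms.append(Chromosome("M", 16_338, is_mito=True))
    return GenomeLayout(tuple(chroms))


class ProbeMap:
    """Ordered genomic probe intervals, sorted and non-overlapping per chromosome.

    Wraps a DataFrame with columns ``chrom, start, end, probe_id``.
    """

    COLUMNS = ("chrom", "start", "end", "probe_id")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            bad = df.index[df["end"] <= df["start"]][0]
            raise ValueError(f"probe {df.loc[bad, 'probe_id']!r} has end <= start")
        if df["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError(f"probes on {chrom} not sorted by start")
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping probes on {chrom}")
        self.df = df
        # contiguous row-index span per chromosome, in file order
        self._spans: dict[str, tuple[int, int]] = {}
        chrom_arr = df["chrom"].to_numpy()
        i = 0
        while i < len(chrom_arr):
            j = i
            while j < len(chrom_arr) and chrom_arr[j] == chrom_arr[i]:
                j += 1
            name = str(chrom_arr[i])
            if name in self._spans:
                raise ValueError(f"chromosome {name} appears in non-contiguous blocks")
            self._spans[name] = (i, j)
            i = j

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeMap) and self.df.equals(other.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._spans)

    def span(self, chrom: str) -> tuple[int, int]:
        """Global row-index range [i, j) of the probes on `chrom`."""
        return self._spans[chrom]

    def chrom_probes(self, chrom: str) -> pd.DataFrame:
        i, j = self._spans[chrom]
        return self.df.iloc[i:j]

    def midpoints(self, chrom: str) -> np.ndarray:
        sub = self.chrom_probes(chrom)
        return (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0

    def mean_spacing(self, chrom: str) -> float:
        starts = self.chrom_probes(chrom)["start"].to_numpy()
        if len(starts) < 2:
            return float("nan")
        return float(np.mean(np.diff(starts)))


@dataclass(frozen=True)
class TruthEvent:
    """A planted copy-number event used as ground truth in simulations."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_number: int
    scope: str  # shared-all | group | private

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("copy number must be in {0,1,3,4} (2 is background)")
        if self.scope not in ("shared-all", "group", "private"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def state(self) -> str:
        return LOSS if self.copy_number < 2 else GAIN


@dataclass
class RatioProfiles:
    """Per-probe log2(test/reference) values for a set of samples.

    ``values``: DataFrame with one row per probe (aligned to a ProbeMap, index
    = probe ids) and one column per sample.  ``groups`` maps sample to group
    label.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("ratio profiles contain non-finite values")
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group label: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Segment:
    """A constant-mean run of probes on one chromosome.

    Probe indices are local to the chromosome and half-open: ``[start_idx,
    end_idx)``.
    """

    chrom: str
    start_idx: int
    end_idx: int
    mean: float

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("segment must contain at least one probe")

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(frozen=True)
class CnvCall:
    """A per-sample gain/loss call passing the CNV rule (|mean| >= 0.5, >= 5 probes)."""

    sample: str
    chrom: str
    start: int
    end: int
    state: str
    mean_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.state not in (GAIN, LOSS):
            raise ValueError(f"call state must be gain or loss, got {self.state!r}")
        if self.state == GAIN and self.mean_log2 < 0:
            raise ValueError("gain call with negative mean")
        if self.state == LOSS and self.mean_log2 > 0:
            raise ValueError("loss call with positive mean")


@dataclass(frozen=True)
class Cnvr:
    """A copy number variable region: the union of overlapping calls across samples."""

    id: str
    chrom: str
    start: int
    end: int
    state: str  # gain | loss | both
    carriers: tuple[str, ...]
    frequency: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNVR end must exceed start")
        if self.state not in (GAIN, LOSS, BOTH):
            raise ValueError(f"CNVR state must be gain/loss/both, got {self.state!r}")
        if len(set(self.carriers)) != len(self.carriers):
            raise ValueError("duplicate carriers")
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureInterval:
    """A gene or QTL interval used for CNVR annotation."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str  # gene | QTL
    name: str = ""
    trait_class: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.id!r} has end <= start")
        if self.kind not in ("gene", "QTL"):
            raise ValueError(f"feature kind must be gene or QTL, got {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Shared bases between two half-open intervals (0 if disjoint or bookended)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
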