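"""Readers and writers for every on-disk format the pipeline uses.

All tables are plain text (TSV for genomic intervals and matrices, CSV for
qPCR wells and phenotypes) with a header row.  Writers prepend ``#`` comment
lines recording the tool version, the generating parameters and the seed;
readers skip them.  Genomic coordinates are 0-based half-open and validated
on read.  Malformed lines are rejected with the file, line number, and
offending field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    Cnvr,
    CnvCall,
    FeatureInterval,
    GenomeLayout,
    ProbeMap,
    RatioProfiles,
    Segment,
    TruthEvent,
)


def _header_lines(kind: str, params: Mapping[str, object] | None) -> list[str]:
    lines = [f"# cnvherd v{__version__} {kind}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        lines.append(f"# {kv}")
    return lines


def _write_table(
    path: Path | str,
    df: pd.DataFrame,
    kind: str,
    params: Mapping[str, object] | None = None,
    sep: str = "\t",
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(kind, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def _read_table(path: Path | str, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_intervals(df: pd.DataFrame, path: Path | str, name_col: str) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        i = bad[0]
        raise ValueError(
            f"{path}: line {i + 2}: record {df.loc[i, name_col]!r} has end <= start"
        )
    if (df["start"] < 0).any():
        i = df.index[df["start"] < 0][0]
        raise ValueError(f"{path}: line {i + 2}: negative start for {df.loc[i, name_col]!r}")


# -- genome ------------------------------------------------------------------

def write_genome(path: Path | str, genome: GenomeLayout, **params: object) -> None:
    df = pd.DataFrame(
        [(c.name, c.length, int(c.is_mito)) for c in genome.chromosomes],
        columns=["chrom", "length", "is_mito"],
    )
    _write_table(path, df, "genome", params)


def read_genome(path: Path | str) -> GenomeLayout:
    df = _read_table(path)
    _require_columns(df, ["chrom", "length", "is_mito"], path)
    from .core import Chromosome

    return GenomeLayout(
        tuple(
            Chromosome(str(r.chrom), int(r.length), bool(r.is_mito))
            for r in df.itertuples()
        )
    )


# -- probes ------------------------------------------------------------------

def write_probes(path: Path | str, probes: ProbeMap, **params: object) -> None:
    _write_table(path, probes.df, "probe map", params)


def read_probes(path: Path | str) -> ProbeMap:
    df = _read_table(path)
    _require_columns(df, list(ProbeMap.COLUMNS), path)
    _check_intervals(df, path, "probe_id")
    return ProbeMap(df)


# -- ratio profiles ----------------------------------------------------------

def write_ratios(path: Path | str, profiles: RatioProfiles, **params: object) -> None:
    df = profiles.values.reset_index().rename(columns={"index": "probe_id"})
    _write_table(path, df, "log2 ratio matrix", params)


def read_ratios(path: Path | str, groups: Mapping[str, str]) -> RatioProfiles:
    df = _read_table(path)
    if "probe_id" not in df.columns:
        raise ValueError(f"{path}: first column must be probe_id")
    values = df.set_index("probe_id")
    values.index.name = None
    counts = values.isna().any(axis=1)
    if counts.any():
        i = int(np.flatnonzero(counts.to_numpy())[0])
        raise ValueError(f"{path}: line {i + 2}: wrong column count or missing value")
    return RatioProfiles(values, dict(groups))


# -- sample groups -----------------------------------------------------------

def write_sample_groups(path: Path | str, groups: Mapping[str, str], **params: object) -> None:
    df = pd.DataFrame(sorted(groups.items()), columns=["sample", "group"])
    _write_table(path, df, "sample groups", params)


def read_sample_groups(path: Path | str) -> dict[str, str]:
    df = _read_table(path)
    _require_columns(df, ["sample", "group"], path)
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


# -- truth events ------------------------------------------------------------

def write_truth(path: Path | str, events: Sequence[TruthEvent], **params: object) -> None:
    df = pd.DataFrame(
        [(e.sample, e.chrom, e.start, e.end, e.copy_number, e.scope) for e in events],
        columns=["sample", "chrom", "start", "end", "copy_number", "scope"],
    )
    _write_table(path, df, "truth events", params)


def read_truth(path: Path | str) -> list[TruthEvent]:
    df = _read_table(path)
    _require_columns(df, ["sample", "chrom", "start", "end", "copy_number", "scope"], path)
    _check_intervals(df, path, "sample")
    return [
        TruthEvent(str(r.sample), str(r.chrom), int(r.start), int(r.end), int(r.copy_number), str(r.scope))
        for r in df.itertuples()
    ]


# -- segments ----------------------------------------------------------------

def write_segments(
    path: Path | str,
    segments: Mapping[str, Sequence[Segment]],
    probes: ProbeMap,
    **params: object,
) -> None:
    rows = []
    for sample, segs in segments.items():
        for s in segs:
            i0, _ = probes.span(s.chrom)
            sub = probes.df
            rows.append(
                (
                    sample,
                    s.chrom,
                    s.start_idx,
                    s.end_idx,
                    int(sub.iloc[i0 + s.start_idx]["start"]),
                    int(sub.iloc[i0 + s.end_idx - 1]["end"]),
                    s.n_probes,
                    s.mean,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start_probe", "end_probe", "start_bp", "end_bp", "n_probes", "mean_log2"],
    )
    _write_table(path, df, "segments", params)


def read_segments(path: Path | str) -> dict[str, list[Segment]]:
    df = _read_table(path)
    _require_columns(df, ["sample", "chrom", "start_probe", "end_probe", "mean_log2"], path)
    out: dict[str, list[Segment]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.sample), []).append(
            Segment(str(r.chrom), int(r.start_probe), int(r.end_probe), float(r.mean_log2))
        )
    return out


# -- CNV calls ---------------------------------------------------------------

def write_calls(path: Path | str, calls: Sequence[CnvCall], **params: object) -> None:
    df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.sample, c.state, c.mean_log2, c.n_probes) for c in calls],
        columns=["chrom", "start", "end", "sample", "state", "mean_log2", "n_probes"],
    )
    _write_table(path, df, "CNV calls", params)


def read_calls(path: Path | str) -> list[CnvCall]:
    df = _read_table(path)
    _require_columns(df, ["chrom", "start", "end", "sample", "state", "mean_log2", "n_probes"], path)
    _check_intervals(df, path, "sample")
    return [
        CnvCall(str(r.sample), str(r.chrom), int(r.start), int(r.end), str(r.state), float(r.mean_log2), int(r.n_probes))
        for r in df.itertuples()
    ]


# -- CNVRs -------------------------------------------------------------------

def write_cnvrs(path: Path | str, cnvrs: Sequence[Cnvr], **params: object) -> None:
    df = pd.DataFrame(
        [
            (
                r.chrom,
                r.start,
                r.end,
                r.id,
                r.state,
                len(r.carriers),
                r.frequency,
                ",".join(r.groups),
                ",".join(r.carriers),
            )
            for r in cnvrs
        ],
        columns=["chrom", "start", "end", "id", "state", "n_carriers", "frequency", "groups", "carriers"],
    )
    _write_table(path, df, "CNVRs", params)


def read_cnvrs(path: Path | str) -> list[Cnvr]:
    df = _read_table(path)
    _require_columns(df, ["chrom", "start", "end", "id", "state", "frequency", "groups", "carriers"], path)
    _check_intervals(df, path, "id")
    out = []
    for r in df.itertuples():
        groups = tuple(str(r.groups).split(",")) if pd.notna(r.groups) and str(r.groups) else ()
        carriers = tuple(str(r.carriers).split(",")) if pd.notna(r.carriers) and str(r.carriers) else ()
        out.append(
            Cnvr(str(r.id), str(r.chrom), int(r.start), int(r.end), str(r.state), carriers, float(r.frequency), groups)
        )
    return out


# -- features ----------------------------------------------------------------

def write_features(path: Path | str, features: Sequence[FeatureInterval], **params: object) -> None:
    df = pd.DataFrame(
        [(f.chrom, f.start, f.end, f.id, f.kind, f.trait_class) for f in features],
        columns=["chrom", "start", "end", "name", "kind", "class"],
    )
    _write_table(path, df, "feature intervals", params)


def read_features(path: Path | str) -> list[FeatureInterval]:
    df = _read_table(path)
    _require_columns(df, ["chrom", "start", "end", "name", "kind"], path)
    _check_intervals(df, path, "name")
    has_class = "class" in df.columns
    out = []
    for i in range(len(df)):
        row = df.iloc[i]
        trait = str(row["class"]) if has_class and pd.notna(row["class"]) else ""
        out.append(
            FeatureInterval(
                str(row["name"]), str(row["chrom"]), int(row["start"]), int(row["end"]),
                str(row["kind"]), str(row["name"]), trait,
            )
        )
    return out


# -- qPCR wells and phenotypes (CSV) -----------------------------------------

def write_wells(path: Path | str, wells: pd.DataFrame, **params: object) -> None:
    _write_table(path, wells, "qPCR wells", params, sep=",")


def read_wells(path: Path | str) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    _require_columns(df, ["sample", "assay", "role", "ct"], path)
    return df


def write_phenotypes(path: Path | str, pheno: pd.DataFrame, **params: object) -> None:
    _write_table(path, pheno, "phenotypes", params, sep=",")


def read_phenotypes(path: Path | str) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    _require_columns(df, ["sample", "farm", "breed", "genotype"], path)
    return df
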