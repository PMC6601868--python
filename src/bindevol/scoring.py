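"""Per-enhancer scores from signal tracks, normalization, and interspecies deltas.

The scoring convention throughout the pipeline: a raw score is the
length-weighted mean signal over the enhancer interval; scores are then
outlier-capped at mu + 3*sigma per column and min-max scaled to [0,1];
interspecies change is the melanogaster-minus-virilis difference of the
normalized scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "ScoreTable",
    "NormalizationParams",
    "mean_signal_over_interval",
    "normalize_scores",
    "delta_table",
    "accessible_pairs",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_score_tsv",
    "write_score_tsv",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval tagged with an enhancer id and species."""

    chrom: str
    start: int
    end: int
    id: str
    species: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} ({self.id})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Sorted, non-overlapping (start, end, value) segments per chromosome.

    Stands in for a normalized coverage track; bases not covered by any
    segment carry value 0.
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty segment on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite values on {chrom}")
            self._segs[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._segs)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._segs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._segs


@dataclass(frozen=True)
class NormalizationParams:
    """Column-wise capping and min-max parameters (cap = mu + 3*sigma)."""

    mu: float
    sigma: float
    cap: float
    post_cap_min: float
    post_cap_max: float


@dataclass
class ScoreTable:
    """Enhancers x conditions matrix of quantitative scores for one species."""

    ids: list[str]
    columns: list[str]
    values: np.ndarray
    species: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score table contains non-finite values")
        if (
            self.normalized
            and self.values.size
            and (self.values.min() < 0 or self.values.max() > 1)
        ):
            raise ValueError("normalized table has values outside [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.columns)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no column {name!r}; have {self.columns}") from None
        return self.values[:, j]

    def subset(self, ids: list[str]) -> "ScoreTable":
        idx = {e: i for i, e in enumerate(self.ids)}
        rows = [idx[i] for i in ids]
        return ScoreTable(
            ids=list(ids),
            columns=list(self.columns),
            values=self.values[rows],
            species=self.species,
            normalized=self.normalized,
        )


def mean_signal_over_interval(track: SignalTrack, iv: GenomicInterval) -> float:
    """Length-weighted mean of the track over [start, end); uncovered bases are 0."""
    if iv.end <= iv.start:
        raise ValueError("empty interval")
    if iv.chrom not in track:
        return 0.0
    starts, ends, values = track.segments(iv.chrom)
    # segments overlapping the window
    lo = int(np.searchsorted(ends, iv.start, side="right"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if lo >= hi:
        return 0.0
    ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
    total = float((ov * values[lo:hi]).sum())
    return total / len(iv)


def normalize_scores(
    raw: ScoreTable,
) -> tuple[ScoreTable, dict[str, NormalizationParams]]:
    """Cap each column at mu + 3*sigma, then min-max scale to [0,1].

    mu and sigma (population convention, divisor n) are computed per column
    over all rows; the same rule applies to ChIP, accessibility and motif
    occupancy columns alike. A constant column maps to all zeros (warned).
    """
    if raw.normalized:
        raise ValueError("table already normalized")
    out = np.empty_like(raw.values)
    params: dict[str, NormalizationParams] = {}
    for j, col in enumerate(raw.columns):
        v = raw.values[:, j]
        mu = float(v.mean())
        sigma = float(v.std())  # population std
        cap = mu + 3.0 * sigma
        capped = np.minimum(v, cap)
        lo, hi = float(capped.min()), float(capped.max())
        if hi > lo:
            out[:, j] = (capped - lo) / (hi - lo)
        else:
            logger.warning("constant column %r: normalized to all zeros", col)
            out[:, j] = 0.0
        params[col] = NormalizationParams(
            mu=mu, sigma=sigma, cap=cap, post_cap_min=lo, post_cap_max=hi
        )
    table = ScoreTable(
        ids=list(raw.ids),
        columns=list(raw.columns),
        values=out,
        species=raw.species,
        normalized=True,
    )
    return table, params


def delta_table(mel: ScoreTable, vir: ScoreTable) -> ScoreTable:
    """Species-1 minus species-2 table of normalized scores (range [-1, 1])."""
    if not (mel.normalized and vir.normalized):
        raise ValueError("delta_table requires normalized tables")
    if mel.ids != vir.ids:
        only_mel = set(mel.ids) - set(vir.ids)
        only_vir = set(vir.ids) - set(mel.ids)
        raise ValueError(
            f"id mismatch: only in first={sorted(only_mel)[:5]}, "
            f"only in second={sorted(only_vir)[:5]}"
        )
    if mel.columns != vir.columns:
        raise ValueError(
            f"column mismatch: {sorted(set(mel.columns) ^ set(vir.columns))}"
        )
    return ScoreTable(
        ids=list(mel.ids),
        columns=list(mel.columns),
        values=mel.values - vir.values,
        species=f"{mel.species}-{vir.species}",
        normalized=False,
    )


def accessible_pairs(
    acc_mel: ScoreTable,
    acc_vir: ScoreTable,
    tp: str,
    threshold: float = 0.3,
) -> list[str]:
    """Ids accessible in at least one species at the time point.

    Inclusion requires max(mel, vir) strictly greater than the threshold
    (default 0.3 on the normalized scale).
    """
    if not (acc_mel.normalized and acc_vir.normalized):
        raise ValueError("accessible_pairs requires normalized tables")
    if acc_mel.ids != acc_vir.ids:
        raise ValueError("id mismatch between species accessibility tables")
    try:
        m = acc_mel.column(tp)
        v = acc_vir.column(tp)
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    keep = np.maximum(m, v) > threshold
    return [i for i, k in zip(acc_mel.ids, keep) if k]


# ---------------------------------------------------------------------------
# plain-text I/O (BED, bedGraph, TSV score matrices)
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    return [
        GenomicInterval(chrom=r.chrom, start=int(r.start), end=int(r.end), id=str(r.name))
        for r in df.itertuples()
    ]


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t+\n")


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        skiprows=_bedgraph_skip(path),
    )
    segs = {
        str(chrom): (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["value"].to_numpy(),
        )
        for chrom, g in df.groupby("chrom", sort=False)
    }
    return SignalTrack(segs)


def _bedgraph_skip(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("track") else 0


def write_bedgraph(track: SignalTrack, path, name: str = "signal") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom in track.chroms:
            starts, ends, values = track.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_score_tsv(path, species: str = "", normalized: bool = False) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ScoreTable(
        ids=[str(i) for i in df.index],
        columns=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        species=species,
        normalized=normalized,
    )


def write_score_tsv(table: ScoreTable, path) -> None:
    df = table.to_frame()
    df.index.name = "enhancer"
    # 17 significant digits so the TSV round-trips bit-exactly
    df.to_csv(path, sep="\t", float_format="%.17g")
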