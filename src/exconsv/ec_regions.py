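"""Exclusive-conservation scoring and region calling.

The exclusive-conservation (EC) statistic of the focal family at reference
position i is

    EC[i] = grade_focal[i] - max over paralog families of grade_other[i]

on the 1-9 grade scale, so EC ranges over [-8, 8] and a high value marks a
position conserved in the focal family but not in either paralog family.
Positions where any involved grade is MASKED or UNDEFINED get EC = 0: they
cannot seed or extend a region but can be bridged across.

Regions are called on a centered moving average (window k = 9) of the EC
track: positions with smoothed EC >= 2 are seeds; every maximal run of
consecutive positive smoothed values is a candidate; runs separated by
fewer than 9 non-positive positions are merged (transitively, spanning the
gap); merged candidates that contain no seed are dropped.  Surviving
regions are labeled EC1, EC2, ... by ascending start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationProfile


@dataclass(frozen=True)
class ECConfig:
    """Region-calling parameters.

    k: moving-average window (odd); seed_threshold: smoothed-EC value a
    region must reach somewhere; merge_gap: bridging bound -- two positive
    runs merge when strictly fewer than this many non-positive positions
    separate them; edge_policy: 'shrink' truncates the window at the track
    boundary, 'drop' zeroes positions where the full window does not fit;
    bridge: disable Step-3 merging when False.
    """

    k: int = 9
    seed_threshold: float = 2.0
    merge_gap: int = 9
    edge_policy: str = "shrink"
    bridge: bool = True

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if self.merge_gap < 1:
            raise ValueError("merge_gap must be >= 1")
        if self.edge_policy not in ("shrink", "drop"):
            raise ValueError("edge_policy must be 'shrink' or 'drop'")
        if not np.isfinite(self.seed_threshold):
            raise ValueError("seed_threshold must be finite")


@dataclass
class ECProfile:
    """EC track (and optionally its smoothed version) for a focal group."""

    ec: np.ndarray
    focal_group: str
    other_groups: tuple[str, ...]
    ma: Optional[np.ndarray] = None
    k: int = 9


@dataclass(frozen=True)
class ECRegion:
    """One called region; reference coordinates, 1-based inclusive."""

    label: str
    start: int
    end: int
    n_seeds: int
    peak_ma: float
    mean_ma: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_seeds < 1:
            raise ValueError("region must contain at least one seed")

    def __len__(self) -> int:
        return self.end - self.start + 1


def ec_score(
    focal: ConservationProfile, others: Sequence[ConservationProfile]
) -> ECProfile:
    """EC track: focal grade minus the best paralog grade per position."""
    if not others:
        raise ValueError("at least one paralog profile is required")
    L = focal.ref_length
    for other in others:
        if other.ref_length != L:
            raise ValueError(
                f"profile length mismatch: {other.group} has {other.ref_length}, "
                f"expected {L}"
            )
    other_grades = np.stack([o.grades for o in others])
    defined = focal.is_defined()
    for o in others:
        defined &= o.is_defined()
    ec = np.where(defined, focal.grades - other_grades.max(axis=0), 0)
    return ECProfile(
        ec=ec.astype(float),
        focal_group=focal.group,
        other_groups=tuple(o.group for o in others),
    )


def moving_average(
    values: Sequence[float] | np.ndarray, k: int, edge_policy: str = "shrink"
) -> np.ndarray:
    """Centered moving average with window k (odd).

    'shrink' averages whatever part of the window fits at the edges;
    'drop' sets edge positions (where the full window does not fit) to 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    if edge_policy not in ("shrink", "drop"):
        raise ValueError("edge_policy must be 'shrink' or 'drop'")
    n = len(v)
    half = k // 2
    csum = np.concatenate(([0.0], np.cumsum(v)))
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    ma = (csum[hi] - csum[lo]) / (hi - lo)
    if edge_policy == "drop":
        full = (np.arange(n) - half >= 0) & (np.arange(n) + half <= n - 1)
        ma = np.where(full, ma, 0.0)
    return ma


def _positive_runs(ma: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of strictly positive values, 0-based inclusive spans."""
    pos = ma > 0
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(pos):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(pos) - 1))
    return runs


def call_regions(
    ma: Sequence[float] | np.ndarray, cfg: ECConfig = ECConfig()
) -> list[ECRegion]:
    """Seed / grow / bridge / filter region calling on a smoothed EC track."""
    ma = np.asarray(ma, dtype=float)
    if ma.ndim != 1 or len(ma) == 0:
        raise ValueError("ma must be a non-empty 1-D vector")
    seeds = np.flatnonzero(ma >= cfg.seed_threshold)
    runs = _positive_runs(ma)
    if not runs:
        return []
    # Bridge: merge runs whose separating gap is < merge_gap (transitive).
    clusters: list[tuple[int, int]] = [runs[0]]
    for start, end in runs[1:]:
        prev_start, prev_end = clusters[-1]
        if cfg.bridge and (start - prev_end - 1) < cfg.merge_gap:
            clusters[-1] = (prev_start, end)
        else:
            clusters.append((start, end))
    regions: list[ECRegion] = []
    for start, end in clusters:
        n_seeds = int(np.sum((seeds >= start) & (seeds <= end)))
        if n_seeds == 0:
            continue
        span = ma[start : end + 1]
        regions.append(
            ECRegion(
                label="",
                start=start + 1,
                end=end + 1,
                n_seeds=n_seeds,
                peak_ma=float(span.max()),
                mean_ma=float(span.mean()),
            )
        )
    return [
        ECRegion(
            label=f"EC{i}",
            start=r.start,
            end=r.end,
            n_seeds=r.n_seeds,
            peak_ma=r.peak_ma,
            mean_ma=r.mean_ma,
        )
        for i, r in enumerate(sorted(regions, key=lambda r: r.start), start=1)
    ]


def compute_ec_profile(
    focal: ConservationProfile,
    others: Sequence[ConservationProfile],
    cfg: ECConfig = ECConfig(),
) -> ECProfile:
    """EC track plus its smoothed version under the given configuration."""
    profile = ec_score(focal, others)
    profile.ma = moving_average(profile.ec, cfg.k, cfg.edge_policy)
    profile.k = cfg.k
    return profile


def ec_pipeline_positions_report(
    focal: ConservationProfile,
    others: Sequence[ConservationProfile],
    cfg: ECConfig = ECConfig(),
    ref_seq: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ECRegion]]:
    """Joined per-position table, regions table, and the region list.

    The per-position table holds (ref_pos, ref_aa, one grade column per
    group, ec, ma, in_region_label); the regions table materializes the
    :class:`ECRegion` fields.
    """
    profile = compute_ec_profile(focal, others, cfg)
    regions = call_regions(profile.ma, cfg)
    L = focal.ref_length
    if ref_seq is not None and len(ref_seq) != L:
        raise ValueError("ref_seq length does not match profile length")
    in_region = np.array([""] * L, dtype=object)
    for region in regions:
        in_region[region.start - 1 : region.end] = region.label
    data = {
        "ref_pos": np.arange(1, L + 1),
        "ref_aa": list(ref_seq) if ref_seq is not None else [""] * L,
        f"grade_{focal.group}": focal.grades,
    }
    for other in others:
        data[f"grade_{other.group}"] = other.grades
    data["ec"] = profile.ec
    data["ma"] = profile.ma
    data["in_region_label"] = in_region
    positions = pd.DataFrame(data)
    regions_df = pd.DataFrame(
        [
            {
                "label": r.label,
                "start": r.start,
                "end": r.end,
                "n_seeds": r.n_seeds,
                "peak_ma": r.peak_ma,
                "mean_ma": r.mean_ma,
            }
            for r in regions
        ],
        columns=["label", "start", "end", "n_seeds", "peak_ma", "mean_ma"],
    )
    return positions, regions_df, regions
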