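"""Invariant-probeset (MNR) quantile normalization with interpolation.

Arrays are normalized against each other using only the probesets that
digestion cannot affect (MNRs): each array's sorted MNR intensities are
replaced by the across-array mean of sorted values, and the resulting
raw -> normalized pairing defines a monotone piecewise-linear map that is
then applied to the variant (MPR) probesets of the same array. Values
outside the knot range are extrapolated linearly from the boundary
segments.

The A and B channels of an array share one map, built from the combined
MNR channel intensities; this preserves within-probeset A/B ratios up to
the map's local slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["NormalizationMap", "quantile_normalize_invariant", "normalize_probes"]


@dataclass
class NormalizationMap:
    """Monotone raw -> normalized mapping as paired sorted knots."""

    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.raw.size == 0:
            raise DataError("empty normalization map")
        if self.raw.size != self.normalized.size:
            raise DataError("normalization map knot arrays differ in length")
        if np.any(np.diff(self.raw) <= 0):
            raise DataError("map knots must be strictly sorted in raw coordinate")
        if np.any(np.diff(self.normalized) < 0):
            raise DataError("normalization map must be non-decreasing")

    def interpolate(self, values) -> np.ndarray:
        """Piecewise-linear interpolation with boundary-slope extrapolation."""
        x = np.asarray(values, dtype=float)
        r, n = self.raw, self.normalized
        if r.size == 1:
            return np.full_like(x, n[0])
        out = np.interp(x, r, n)
        lo = x < r[0]
        if lo.any():
            slope = (n[1] - n[0]) / (r[1] - r[0])
            out[lo] = n[0] + slope * (x[lo] - r[0])
        hi = x > r[-1]
        if hi.any():
            slope = (n[-1] - n[-2]) / (r[-1] - r[-2])
            out[hi] = n[-1] + slope * (x[hi] - r[-1])
        return out


def _collapse_ties(raw_sorted: np.ndarray, norm_sorted: np.ndarray) -> NormalizationMap:
    """Average normalized values over tied raw values to keep knots strict."""
    uniq, inverse = np.unique(raw_sorted, return_inverse=True)
    if uniq.size == raw_sorted.size:
        return NormalizationMap(raw_sorted, norm_sorted)
    sums = np.zeros(uniq.size)
    counts = np.zeros(uniq.size)
    np.add.at(sums, inverse, norm_sorted)
    np.add.at(counts, inverse, 1)
    return NormalizationMap(uniq, sums / counts)


def quantile_normalize_invariant(matrix: pd.DataFrame):
    """Quantile-normalize invariant probesets between arrays.

    `matrix` is probes x arrays. Each array's sorted values are replaced
    by the across-array mean of sorted values (ties within an array get
    the average of their ranks' targets). Returns the normalized matrix
    and a per-array NormalizationMap.
    """
    if matrix.shape[1] < 2:
        raise DataError("quantile normalization needs at least 2 arrays")
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataError("negative intensities in invariant matrix")
    if np.any(np.nanstd(values, axis=0) == 0):
        raise DataError("all-constant array: degenerate quantiles")

    order = np.argsort(values, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)

    normalized = np.empty_like(values)
    maps = {}
    for j, col in enumerate(matrix.columns):
        raw_sorted = sorted_vals[:, j]
        # average targets over tied raw values so equal inputs map equally
        m = _collapse_ties(raw_sorted, target)
        normalized[:, j] = m.interpolate(values[:, j])
        maps[col] = m
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns), maps


def normalize_probes(probes: pd.DataFrame, mnr_ids) -> tuple[pd.DataFrame, dict]:
    """Normalize a long-format probe table through per-array MNR maps.

    An array is one (sample_id, replicate) pair. The map for each array is
    built from the combined A and B channel intensities of its MNR
    probesets and applied to every probeset's channels on that array.
    Adds `normalized_A` / `normalized_B` columns.
    """
    mnr_ids = set(mnr_ids)
    if not mnr_ids:
        raise DataError("no MNR probesets supplied for normalization")
    is_mnr = probes["probeset_id"].isin(mnr_ids)
    if not is_mnr.any():
        raise DataError("probe table contains none of the supplied MNR probesets")

    mnr = probes.loc[is_mnr].sort_values(["probeset_id", "sample_id", "replicate"],
                                         kind="mergesort")
    arrays = {}
    for (sample, rep), grp in mnr.groupby(["sample_id", "replicate"], sort=True):
        stacked = np.concatenate([grp["intensity_A"].to_numpy(),
                                  grp["intensity_B"].to_numpy()])
        arrays[(sample, rep)] = stacked
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise DataError("arrays have unequal MNR probe counts")

    matrix = pd.DataFrame(arrays)
    _, maps = quantile_normalize_invariant(matrix)

    out = probes.copy()
    norm_a = np.empty(len(out))
    norm_b = np.empty(len(out))
    grouped = out.groupby(["sample_id", "replicate"], sort=False)
    for key, idx in grouped.indices.items():
        m = maps[key]
        norm_a[idx] = m.interpolate(out["intensity_A"].to_numpy()[idx])
        norm_b[idx] = m.interpolate(out["intensity_B"].to_numpy()[idx])
    out["normalized_A"] = norm_a
    out["normalized_B"] = norm_b
    return out, maps
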