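"""Neighborhood gray-tone difference matrix (NGTDM) on 2-D patches.

The NGTDM of a gray-level image accumulates, per gray tone ``i``, the
absolute difference between each pixel of tone ``i`` and the mean tone of
its neighborhood (center excluded), together with the occurrence
probability ``p(i)`` of each tone among the pixels that enter the matrix.
From the matrix three classical texture descriptors are derived:

* **coarseness** — ``1 / (eps + sum_i p(i) s(i))``: large for images built
  of big uniform granules, capped at ``1/eps`` for a constant region.
* **contrast** — ``[1/(Ng(Ng-1)) sum_ij p(i)p(j)(i-j)^2] * [1/n sum_i s(i)]``:
  the product of gray-tone dispersion and mean neighborhood difference.
* **busyness** — ``[sum_i p(i)s(i)] / [sum_ij |i p(i) - j p(j)|]`` over
  tones with ``p != 0``: high when intensity alternates at high spatial
  frequency.

Here patches are small 2-D windows cut from a quantized PET volume, so
cells may fall outside the image; a validity grid marks real cells.  Two
pixel-eligibility policies are supported:

``strict-interior``
    a pixel enters the matrix only if its full ``(2d+1)^2`` neighborhood
    is inside the patch and valid (the classical definition);
``all-valid-neighbors``
    a pixel enters if it is valid and has at least one valid neighbor;
    the neighborhood mean is taken over the valid neighbors that exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_EPSILON",
    "POLICIES",
    "QuantizedPatch",
    "NgtdmTable",
    "TextureTriplet",
    "EmptyNgtdmError",
    "build_ngtdm",
    "coarseness",
    "contrast",
    "busyness",
    "texture_triplet",
]

#: Regularizer added to sum(p*s) in the coarseness denominator.  Must be
#: far below one bin-difference unit; 1/DEFAULT_EPSILON is the coarseness
#: of a perfectly uniform region.
DEFAULT_EPSILON = 1e-8

POLICIES = ("strict-interior", "all-valid-neighbors")


class EmptyNgtdmError(ValueError):
    """No pixel is eligible under the chosen neighborhood policy."""


@dataclass(frozen=True)
class QuantizedPatch:
    """A 2-D patch of gray-tone bin indices with a validity grid.

    ``values`` holds integer bin indices (>= 1 wherever ``valid``);
    ``valid`` is False for cells that carry no data (e.g. padding beyond
    the image boundary).
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        valid = np.asarray(self.valid, dtype=bool)
        if values.ndim != 2 or valid.shape != values.shape:
            raise ValueError("values must be 2-D and match valid's shape")
        if not valid.any():
            raise ValueError("patch has no valid cell")
        if not np.issubdtype(values.dtype, np.integer):
            raise TypeError("bin indices must be integers")
        if (values[valid] < 1).any():
            raise ValueError("valid bin indices must be >= 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)


@dataclass(frozen=True)
class NgtdmTable:
    """NGTDM components for one patch.

    ``s`` and ``p`` are dense arrays indexed by bin (index 0 unused) and
    cover bins ``1..len(s)-1``; ``p`` sums to one over the pixels counted
    in ``n_considered``.
    """

    s: np.ndarray
    p: np.ndarray
    n_considered: int

    @property
    def levels_present(self) -> np.ndarray:
        """Bin indices with p(i) > 0, ascending."""
        return np.flatnonzero(self.p > 0)

    @property
    def n_gray_levels(self) -> int:
        """Ng: number of gray tones present among considered pixels."""
        return int((self.p > 0).sum())


@dataclass(frozen=True)
class TextureTriplet:
    """Coarseness, contrast and busyness of one patch/voxel/lesion."""

    coarseness: float
    contrast: float
    busyness: float

    def as_array(self) -> np.ndarray:
        return np.array([self.coarseness, self.contrast, self.busyness])


def build_ngtdm(
    patch: QuantizedPatch,
    distance: int = 1,
    policy: str = "strict-interior",
) -> NgtdmTable:
    """Construct the NGTDM of a quantized 2-D patch.

    For each eligible pixel with bin value ``i``, ``|i - A|`` is added to
    ``s(i)`` where ``A`` is the mean bin value of its valid neighbors
    (center excluded) within Chebyshev distance ``distance``; ``p(i)`` is
    the fraction of eligible pixels carrying value ``i``.

    Raises
    ------
    EmptyNgtdmError
        If no pixel is eligible (the caller treats the patch as
        feature-undefined).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if distance < 1:
        raise ValueError("distance must be a positive integer")

    values = patch.values
    valid = patch.valid
    h, w = values.shape
    d = distance
    k = 2 * d + 1

    vals_f = np.where(valid, values, 0).astype(np.float64)
    cnt_f = valid.astype(np.float64)
    pad_v = np.zeros((h + 2 * d, w + 2 * d))
    pad_c = np.zeros_like(pad_v)
    pad_v[d : d + h, d : d + w] = vals_f
    pad_c[d : d + h, d : d + w] = cnt_f

    win_sum = np.zeros((h, w))
    win_cnt = np.zeros((h, w))
    for di in range(k):
        for dj in range(k):
            win_sum += pad_v[di : di + h, dj : dj + w]
            win_cnt += pad_c[di : di + h, dj : dj + w]
    neigh_sum = win_sum - vals_f
    neigh_cnt = win_cnt - cnt_f

    if policy == "strict-interior":
        eligible = valid & (win_cnt == k * k)
    else:
        eligible = valid & (neigh_cnt >= 1)
    if not eligible.any():
        raise EmptyNgtdmError("no pixel eligible under policy " + policy)

    bins = values[eligible]
    mean_neigh = neigh_sum[eligible] / neigh_cnt[eligible]
    diffs = np.abs(bins - mean_neigh)

    n_levels = int(values[valid].max())
    s = np.bincount(bins, weights=diffs, minlength=n_levels + 1)
    counts = np.bincount(bins, minlength=n_levels + 1)
    p = counts / bins.size
    return NgtdmTable(s=s, p=p, n_considered=int(bins.size))


def coarseness(table: NgtdmTable, epsilon: float = DEFAULT_EPSILON) -> float:
    """``1 / (epsilon + sum_i p(i) s(i))``; equals 1/epsilon for a
    constant region (the defined maximum)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return float(1.0 / (epsilon + np.dot(table.p, table.s)))


def contrast(table: NgtdmTable) -> float:
    """Gray-tone dispersion times mean neighborhood difference.

    Returns 0 by convention when a single gray tone is present (Ng = 1),
    so a constant region never yields NaN in lesion averages.
    """
    levels = table.levels_present
    ng = levels.size
    if ng <= 1:
        return 0.0
    p = table.p[levels]
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    dispersion = float((np.outer(p, p) * (ii - jj) ** 2).sum()) / (ng * (ng - 1))
    mean_diff = float(table.s.sum()) / table.n_considered
    return dispersion * mean_diff


def busyness(table: NgtdmTable) -> float:
    """``sum_i p(i)s(i)`` over ``sum_ij |i p(i) - j p(j)|`` (tones with
    p != 0); 0 by convention when the denominator vanishes."""
    levels = table.levels_present
    ip = levels * table.p[levels]
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
    if denom == 0.0:
        return 0.0
    return float(np.dot(table.p, table.s)) / denom


def texture_triplet(
    table: NgtdmTable, epsilon: float = DEFAULT_EPSILON
) -> TextureTriplet:
    """All three NGTDM features of one table."""
    return TextureTriplet(
        coarseness=coarseness(table, epsilon),
        contrast=contrast(table),
        busyness=busyness(table),
    )
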