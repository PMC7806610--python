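"""Segmentation of membrane-localised signal: six methods, one contract.

The pipeline quantifies a sarcolemmal analyte whose histogram is dominated
by background/interior pixels; the whole-image mean therefore badly
underestimates the membrane concentration.  Each method here produces a
boolean mask of "positive" pixels:

* global thresholds — median (keep pixels >= the image median) and Otsu
  (maximise between-class variance on a 256-bin histogram);
* local adaptive thresholds — Sauvola and Phansalkar, both built on a
  local window mean m and SD s;
* optimal 1-D clustering — k-means and k-medians by dynamic programming
  over contiguous partitions of the sorted values (the Ckmeans.1d.dp
  formulation), which is globally optimal and involves no random
  initialisation, so every mask is bit-reproducible.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu as _skimage_otsu

from .core import ElementalImage
from .errors import ConfigError, DegenerateInputError

# --------------------------------------------------------------------------
# result containers


@dataclass
class ThresholdParams:
    """Window size and sensitivity parameters for the local methods.

    Defaults follow the methods' original publications: Sauvola k=0.5 with
    R = half the image dynamic range; Phansalkar k=0.25, p=2, q=10, R=0.5
    on [0,1]-normalised data.  The 15 px window is roughly one
    membrane-to-membrane spacing at the super-resolved pixel pitch.
    """

    window_px: int = 15
    k_sauvola: float = 0.5
    r_sauvola: float | None = None  # None -> half the image dynamic range
    k_phan: float = 0.25
    p_phan: float = 2.0
    q_phan: float = 10.0
    r_phan: float = 0.5

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ConfigError(f"window_px must be odd and >= 3, got {self.window_px}")
        if self.r_sauvola is not None and self.r_sauvola <= 0:
            raise ConfigError("r_sauvola must be > 0")
        if self.r_phan <= 0:
            raise ConfigError("r_phan must be > 0")


@dataclass
class ClusterModel:
    """Optimal 1-D clustering: ordered centers and the cuts between them.

    Cluster indices are 1-based; ``boundaries`` holds the k-1 midpoints
    between adjacent cluster edges, so assignment is a pure value lookup.
    """

    k: int
    boundaries: np.ndarray
    centers: np.ndarray
    wcss: float
    criterion: str  # "means" | "medians"

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map values to 1-based cluster indices via the stored boundaries."""
        return np.digitize(np.asarray(values), self.boundaries, right=True) + 1


@dataclass
class SegmentationResult:
    """Boolean mask plus the method descriptor that produced it."""

    mask: np.ndarray
    method: str
    thresholds_or_model: object
    positive_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.positive_fraction = float(self.mask.mean()) if self.mask.size else 0.0


# --------------------------------------------------------------------------
# global thresholds


def threshold_median(img: ElementalImage) -> SegmentationResult:
    """Keep every pixel at or above the image median."""
    v = img.values
    if v.size == 0:
        raise DegenerateInputError("empty image")
    t = float(np.median(v))
    return SegmentationResult(mask=v >= t, method="median", thresholds_or_model=t)


def threshold_otsu(img: ElementalImage, nbins: int = 256) -> SegmentationResult:
    """Otsu's threshold: maximise between-class variance on a binned histogram."""
    v = img.values
    if np.ptp(v) == 0:
        raise DegenerateInputError("Otsu needs >= 2 distinct values")
    t = float(_skimage_otsu(v, nbins=nbins))
    return SegmentationResult(mask=v > t, method="otsu", thresholds_or_model=t)


def exact_otsu_threshold(values: np.ndarray) -> float:
    """Otsu's cut on the exact (unbinned) values.

    Maximises w0*w1*(mu0-mu1)^2 over all cuts between consecutive sorted
    values; equivalent to optimal 2-means on the same data.  Returns the
    largest value of the lower class (mask rule: value > threshold).
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise DegenerateInputError("need >= 2 distinct values")
    csum = np.cumsum(x)
    total = csum[-1]
    i = np.arange(1, n)  # lower class = x[:i]
    mu0 = csum[:-1] / i
    mu1 = (total - csum[:-1]) / (n - i)
    crit = i * (n - i) * (mu0 - mu1) ** 2
    valid = x[1:] > x[:-1]  # a cut must fall between distinct values
    crit = np.where(valid, crit, -np.inf)
    return float(x[int(np.argmax(crit)) ])


# --------------------------------------------------------------------------
# local adaptive thresholds


def _local_mean_sd(values: np.ndarray, window_px: int) -> tuple:
    if window_px >= min(values.shape):
        raise ConfigError(
            f"window {window_px} px does not fit the {values.shape} image"
        )
    m = ndimage.uniform_filter(values, size=window_px, mode="reflect")
    m2 = ndimage.uniform_filter(values * values, size=window_px, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m, s


def sauvola_formula(m, s, k: float, r: float):
    """Sauvola threshold T = m * (1 + k*(s/R - 1)) for local mean m and SD s."""
    return m * (1.0 + k * (s / r - 1.0))


def phansalkar_formula(m, s, k: float, p: float, q: float, r: float):
    """Phansalkar threshold T = m * (1 + p*exp(-q*m) + k*(s/R - 1)).

    The exponential term lowers the threshold in dim regions so that
    low-contrast positives survive; with p = 0 it degenerates to Sauvola.
    """
    return m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))


def sauvola_threshold_map(
    values: np.ndarray, k: float, r: float, window_px: int
) -> np.ndarray:
    """Per-pixel Sauvola threshold from windowed local statistics."""
    m, s = _local_mean_sd(values, window_px)
    return sauvola_formula(m, s, k, r)


def threshold_sauvola(img: ElementalImage, params: ThresholdParams | None = None
                      ) -> SegmentationResult:
    params = params or ThresholdParams()
    v = img.values
    r = params.r_sauvola if params.r_sauvola is not None else max(np.ptp(v) / 2.0, 1e-12)
    t = sauvola_threshold_map(v, params.k_sauvola, r, params.window_px)
    return SegmentationResult(
        mask=v > t,
        method=f"sauvola(window={params.window_px}, k={params.k_sauvola}, R={r:.6g})",
        thresholds_or_model=t,
    )


def phansalkar_threshold_map(
    values01: np.ndarray, k: float, p: float, q: float, r: float, window_px: int
) -> np.ndarray:
    """Per-pixel Phansalkar threshold; expects data normalised to [0, 1]."""
    m, s = _local_mean_sd(values01, window_px)
    return phansalkar_formula(m, s, k, p, q, r)


def threshold_phansalkar(img: ElementalImage, params: ThresholdParams | None = None
                         ) -> SegmentationResult:
    """Phansalkar's low-contrast adaptation of Sauvola, on [0,1]-normalised data."""
    params = params or ThresholdParams()
    v = img.values
    lo, span = float(v.min()), float(np.ptp(v))
    if span == 0:
        raise DegenerateInputError("Phansalkar needs a non-constant image")
    v01 = (v - lo) / span
    t01 = phansalkar_threshold_map(
        v01, params.k_phan, params.p_phan, params.q_phan, params.r_phan, params.window_px
    )
    return SegmentationResult(
        mask=v01 > t01,
        method=(
            f"phansalkar(window={params.window_px}, k={params.k_phan}, "
            f"p={params.p_phan}, q={params.q_phan}, R={params.r_phan})"
        ),
        thresholds_or_model=t01 * span + lo,  # thresholds back in original units
    )


# --------------------------------------------------------------------------
# optimal 1-D clustering (dynamic programming over contiguous partitions)


def _collapse(values) -> tuple:
    """Sorted unique values with multiplicity weights."""
    x, w = np.unique(np.asarray(values, dtype=np.float64).ravel(), return_counts=True)
    return x, w.astype(np.float64)


class _CostSSE:
    """O(1) weighted sum of squared deviations from the mean of x[i..j]."""

    def __init__(self, x: np.ndarray, w: np.ndarray):
        self.W = np.concatenate([[0.0], np.cumsum(w)])
        self.S = np.concatenate([[0.0], np.cumsum(w * x)])
        self.S2 = np.concatenate([[0.0], np.cumsum(w * x * x)])
        self._Wl = self.W.tolist()
        self._Sl = self.S.tolist()
        self._S2l = self.S2.tolist()

    def cost(self, i: int, j: int) -> float:
        w = self._Wl[j + 1] - self._Wl[i]
        s = self._Sl[j + 1] - self._Sl[i]
        return max(self._S2l[j + 1] - self._S2l[i] - s * s / w, 0.0)

    def first_costs(self) -> np.ndarray:
        """cost(0, j) for all j, vectorised."""
        w = self.W[1:]
        s = self.S[1:]
        return np.clip(self.S2[1:] - s * s / w, 0.0, None)


class _CostSAE:
    """O(log n) weighted sum of absolute deviations from the median of x[i..j]."""

    def __init__(self, x: np.ndarray, w: np.ndarray):
        self.x = x
        self.W = np.concatenate([[0.0], np.cumsum(w)])
        self.S = np.concatenate([[0.0], np.cumsum(w * x)])
        self._xl = x.tolist()
        self._Wl = self.W.tolist()
        self._Sl = self.S.tolist()

    def _median_index(self, i: int, j: int) -> int:
        half = 0.5 * (self._Wl[j + 1] + self._Wl[i])
        m = bisect_left(self._Wl, half, i + 1, j + 1) - 1
        return min(max(m, i), j)

    def cost(self, i: int, j: int) -> float:
        m = self._median_index(i, j)
        xm = self._xl[m]
        left = xm * (self._Wl[m + 1] - self._Wl[i]) - (self._Sl[m + 1] - self._Sl[i])
        right = (self._Sl[j + 1] - self._Sl[m + 1]) - xm * (self._Wl[j + 1] - self._Wl[m + 1])
        return max(left + right, 0.0)

    def first_costs(self) -> np.ndarray:
        n = len(self.x)
        return np.array([self.cost(0, j) for j in range(n)])


def _dp_layers(cost, n: int, kmax: int) -> tuple:
    """Divide-and-conquer DP: optimal costs/splits for 1..kmax clusters.

    Returns (wcss_per_k, split_table) where split_table[m][j] is the start
    index of the last cluster in the optimal m-partition of x[0..j].  Ties
    are broken toward the leftmost optimal split, which makes the result
    deterministic.
    """
    d_prev = cost.first_costs()
    wcss = [float(d_prev[n - 1])]
    splits = [np.zeros(n, dtype=np.int64)]
    for m in range(2, kmax + 1):
        d_cur = np.full(n, np.inf)
        t_cur = np.zeros(n, dtype=np.int64)
        dp = d_prev.tolist()

        def solve(lo: int, hi: int, optlo: int, opthi: int) -> None:
            if lo > hi:
                return
            mid = (lo + hi) // 2
            best = np.inf
            bestt = -1
            tmin = max(m - 1, optlo)
            tmax = min(mid, opthi)
            for t in range(tmin, tmax + 1):
                c = dp[t - 1] + cost.cost(t, mid)
                if c < best:  # strict: ties keep the leftmost split
                    best = c
                    bestt = t
            d_cur[mid] = best
            t_cur[mid] = bestt
            solve(lo, mid - 1, optlo, bestt)
            solve(mid + 1, hi, bestt, opthi)

        solve(m - 1, n - 1, 1, n - 1)
        wcss.append(float(d_cur[n - 1]))
        splits.append(t_cur)
        d_prev = d_cur
    return wcss, splits


def _backtrack(splits, n: int, k: int) -> list:
    """Recover cluster start indices from the DP split tables."""
    starts = []
    j = n - 1
    for m in range(k, 1, -1):
        t = int(splits[m - 1][j])
        starts.append(t)
        j = t - 1
    starts.append(0)
    return starts[::-1]


def _cluster_1d(values, k: int, criterion: str) -> ClusterModel:
    x, w = _collapse(values)
    n = len(x)
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if n < k:
        raise DegenerateInputError(
            f"need >= {k} distinct values for k={k}, got {n}"
        )
    cost = _CostSSE(x, w) if criterion == "means" else _CostSAE(x, w)
    wcss, splits = _dp_layers(cost, n, k)
    starts = _backtrack(splits, n, k)
    edges = starts[1:] + [n]
    centers = []
    boundaries = []
    for ci, (a, b) in enumerate(zip(starts, edges)):
        xs, ws = x[a:b], w[a:b]
        if criterion == "means":
            centers.append(float(np.average(xs, weights=ws)))
        else:
            rep = np.repeat(xs, ws.astype(int)) if np.all(ws == ws.astype(int)) else xs
            centers.append(float(np.median(rep)))
        if ci > 0:
            boundaries.append(0.5 * (x[a - 1] + x[a]))
    return ClusterModel(
        k=k,
        boundaries=np.array(boundaries),
        centers=np.array(centers),
        wcss=wcss[k - 1],
        criterion=criterion,
    )


def cluster_kmeans_1d(values, k: int) -> ClusterModel:
    """Globally optimal 1-D k-means: minimise within-cluster sum of squares.

    Dynamic programming over contiguous partitions of the sorted values —
    no random initialisation, deterministic, exact.
    """
    return _cluster_1d(values, k, "means")


def cluster_kmedians_1d(values, k: int) -> ClusterModel:
    """Globally optimal 1-D k-medians: minimise within-cluster L1 deviations."""
    return _cluster_1d(values, k, "medians")


def mask_from_clusters(
    img: ElementalImage, model: ClusterModel, keep=(2, 3)
) -> SegmentationResult:
    """Mask of pixels whose cluster index is in ``keep`` (1-based).

    The default keeps clusters 2 and 3 of a k=3 model: the membrane band
    and the high-expression (revertant / junction) tail, excluding the
    background-plus-interior cluster.
    """
    keep = set(int(i) for i in keep)
    if not keep:
        raise ConfigError("keep must name at least one cluster")
    if not keep <= set(range(1, model.k + 1)):
        raise ConfigError(f"keep={sorted(keep)} outside 1..{model.k}")
    assignment = model.assign(img.values)
    mask = np.isin(assignment, sorted(keep))
    return SegmentationResult(
        mask=mask,
        method=f"k{model.criterion}(k={model.k}, keep={sorted(keep)})",
        thresholds_or_model=model,
    )


def select_k(values, k_range=range(2, 10), criterion: str = "means") -> pd.DataFrame:
    """Diagnostics table for choosing k: WCSS, elbow drops and BIC per k.

    Emits the evidence only — cluster-count selection on these images is
    an operator decision (the elbow is rarely unambiguous); the pipeline
    default is k=3.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > 9:
        raise ConfigError("k_range must lie within [2, 9]")
    x, w = _collapse(values)
    n_total = int(np.sum(w))
    if len(x) < ks[-1]:
        raise DegenerateInputError(f"need >= {ks[-1]} distinct values")
    cost = _CostSSE(x, w) if criterion == "means" else _CostSAE(x, w)
    wcss_all, _ = _dp_layers(cost, len(x), ks[-1])
    rows = []
    prev = None
    for k in ks:
        wcss = wcss_all[k - 1]
        with np.errstate(divide="ignore"):
            bic = (
                n_total * np.log(wcss / n_total) + k * np.log(n_total)
                if wcss > 0
                else -np.inf
            )
        rows.append(
            {
                "k": k,
                "wcss": wcss,
                "wcss_drop": (prev - wcss) if prev is not None else np.nan,
                "wcss_ratio": (wcss / prev) if prev not in (None, 0.0) else np.nan,
                "bic": bic,
            }
        )
        prev = wcss
    return pd.DataFrame(rows)


#: the six methods compared by the segmentation report
METHOD_NAMES = ("median", "otsu", "sauvola", "phansalkar", "kmeans", "kmedians")


def run_method(
    img: ElementalImage,
    method: str,
    params: ThresholdParams | None = None,
    k: int = 3,
    keep=(2, 3),
) -> SegmentationResult:
    """Dispatch one of the six segmentation methods by name."""
    if method == "median":
        return threshold_median(img)
    if method == "otsu":
        return threshold_otsu(img)
    if method == "sauvola":
        return threshold_sauvola(img, params)
    if method == "phansalkar":
        return threshold_phansalkar(img, params)
    if method == "kmeans":
        return mask_from_clusters(img, cluster_kmeans_1d(img.values, k), keep)
    if method == "kmedians":
        return mask_from_clusters(img, cluster_kmedians_1d(img.values, k), keep)
    raise ConfigError(f"unknown segmentation method {method!r}; choose from {METHOD_NAMES}")
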