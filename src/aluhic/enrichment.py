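"""Per-pair TE metrics, frequency binning and the correlation machinery.

Three metrics are computed per bin-pair and repeat selector:

``coverage``          fraction of the combined two-bin region (2 x bin_size)
                      covered by the merged copies of the selector;
``enrichment_score``  number of copies whose midpoint falls in the region;
``density``           enrichment_score normalised by the maximum possible
                      same-family copies, i.e. count * mean_family_length /
                      (2 x bin_size), with the mean copy length computed
                      genome-wide over the selector.

Retained pairs are binned into equal-width frequency bins; the Pearson
correlation is computed between per-bin mean frequency and per-bin mean
metric, with a two-sided t test at n-2 degrees of freedom. Two correlations
are compared with a Fisher-z two-sample z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import CoverageIndex, subfamily_group
from .types import BinPair, TEAnnotation

METRIC_KINDS = ("coverage", "density", "enrichment_score")

#: selectors reported by family_profile: the four classes, the Alu split
#: of SINE, the active LINE family and the three Alu age groups.
PROFILE_SELECTORS = (
    "SINE", "LINE", "LTR", "DNA",
    "Alu", "SINE_non_Alu", "L1",
    "AluJ", "AluS", "AluY",
)

_CLASSES = {"SINE", "LINE", "LTR", "DNA"}
_ALU_GROUPS = {"AluJ", "AluS", "AluY"}


def select_records(
    annotations: list[TEAnnotation], selector: str
) -> list[TEAnnotation]:
    """Subset of the annotation matching a class/family/group selector."""
    if selector in _CLASSES:
        return [t for t in annotations if t.te_class == selector]
    if selector == "Alu":
        return [t for t in annotations if t.family == "Alu"]
    if selector == "SINE_non_Alu":
        return [
            t for t in annotations
            if t.te_class == "SINE" and t.family != "Alu"
        ]
    if selector in _ALU_GROUPS:
        return [
            t for t in annotations
            if t.family == "Alu" and subfamily_group(t.subfamily) == selector
        ]
    return [t for t in annotations if t.family == selector]


@dataclass
class _SelectorData:
    midpoints: dict  # chrom -> sorted int64 array
    coverage: dict  # chrom -> CoverageIndex
    mean_length: float
    n_copies: int


class TEIndex:
    """Cached per-selector midpoint and coverage indexes over an annotation."""

    def __init__(self, annotations: list[TEAnnotation]):
        self.annotations = list(annotations)
        self._cache: dict[str, _SelectorData] = {}

    def selector_data(self, selector: str) -> _SelectorData:
        if selector not in self._cache:
            records = select_records(self.annotations, selector)
            mids: dict[str, list] = {}
            spans: dict[str, list] = {}
            total_len = 0
            for t in records:
                iv = t.interval
                mids.setdefault(iv.chrom, []).append(iv.midpoint)
                spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
                total_len += len(iv)
            self._cache[selector] = _SelectorData(
                midpoints={
                    c: np.sort(np.array(v, dtype=np.int64))
                    for c, v in mids.items()
                },
                coverage={
                    c: CoverageIndex(
                        np.array([s for s, _ in v], dtype=np.int64),
                        np.array([e for _, e in v], dtype=np.int64),
                    )
                    for c, v in spans.items()
                },
                mean_length=(total_len / len(records)) if records else 0.0,
                n_copies=len(records),
            )
        return self._cache[selector]


def _as_index(annotations) -> TEIndex:
    return annotations if isinstance(annotations, TEIndex) else TEIndex(annotations)


def te_metrics(
    pairs: list[BinPair],
    annotations,
    selector: str,
    kind: str,
    mean_family_length: float | None = None,
) -> np.ndarray:
    """Metric value for every pair (vectorised); see module docstring."""
    if kind not in METRIC_KINDS:
        raise ValueError(f"kind must be one of {METRIC_KINDS}")
    index = _as_index(annotations)
    data = index.selector_data(selector)
    if kind == "density":
        mean_len = data.mean_length if mean_family_length is None else mean_family_length
        if mean_len <= 0:
            raise ValueError("mean_family_length must be positive for density")
    out = np.zeros(len(pairs))
    # group pairs by chromosome for vectorised queries
    by_chrom: dict[str, list] = {}
    for k, p in enumerate(pairs):
        by_chrom.setdefault(p.chrom, []).append(k)
    for chrom, idxs in by_chrom.items():
        sub = [pairs[k] for k in idxs]
        si = np.array([p.start_i for p in sub], dtype=np.int64)
        sj = np.array([p.start_j for p in sub], dtype=np.int64)
        bs = np.array([p.bin_size for p in sub], dtype=np.int64)
        region_len = 2 * bs
        if kind == "coverage":
            cov = data.coverage.get(chrom)
            if cov is None:
                continue
            bases = cov.covered(si, si + bs) + cov.covered(sj, sj + bs)
            out[idxs] = bases / region_len
        else:
            mids = data.midpoints.get(chrom)
            if mids is None:
                continue
            count = (
                np.searchsorted(mids, si + bs) - np.searchsorted(mids, si)
                + np.searchsorted(mids, sj + bs) - np.searchsorted(mids, sj)
            )
            if kind == "enrichment_score":
                out[idxs] = count
            else:
                out[idxs] = count * mean_len / region_len
    return out


def te_metric(
    pair: BinPair,
    annotations,
    selector: str,
    kind: str,
    mean_family_length: float | None = None,
) -> float:
    """Single-pair convenience wrapper around :func:`te_metrics`."""
    return float(
        te_metrics([pair], annotations, selector, kind, mean_family_length)[0]
    )


@dataclass(frozen=True)
class FrequencyBin:
    """One equal-width frequency bin's summary point."""

    index: int
    left: float
    right: float
    n_pairs: int
    mean_frequency: float
    mean_metric: float


def bin_by_frequency(frequencies, values, n_bins: int) -> list[FrequencyBin]:
    """Equal-width binning over [min, max] of the frequencies.

    The last bin is right-closed; empty bins are dropped. Each bin's x is
    the mean member frequency and its y the mean member metric.
    """
    x = np.asarray(frequencies, dtype=float)
    y = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < 3:
        raise ValueError("need at least 3 pairs to bin")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("all frequencies identical; cannot bin")
    width = (hi - lo) / n_bins
    idx = np.minimum(((x - lo) / width).astype(np.int64), n_bins - 1)
    bins = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        bins.append(
            FrequencyBin(
                index=b,
                left=lo + b * width,
                right=lo + (b + 1) * width,
                n_pairs=n,
                mean_frequency=float(x[sel].mean()),
                mean_metric=float(y[sel].mean()),
            )
        )
    return bins


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided t-test p over n binned points."""

    r: float
    p: float
    n: int
    label: str = ""


def correlate_xy(x, y, label: str = "") -> CorrelationResult:
    """Pearson correlation with two-sided t significance (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.all(y == y[0]):
        raise ValueError("metric is constant; correlation undefined")
    if np.all(x == x[0]):
        raise ValueError("frequency is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=int(x.size), label=label
    )


def correlate_bins(bins: list[FrequencyBin], label: str = "") -> CorrelationResult:
    """Correlation over the binned summary points."""
    return correlate_xy(
        [b.mean_frequency for b in bins],
        [b.mean_metric for b in bins],
        label=label,
    )


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p of a Pearson r over n points (t test, df = n - 2)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class ZTestResult:
    """Fisher-z comparison of two independent Pearson correlations."""

    z: float
    p: float


def compare_correlations(
    res1: CorrelationResult, res2: CorrelationResult
) -> ZTestResult:
    """Two-sample z test on Fisher-transformed correlations."""
    for res in (res1, res2):
        if res.n < 4:
            raise ValueError("each correlation needs n >= 4")
        if abs(res.r) >= 1:
            raise ValueError("|r| = 1: Fisher transform diverges")
    z1, z2 = math.atanh(res1.r), math.atanh(res2.r)
    se = math.sqrt(1.0 / (res1.n - 3) + 1.0 / (res2.n - 3))
    z = (z1 - z2) / se
    return ZTestResult(z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def family_profile(
    pairs: list[BinPair],
    annotations,
    n_bins: int = 50,
    kind: str = "density",
    selectors=PROFILE_SELECTORS,
) -> dict:
    """One CorrelationResult per selector (None where no copies exist)."""
    index = _as_index(annotations)
    freqs = np.array([p.frequency for p in pairs], dtype=float)
    out = {}
    for selector in selectors:
        data = index.selector_data(selector)
        if data.n_copies == 0:
            out[selector] = None
            continue
        values = te_metrics(pairs, index, selector, kind)
        bins = bin_by_frequency(freqs, values, n_bins)
        out[selector] = correlate_bins(bins, label=f"{selector}:{kind}")
    return out
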