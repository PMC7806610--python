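"""Masked quantification, replicate statistics and the Grubbs outlier test.

Each serial section yields one masked mean concentration; replicates
(typically n = 7 consecutive sections) are summarised as mean, SD and CV%
after a single-pass one-sided Grubbs test at alpha = 0.05.  One-sided
critical values reproduce the conventional tabulated values (1.938 for
n = 7); at most one value is ever removed, since iterating the test
inflates the type-I error.  Sections whose mean falls below the LLOQ are
reported separately as "< LLOQ" and excluded from the CV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import UNIT_UGKG, ElementalImage
from .errors import DegenerateInputError, UnitError
from .segment import SegmentationResult

log = logging.getLogger(__name__)

#: FDA bioanalytical guidance bound for ligand-binding assays
FDA_CV_LIMIT_PERCENT = 20.0


@dataclass
class SectionQuant:
    """Masked mean concentration of one section."""

    section_id: str
    mean_conc_ugkg: float
    n_mask_pixels: int
    method: str
    below_lloq: bool = False
    empty_mask: bool = False

    def formatted(self) -> str:
        return "< LLOQ" if self.below_lloq else f"{self.mean_conc_ugkg:.6g}"


@dataclass
class GrubbsResult:
    g_statistic: float
    g_critical: float
    alpha: float
    outlier_index: int | None
    removed: bool


@dataclass
class ReplicateReport:
    """Replicate summary mirroring a per-sample results-table row."""

    sections: list
    mean_ugkg: float
    sd_ugkg: float
    cv_percent: float
    grubbs: GrubbsResult
    n_used: int
    lloq_ugkg: float | None = None
    n_below_lloq: int = 0
    cv_within_fda_limit: bool = field(init=False)

    def __post_init__(self) -> None:
        self.cv_within_fda_limit = self.cv_percent <= FDA_CV_LIMIT_PERCENT


def masked_mean_concentration(
    img: ElementalImage,
    seg: SegmentationResult,
    lloq_ugkg: float | None = None,
    section_id: str = "section",
) -> SectionQuant:
    """Mean concentration over the positive mask of one section."""
    img.require_unit(UNIT_UGKG, "masked_mean_concentration")
    if seg.mask.shape != img.values.shape:
        raise UnitError(
            f"mask shape {seg.mask.shape} does not match image shape {img.values.shape}"
        )
    n = int(seg.mask.sum())
    if n == 0:
        log.warning("%s: empty segmentation mask", section_id)
        return SectionQuant(
            section_id=section_id,
            mean_conc_ugkg=0.0,
            n_mask_pixels=0,
            method=seg.method,
            below_lloq=lloq_ugkg is not None,
            empty_mask=True,
        )
    mean = float(img.values[seg.mask].mean())
    return SectionQuant(
        section_id=section_id,
        mean_conc_ugkg=mean,
        n_mask_pixels=n,
        method=seg.method,
        below_lloq=(lloq_ugkg is not None and mean < lloq_ugkg),
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """One-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/n quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise DegenerateInputError(f"Grubbs test needs n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise DegenerateInputError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Single-pass Grubbs test: flag at most one outlier.

    G = max|x_i - mean| / s (sample SD); the extreme value is removed iff
    G exceeds the one-sided critical value.  A zero-SD sample yields
    G = 0 and no removal.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise DegenerateInputError(f"Grubbs test needs >= 3 values, got {x.size}")
    gcrit = grubbs_critical_value(x.size, alpha)
    s = x.std(ddof=1)
    if s == 0:
        return GrubbsResult(0.0, gcrit, alpha, None, False)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    removed = g > gcrit
    return GrubbsResult(g, gcrit, alpha, idx if removed else None, removed)


def replicate_stats(
    sections: list,
    alpha: float = 0.05,
    lloq_ugkg: float | None = None,
) -> ReplicateReport:
    """Mean, SD and CV% across replicate sections after outlier screening.

    Sections flagged below the LLOQ are excluded from the statistics and
    counted separately.  The Grubbs test runs only when >= 3 quantifiable
    sections remain.
    """
    if len(sections) < 2:
        raise DegenerateInputError("replicate_stats needs >= 2 sections")
    usable = [s for s in sections if not s.below_lloq and not s.empty_mask]
    n_below = len(sections) - len(usable)
    if len(usable) < 2:
        raise DegenerateInputError(
            f"only {len(usable)} quantifiable sections (>= 2 required)"
        )
    means = np.array([s.mean_conc_ugkg for s in usable])
    if means.size >= 3:
        gr = grubbs_test(means, alpha)
    else:
        gr = GrubbsResult(0.0, np.nan, alpha, None, False)
    if gr.removed:
        log.info(
            "Grubbs: removed section %s (G=%.3f > %.3f)",
            usable[gr.outlier_index].section_id, gr.g_statistic, gr.g_critical,
        )
        means = np.delete(means, gr.outlier_index)
    if means.size < 2:
        raise DegenerateInputError("fewer than 2 sections survive outlier removal")
    mean = float(means.mean())
    sd = float(means.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    return ReplicateReport(
        sections=list(sections),
        mean_ugkg=mean,
        sd_ugkg=sd,
        cv_percent=cv,
        grubbs=gr,
        n_used=int(means.size),
        lloq_ugkg=lloq_ugkg,
        n_below_lloq=n_below,
    )
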