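"""VAF-density genomic-complexity inference: MATH score and VAF-peak count.

The MATH (mutant-allele tumour heterogeneity) score is
``100 * MAD / median`` over a sample's variant allele frequencies, with
MAD scaled by 1.4826 for normal consistency; it measures the width of the
VAF distribution.  Low-complexity tumours driven by a single clonal
expansion show one VAF peak and a low MATH score, whereas branched,
multi-subclone tumours show several peaks and a higher score.  Peaks are
counted by fitting one-dimensional Gaussian mixtures over a clonal VAF
window and selecting the component count by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "NotComputable",
    "ComplexityResult",
    "math_score",
    "count_vaf_peaks",
    "complexity_threshold",
]

MAD_SCALE = 1.4826  # normal-consistency constant


class NotComputable(ValueError):
    """The requested statistic is undefined for this input (distinct from 0)."""


@dataclass
class ComplexityResult:
    """Per-sample genomic-complexity summary."""

    sample_id: str
    math_score: float | None
    n_vaf_peaks: int
    peak_means: list[float]
    peak_weights: list[float]
    n_vaf_used: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (len(self.peak_means) == len(self.peak_weights) == self.n_vaf_peaks):
            raise ValueError("peak lists must match n_vaf_peaks")
        if any(b <= a for a, b in zip(self.peak_means, self.peak_means[1:])):
            raise ValueError("peak_means must be strictly increasing")


def math_score(vafs: Sequence[float]) -> float:
    """MATH score: ``100 * 1.4826 * median(|v - median|) / median``.

    Requires at least two VAFs in (0, 1] with a positive median; raises
    :class:`NotComputable` otherwise.  Invariant to rescaling all VAFs by
    a positive constant.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise NotComputable("MATH requires at least 2 VAFs")
    if np.any((v <= 0) | (v > 1)):
        raise ValueError("VAFs must lie in (0, 1]")
    med = float(np.median(v))
    if med <= 0:
        raise NotComputable("MATH requires a positive median VAF")
    mad = MAD_SCALE * float(np.median(np.abs(v - med)))
    return 100.0 * mad / med


def count_vaf_peaks(
    vafs: Sequence[float],
    sample_id: str = "",
    vaf_window: tuple[float, float] = (0.05, 0.75),
    k_max: int = 5,
    min_weight: float = 0.05,
    seed: int = 0,
) -> ComplexityResult:
    """Count discrete VAF peaks by BIC-selected 1-D Gaussian mixtures.

    VAFs inside ``vaf_window`` (the upper clip avoids LOH/copy-number
    driven frequencies dominating the fit) are modelled with Gaussian
    mixtures for k = 1..``k_max``; the BIC-minimal k is selected with ties
    resolved toward smaller k.  Components with mixture weight below
    ``min_weight`` are discarded and the remaining weights renormalised.
    Deterministic given ``seed``.

    Fewer than 10 in-window VAFs yields a degenerate single-peak result
    flagged ``low_confidence``; no in-window VAFs raises
    :class:`NotComputable`.
    """
    v = np.asarray(vafs, dtype=float)
    lo, hi = vaf_window
    inside = v[(v >= lo) & (v <= hi)]
    math = None
    if v.size >= 2 and np.median(v) > 0:
        math = math_score(v)
    if inside.size == 0:
        raise NotComputable("no VAFs inside the clonal window")
    if inside.size < 10:
        return ComplexityResult(
            sample_id=sample_id,
            math_score=math,
            n_vaf_peaks=1,
            peak_means=[float(np.mean(inside))],
            peak_weights=[1.0],
            n_vaf_used=int(inside.size),
            low_confidence=True,
        )
    x = inside.reshape(-1, 1)
    best: GaussianMixture | None = None
    best_bic = np.inf
    for k in range(1, k_max + 1):
        if k > inside.size:
            break
        with warnings.catch_warnings():
            # constant VAFs collapse k-means init to one cluster; harmless
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=1e-6,  # jitter guard for (near-)constant VAFs
                n_init=3,
                init_params="kmeans",
                random_state=seed,
            ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:  # strict: BIC ties resolve toward smaller k
            best, best_bic = gm, bic
    assert best is not None
    means = best.means_.ravel()
    weights = best.weights_.ravel()
    keep = weights >= min_weight
    if not keep.any():
        keep[np.argmax(weights)] = True
    means, weights = means[keep], weights[keep]
    order = np.argsort(means)
    means, weights = means[order], weights[order]
    # merge numerically coincident components
    m_out: list[float] = []
    w_out: list[float] = []
    for m, w in zip(means, weights):
        if m_out and m - m_out[-1] < 1e-9:
            w_out[-1] += w
        else:
            m_out.append(float(m))
            w_out.append(float(w))
    total = sum(w_out)
    w_out = [w / total for w in w_out]
    return ComplexityResult(
        sample_id=sample_id,
        math_score=math,
        n_vaf_peaks=len(m_out),
        peak_means=m_out,
        peak_weights=w_out,
        n_vaf_used=int(inside.size),
    )


def complexity_threshold(results: Sequence[ComplexityResult]) -> float:
    """Median MATH score among samples with a single VAF peak.

    This is the cut-point used to sub-split TP53wt/CTNNB1wt tumours into
    low- vs high-complexity groups.
    """
    scores = [
        r.math_score
        for r in results
        if r.n_vaf_peaks == 1 and r.math_score is not None
    ]
    if not scores:
        raise NotComputable(
            "no single-peak samples with a MATH score; "
            "supply an explicit complexity threshold"
        )
    return float(np.median(scores))
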