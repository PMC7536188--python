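"""Per-sample mutation metrics and a z-score copy-number caller.

TMB is the count of mutations remaining after filtering (hypermutated
above 250, ultramutated above 1000).  The MSI score is the count of short
insertions/deletions, a microsatellite-instability proxy.  The substitution
spectrum collapses the twelve single-nucleotide changes onto the six
pyrimidine-reference classes.  Copy-number gains/losses are called per gene
as z-scores against a pooled reference population (here the TP53
wild-type samples), requiring both a z-score beyond ``sd_threshold``
standard deviations and a two-sided normal p-value below ``alpha``.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import MutatorClass, SPECTRUM_CLASSES, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tmb",
    "classify_mutator",
    "compute_msi_score",
    "compute_spectrum",
    "call_cna",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_single_sample(variants: Sequence[VariantCall]) -> None:
    ids = {v.sample_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(ids)}")


def compute_tmb(variants: Sequence[VariantCall]) -> int:
    """Tumour mutational burden: distinct filtered mutations in one sample.

    Duplicate observations of the same normalised variant key count once.
    """
    _check_single_sample(variants)
    return len({v.key for v in variants})


def classify_mutator(tmb: int) -> MutatorClass:
    """Classify TMB: >1000 ultramutated, >250 hypermutated, else normal."""
    if tmb < 0:
        raise ValueError("tmb must be non-negative")
    if tmb > 1000:
        return MutatorClass.ULTRAMUTATED
    if tmb > 250:
        return MutatorClass.HYPERMUTATED
    return MutatorClass.NORMAL


def compute_msi_score(
    variants: Sequence[VariantCall], max_indel_len: int = 5
) -> int:
    """Count short InDels (length difference 1..``max_indel_len`` bp)."""
    _check_single_sample(variants)
    return sum(
        1
        for v in variants
        if 1 <= abs(len(v.ref) - len(v.alt)) <= max_indel_len
    )


def compute_spectrum(variants: Sequence[VariantCall]) -> tuple[float, ...]:
    """Fractions of the six pyrimidine-collapsed substitution classes.

    Purine-reference changes are complemented onto their pyrimidine
    equivalent (G>A == C>T, etc.).  InDels and non-ACGT alleles are
    ignored.  Returns the all-zero vector when no SNVs are present.
    """
    counts: Counter[str] = Counter()
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue
        ref, alt = v.ref, v.alt
        if ref not in "ACGT" or alt not in "ACGT":
            continue
        if ref in "AG":  # collapse to pyrimidine reference strand
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    if total == 0:
        return (0.0,) * 6
    return tuple(counts.get(c, 0) / total for c in SPECTRUM_CLASSES)


def call_cna(
    score_matrix: pd.DataFrame,
    reference_samples: Sequence[str],
    sd_threshold: float = 5.0,
    alpha: float = 0.05,
) -> dict[str, list[tuple[str, str]]]:
    """Call per-gene copy-number gains/losses against a reference population.

    ``score_matrix`` is genes x samples.  For each gene, the reference mean
    and standard deviation are estimated from ``reference_samples``; a
    sample is called ``gain`` at that gene when its z-score exceeds
    ``sd_threshold`` with two-sided normal p < ``alpha``, and ``loss``
    symmetrically below.  Genes with zero reference variance are skipped
    with a warning.  Returns per-sample event lists; a sample's CNA burden
    is the length of its list.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference_samples must be non-empty")
    missing = [s for s in reference_samples if s not in score_matrix.columns]
    if missing:
        raise ValueError(f"reference samples absent from matrix: {missing}")
    ref = score_matrix[reference_samples]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    usable = sd > 0
    skipped = sd.index[~usable]
    if len(skipped):
        logger.warning(
            "skipping %d gene(s) with zero reference variance: %s",
            len(skipped), list(skipped[:5]),
        )
    z = score_matrix.loc[usable].sub(mean[usable], axis=0).div(sd[usable], axis=0)
    pvals = 2.0 * stats.norm.sf(np.abs(z.to_numpy()))
    events: dict[str, list[tuple[str, str]]] = {s: [] for s in score_matrix.columns}
    genes = z.index.to_numpy()
    for j, sample in enumerate(z.columns):
        zj = z.iloc[:, j].to_numpy()
        sig = pvals[:, j] < alpha
        for g in genes[(zj > sd_threshold) & sig]:
            events[sample].append((g, "gain"))
        for g in genes[(zj < -sd_threshold) & sig]:
            events[sample].append((g, "loss"))
        events[sample].sort()
    return events
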