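"""Consensus majority-vote merging and the variant-filtering cascade.

Somatic calls from multiple callers are retained when a majority agree
(default: at least 2 of 3).  Surviving calls then pass through a quality
cascade — sequencing depth >= 20x, VAF >= 10%, population allele frequency
below the common-variant cutoff, no orientation-bias artifact flag — and a
functional filter driven by consequence class plus ClinVar / PolyPhen /
SIFT annotations.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .io_model import (
    ClinVar,
    Consequence,
    MmrStatus,
    PolyPhen,
    Sift,
    TRUNCATING,
    VariantCall,
    VariantKey,
)

__all__ = [
    "consensus_filter",
    "apply_quality_filters",
    "apply_functional_filter",
    "classify_mmr_status",
    "DEFAULT_MMR_GENES",
    "RemovalReason",
]

#: Mismatch-repair gene panel (configurable via the ``mmr_genes`` argument).
DEFAULT_MMR_GENES = frozenset(
    {"MLH1", "MLH3", "MSH2", "MSH3", "MSH4", "MSH6", "PMS1", "PMS2"}
)

#: First-failing removal reasons in cascade order.
RemovalReason = str
_REASONS = ("depth", "vaf", "common", "artifact")


def consensus_filter(
    calls_by_caller: Mapping[VariantKey, Iterable[str]],
    min_callers: int = 2,
) -> set[VariantKey]:
    """Retain variant keys supported by at least ``min_callers`` callers.

    With three callers the default of 2 implements majority voting;
    ``min_callers=1`` is the union of call sets and ``min_callers`` equal
    to the number of callers seen is their intersection.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    all_callers = set()
    for callers in calls_by_caller.values():
        all_callers.update(callers)
    if calls_by_caller and min_callers > len(all_callers):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(all_callers)} "
            f"caller(s) present in the input"
        )
    return {
        key for key, callers in calls_by_caller.items()
        if len(set(callers)) >= min_callers
    }


def apply_quality_filters(
    variants: Sequence[VariantCall],
    min_depth: int = 20,
    min_vaf: float = 0.10,
    max_pop_af: float = 0.01,
    drop_orientation_bias: bool = True,
) -> tuple[list[VariantCall], list[tuple[VariantCall, RemovalReason]]]:
    """Apply the depth / VAF / common-variant / artifact quality cascade.

    A variant is kept when depth >= ``min_depth``, VAF >= ``min_vaf``
    (boundary inclusive), its population allele frequency is missing or
    below ``max_pop_af``, and it carries no orientation-bias artifact flag
    (when ``drop_orientation_bias``).  Each removed variant is tagged with
    its *first* failing reason, evaluated in the order depth, vaf, common,
    artifact, so removal counts are additive for flow-diagram reporting.
    """
    if min_depth < 0 or not (0.0 <= min_vaf <= 1.0) or not (0.0 <= max_pop_af <= 1.0):
        raise ValueError("filter thresholds out of range")
    kept: list[VariantCall] = []
    removed: list[tuple[VariantCall, RemovalReason]] = []
    for v in variants:
        if v.depth < min_depth:
            removed.append((v, "depth"))
        elif v.vaf < min_vaf:
            removed.append((v, "vaf"))
        elif v.population_af is not None and v.population_af >= max_pop_af:
            removed.append((v, "common"))
        elif drop_orientation_bias and v.orientation_bias_flag:
            removed.append((v, "artifact"))
        else:
            kept.append(v)
    return kept, removed


def apply_functional_filter(variants: Sequence[VariantCall]) -> list[VariantCall]:
    """Drop likely non-functional variants.

    Rule table (first match wins):

    ==========================  ========
    condition                   outcome
    ==========================  ========
    ClinVar pathogenic          keep
    ClinVar benign              drop
    synonymous                  drop
    truncating class            keep
    missense, PolyPhen benign
      AND SIFT tolerated        drop
    anything else (incl.
      missing predictions)      keep
    ==========================  ========
    """
    kept = []
    for v in variants:
        if v.clinvar is ClinVar.PATHOGENIC:
            kept.append(v)
        elif v.clinvar is ClinVar.BENIGN:
            continue
        elif v.consequence is Consequence.SYNONYMOUS:
            continue
        elif v.consequence in TRUNCATING:
            kept.append(v)
        elif (
            v.consequence is Consequence.MISSENSE
            and v.polyphen is PolyPhen.BENIGN
            and v.sift is Sift.TOLERATED
        ):
            continue
        else:
            kept.append(v)
    return kept


def classify_mmr_status(
    variants: Sequence[VariantCall],
    mmr_genes: frozenset[str] = DEFAULT_MMR_GENES,
) -> MmrStatus:
    """Classify a sample's mismatch-repair mutation status.

    ``high_impact`` when any MMR-gene variant is frameshifting, nonsense or
    splice-site; ``missense_only`` when MMR-gene variants exist but none is
    high impact; ``wt`` otherwise.
    """
    if not mmr_genes:
        raise ValueError("mmr_genes must be non-empty")
    hit = [v for v in variants if v.gene in mmr_genes]
    if any(v.consequence in TRUNCATING for v in hit):
        return MmrStatus.HIGH_IMPACT
    if hit:
        return MmrStatus.MISSENSE_ONLY
    return MmrStatus.WT


def removal_report(
    removed: Sequence[tuple[VariantCall, RemovalReason]],
) -> dict[RemovalReason, int]:
    """Tally removals per first-failing reason, in cascade order."""
    counts = Counter(reason for _, reason in removed)
    return {r: counts.get(r, 0) for r in _REASONS}
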