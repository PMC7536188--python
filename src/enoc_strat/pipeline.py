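"""End-to-end orchestration: filter -> metrics -> complexity -> stratify -> survive.

``run_pipeline`` drives a config-driven run over a MAF + clinical CSV, a
simulated cohort, or the packaged fixture cohort, writing stage outputs
and a reproducibility manifest under a run directory.  Rerunning with the
same config and seed reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling_filters import (
    DEFAULT_MMR_GENES,
    apply_functional_filter,
    apply_quality_filters,
    classify_mmr_status,
)
from .complexity import NotComputable, complexity_threshold, count_vaf_peaks
from .io_model import SampleProfile, VariantCall, read_clinical, read_maf
from .metrics import (
    classify_mutator,
    compute_msi_score,
    compute_spectrum,
    compute_tmb,
)
from .stratify import (
    build_mutation_matrix,
    classify_pristine,
    cluster_samples,
    cohort_crosstab,
    test_cooccurrence,
)
from .survival import cox_fit, km_estimate, logrank, median_followup_reverse_km
from .synthetic_data import (
    SimulationConfig,
    calls_from_frame,
    load_fixture,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "profile_sample", "profile_cohort", "default_config"]


def default_config() -> dict:
    """All pipeline thresholds with their default values."""
    return {
        "seed": 0,
        "min_callers": 2,
        "min_depth": 20,
        "min_vaf": 0.10,
        "max_pop_af": 0.01,
        "drop_orientation_bias": True,
        "max_indel_len": 5,
        "vaf_window": [0.05, 0.75],
        "k_max": 5,
        "min_weight": 0.05,
        "top_n_genes": 50,
        "sd_threshold": 5.0,
        "cna_alpha": 0.05,
    }


def profile_sample(
    sample_id: str,
    calls: Sequence[VariantCall],
    max_indel_len: int = 5,
    mmr_genes=DEFAULT_MMR_GENES,
) -> SampleProfile:
    """Derive the per-sample metric profile from quality-filtered calls.

    The MSI score counts InDels before the functional filter; TMB,
    spectrum and gene flags use the functionally filtered set.
    """
    msi = compute_msi_score(calls, max_indel_len=max_indel_len)
    functional = apply_functional_filter(calls)
    tmb = compute_tmb(functional)
    return SampleProfile(
        sample_id=sample_id,
        tmb=tmb,
        msi_score=msi,
        spectrum=compute_spectrum(functional),
        math_score=None,
        n_vaf_peaks=None,
        mutated_genes=frozenset(v.gene for v in functional),
        mutator_class=classify_mutator(tmb),
        mmr_status=classify_mmr_status(functional, mmr_genes),
    )


def profile_cohort(
    calls_by_sample: dict[str, list[VariantCall]],
    cfg: dict,
) -> tuple[list[SampleProfile], dict[str, object]]:
    """Quality-filter, profile and complexity-score every sample.

    Returns profiles (with MATH and peak counts filled in) plus the
    per-sample complexity results keyed by sample id.
    """
    seed = int(cfg.get("seed", 0))
    profiles: list[SampleProfile] = []
    complexity_results: dict[str, object] = {}
    for sample_id in sorted(calls_by_sample):
        kept, _removed = apply_quality_filters(
            calls_by_sample[sample_id],
            min_depth=cfg["min_depth"],
            min_vaf=cfg["min_vaf"],
            max_pop_af=cfg["max_pop_af"],
            drop_orientation_bias=cfg["drop_orientation_bias"],
        )
        prof = profile_sample(sample_id, kept, max_indel_len=cfg["max_indel_len"])
        vafs = [v.vaf for v in kept]
        try:
            res = count_vaf_peaks(
                vafs,
                sample_id=sample_id,
                vaf_window=tuple(cfg["vaf_window"]),
                k_max=cfg["k_max"],
                min_weight=cfg["min_weight"],
                seed=seed,
            )
            prof.math_score = res.math_score
            prof.n_vaf_peaks = res.n_vaf_peaks
            complexity_results[sample_id] = res
        except NotComputable:
            logger.warning("complexity not computable for %s", sample_id)
        profiles.append(prof)
    return profiles, complexity_results


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    fixture: bool = False,
    simulate: bool = False,
) -> dict:
    """Run the full stratification pipeline and write a report bundle.

    ``config`` is a dict or a YAML path; missing keys fall back to
    :func:`default_config`.  Exactly one input mode applies: ``fixture``
    (the packaged deterministic cohort), ``simulate`` (synthetic cohort at
    the configured size and seed), or paths ``maf`` + ``clinical`` in the
    config.  Returns a summary dict; all tables and the manifest are
    written under ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user_cfg = yaml.safe_load(fh) or {}
    else:
        user_cfg = dict(config)
    cfg = {**default_config(), **user_cfg}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"mode": "fixture" if fixture else "simulate" if simulate else "files"}

    if fixture:
        flags = load_fixture()
        summary.update(_analyse_flag_cohort(flags, out))
    else:
        if simulate:
            sim_cfg = SimulationConfig(
                n_samples=int(cfg.get("n_samples", 112)), seed=int(cfg["seed"])
            )
            sim = simulate_cohort(sim_cfg)
            calls_by_sample = calls_from_frame(sim.variants)
            clinical = sim.cohort
            sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        else:
            if "maf" not in cfg or "clinical" not in cfg:
                raise ValueError(
                    "config must provide 'maf' and 'clinical' paths "
                    "(or use fixture/simulate mode)"
                )
            calls = read_maf(cfg["maf"])
            calls_by_sample = {}
            for c in calls:
                calls_by_sample.setdefault(c.sample_id, []).append(c)
            clin_records = read_clinical(cfg["clinical"])
            clinical = pd.DataFrame(
                [
                    {
                        "sample_id": r.sample_id,
                        "age_years": r.age_years,
                        "stage_group": (
                            "missing" if r.stage.value == "missing"
                            else "III_IV" if r.stage.value in ("III", "IV")
                            else "I_II"
                        ),
                        "rd": r.rd.value,
                        "decade": r.decade,
                        "concurrent_endometrial": r.concurrent_endometrial,
                        "dss_time_years": r.dss_time_years,
                        "dss_event": r.dss_event,
                        "pfs_time_years": r.pfs_time_years,
                        "pfs_event": r.pfs_event,
                    }
                    for r in clin_records
                ]
            )
        profiles, complexity_results = profile_cohort(calls_by_sample, cfg)
        summary.update(
            _analyse_profiles(profiles, complexity_results, clinical, cfg, out)
        )

    manifest = {
        "config": cfg,
        "config_hash": _hash_config(cfg),
        "seed": int(cfg["seed"]),
        "mode": summary["mode"],
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary["manifest_hash"] = _hash_config(manifest)
    return summary


def _analyse_flag_cohort(flags: pd.DataFrame, out: Path) -> dict:
    """Crosstabs + exclusivity + survival on a flag-level cohort (fixture)."""
    crosstabs = {}
    for name, (row, col) in {
        "tp53_x_ctnnb1": ("tp53_status", "ctnnb1_status"),
        "tp53_x_sox8": ("tp53_status", "sox8"),
        "tp53_x_stage": ("tp53_status", "stage_group"),
        "tp53_x_rd": ("tp53_status", "rd"),
        "tp53_x_endometrial": ("tp53_status", "concurrent_endometrial"),
        "ctnnb1_x_stage": ("ctnnb1_status", "stage_group"),
        "ctnnb1_x_rd": ("ctnnb1_status", "rd"),
        "mmr_x_tp53": ("mmr_status_binary", "tp53_status"),
        "pole_x_mmr": ("pole_status", "mmr_status_binary"),
    }.items():
        ct = cohort_crosstab(flags, row, col)
        ct.counts.to_csv(out / f"crosstab_{name}_counts.tsv", sep="\t")
        ct.percent.to_csv(out / f"crosstab_{name}_percent.tsv", sep="\t")
        crosstabs[name] = ct

    calls = [
        classify_pristine(bool(r.tp53), bool(r.ctnnb1), sample_id=r.sample_id)
        for r in flags.itertuples(index=False)
    ]
    pd.DataFrame(
        [{"sample_id": c.sample_id, "subtype": c.subtype.value} for c in calls]
    ).to_csv(out / "pristine_calls.tsv", sep="\t", index=False)

    km = km_estimate(flags["dss_time_years"], flags["dss_event"], label="DSS")
    cox = cox_fit(
        flags.assign(group=np.where(flags["tp53"], "TP53m", "TP53wt")),
        "dss_time_years", "dss_event", "group", reference="TP53wt",
    )
    cox.summary.to_csv(out / "cox_dss.tsv", sep="\t")
    followup = median_followup_reverse_km(
        flags["dss_time_years"], flags["dss_event"]
    )
    logrank_p = logrank(
        flags["dss_time_years"], flags["dss_event"], flags["subtype"]
    )
    return {
        "n_samples": len(flags),
        "crosstabs": crosstabs,
        "five_year_dss": km.survival_at(5.0),
        "median_followup": followup,
        "tp53_hr": cox.hr("group[TP53m]"),
        "subtype_logrank_p": logrank_p,
    }


def _analyse_profiles(
    profiles, complexity_results, clinical: pd.DataFrame, cfg: dict, out: Path
) -> dict:
    from .io_model import write_profiles

    matrix = build_mutation_matrix(profiles, top_n=cfg["top_n_genes"])
    clustering = cluster_samples(matrix)
    (out / "dendrogram.nwk").write_text(clustering.newick() + "\n")
    excl = (
        test_cooccurrence(matrix, "TP53", "CTNNB1")
        if "TP53" in matrix.genes and "CTNNB1" in matrix.genes
        else None
    )
    try:
        threshold = complexity_threshold(list(complexity_results.values()))
    except NotComputable:
        threshold = None
    calls = []
    for p in profiles:
        calls.append(
            classify_pristine(
                "TP53" in p.mutated_genes,
                "CTNNB1" in p.mutated_genes,
                math=p.math_score,
                threshold=threshold,
                sample_id=p.sample_id,
            )
        )
    write_profiles(profiles, out / "profiles.tsv")
    pristine = pd.DataFrame(
        [{"sample_id": c.sample_id, "subtype": c.subtype.value,
          "rules_fired": "|".join(c.rules_fired)} for c in calls]
    )
    pristine.to_csv(out / "pristine_calls.tsv", sep="\t", index=False)

    merged = clinical.merge(pristine, on="sample_id", how="inner")
    results: dict = {
        "n_samples": len(profiles),
        "median_tmb": float(np.median([p.tmb for p in profiles])),
        "complexity_threshold": threshold,
        "exclusivity_p": excl.p_value if excl else None,
        "exclusivity_direction": excl.direction if excl else None,
    }
    if len(merged) and merged["dss_event"].any():
        km = km_estimate(merged["dss_time_years"], merged["dss_event"], label="DSS")
        results["five_year_dss"] = km.survival_at(5.0)
        merged["tp53_group"] = np.where(
            merged["subtype"] == "TP53m", "TP53m", "TP53wt"
        )
        if merged["tp53_group"].nunique() == 2:
            cox = cox_fit(
                merged, "dss_time_years", "dss_event", "tp53_group",
                reference="TP53wt",
            )
            cox.summary.to_csv(out / "cox_dss.tsv", sep="\t")
            results["tp53_hr"] = cox.hr("tp53_group[TP53m]")
    return results
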