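"""Synthetic cohort generator and the deterministic fixture cohort.

The generator emulates the statistical structure the downstream analysis
assumes for an endometrioid ovarian carcinoma cohort: gene-level mutation
frequencies, TP53/CTNNB1 mutual exclusivity with a single co-mutant cell
probability, POLE-MMR co-occurrence, a hypermutator tumour-mutational-
burden tail, unimodal vs multimodal VAF architectures by subtype, and
subtype-specific survival hazards with independent censoring.

``make_fixture_cohort`` builds the 112-sample deterministic cohort whose
marginal and joint counts reproduce the printed cross-tabulations the
pipeline is validated against; it is validated on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .io_model import VariantCall, read_maf  # noqa: F401  (re-export convenience)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "draw_mutation_flags",
    "draw_vafs",
    "simulate_survival_times",
    "simulate_two_group_survival",
    "make_fixture_cohort",
    "load_fixture",
    "calls_from_frame",
]

#: Cohort gene-level mutation frequencies (fraction of samples mutated).
DEFAULT_GENE_FREQS = {
    "CTNNB1": 0.429,
    "PIK3CA": 0.429,
    "ARID1A": 0.357,
    "PTEN": 0.295,
    "KRAS": 0.259,
    "TP53": 0.259,
    "SOX8": 0.188,
    "POLE": 0.063,
}

#: Joint TP53 x CTNNB1 mutation cell probabilities (sum to 1).
DEFAULT_EXCLUSIVITY = {
    "both": 1 / 112,
    "tp53_only": 28 / 112,
    "ctnnb1_only": 47 / 112,
    "neither": 36 / 112,
}

#: Exponential DSS hazards per subtype (per year).  The TP53-mutant rate
#: corresponds to a median DSS of 3.78 years; TP53wt/CTNNB1wt is 0.37x
#: that and CTNNB1m a further 0.31x, so the implied TP53m-vs-rest rate
#: ratio is ~4.4 and CTNNB1m carries a strongly favourable hazard.
_TP53M_RATE = math.log(2) / 3.78
DEFAULT_SURVIVAL_RATES = {
    "TP53m": _TP53M_RATE,
    "TP53wt_CTNNB1wt": 0.37 * _TP53M_RATE,
    "TP53wt_CTNNB1m": 0.31 * 0.37 * _TP53M_RATE,
}

#: Per-subtype probability of advanced (III/IV) stage and macroscopic
#: residual disease, anchored to the printed subgroup rates.
DEFAULT_STAGE_MODEL = {"TP53m": 14 / 29, "TP53wt_CTNNB1m": 4 / 45, "TP53wt_CTNNB1wt": 6 / 36}
DEFAULT_RD_MODEL = {"TP53m": 12 / 27, "TP53wt_CTNNB1m": 5 / 45, "TP53wt_CTNNB1wt": 6 / 33}
DEFAULT_ENDOMETRIAL_MODEL = {"TP53m": 1 / 29, "TP53wt_CTNNB1m": 18 / 83, "TP53wt_CTNNB1wt": 18 / 83}

MMR_GENE_CYCLE = ("MSH3", "MSH6", "MLH3", "MSH4", "MLH1", "MSH2", "PMS1", "PMS2")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults encode the study conditions: a 112-sample cohort, the
    printed gene frequencies and TP53/CTNNB1 exclusivity table, MMR
    enrichment in POLE-mutant tumours (5/7 vs 15/105), a negative-binomial
    mutation burden with median 78 and a hypermutator tail, median
    per-sample coverage 89.5x, and subtype survival hazards anchored to
    the printed hazard ratios.  ``seed`` is mandatory.
    """

    n_samples: int = 112
    seed: int = 0
    gene_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQS)
    )
    exclusivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSIVITY)
    )
    p_mmr_given_pole: float = 5 / 7
    p_mmr_given_polewt: float = 15 / 105
    p_high_impact_given_mmr: float = 0.5
    tmb_mean: float = 77.5  # NB(r=4) baseline; cohort median 78 with the hypermutator tail
    tmb_dispersion: float = 4.0
    tmb_min: int = 20
    hypermut_multiplier: float = 6.0  # POLEm or high-impact MMRm
    ultramut_multiplier: float = 20.0  # POLEm and MMRm together
    indel_frac: float = 0.12
    indel_frac_msi: float = 0.35  # high-impact MMRm samples
    median_coverage: float = 89.5
    coverage_sigma: float = 0.3
    survival_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_RATES)
    )
    pfs_rate_multiplier: float = 1.6
    censor_rate: float = 0.055
    admin_cap_years: float = 25.0
    stage_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MODEL)
    )
    rd_model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RD_MODEL))
    endometrial_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENDOMETRIAL_MODEL)
    )

    def validate(self) -> None:
        cells = self.exclusivity
        expected = {"both", "tp53_only", "ctnnb1_only", "neither"}
        if set(cells) != expected:
            raise ValueError(f"exclusivity must have cells {sorted(expected)}")
        if any(not (0.0 <= v <= 1.0) for v in cells.values()):
            raise ValueError("exclusivity cell probabilities must lie in [0, 1]")
        if abs(sum(cells.values()) - 1.0) > 1e-9:
            raise ValueError("exclusivity cells must sum to 1")
        for name, p in [
            ("p_mmr_given_pole", self.p_mmr_given_pole),
            ("p_mmr_given_polewt", self.p_mmr_given_polewt),
            ("p_high_impact_given_mmr", self.p_high_impact_given_mmr),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not (0.0 <= f <= 1.0) for f in self.gene_freqs.values()):
            raise ValueError("gene frequencies must lie in [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedCohort:
    """Generator output: MAF-style variants, clinical table, latent truth."""

    variants: pd.DataFrame
    cohort: pd.DataFrame
    truth: pd.DataFrame


def _subtype(tp53: bool, ctnnb1: bool) -> str:
    if tp53:
        return "TP53m"
    return "TP53wt_CTNNB1m" if ctnnb1 else "TP53wt_CTNNB1wt"


def draw_mutation_flags(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sample driver mutation indicators.

    TP53/CTNNB1 come from the configured joint exclusivity table; MMR
    status is drawn conditionally on POLE; the remaining genes are
    independent Bernoulli at their marginal frequencies.
    """
    config.validate()
    n = config.n_samples
    cells = ["both", "tp53_only", "ctnnb1_only", "neither"]
    probs = [config.exclusivity[c] for c in cells]
    draw = rng.choice(len(cells), size=n, p=probs)
    tp53 = np.isin(draw, [0, 1])
    ctnnb1 = np.isin(draw, [0, 2])
    pole = rng.random(n) < config.gene_freqs.get("POLE", 0.0)
    p_mmr = np.where(pole, config.p_mmr_given_pole, config.p_mmr_given_polewt)
    mmr = rng.random(n) < p_mmr
    mmr_high = mmr & (rng.random(n) < config.p_high_impact_given_mmr)
    flags = pd.DataFrame(
        {
            "sample_id": [f"SIM{i+1:04d}" for i in range(n)],
            "TP53": tp53,
            "CTNNB1": ctnnb1,
            "POLE": pole,
            "MMR": mmr,
            "mmr_high_impact": mmr_high,
        }
    )
    for gene, freq in config.gene_freqs.items():
        if gene in ("TP53", "CTNNB1", "POLE"):
            continue
        flags[gene] = rng.random(n) < freq
    flags["subtype"] = [_subtype(t, c) for t, c in zip(tp53, ctnnb1)]
    return flags


def simulate_survival_times(
    rates: np.ndarray,
    rng: np.random.Generator,
    censor_rate: float,
    admin_cap_years: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with independent exponential + administrative censoring."""
    n = len(rates)
    t_event = rng.exponential(1.0 / rates)
    t_cens = rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0 else np.full(n, np.inf)
    t_cens = np.minimum(t_cens, admin_cap_years)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return time, event


_VAF_ARCHITECTURES = {
    1: ([0.42], [1.0]),
    2: ([0.42, 0.18], [0.6, 0.4]),
    3: ([0.45, 0.25, 0.12], [0.5, 0.3, 0.2]),
}
_BETA_CONC = 160.0  # concentration of per-clone Beta VAF components


def draw_vafs(
    n_variants: int, n_clones: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw true VAFs from the per-subtype clonal mixture architecture."""
    means, weights = _VAF_ARCHITECTURES[n_clones]
    comp = rng.choice(len(means), size=n_variants, p=weights)
    mean = np.asarray(means)[comp]
    return rng.beta(mean * _BETA_CONC, (1 - mean) * _BETA_CONC)


def simulate_two_group_survival(
    n: int,
    hr: float,
    seed: int,
    p_group: float = 29 / 112,
    base_rate: float = 0.37 * _TP53M_RATE,
    censor_rate: float = 0.055,
    admin_cap_years: float = 25.0,
) -> pd.DataFrame:
    """Two-group exponential survival cohort with a known true hazard ratio.

    The exposed group (probability ``p_group``) has hazard ``hr`` times
    ``base_rate``; censoring is independent exponential plus an
    administrative cap.  Used for hazard-ratio parameter-recovery studies.
    """
    rng = np.random.default_rng(seed)
    group = rng.random(n) < p_group
    rates = np.where(group, hr * base_rate, base_rate)
    time, event = simulate_survival_times(rates, rng, censor_rate, admin_cap_years)
    return pd.DataFrame(
        {"group": np.where(group, "exposed", "reference"),
         "time": time, "event": event}
    )

# pyrimidine-collapsed substitution classes with a C>T / C>A rich bias
_SNV_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_SNV_WEIGHTS = [0.22, 0.06, 0.40, 0.05, 0.17, 0.10]


def _sample_variants(
    flags: pd.Series,
    tmb: int,
    n_clones: int,
    indel_frac: float,
    coverage: float,
    rng: np.random.Generator,
    driver_genes: list[str],
) -> pd.DataFrame:
    true_vaf = draw_vafs(tmb, n_clones, rng)
    depth = np.maximum(rng.poisson(coverage, size=tmb), 15)
    alt = rng.binomial(depth, true_vaf)
    alt = np.maximum(alt, 1)
    is_indel = rng.random(tmb) < indel_frac

    genes = [f"PSG{rng.integers(1, 20000):05d}" for _ in range(tmb)]
    consequences = list(
        rng.choice(
            ["missense", "nonsense", "synonymous", "other"],
            size=tmb, p=[0.62, 0.08, 0.2, 0.1],
        )
    )
    # place one variant in each mutated driver gene
    mmr_cycle = 0
    for j, gene in enumerate(driver_genes):
        if j >= tmb:
            break
        if gene == "MMR":
            genes[j] = MMR_GENE_CYCLE[mmr_cycle % len(MMR_GENE_CYCLE)]
            mmr_cycle += 1
            consequences[j] = (
                "frameshift_indel" if flags["mmr_high_impact"] else "missense"
            )
            is_indel[j] = consequences[j] == "frameshift_indel"
        else:
            genes[j] = gene
            consequences[j] = "missense"
            is_indel[j] = False
    for j in range(len(driver_genes), tmb):
        if is_indel[j]:
            consequences[j] = str(
                rng.choice(["frameshift_indel", "inframe_indel"], p=[0.7, 0.3])
            )

    refs, alts = [], []
    bases = "ACGT"
    for j in range(tmb):
        if is_indel[j]:
            ins = rng.random() < 0.4
            length = int(rng.integers(1, 4))
            anchor = bases[rng.integers(4)]
            tail = "".join(bases[rng.integers(4)] for _ in range(length))
            if ins:
                refs.append(anchor)
                alts.append(anchor + tail)
            else:
                refs.append(anchor + tail)
                alts.append(anchor)
        else:
            cls = _SNV_CLASSES[rng.choice(6, p=_SNV_WEIGHTS)]
            ref, alt_b = cls.split(">")
            if rng.random() < 0.5:  # random strand
                comp_map = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref, alt_b = comp_map[ref], comp_map[alt_b]
            refs.append(ref)
            alts.append(alt_b)

    return pd.DataFrame(
        {
            "sample_id": flags["sample_id"],
            "chrom": [str(rng.integers(1, 23)) for _ in range(tmb)],
            "pos": rng.integers(1, 200_000_000, size=tmb),
            "ref": refs,
            "alt": alts,
            "gene": genes,
            "consequence": consequences,
            "depth": depth,
            "alt_depth": alt,
            "vaf": alt / depth,
            "true_vaf": true_vaf,
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full synthetic cohort; deterministic given ``config.seed``.

    Returns MAF-style variant records, a clinical table and a truth table
    carrying each sample's generating subtype, clone count and burden.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    flags = draw_mutation_flags(config, rng)
    n = config.n_samples
    if n == 0:
        empty = pd.DataFrame()
        return SimulatedCohort(variants=empty, cohort=empty, truth=empty)

    # mutation burden with hypermutator tail
    r = config.tmb_dispersion
    p = r / (r + config.tmb_mean)
    base_tmb = rng.negative_binomial(r, p, size=n)
    mult = np.ones(n)
    hyper = flags["POLE"].to_numpy() | flags["mmr_high_impact"].to_numpy()
    ultra = flags["POLE"].to_numpy() & flags["MMR"].to_numpy()
    mult[hyper] = config.hypermut_multiplier
    mult[ultra] = config.ultramut_multiplier
    tmb = np.maximum((base_tmb * mult).astype(int), config.tmb_min)

    n_clones = np.where(
        flags["TP53"], rng.integers(2, 4, size=n), 1
    )
    coverage = config.median_coverage * np.exp(
        rng.normal(0.0, config.coverage_sigma, size=n)
    )

    frames = []
    for i in range(n):
        row = flags.iloc[i]
        drivers = [
            g for g in config.gene_freqs if g != "POLE" and row.get(g, False)
        ]
        if row["POLE"]:
            drivers.append("POLE")
        drivers += ["MMR"] * int(row["MMR"])
        indel_frac = (
            config.indel_frac_msi if row["mmr_high_impact"] else config.indel_frac
        )
        frames.append(
            _sample_variants(
                row, int(tmb[i]), int(n_clones[i]), indel_frac,
                float(coverage[i]), rng, drivers,
            )
        )
    variants = pd.concat(frames, ignore_index=True)

    # survival + clinical covariates
    subtype = flags["subtype"].to_numpy()
    rates = np.array([config.survival_rates[s] for s in subtype])
    dss_time, dss_event = simulate_survival_times(
        rates, rng, config.censor_rate, config.admin_cap_years
    )
    pfs_time, pfs_event = simulate_survival_times(
        rates * config.pfs_rate_multiplier, rng,
        config.censor_rate, config.admin_cap_years,
    )
    adv = rng.random(n) < np.array([config.stage_model[s] for s in subtype])
    macro = rng.random(n) < np.array([config.rd_model[s] for s in subtype])
    endo = rng.random(n) < np.array(
        [config.endometrial_model[s] for s in subtype]
    )
    age = np.round(rng.normal(np.where(flags["TP53"], 61.0, 57.0), 10.0), 1)
    cohort = pd.DataFrame(
        {
            "sample_id": flags["sample_id"],
            "age_years": np.clip(age, 25, 95),
            "stage": np.where(adv, "III", "I"),
            "stage_group": np.where(adv, "III_IV", "I_II"),
            "rd": np.where(macro, "macroscopic", "zero_macroscopic"),
            "decade": rng.choice(["1980s", "1990s", "2000s", "2010s"], size=n),
            "concurrent_endometrial": endo,
            "grade": rng.choice(["1", "2", "3"], size=n),
            "dss_time_years": np.round(dss_time, 4),
            "dss_event": dss_event,
            "pfs_time_years": np.round(pfs_time, 4),
            "pfs_event": pfs_event,
        }
    )
    truth = flags.copy()
    truth["n_clones"] = n_clones
    truth["tmb"] = tmb
    truth["coverage"] = coverage
    return SimulatedCohort(variants=variants, cohort=cohort, truth=truth)


def calls_from_frame(variants: pd.DataFrame) -> dict[str, list[VariantCall]]:
    """Convert a MAF-style variants frame to per-sample VariantCall lists."""
    from .io_model import _parse_consequence  # shared alias table

    out: dict[str, list[VariantCall]] = {}
    for row in variants.itertuples(index=False):
        call = VariantCall(
            sample_id=row.sample_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            consequence=_parse_consequence(row.consequence),
            depth=int(row.depth),
            alt_depth=int(row.alt_depth),
        )
        out.setdefault(call.sample_id, []).append(call)
    return out


# ---------------------------------------------------------------------------
# Deterministic fixture cohort


def make_fixture_cohort() -> pd.DataFrame:
    """Build the 112-sample deterministic fixture cohort.

    Marginal and joint counts reproduce the printed cross-tabulations:
    29 TP53m; 48 CTNNB1m with exactly one TP53m/CTNNB1m co-mutant (47/83
    CTNNB1m among TP53wt); SOX8m 10/29 in TP53m vs 11/83 in TP53wt; 20
    MMRm with 18 TP53wt; 7 POLEm with 5 MMRm; stage III/IV 14/29 vs 10/81
    (2 stage-missing); macroscopic RD 12/27 vs 11/78 (7 RD-missing);
    concurrent endometrial carcinoma 1/29 vs 18/83; CTNNB1m subgroup
    41/46 stage I/II and 40/46 zero-RD.  Survival columns are
    deterministic and ordered so the TP53m group has the poorest outcome.
    Validated on construction.
    """
    n = 112
    ids = [f"S{i+1:03d}" for i in range(n)]
    df = pd.DataFrame({"sample_id": ids})
    idx = np.arange(n)

    tp53 = idx < 29
    ctnnb1 = np.zeros(n, bool)
    ctnnb1[0] = True  # the single TP53m/CTNNB1m co-mutant
    ctnnb1[29:76] = True  # 47 TP53wt CTNNB1m
    sox8 = np.zeros(n, bool)
    sox8[1:11] = True  # 10 in TP53m
    sox8[29:40] = True  # 11 in TP53wt
    mmr = np.zeros(n, bool)
    mmr[1:3] = True  # 2 in TP53m
    mmr[76:94] = True  # 18 in TP53wt
    pole = np.zeros(n, bool)
    pole[76:81] = True  # 5 POLEm with MMRm
    pole[94:96] = True  # 2 POLEm without MMRm
    mmr_high = np.zeros(n, bool)
    mmr_high[76:86] = True  # 10 of the 18 TP53wt MMRm are high impact

    stage = np.full(n, "I_II", dtype=object)
    stage[0] = "III_IV"  # co-mutant
    stage[1:14] = "III_IV"  # 13 more TP53m -> 14/29 advanced
    stage[29:31] = "missing"  # the 2 stage-missing cases (CTNNB1m, TP53wt)
    stage[31:35] = "III_IV"  # 4 advanced among evaluable TP53wt CTNNB1m
    stage[76:82] = "III_IV"  # 6 advanced among TP53wt CTNNB1wt

    rd = np.full(n, "zero_macroscopic", dtype=object)
    rd[0] = "macroscopic"
    rd[1:12] = "macroscopic"  # 12/27 macroscopic in TP53m
    rd[27:29] = "missing"  # 2 RD-missing in TP53m
    rd[29:31] = "missing"  # 2 RD-missing in CTNNB1m
    rd[31:36] = "macroscopic"  # 5 macroscopic among TP53wt CTNNB1m
    rd[76:79] = "missing"  # 3 RD-missing in TP53wt CTNNB1wt
    rd[79:85] = "macroscopic"  # 6 macroscopic among TP53wt CTNNB1wt

    endo = np.zeros(n, bool)
    endo[28] = True  # 1/29 in TP53m
    endo[94:112] = True  # 18/83 in TP53wt

    df["tp53"] = tp53
    df["ctnnb1"] = ctnnb1
    df["sox8"] = sox8
    df["mmr"] = mmr
    df["mmr_high_impact"] = mmr_high
    df["pole"] = pole
    df["tp53_status"] = np.where(tp53, "TP53m", "TP53wt")
    df["ctnnb1_status"] = np.where(ctnnb1, "CTNNB1m", "CTNNB1wt")
    df["pole_status"] = np.where(pole, "POLEm", "POLEwt")
    df["mmr_status_binary"] = np.where(mmr, "MMRm", "MMRwt")
    df["stage_group"] = stage
    df["rd"] = rd
    df["concurrent_endometrial"] = endo

    subtype = np.where(tp53, "TP53m", np.where(ctnnb1, "TP53wt_CTNNB1m", "TP53wt_CTNNB1wt"))
    df["subtype"] = subtype

    # deterministic clinical covariates and survival endpoints
    df["age_years"] = np.where(tp53, 61.0, 57.0) + (idx % 7) - 3.0
    df["decade"] = [("1980s", "1990s", "2000s", "2010s")[i % 4] for i in idx]
    df["grade"] = [str(1 + i % 3) for i in idx]
    within = np.concatenate([np.arange(29), np.arange(47), np.arange(36)])
    dss_time = np.empty(n)
    dss_event = np.zeros(n, bool)
    # TP53m: 20 early deaths (median ~3.8 y), 9 long-term censored
    grp = slice(0, 29)
    dss_time[grp] = np.where(within[:29] < 20, 1.0 + 0.3 * within[:29], 12.0 + 0.5 * within[:29])
    dss_event[grp] = within[:29] < 20
    # TP53wt/CTNNB1m: 5 deaths, long censored follow-up
    grp = slice(29, 76)
    dss_time[grp] = np.where(within[29:76] < 5, 4.0 + 1.0 * within[29:76], 10.0 + 0.3 * within[29:76])
    dss_event[grp] = within[29:76] < 5
    # TP53wt/CTNNB1wt: 12 deaths, intermediate
    grp = slice(76, 112)
    dss_time[grp] = np.where(within[76:] < 12, 2.0 + 0.7 * within[76:], 11.0 + 0.4 * within[76:])
    dss_event[grp] = within[76:] < 12
    df["dss_time_years"] = np.round(dss_time, 3)
    df["dss_event"] = dss_event
    df["pfs_time_years"] = np.round(np.maximum(dss_time * 0.7, 0.2), 3)
    df["pfs_event"] = dss_event

    _validate_fixture(df)
    return df


def _validate_fixture(df: pd.DataFrame) -> None:
    """Assert every printed count the fixture must reproduce."""
    t = df["tp53"]
    c = df["ctnnb1"]
    checks = [
        (len(df), 112),
        (int(t.sum()), 29),
        (int(c.sum()), 48),
        (int((t & c).sum()), 1),
        (int((~t & c).sum()), 47),
        (int(df.loc[t, "sox8"].sum()), 10),
        (int(df.loc[~t, "sox8"].sum()), 11),
        (int(df["mmr"].sum()), 20),
        (int(df.loc[~t, "mmr"].sum()), 18),
        (int(df["pole"].sum()), 7),
        (int((df["pole"] & df["mmr"]).sum()), 5),
        (int((df.loc[t, "stage_group"] == "III_IV").sum()), 14),
        (int((df.loc[t, "stage_group"] != "missing").sum()), 29),
        (int((df.loc[~t, "stage_group"] == "III_IV").sum()), 10),
        (int((df.loc[~t, "stage_group"] != "missing").sum()), 81),
        (int((df.loc[t, "rd"] == "macroscopic").sum()), 12),
        (int((df.loc[t, "rd"] != "missing").sum()), 27),
        (int((df.loc[~t, "rd"] == "macroscopic").sum()), 11),
        (int((df.loc[~t, "rd"] != "missing").sum()), 78),
        (int(df.loc[t, "concurrent_endometrial"].sum()), 1),
        (int(df.loc[~t, "concurrent_endometrial"].sum()), 18),
        (int((df.loc[c, "stage_group"] == "I_II").sum()), 41),
        (int((df.loc[c, "stage_group"] != "missing").sum()), 46),
        (int((df.loc[c, "rd"] == "zero_macroscopic").sum()), 40),
        (int((df.loc[c, "rd"] != "missing").sum()), 46),
    ]
    for got, want in checks:
        if got != want:
            raise AssertionError(f"fixture validation failed: got {got}, want {want}")


def load_fixture() -> pd.DataFrame:
    """Load the packaged fixture cohort CSV (identical to make_fixture_cohort)."""
    with resources.files("enoc_strat.data").joinpath("fixture_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("tp53", "ctnnb1", "sox8", "mmr", "mmr_high_impact", "pole",
                "concurrent_endometrial", "dss_event", "pfs_event"):
        df[col] = df[col].astype(bool)
    df["grade"] = df["grade"].astype(str)
    return df
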