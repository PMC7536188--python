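"""Domain types and readers/writers for variant, clinical and copy-number inputs.

Coordinates are 1-based and fully closed throughout (MAF/VCF convention).
Alleles at a site are normalised by trimming shared suffix bases before
shared prefix bases (VCF parsimony convention), so equivalent InDel
representations produced by different callers collide on one key.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "ClinVar",
    "PolyPhen",
    "Sift",
    "MutatorClass",
    "MmrStatus",
    "VariantCall",
    "SampleProfile",
    "CohortRecord",
    "GeneMutationMatrix",
    "VariantKey",
    "normalize_key",
    "read_maf",
    "read_caller_vcfs",
    "read_clinical",
    "read_cn_matrix",
    "write_profiles",
    "read_profiles",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Truncating consequence classes treated as functional regardless of
#: in-silico predictions.
TRUNCATING = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT_INDEL, Consequence.SPLICE_SITE}
)

# Accepts both our canonical names and the common GDC-MAF vocabulary.
_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_mutation": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "nonsense_mutation": Consequence.NONSENSE,
    "stop_gained": Consequence.NONSENSE,
    "frameshift_indel": Consequence.FRAMESHIFT_INDEL,
    "frame_shift_del": Consequence.FRAMESHIFT_INDEL,
    "frame_shift_ins": Consequence.FRAMESHIFT_INDEL,
    "frameshift_variant": Consequence.FRAMESHIFT_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "in_frame_del": Consequence.INFRAME_INDEL,
    "in_frame_ins": Consequence.INFRAME_INDEL,
    "splice_site": Consequence.SPLICE_SITE,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "synonymous": Consequence.SYNONYMOUS,
    "silent": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}


class ClinVar(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class PolyPhen(str, enum.Enum):
    DAMAGING = "damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class Sift(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class MutatorClass(str, enum.Enum):
    NORMAL = "normal"
    HYPERMUTATED = "hypermutated"
    ULTRAMUTATED = "ultramutated"


class MmrStatus(str, enum.Enum):
    WT = "wt"
    MISSENSE_ONLY = "missense_only"
    HIGH_IMPACT = "high_impact"


#: The six pyrimidine-collapsed single-nucleotide substitution classes.
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class VariantCall:
    """One annotated somatic variant observation in one sample.

    ``vaf`` is recomputed from ``alt_depth / depth`` when not supplied.
    An InDel is any call with ``len(ref) != len(alt)``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    depth: int
    alt_depth: int
    vaf: float | None = None
    callers: frozenset[str] = field(default_factory=frozenset)
    population_af: float | None = None
    clinvar: ClinVar = ClinVar.UNKNOWN
    polyphen: PolyPhen = PolyPhen.MISSING
    sift: Sift = Sift.MISSING
    orientation_bias_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} > depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        computed = self.alt_depth / self.depth if self.depth > 0 else 0.0
        if self.vaf is None:
            self.vaf = computed
        elif self.depth > 0 and abs(self.vaf - computed) > 1e-9:
            raise ValueError(
                f"vaf {self.vaf} inconsistent with alt_depth/depth {computed:.6g}"
            )
        self.callers = frozenset(self.callers)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> "VariantKey":
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleProfile:
    """Per-sample derived mutation metrics."""

    sample_id: str
    tmb: int
    msi_score: int
    spectrum: tuple[float, ...]  # fractions over SPECTRUM_CLASSES
    math_score: float | None
    n_vaf_peaks: int | None
    mutated_genes: frozenset[str]
    mutator_class: MutatorClass
    mmr_status: MmrStatus
    cna_burden: int | None = None

    def __post_init__(self) -> None:
        if len(self.spectrum) != 6:
            raise ValueError("spectrum must have 6 fractions")
        if any(not (0.0 <= f <= 1.0) for f in self.spectrum):
            raise ValueError("spectrum fractions must lie in [0, 1]")
        if self.mutator_class is MutatorClass.ULTRAMUTATED and self.tmb <= 1000:
            raise ValueError("ultramutated requires tmb > 1000")
        if self.mutator_class is MutatorClass.HYPERMUTATED and self.tmb <= 250:
            raise ValueError("hypermutated requires tmb > 250")
        self.mutated_genes = frozenset(self.mutated_genes)


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    MISSING = "missing"


class ResidualDisease(str, enum.Enum):
    ZERO_MACROSCOPIC = "zero_macroscopic"
    MACROSCOPIC = "macroscopic"
    MISSING = "missing"


@dataclass
class CohortRecord:
    """Per-sample clinical covariates and survival endpoints.

    DSS is disease-specific survival (death from disease is the event;
    death from other causes is censored at death); PFS is progression-free
    survival.  Times are years from pathologically confirmed diagnosis.
    """

    sample_id: str
    age_years: float
    stage: Stage
    rd: ResidualDisease
    decade: str
    concurrent_endometrial: bool
    grade: str
    dss_time_years: float
    dss_event: bool
    pfs_time_years: float
    pfs_event: bool

    def __post_init__(self) -> None:
        if self.dss_time_years < 0 or self.pfs_time_years < 0:
            raise ValueError("survival times must be non-negative")


@dataclass
class GeneMutationMatrix:
    """Binary samples x genes mutation-status matrix (1 = mutant, 0 = wild-type)."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_samples, n_genes), entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("matrix shape does not match sample/gene lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]


# ---------------------------------------------------------------------------
# Variant-key normalisation

VariantKey = tuple[str, int, str, str]


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce (chrom, pos, ref, alt) to its parsimonious representation.

    Shared allele *suffix* bases are removed first, then shared *prefix*
    bases (advancing ``pos`` for each prefix base removed), so equivalent
    spellings of the same InDel collide — e.g. the deletion written as
    ``pos 100 ATT>AT`` and as ``pos 101 TT>T`` both normalise to
    ``(101, "T", "")``.  A pure insertion/deletion therefore ends with one
    empty allele; keys are internal identifiers, not VCF records.  The
    operation is idempotent.  Left-alignment *through* a repeat run would
    need the reference sequence and is not attempted: padding invariance
    is exact whenever the trimmed alleles are both non-empty.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


# ---------------------------------------------------------------------------
# MAF-style TSV

MAF_REQUIRED_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "depth",
    "alt_depth",
)

_MAF_OPTIONAL_DEFAULTS = {
    "callers": "",
    "population_af": "",
    "clinvar": "unknown",
    "polyphen": "missing",
    "sift": "missing",
    "orientation_bias_flag": "False",
}


def _parse_consequence(raw: str) -> Consequence:
    key = str(raw).strip().lower()
    if key not in _CONSEQUENCE_ALIASES:
        raise ValueError(f"unknown consequence {raw!r}")
    return _CONSEQUENCE_ALIASES[key]


def _parse_bool(raw) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    return str(raw).strip().lower() in {"true", "1", "yes", "t"}


def read_maf(path: str | Path) -> list[VariantCall]:
    """Read a MAF-style TSV into :class:`VariantCall` records.

    The header must name all of :data:`MAF_REQUIRED_COLUMNS`; unknown
    columns are ignored.  Rows with unparseable or invariant-violating
    fields raise :class:`FormatError` naming the 1-based data-row number.
    VAF is always recomputed from ``alt_depth / depth``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file {path} missing mandatory column(s): {missing}")
    if df.empty:
        logger.warning("MAF file %s contains no data rows", path)
        return []
    for col, default in _MAF_OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    records: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pop_af = str(row.population_af).strip()
            records.append(
                VariantCall(
                    sample_id=str(row.sample_id).strip(),
                    chrom=str(row.chrom).strip(),
                    pos=int(row.pos),
                    ref=str(row.ref).strip().upper(),
                    alt=str(row.alt).strip().upper(),
                    gene=str(row.gene).strip(),
                    consequence=_parse_consequence(row.consequence),
                    depth=int(row.depth),
                    alt_depth=int(row.alt_depth),
                    callers=frozenset(
                        c.strip()
                        for c in str(row.callers).replace(",", ";").split(";")
                        if c.strip()
                    ),
                    population_af=float(pop_af) if pop_af else None,
                    clinvar=ClinVar(str(row.clinvar).strip().lower() or "unknown"),
                    polyphen=PolyPhen(str(row.polyphen).strip().lower() or "missing"),
                    sift=Sift(str(row.sift).strip().lower() or "missing"),
                    orientation_bias_flag=_parse_bool(row.orientation_bias_flag),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"MAF file {path}, data row {i}: {exc}") from exc
    return records


def write_maf(variants: Iterable[VariantCall], path: str | Path) -> None:
    """Write variants back to the MAF-style TSV schema read by :func:`read_maf`."""
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "depth": v.depth,
                "alt_depth": v.alt_depth,
                "callers": ";".join(sorted(v.callers)),
                "population_af": "" if v.population_af is None else v.population_af,
                "clinvar": v.clinvar.value,
                "polyphen": v.polyphen.value,
                "sift": v.sift.value,
                "orientation_bias_flag": v.orientation_bias_flag,
            }
        )
    cols = list(MAF_REQUIRED_COLUMNS) + list(_MAF_OPTIONAL_DEFAULTS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-caller VCF-lite

def read_caller_vcfs(
    paths: Mapping[str, str | Path],
) -> dict[VariantKey, set[str]]:
    """Read per-caller VCF-lite files and pool caller support per variant key.

    Each file holds tab-separated ``CHROM POS ID REF ALT ...`` data lines
    (``#``-prefixed header lines ignored).  Multi-allelic ALT fields are
    split and voted per alternate allele.  Keys are normalised with
    :func:`normalize_key` so equivalent InDel spellings collide.
    """
    support: dict[VariantKey, set[str]] = {}
    for caller, path in paths.items():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n\r")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise FormatError(
                        f"{path}, line {lineno}: expected >= 5 tab-separated "
                        f"fields (CHROM POS ID REF ALT), got {len(fields)}"
                    )
                chrom, pos_s, _id, ref, alt_field = fields[:5]
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}, line {lineno}: non-integer POS {pos_s!r}"
                    ) from exc
                for alt in alt_field.split(","):
                    alt = alt.strip()
                    if not alt or alt == ".":
                        continue
                    key = normalize_key(chrom, pos, ref, alt)
                    support.setdefault(key, set()).add(caller)
    return support


# ---------------------------------------------------------------------------
# Clinical CSV

def read_clinical(path: str | Path) -> list[CohortRecord]:
    """Read the cohort clinical CSV into :class:`CohortRecord` rows."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        "sample_id", "age_years", "stage", "rd", "decade",
        "concurrent_endometrial", "grade",
        "dss_time_years", "dss_event", "pfs_time_years", "pfs_event",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"clinical CSV {path} missing column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                CohortRecord(
                    sample_id=str(row.sample_id),
                    age_years=float(row.age_years),
                    stage=Stage(str(row.stage).strip() or "missing"),
                    rd=ResidualDisease(str(row.rd).strip() or "missing"),
                    decade=str(row.decade),
                    concurrent_endometrial=_parse_bool(row.concurrent_endometrial),
                    grade=str(row.grade),
                    dss_time_years=float(row.dss_time_years),
                    dss_event=_parse_bool(row.dss_event),
                    pfs_time_years=float(row.pfs_time_years),
                    pfs_event=_parse_bool(row.pfs_event),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"clinical CSV {path}, data row {i}: {exc}") from exc
    return records


def read_cn_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples copy-number score TSV (gene symbols as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"copy-number matrix {path} is empty")
    return df.astype(float)


# ---------------------------------------------------------------------------
# SampleProfile TSV round-trip

_PROFILE_COLUMNS = (
    ["sample_id", "tmb", "msi_score"]
    + [f"spectrum_{c.replace('>', '_')}" for c in SPECTRUM_CLASSES]
    + ["math_score", "n_vaf_peaks", "mutated_genes", "mutator_class",
       "mmr_status", "cna_burden"]
)


def write_profiles(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    """Write profiles as TSV with a deterministic column order.

    Round-trips losslessly through :func:`read_profiles`; the six spectrum
    fractions are serialised to fixed columns.
    """
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "tmb": p.tmb,
            "msi_score": p.msi_score,
            "math_score": "" if p.math_score is None else repr(float(p.math_score)),
            "n_vaf_peaks": "" if p.n_vaf_peaks is None else p.n_vaf_peaks,
            "mutated_genes": ";".join(sorted(p.mutated_genes)),
            "mutator_class": p.mutator_class.value,
            "mmr_status": p.mmr_status.value,
            "cna_burden": "" if p.cna_burden is None else p.cna_burden,
        }
        for cls, frac in zip(SPECTRUM_CLASSES, p.spectrum):
            row[f"spectrum_{cls.replace('>', '_')}"] = repr(float(frac))
        rows.append(row)
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[SampleProfile]:
    """Read a profiles TSV written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"profile TSV {path} missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        spectrum = tuple(
            float(d[f"spectrum_{c.replace('>', '_')}"]) for c in SPECTRUM_CLASSES
        )
        out.append(
            SampleProfile(
                sample_id=d["sample_id"],
                tmb=int(d["tmb"]),
                msi_score=int(d["msi_score"]),
                spectrum=spectrum,
                math_score=float(d["math_score"]) if d["math_score"] else None,
                n_vaf_peaks=int(d["n_vaf_peaks"]) if d["n_vaf_peaks"] else None,
                mutated_genes=frozenset(
                    g for g in d["mutated_genes"].split(";") if g
                ),
                mutator_class=MutatorClass(d["mutator_class"]),
                mmr_status=MmrStatus(d["mmr_status"]),
                cna_burden=int(d["cna_burden"]) if d["cna_burden"] else None,
            )
        )
    return out
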