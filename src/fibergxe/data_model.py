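"""Domain types, phenotype/genotype I/O, exposure derivation and exclusion filters.

The unit of analysis is a matched pair: one incident obesity case and one
normal-weight control drawn from the same cohort, matched on sex and age
(within five years). Dietary fiber is analysed as a nutrient density —
grams per 4186 kJ (= 1000 kcal) of reported energy intake — which removes
the trivial correlation between absolute fiber and total energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError
from .genetics import SnpPanel

__all__ = [
    "KJ_PER_DENSITY_UNIT",
    "SubjectRecord",
    "GenotypeMatrix",
    "ExposureRecord",
    "OutcomeFlags",
    "OutcomeThresholds",
    "MatchedCohort",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "read_genotypes_vcf",
    "fiber_density",
    "assign_quartiles",
    "classify_outcomes",
    "energy_misreport_filter",
]

log = logging.getLogger(__name__)

#: energy denominator of the fiber-density unit: g per 4186 kJ == g per 1000 kcal
KJ_PER_DENSITY_UNIT = 4186.0

SEX_CODES = ("M", "F")
SMOKING_CODES = ("current", "ex", "never")
ACTIVITY_CODES = ("low", "moderate", "high")


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: phenotype, diet and matching information."""

    subject_id: str
    matched_set_id: str
    is_case: bool
    age: float  # years
    sex: str  # "M" / "F"
    bmi: float  # kg/m^2
    waist: float  # cm
    hip: float  # cm
    energy: float  # kJ/day
    fiber: float  # g/day
    education_years: float
    smoking: str  # current / ex / never
    activity: str  # low / moderate / high

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValidationError(f"{self.subject_id}: sex must be one of {SEX_CODES}")
        if self.smoking not in SMOKING_CODES:
            raise ValidationError(f"{self.subject_id}: smoking must be one of {SMOKING_CODES}")
        if self.activity not in ACTIVITY_CODES:
            raise ValidationError(f"{self.subject_id}: activity must be one of {ACTIVITY_CODES}")
        if not self.energy > 0:
            raise ValidationError(f"{self.subject_id}: energy must be positive")
        if self.fiber < 0:
            raise ValidationError(f"{self.subject_id}: fiber must be non-negative")
        if not self.bmi > 0:
            raise ValidationError(f"{self.subject_id}: bmi must be positive")
        if not self.hip > 0:
            raise ValidationError(f"{self.subject_id}: hip must be positive")


_PHENOTYPE_COLUMNS = [f.name for f in fields(SubjectRecord)]
_NUMERIC_FIELDS = ("age", "bmi", "waist", "hip", "energy", "fiber", "education_years")


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read subject phenotypes from a delimited text file (CSV or TSV).

    The header must name every :class:`SubjectRecord` field; row order is
    preserved. A missing column raises :class:`FormatError` naming it; an
    unparseable numeric raises :class:`FormatError` citing the 1-based file
    line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _PHENOTYPE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[SubjectRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        kwargs: dict[str, object] = {}
        for name in _PHENOTYPE_COLUMNS:
            raw = getattr(row, name)
            if name in _NUMERIC_FIELDS:
                try:
                    kwargs[name] = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}, line {line_no}: cannot parse {name}={raw!r} as a number"
                    ) from exc
            elif name == "is_case":
                lowered = str(raw).strip().lower()
                if lowered in ("1", "true", "case", "yes"):
                    kwargs[name] = True
                elif lowered in ("0", "false", "control", "no"):
                    kwargs[name] = False
                else:
                    raise FormatError(
                        f"{path}, line {line_no}: cannot parse is_case={raw!r} as a boolean"
                    )
            else:
                kwargs[name] = str(raw)
        try:
            records.append(SubjectRecord(**kwargs))
        except ValidationError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
    return records


def write_phenotypes(records: Sequence[SubjectRecord], path: str | Path, sep: str = ",") -> None:
    """Write subject records as delimited text; inverse of :func:`read_phenotypes`."""
    frame = records_to_frame(records)
    frame["is_case"] = frame["is_case"].astype(int)
    frame.to_csv(path, sep=sep, index=False)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a DataFrame with one column per field."""
    return pd.DataFrame(
        [{name: getattr(r, name) for name in _PHENOTYPE_COLUMNS} for r in records],
        columns=_PHENOTYPE_COLUMNS,
    )


@dataclass
class GenotypeMatrix:
    """Risk-allele dose (0/1/2, NaN = missing) per subject per panel SNP."""

    subject_ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray  # float array, shape (n_subjects, n_snps)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValidationError("genotype doses must be 0, 1, 2 or missing")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject_id in genotype matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.subject_ids, columns=self.snp_ids)

    def dose(self, snp_id: str) -> pd.Series:
        return self.to_frame()[snp_id]


def read_genotypes(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read genotype calls and recode them as risk-allele doses.

    Expects a TSV with a ``subject_id`` column and one column per panel SNP
    holding two-character allele pairs (e.g. ``GT``); ``NN``, ``--`` or an
    empty cell mean missing. Alleles inconsistent with the panel raise
    :class:`FormatError`. Files ending in ``.vcf`` are dispatched to
    :func:`read_genotypes_vcf`.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_genotypes_vcf(path, panel)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "subject_id" not in frame.columns:
        raise FormatError(f"{path}: missing required column subject_id")
    missing_snps = [s for s in panel.snp_ids if s not in frame.columns]
    if missing_snps:
        raise FormatError(f"{path}: missing SNP column(s): {', '.join(missing_snps)}")
    subject_ids = frame["subject_id"].tolist()
    counts = np.full((len(subject_ids), len(panel)), np.nan)
    for j, snp in enumerate(panel):
        valid = {snp.major_allele, snp.minor_allele}
        for i, call in enumerate(frame[snp.snp_id]):
            call = call.strip().upper()
            if call in ("", "NN", "--", "NA", "."):
                continue
            if len(call) != 2 or not set(call) <= valid:
                raise FormatError(
                    f"{path}: subject {subject_ids[i]!r}, SNP {snp.snp_id}: "
                    f"call {call!r} inconsistent with alleles {sorted(valid)}"
                )
            counts[i, j] = call.count(snp.risk_allele)
    return GenotypeMatrix(subject_ids=subject_ids, snp_ids=panel.snp_ids, counts=counts)


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Minimal VCF reader: biallelic sites, GT field only, uncompressed text."""
    path = Path(path)
    samples: list[str] | None = None
    by_snp: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            if samples is None:
                raise FormatError(f"{path}: data line before #CHROM header")
            snp_id, ref, alt = parts[2], parts[3], parts[4]
            if snp_id not in panel.snp_ids:
                continue
            snp = panel[snp_id]
            if "," in alt:
                raise FormatError(f"{path}: {snp_id} is not biallelic (ALT={alt!r})")
            if {ref, alt} != {snp.major_allele, snp.minor_allele}:
                raise FormatError(
                    f"{path}: {snp_id} alleles {ref}/{alt} inconsistent with panel "
                    f"{snp.major_allele}/{snp.minor_allele}"
                )
            fmt = parts[8].split(":")
            try:
                gt_index = fmt.index("GT")
            except ValueError as exc:
                raise FormatError(f"{path}: {snp_id} has no GT field") from exc
            risk_is_alt = snp.risk_allele == alt
            doses = np.full(len(samples), np.nan)
            for i, cell in enumerate(parts[9:]):
                gt = cell.split(":")[gt_index].replace("|", "/")
                if "." in gt:
                    continue
                alleles = gt.split("/")
                if len(alleles) != 2 or not set(alleles) <= {"0", "1"}:
                    raise FormatError(f"{path}: {snp_id} sample {samples[i]}: bad GT {gt!r}")
                n_alt = sum(a == "1" for a in alleles)
                doses[i] = n_alt if risk_is_alt else 2 - n_alt
            by_snp[snp_id] = doses
    if samples is None:
        raise FormatError(f"{path}: no #CHROM header found")
    missing = [s for s in panel.snp_ids if s not in by_snp]
    if missing:
        raise FormatError(f"{path}: missing panel SNP record(s): {', '.join(missing)}")
    counts = np.column_stack([by_snp[s] for s in panel.snp_ids])
    return GenotypeMatrix(subject_ids=list(samples), snp_ids=panel.snp_ids, counts=counts)


def write_genotypes(
    matrix: GenotypeMatrix, panel: SnpPanel, path: str | Path
) -> None:
    """Write a genotype matrix as the allele-pair TSV that :func:`read_genotypes` reads."""
    columns: dict[str, list[str]] = {"subject_id": list(matrix.subject_ids)}
    for j, snp in enumerate(panel):
        calls = []
        for dose in matrix.counts[:, j]:
            if np.isnan(dose):
                calls.append("NN")
            else:
                n_risk = int(dose)
                calls.append(snp.risk_allele * n_risk + snp.nonrisk_allele * (2 - n_risk))
        columns[snp.snp_id] = calls
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def fiber_density(fiber, energy):
    """Fiber intake as a nutrient density: g per 4186 kJ of reported energy.

    Accepts scalars or arrays; ``energy`` must be strictly positive.
    """
    fiber = np.asarray(fiber, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if (energy <= 0).any():
        raise DomainError("energy must be positive to form a fiber density")
    out = fiber * KJ_PER_DENSITY_UNIT / energy
    return float(out) if out.ndim == 0 else out


#: quartile cutoffs of fiber density (g/4186 kJ) as printed for the source cohort
PRINTED_FIBER_CUTOFFS = (7.06, 9.13, 11.26)


def assign_quartiles(
    densities: Sequence[float] | np.ndarray,
    cutoffs: Sequence[float] | None = None,
) -> tuple[np.ndarray, dict[int, float]]:
    """Assign fiber-density quartiles and return per-quartile medians.

    With ``cutoffs=None`` the three cut points are the empirical 25/50/75
    percentiles of the input. With fixed cutoffs ``(c1, c2, c3)`` the
    intervals are closed as printed at 2-decimal resolution: Q1 < c1,
    c1 <= Q2 <= c2, c2 < Q3 <= c3, Q4 > c3, after rounding each value to two
    decimals so that a value in a printed gap (e.g. 9.135 between "9.13" and
    "9.14") falls to the nearer interval.

    Returns ``(labels, medians)`` where labels are 1..4 and ``medians`` maps
    each occupied quartile to the median density of its members (the trend
    test's continuous scores).
    """
    d = np.asarray(densities, dtype=float)
    if d.ndim != 1:
        raise DomainError("densities must be one-dimensional")
    if cutoffs is None:
        if d.size < 4:
            raise DomainError("need at least 4 subjects to form empirical quartiles")
        c1, c2, c3 = np.percentile(d, [25, 50, 75])
        values = d
    else:
        if len(cutoffs) != 3:
            raise DomainError("cutoffs must be three increasing values")
        c1, c2, c3 = cutoffs
        values = np.round(d, 2)
    if not (c1 <= c2 <= c3):
        raise DomainError("cutoffs must be non-decreasing")
    labels = np.select(
        [values < c1, values <= c2, values <= c3], [1, 2, 3], default=4
    ).astype(int)
    medians = {q: float(np.median(d[labels == q])) for q in (1, 2, 3, 4) if (labels == q).any()}
    return labels, medians


@dataclass(frozen=True)
class ExposureRecord:
    """Derived fiber exposure for one subject."""

    fiber_density: float  # g per 4186 kJ
    quartile: int  # 1..4
    high_fiber: bool  # absolute intake >= 14 g/day


#: absolute fiber intake (g/day) separating the high/low strata
HIGH_FIBER_CUTOFF_G_DAY = 14.0


@dataclass(frozen=True)
class OutcomeThresholds:
    """Anthropometric cutoffs; defaults exactly as used in the source analysis."""

    bmi_obese: float = 30.0  # kg/m^2, inclusive
    waist_abdominal: float = 95.0  # cm, exclusive, both sexes
    whr_male: float = 0.8  # exclusive
    whr_female: float = 0.9  # exclusive


@dataclass(frozen=True)
class OutcomeFlags:
    obese: bool
    abdominal_obese: bool
    high_whr: bool


def classify_outcomes(
    record: SubjectRecord, thresholds: OutcomeThresholds | None = None
) -> OutcomeFlags:
    """Deterministic obesity phenotype flags for one subject.

    ``obese``: BMI at or above 30 kg/m^2. ``abdominal_obese``: waist above
    95 cm in either sex. ``high_whr``: waist-to-hip ratio above 0.8 (men) or
    0.9 (women) — thresholds are configurable via :class:`OutcomeThresholds`.
    """
    t = thresholds or OutcomeThresholds()
    if record.hip <= 0:
        raise DomainError(f"{record.subject_id}: hip must be positive to form WHR")
    whr = record.waist / record.hip
    whr_cut = t.whr_male if record.sex == "M" else t.whr_female
    return OutcomeFlags(
        obese=record.bmi >= t.bmi_obese,
        abdominal_obese=record.waist > t.waist_abdominal,
        high_whr=whr > whr_cut,
    )


def _sex_mean_energy_predictor(records: Sequence[SubjectRecord]) -> np.ndarray:
    """Default energy-requirement predictor: sex-specific mean reported intake."""
    energy = np.array([r.energy for r in records])
    sex = np.array([r.sex for r in records])
    pred = np.empty_like(energy)
    for code in SEX_CODES:
        mask = sex == code
        if mask.any():
            pred[mask] = energy[mask].mean()
    return pred


def energy_misreport_filter(
    records: Sequence[SubjectRecord],
    predictor: Callable[[Sequence[SubjectRecord]], np.ndarray] | None = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Drop implausible energy reporters (and their matched partners).

    Each subject's reported energy intake is divided by a predicted intake
    (default predictor: sex-specific sample mean; any callable mapping the
    record list to positive predictions may be supplied). Subjects whose
    ratio falls outside mean +/- 3 SD of the ratio distribution are removed,
    along with every other member of their matched set, so the 1:1 structure
    survives filtering. Returns the kept records plus an exclusion log with
    columns ``subject_id, matched_set_id, ratio, reason``.
    """
    empty_log = pd.DataFrame(columns=["subject_id", "matched_set_id", "ratio", "reason"])
    if len(records) == 0:
        return [], empty_log
    predictor = predictor or _sex_mean_energy_predictor
    predicted = np.asarray(predictor(records), dtype=float)
    if predicted.shape != (len(records),) or (predicted <= 0).any():
        raise DomainError("predictor must return one positive prediction per subject")
    ratios = np.array([r.energy for r in records]) / predicted
    sd = ratios.std(ddof=1) if len(records) > 1 else 0.0
    if sd == 0:  # degenerate spread: nothing can be an outlier
        return list(records), empty_log
    lo, hi = ratios.mean() - 3 * sd, ratios.mean() + 3 * sd
    outliers = (ratios < lo) | (ratios > hi)
    dropped_sets = {r.matched_set_id for r, bad in zip(records, outliers) if bad}
    kept, log_rows = [], []
    for record, ratio, bad in zip(records, ratios, outliers):
        if bad:
            log_rows.append((record.subject_id, record.matched_set_id, ratio, "misreport"))
        elif record.matched_set_id in dropped_sets:
            log_rows.append((record.subject_id, record.matched_set_id, ratio, "partner"))
        else:
            kept.append(record)
    for sid, mid, ratio, reason in log_rows:
        log.info("excluding %s (set %s): energy ratio %.3f [%s]", sid, mid, ratio, reason)
    return kept, pd.DataFrame(log_rows, columns=empty_log.columns)


@dataclass
class MatchedCohort:
    """A validated 1:1 matched case-control cohort with genotypes."""

    records: list[SubjectRecord]
    genotypes: GenotypeMatrix
    panel: SnpPanel

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, *, strict_matching: bool = False) -> None:
        """Check the 1-case/1-control set structure (and optionally matching rules)."""
        by_set: dict[str, list[SubjectRecord]] = {}
        for r in self.records:
            by_set.setdefault(r.matched_set_id, []).append(r)
        for set_id, members in by_set.items():
            n_cases = sum(r.is_case for r in members)
            if n_cases != 1 or len(members) < 2:
                raise ValidationError(
                    f"matched set {set_id!r}: need exactly 1 case and >=1 control, "
                    f"got {n_cases} case(s) among {len(members)} member(s)"
                )
            if strict_matching:
                case = next(r for r in members if r.is_case)
                for ctrl in (r for r in members if not r.is_case):
                    if ctrl.sex != case.sex:
                        raise ValidationError(f"matched set {set_id!r}: sexes differ")
                    if abs(ctrl.age - case.age) > 5:
                        raise ValidationError(f"matched set {set_id!r}: age difference > 5 years")
        geno_ids = set(self.genotypes.subject_ids)
        missing = [r.subject_id for r in self.records if r.subject_id not in geno_ids]
        if missing:
            raise ValidationError(f"subjects without genotypes: {missing[:5]}...")

    @property
    def n_sets(self) -> int:
        return len({r.matched_set_id for r in self.records})

    def phenotype_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def dose_frame(self) -> pd.DataFrame:
        """Genotype doses aligned to the phenotype record order."""
        return self.genotypes.to_frame().loc[[r.subject_id for r in self.records]]
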