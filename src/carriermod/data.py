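"""Core data containers and file I/O for carrier-cohort analyses.

The analysis unit is a *mutation carrier*: a woman carrying a pathogenic
variant in a high-risk gene, followed from age 18 for breast and ovarian
cancer. Records carry the event and censoring ages needed to build the two
single-disease endpoint views and the joint competing-risks endpoint.

Conventions
-----------
* Ages are in years; hazard lookups floor to whole years on an 18-80 grid.
* Within-year ties are broken with priority breast < ovarian < surgery <
  censoring.
* Genotypes count copies of allele 2 (the ALT / minor-labelled allele of the
  input file); dosages are expected allele-2 counts in [0, 2].
* Allele-2 frequency is always recomputed from data, never trusted from
  metadata; the conventional reported frequency is taken among unaffected
  carriers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CarrierRecord",
    "EndpointView",
    "CompetingEndpoint",
    "SNPRecord",
    "GenotypeMatrix",
    "IncidenceCurve",
    "EffectTable",
    "PhenotypeValidationError",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "endpoint_view",
    "competing_endpoint",
]

AGE_MIN = 18
AGE_MAX = 100
GRID_START = 18
GRID_END = 80

MUTATION_CLASSES = ("class1", "class2", "other")
ER_STATUSES = ("positive", "negative", "unknown")

_AGE_FIELDS = ("age_last_followup", "age_bc", "age_oc", "age_mastectomy", "age_rrso")


class PhenotypeValidationError(ValueError):
    """Raised when a phenotype row violates a record invariant."""


@dataclass
class CarrierRecord:
    """One mutation carrier's phenotype.

    Absent event ages are ``None``. ``stratum`` is the country (or
    super-stratum) label used for stratified analyses; ``aj_flag`` marks
    Ashkenazi ancestry used to split North-American strata.
    """

    sample_id: str
    family_id: str
    stratum: str
    aj_flag: bool = False
    birth_year: int = 1950
    age_last_followup: float = 50.0
    age_bc: float | None = None
    age_oc: float | None = None
    age_mastectomy: float | None = None
    age_rrso: float | None = None
    mutation_class: str = "other"
    er_status: str = "unknown"

    def validate(self) -> None:
        for name in _AGE_FIELDS:
            v = getattr(self, name)
            if v is None:
                if name == "age_last_followup":
                    raise PhenotypeValidationError("age_last_followup is mandatory")
                continue
            if not np.isfinite(v):
                raise PhenotypeValidationError(f"{name} is not a finite number")
            if not (AGE_MIN <= v <= AGE_MAX):
                raise PhenotypeValidationError(
                    f"{name}={v} outside the allowed range [{AGE_MIN}, {AGE_MAX}]"
                )
        if self.mutation_class not in MUTATION_CLASSES:
            raise PhenotypeValidationError(
                f"mutation_class={self.mutation_class!r} not one of {MUTATION_CLASSES}"
            )
        if self.er_status not in ER_STATUSES:
            raise PhenotypeValidationError(
                f"er_status={self.er_status!r} not one of {ER_STATUSES}"
            )


@dataclass(frozen=True)
class EndpointView:
    """Single-disease endpoint: follow-up time and affection status."""

    time: float
    affected: bool
    disease: str


@dataclass(frozen=True)
class CompetingEndpoint:
    """Joint two-disease endpoint with disease-specific at-risk horizons.

    Follow-up for events stops at the first cancer diagnosis; each disease
    additionally has its own surgical censoring (mastectomy for breast, RRSO
    for ovarian), so the two at-risk horizons may differ.
    """

    time_bc: float
    event_bc: bool
    time_oc: float
    event_oc: bool

    @property
    def event(self) -> str:
        if self.event_bc:
            return "breast"
        if self.event_oc:
            return "ovarian"
        return "none"

    @property
    def time(self) -> float:
        """Age at first cancer, or the later of the two censoring horizons."""
        if self.event_bc:
            return self.time_bc
        if self.event_oc:
            return self.time_oc
        return max(self.time_bc, self.time_oc)


# tie priority: smaller rank wins when ages are equal
_PRIORITY = {"bc": 0, "oc": 1, "surgery": 2, "censor": 3}


def _first_event(candidates: list[tuple[float | None, str]]) -> tuple[float, str]:
    present = [(t, k) for t, k in candidates if t is not None]
    return min(present, key=lambda tk: (tk[0], _PRIORITY[tk[1]]))


def endpoint_view(record: CarrierRecord, disease: str) -> EndpointView:
    """Map a carrier record to the single-disease censoring convention.

    Breast view: follow-up ends at the first of breast cancer, ovarian
    cancer, bilateral mastectomy, or last observation; affected only if
    breast cancer comes first (an ovarian diagnosis censors).

    Ovarian view: follow-up ends at the first of ovarian cancer, RRSO, or
    last observation. Breast cancer is *not* a censoring event here, so
    ovarian cancer diagnosed after a breast cancer still counts as affected.
    """
    if disease == "breast":
        t, kind = _first_event(
            [
                (record.age_bc, "bc"),
                (record.age_oc, "oc"),
                (record.age_mastectomy, "surgery"),
                (record.age_last_followup, "censor"),
            ]
        )
        return EndpointView(time=t, affected=kind == "bc", disease="breast")
    if disease == "ovarian":
        t, kind = _first_event(
            [
                (record.age_oc, "oc"),
                (record.age_rrso, "surgery"),
                (record.age_last_followup, "censor"),
            ]
        )
        return EndpointView(time=t, affected=kind == "oc", disease="ovarian")
    raise ValueError(f"unknown disease {disease!r}")


def competing_endpoint(record: CarrierRecord) -> CompetingEndpoint:
    """Map a record to the joint competing-risks endpoint.

    The first cancer diagnosis ends follow-up for both diseases (a later
    second cancer is discarded). Surgery before any cancer censors only the
    corresponding disease, so the breast horizon may extend past an RRSO and
    vice versa.
    """
    cancers = [(record.age_bc, "bc"), (record.age_oc, "oc")]
    present = [(t, k) for t, k in cancers if t is not None]
    first_cancer = min(present, key=lambda tk: (tk[0], _PRIORITY[tk[1]])) if present else None

    def horizon(surgery_age: float | None) -> float:
        cands: list[tuple[float | None, str]] = [
            (surgery_age, "surgery"),
            (record.age_last_followup, "censor"),
        ]
        if first_cancer is not None:
            cands.append((first_cancer[0], first_cancer[1]))
        return _first_event(cands)[0]

    t_bc = horizon(record.age_mastectomy)
    t_oc = horizon(record.age_rrso)
    ev_bc = first_cancer is not None and first_cancer[1] == "bc" and first_cancer[0] <= t_bc
    ev_oc = first_cancer is not None and first_cancer[1] == "oc" and first_cancer[0] <= t_oc
    return CompetingEndpoint(time_bc=t_bc, event_bc=ev_bc, time_oc=t_oc, event_oc=ev_oc)


@dataclass
class SNPRecord:
    """One marker: identifiers, alleles and (optionally) imputation accuracy."""

    snp_id: str
    chrom: str = "0"
    pos: int = 0
    allele1: str = "A"
    allele2: str = "B"
    freq2: float | None = None
    info_r2: float | None = None


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-2 counts or dosages, NaN for missing.

    Hard calls are 0/1/2; dosages live in [0, 2]. A column is either all
    hard calls or all dosages, flagged per SNP in ``dosage``.
    """

    samples: list[str]
    snps: list[SNPRecord]
    values: np.ndarray  # float (n_samples, n_snps), NaN = missing
    dosage: np.ndarray | None = None  # bool per SNP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.dosage is None:
            self.dosage = np.zeros(len(self.snps), dtype=bool)
        else:
            self.dosage = np.asarray(self.dosage, dtype=bool)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            samples=list(sample_ids),
            snps=list(self.snps),
            values=self.values[idx],
            dosage=self.dosage.copy(),
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        ids = self.snp_ids
        j = np.array([ids.index(s) for s in snp_ids], dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[k] for k in j],
            values=self.values[:, j],
            dosage=self.dosage[j],
        )

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.values), axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.values), axis=0)

    def allele2_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Allele-2 frequency per SNP over non-missing calls (optionally
        restricted to a boolean sample mask)."""
        v = self.values if mask is None else self.values[mask]
        obs = ~np.isnan(v)
        tot = np.where(obs, v, 0.0).sum(axis=0)
        n = obs.sum(axis=0)
        return np.divide(
            tot, 2.0 * n, out=np.full(v.shape[1], np.nan), where=n > 0
        )


@dataclass
class IncidenceCurve:
    """Age-specific yearly hazard for one disease on a contiguous grid."""

    disease: str
    ages: np.ndarray  # integer years, contiguous
    rate: np.ndarray  # per-year hazard, >= 0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.ages.shape != self.rate.shape:
            raise ValueError("ages and rate must have the same length")
        if len(self.ages) and np.any(np.diff(self.ages) != 1):
            raise ValueError("age grid must be contiguous yearly")
        if np.any(self.rate < 0):
            raise ValueError("incidence rates must be non-negative")

    @classmethod
    def from_csv(cls, path, disease: str = "breast") -> "IncidenceCurve":
        df = pd.read_csv(path)
        return cls(disease=disease, ages=df["age"].to_numpy(), rate=df["rate"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "rate": self.rate}).to_csv(path, index=False)

    def cumulative_risk(self) -> np.ndarray:
        """Cumulative incidence 1 - prod(1 - rate) at the end of each year."""
        return 1.0 - np.cumprod(1.0 - self.rate)


@dataclass
class EffectTable:
    """Per-SNP multiplicative effects: (snp_id, per-allele HR, allele-2 freq)."""

    snp_ids: list[str]
    hr: np.ndarray
    freq2: np.ndarray

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        self.freq2 = np.asarray(self.freq2, dtype=float)
        if np.any(self.hr <= 0):
            raise ValueError("hazard ratios must be positive")
        if np.any((self.freq2 < 0) | (self.freq2 > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_tsv(cls, path) -> "EffectTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            snp_ids=df["snp_id"].astype(str).tolist(),
            hr=df["per_allele_hr"].to_numpy(),
            freq2=df["freq2"].to_numpy(),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"snp_id": self.snp_ids, "per_allele_hr": self.hr, "freq2": self.freq2}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotype I/O
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = [f.name for f in fields(CarrierRecord)]
_MANDATORY = ("sample_id", "family_id", "stratum", "age_last_followup")


def read_phenotypes(path) -> list[CarrierRecord]:
    """Read a phenotype CSV/TSV (header = CarrierRecord fields, blank = absent).

    Rows violating record invariants are rejected with row-numbered messages;
    duplicated sample ids are an error.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        path,
        sep=sep,
        comment="#",
        dtype={"sample_id": str, "family_id": str},
        float_precision="round_trip",
    )
    for col in _MANDATORY:
        if col not in df.columns:
            raise PhenotypeValidationError(f"missing mandatory column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise PhenotypeValidationError(f"duplicated sample_id: {sorted(set(dup))}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        kwargs = {}
        for name in _PHENO_COLUMNS:
            if name not in d or pd.isna(d[name]) or d[name] == "":
                continue
            kwargs[name] = d[name]
        for name in _AGE_FIELDS:
            if name in kwargs:
                try:
                    kwargs[name] = float(kwargs[name])
                except (TypeError, ValueError) as exc:
                    raise PhenotypeValidationError(
                        f"row {i}: non-numeric {name}: {kwargs[name]!r}"
                    ) from exc
        if "aj_flag" in kwargs:
            kwargs["aj_flag"] = str(kwargs["aj_flag"]).lower() in ("true", "1", "yes")
        if "birth_year" in kwargs:
            kwargs["birth_year"] = int(kwargs["birth_year"])
        rec = CarrierRecord(**kwargs)
        try:
            rec.validate()
        except PhenotypeValidationError as exc:
            raise PhenotypeValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_phenotypes(records: Iterable[CarrierRecord], path) -> None:
    rows = []
    for r in records:
        d = {name: getattr(r, name) for name in _PHENO_COLUMNS}
        rows.append(d)
    df = pd.DataFrame(rows, columns=_PHENO_COLUMNS)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path, mode: str = "hardcall") -> GenotypeMatrix:
    """Read genotypes from VCF (GT or DS) or a TSV matrix.

    TSV dialect: first column ``sample_id``, one column per SNP, cells are
    allele-2 counts/dosages with NA for missing.
    """
    if mode not in ("hardcall", "dosage"):
        raise ValueError("mode must be 'hardcall' or 'dosage'")
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(p, mode)
    return _read_tsv_matrix(p, mode)


def _read_tsv_matrix(path: str, mode: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    samples = df["sample_id"].tolist()
    snp_cols = [c for c in df.columns if c != "sample_id"]
    values = df[snp_cols].to_numpy(dtype=float)
    snps = [SNPRecord(snp_id=c, chrom="0", pos=j + 1) for j, c in enumerate(snp_cols)]
    dosage = np.full(len(snps), mode == "dosage")
    if mode == "hardcall":
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("hardcall matrix contains non-integer genotype values")
    return GenotypeMatrix(samples=samples, snps=snps, values=values, dosage=dosage)


def _read_vcf(path: str, mode: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snps: list[SNPRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        alt = var.ALT[0] if var.ALT else "."
        info_r2 = var.INFO.get("INFO_R2", var.INFO.get("R2", None))
        snps.append(
            SNPRecord(
                snp_id=snp_id,
                chrom=str(var.CHROM),
                pos=int(var.POS),
                allele1=var.REF,
                allele2=alt,
                info_r2=float(info_r2) if info_r2 is not None else None,
            )
        )
        if mode == "dosage":
            ds = var.format("DS")
            if ds is None:
                raise ValueError(f"{snp_id}: no DS field in dosage mode")
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gt = np.asarray(var.genotype.array())  # (n, ploidy+1)
            alleles = gt[:, :2].astype(float)
            missing = (alleles < 0).any(axis=1)
            col = alleles.sum(axis=1)
            col[missing] = np.nan
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    dosage = np.full(len(snps), mode == "dosage")
    return GenotypeMatrix(samples=samples, snps=snps, values=values, dosage=dosage)


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.snp_ids)
    df.insert(0, "sample_id", matrix.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT (hard calls) or DS (dosages)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in dict.fromkeys(
            (s.chrom if s.chrom != "0" else "1") for s in matrix.snps
        ):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, snp in enumerate(matrix.snps):
            col = matrix.values[:, j]
            if matrix.dosage[j]:
                cells = [("." if np.isnan(v) else f"{v:.4g}") for v in col]
                fmt = "DS"
            else:
                gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                cells = [("./." if np.isnan(v) else gt_map[v]) for v in col]
                fmt = "GT"
            chrom = snp.chrom if snp.chrom != "0" else "1"
            pos = snp.pos if snp.pos > 0 else j + 1
            fh.write(
                f"{chrom}\t{pos}\t{snp.snp_id}\t{snp.allele1}\t{snp.allele2}"
                f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )
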