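"""Tabular input/output and shared domain types.

All inclusion and insolubility quantities are held internally as fractions in
``[0, 1]``; percent scales appear only at file boundaries.  Junction
coordinates are 0-based half-open, following the Leafcutter counts convention.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("splicestrat")

DIAGNOSES = frozenset({"ALS", "ALS-FTD", "FTD-MND", "neuro-normal"})
GENOTYPES = frozenset({"none", "C9", "SOD1"})
SEXES = frozenset({"F", "M", "unknown"})

#: Diagnoses that imply clinical/pathological FTD involvement.
FTD_DIAGNOSES = frozenset({"ALS-FTD", "FTD-MND"})

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


@dataclass(frozen=True)
class Patient:
    """Clinical metadata for one cohort member."""

    patient_id: str
    diagnosis: str
    genotype: str = "none"
    ftd_symptoms: bool = False
    sex: str = "unknown"
    has_motor_cortex: bool = True
    has_insolubility: bool = True

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r} for {self.patient_id!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r} for {self.patient_id!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.patient_id!r}")
        if self.diagnosis in FTD_DIAGNOSES and not self.ftd_symptoms:
            # ALS-FTD and FTD-MND are both counted as "symptoms of FTD".
            object.__setattr__(self, "ftd_symptoms", True)

    @property
    def is_control(self) -> bool:
        """Neurologically normal and SOD1-ALS cases serve as the control set."""
        return self.diagnosis == "neuro-normal" or self.genotype == "SOD1"


@dataclass(frozen=True)
class ExonAnnotation:
    exon_id: str
    gene: str
    regulation: str  # "enhanced" or "repressed"

    def __post_init__(self) -> None:
        if self.regulation not in ("enhanced", "repressed"):
            raise ValueError(f"regulation must be enhanced/repressed, got {self.regulation!r}")


@dataclass(frozen=True)
class PSIMeasurement:
    """One replicate measurement of exon inclusion, stored as a fraction."""

    patient_id: str
    exon_id: str
    replicate: int
    inclusion_fraction: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if not 0.0 <= self.inclusion_fraction <= 1.0:
            raise ValueError(
                f"inclusion_fraction {self.inclusion_fraction} outside [0,1] "
                f"({self.patient_id}/{self.exon_id})"
            )


@dataclass(frozen=True)
class BandIntensities:
    """SOL/SS/SI band intensities for one fractionation lane set."""

    patient_id: str
    protein: str
    speed: str  # "g180k" or "g21k"
    replicate: int
    sol: float
    ss: float
    si: float

    def __post_init__(self) -> None:
        if self.speed not in ("g180k", "g21k"):
            raise ValueError(f"speed must be g180k/g21k, got {self.speed!r}")
        if min(self.sol, self.ss, self.si) < 0:
            raise ValueError(f"negative band intensity for {self.patient_id}/{self.protein}")
        if self.sol + self.ss + self.si <= 0:
            raise ValueError(f"all-zero band intensities for {self.patient_id}/{self.protein}")


@dataclass(frozen=True)
class JunctionRow:
    """One intron (split-read junction) with per-sample counts.

    Coordinates are 0-based, half-open (BED-like); strand is not modeled.
    """

    chrom: str
    start: int
    end: int
    cluster_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end <= start for {self.key}")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative count for {self.key}")

    @property
    def key(self) -> str:
        base = f"{self.chrom}:{self.start}:{self.end}"
        return f"{base}:{self.cluster_id}" if self.cluster_id else base

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_bool(token: str, context: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {token!r} in {context}")


def read_clinical(path: str | os.PathLike) -> list[Patient]:
    """Read a clinical metadata table (TSV/CSV with header).

    Required columns: patient_id, diagnosis, genotype, ftd_symptoms, sex.
    Optional availability flags has_motor_cortex / has_insolubility default
    to true when absent.  Duplicate patient ids and unknown diagnosis tokens
    are errors.
    """
    df = _read_table(path)
    required = {"patient_id", "diagnosis", "genotype", "ftd_symptoms", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    patients: list[Patient] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            raise ValueError(f"duplicate patient_id {pid!r} in {path}")
        seen.add(pid)
        diagnosis = str(row["diagnosis"])
        if diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {diagnosis!r} at row {i} (patient {pid!r})")
        patients.append(
            Patient(
                patient_id=pid,
                diagnosis=diagnosis,
                genotype=str(row["genotype"]),
                ftd_symptoms=_parse_bool(row["ftd_symptoms"], f"row {i}"),
                sex=str(row["sex"]),
                has_motor_cortex=(
                    _parse_bool(row["has_motor_cortex"], f"row {i}")
                    if "has_motor_cortex" in df.columns
                    else True
                ),
                has_insolubility=(
                    _parse_bool(row["has_insolubility"], f"row {i}")
                    if "has_insolubility" in df.columns
                    else True
                ),
            )
        )
    return patients


def read_psi_table(
    path: str | os.PathLike,
    annotation: Sequence[ExonAnnotation] | None = None,
    scale: str = "percent",
) -> list[PSIMeasurement]:
    """Read a long-format exon inclusion table.

    Columns: patient_id, exon_id, replicate, value.  ``scale`` declares
    whether values are percents in [0,100] or fractions in [0,1]; everything
    is stored as a fraction.  Exon ids absent from ``annotation`` produce a
    warning but are retained.
    """
    if scale not in ("percent", "fraction"):
        raise ValueError(f"scale must be percent/fraction, got {scale!r}")
    df = _read_table(path)
    required = {"patient_id", "exon_id", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSI table missing columns: {sorted(missing)}")
    known = {a.exon_id for a in annotation} if annotation is not None else None
    limit = 100.0 if scale == "percent" else 1.0
    out: list[PSIMeasurement] = []
    for i, row in df.iterrows():
        value = float(row["value"])
        if not 0.0 <= value <= limit:
            raise ValueError(f"value {value} outside declared {scale} scale at row {i}")
        exon_id = str(row["exon_id"])
        if known is not None and exon_id not in known:
            logger.warning("exon_id %r (row %d) not in annotation; retained", exon_id, i)
        out.append(
            PSIMeasurement(
                patient_id=str(row["patient_id"]),
                exon_id=exon_id,
                replicate=int(row["replicate"]),
                inclusion_fraction=value / limit,
            )
        )
    return out


def read_densitometry(path: str | os.PathLike) -> list[BandIntensities]:
    """Read long-format fractionation densitometry into lane-set records.

    Columns: patient_id, protein, speed, replicate, fraction (SOL/SS/SI),
    intensity.  The three fractions of one (patient, protein, speed,
    replicate) key are assembled into one :class:`BandIntensities`; a key
    missing any fraction is an error.
    """
    df = _read_table(path)
    required = {"patient_id", "protein", "speed", "replicate", "fraction", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    records: list[BandIntensities] = []
    grouped = df.groupby(["patient_id", "protein", "speed", "replicate"], sort=True)
    for key, sub in grouped:
        fractions = {str(f).upper(): float(v) for f, v in zip(sub["fraction"], sub["intensity"])}
        needed = {"SOL", "SS", "SI"}
        if set(fractions) != needed:
            raise ValueError(f"incomplete fractions {sorted(fractions)} for key {key}")
        pid, protein, speed, rep = key
        records.append(
            BandIntensities(
                patient_id=str(pid),
                protein=str(protein),
                speed=str(speed),
                replicate=int(rep),
                sol=fractions["SOL"],
                ss=fractions["SS"],
                si=fractions["SI"],
            )
        )
    return records


def parse_junction_key(key: str) -> tuple[str, int, int, str]:
    """Parse ``chrom:start:end[:cluster]`` into its components."""
    parts = key.split(":")
    if len(parts) == 3:
        chrom, start, end = parts
        cluster = ""
    elif len(parts) == 4:
        chrom, start, end, cluster = parts
    else:
        raise ValueError(f"malformed junction key {key!r}")
    return chrom, int(start), int(end), cluster


def read_junction_counts(path: str | os.PathLike) -> tuple[list[JunctionRow], list[str]]:
    """Read a Leafcutter-style junction counts file.

    First whitespace-separated column holds ``chrom:start:end[:cluster]``
    keys; the header row names the samples.  Returns the rows and the sample
    list.
    """
    rows: list[JunctionRow] = []
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"empty junction counts file {path}")
        samples = header[1:] if len(header) > 1 else []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            chrom, start, end, cluster = parse_junction_key(fields[0])
            try:
                counts = tuple(int(c) for c in fields[1:])
            except ValueError as exc:
                raise ValueError(f"non-integer count at line {lineno} of {path}") from exc
            if len(counts) != len(samples):
                raise ValueError(
                    f"line {lineno}: {len(counts)} counts for {len(samples)} samples"
                )
            rows.append(JunctionRow(chrom, start, end, cluster, counts))
    return rows, samples


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    allow_empty: bool = False,
    percent_columns: Iterable[str] = (),
    sort_by: str | Sequence[str] | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write a result table as TSV with a deterministic row order.

    ``percent_columns`` are fractional columns rendered as percents (x100),
    matching how the field reports inclusion and insolubility.
    """
    if df.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path} (pass allow_empty=True)")
    out = df.copy()
    for col in percent_columns:
        if col in out.columns:
            out[col] = out[col] * 100.0
    if sort_by is None:
        sort_by = list(out.columns[:1]) if len(out.columns) else None
    if sort_by:
        out = out.sort_values(list(sort_by) if not isinstance(sort_by, str) else [sort_by])
    out.to_csv(path, sep="\t", index=False, float_format=float_format)


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read TSV or CSV based on a sniff of the header line."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first or "," not in first else ","
    return pd.read_csv(path, sep=sep, dtype=str).apply(lambda s: s.str.strip() if s.dtype == object else s)


def configure_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
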