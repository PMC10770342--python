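"""Typed data model and readers/writers for the pipeline's tabular inputs.

The pipeline consumes four kinds of tables:

* per-sample variant calls (TSV, or a minimal VCF dialect) carrying the
  amplicon caller's read counts (TA/TR/TO) and random-forest probability score,
  for plasma, buffy coat, saliva and FFPE tumour samples;
* a BED file of panel hotspot target regions;
* a ddPCR results table (CSV);
* a clinical table (CSV) with treatment arm, pCR, node status and follow-up.

Coordinate conventions: variant positions are 1-based (VCF convention); BED
intervals are 0-based half-open, stored exactly as read.  Chromosome names are
compared verbatim — no "chr" aliasing unless a caller opts in elsewhere.

Timing uses ``collection_day``: days relative to the last day of primary
treatment (negative = pre-treatment).  :func:`day_offset` converts a date pair.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, InvariantError, RowError


class Source(str, enum.Enum):
    PLASMA = "plasma"
    BUFFY_COAT = "buffy_coat"
    SALIVA = "saliva"
    TUMOUR_FFPE = "tumour_ffpe"


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class Arm(str, enum.Enum):
    NAT = "NAT"
    ADJ = "ADJ"


class Pcr(str, enum.Enum):
    YES = "yes"
    NO = "no"
    NOT_APPLICABLE = "not_applicable"


class NodeStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: two calls are concordant iff all four fields match."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # used in ledgers and error messages
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample.

    ``ta`` counts reads carrying the called alternative allele, ``tr`` the
    reference allele, ``to`` any other (third/fourth) alleles.  The upstream
    caller's wording for TA is ambiguous ("second alternative allele"); here TA
    is taken as the called alternative allele's read count.  ``rf_score`` is
    the caller's random-forest probability that the call is a true mutation
    rather than an artifact; it may be missing.
    """

    participant_id: str
    sample_id: str
    source: Source
    collection_day: int
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    ta: int
    tr: int
    to: int
    rf_score: float | None = None
    impact: Impact | None = None

    def __post_init__(self):
        if self.ta < 0 or self.tr < 0 or self.to < 0:
            raise InvariantError(f"negative read count (ta={self.ta}, tr={self.tr}, to={self.to})")
        if self.ta + self.tr + self.to <= 0:
            raise InvariantError("ta + tr + to must be > 0")
        if self.pos < 1:
            raise InvariantError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvariantError(f"ref == alt ({self.ref!r})")
        if self.rf_score is not None and not (0.0 <= self.rf_score <= 1.0):
            raise InvariantError(f"rf_score {self.rf_score} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.ta + self.tr + self.to


@dataclass(frozen=True)
class TargetRegion:
    """One panel hotspot interval, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    gene: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise InvariantError(f"start {self.start} >= end {self.end}")

    def contains_pos(self, pos_1based: int) -> bool:
        """Whether a 1-based variant position falls in this interval."""
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class DdpcrAssay:
    """Droplet-level evidence for one variant in one participant.

    ``fluorescence_ratio`` is the mutant-channel signal divided by the matched
    wild-type-only control signal; whether amplitudes or concentrations are
    compared is left to the data producer — the field is a plain ratio.
    """

    key: VariantKey
    participant_id: str
    fam_droplets: int
    fluorescence_ratio: float
    total_droplets: int | None = None

    def __post_init__(self):
        if self.fam_droplets < 0:
            raise InvariantError("fam_droplets must be >= 0")
        if self.fluorescence_ratio < 0:
            raise InvariantError("fluorescence_ratio must be >= 0")
        if self.total_droplets is not None and self.fam_droplets > self.total_droplets:
            raise InvariantError(
                f"fam_droplets {self.fam_droplets} > total_droplets {self.total_droplets}"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """Clinical covariates and survival follow-up for one participant.

    ``followup_day`` and ``event_day`` are days since treatment completion;
    ``event`` marks observed progression or death.  ``pcr`` is
    ``not_applicable`` exactly for adjuvant-arm participants (pathologic
    complete response is defined only after neoadjuvant therapy).
    """

    participant_id: str
    arm: Arm
    pcr: Pcr
    age_group: str
    tumour_stage: str
    node_status: NodeStatus
    capecitabine: bool
    followup_day: int
    event: bool
    event_day: int | None = None

    def __post_init__(self):
        if self.followup_day < 0:
            raise InvariantError("followup_day must be >= 0")
        if self.event:
            if self.event_day is None:
                raise InvariantError("event=true requires event_day")
            if self.event_day > self.followup_day:
                raise InvariantError(
                    f"event_day {self.event_day} > followup_day {self.followup_day}"
                )
        if (self.pcr is Pcr.NOT_APPLICABLE) != (self.arm is Arm.ADJ):
            raise InvariantError("pcr must be not_applicable iff arm is ADJ")


def day_offset(sample_date: str, treatment_end_date: str) -> int:
    """Days from treatment completion to sample collection (ISO dates)."""
    d = _dt.date.fromisoformat(sample_date) - _dt.date.fromisoformat(treatment_end_date)
    return d.days


# ---------------------------------------------------------------------------
# Variant tables

VARIANT_COLUMNS = [
    "participant_id", "sample_id", "source", "collection_day", "chrom", "pos",
    "ref", "alt", "gene", "ta", "tr", "to", "rf_score", "impact",
]
_OPTIONAL_VARIANT_COLUMNS = {"rf_score", "impact"}


def _parse_variant_row(row: dict) -> VariantCall:
    rf = row.get("rf_score")
    rf_score = None if rf in (None, "", ".", "NA") else float(rf)
    imp = row.get("impact")
    impact = None if imp in (None, "", ".", "NA") else Impact(imp)
    return VariantCall(
        participant_id=str(row["participant_id"]),
        sample_id=str(row["sample_id"]),
        source=Source(row["source"]),
        collection_day=_as_int(row["collection_day"], "collection_day"),
        chrom=str(row["chrom"]),
        pos=_as_int(row["pos"], "pos"),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row["gene"]),
        ta=_as_int(row["ta"], "ta"),
        tr=_as_int(row["tr"], "tr"),
        to=_as_int(row["to"], "to"),
        rf_score=rf_score,
        impact=impact,
    )


def _as_int(value, name: str) -> int:
    try:
        return int(str(value))
    except (TypeError, ValueError):
        raise ValueError(f"non-integer {name} field: {value!r}")


def _read_rows(path, parse_row, mandatory, optional, sep, on_error):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        missing = [c for c in mandatory if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        records, errors = [], []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(parse_row(row))
            except (InvariantError, ValueError, KeyError) as exc:
                err = RowError(i, str(exc))
                if on_error == "collect":
                    errors.append(err)
                else:
                    raise err from exc
    return records, errors


def read_variant_table(path, dialect: str = "tsv", on_error: str = "raise"):
    """Read a variant call table.

    Parameters
    ----------
    path : path-like
        TSV file (``dialect="tsv"``) or minimal VCF (``dialect="vcf_min"``).
    dialect : {"tsv", "vcf_min"}
        The VCF dialect expects per-record INFO keys PID, SID, SRC, DAY, GENE,
        TA, TR, TO and optionally RF and IMPACT.
    on_error : {"raise", "collect"}
        With ``"collect"`` invalid rows are returned as :class:`RowError`
        objects alongside the valid records instead of aborting the parse.

    Returns
    -------
    list[VariantCall], or (list[VariantCall], list[RowError]) when collecting.
    """
    if dialect == "tsv":
        records, errors = _read_rows(
            path, _parse_variant_row, VARIANT_COLUMNS[:12], _OPTIONAL_VARIANT_COLUMNS,
            "\t", on_error,
        )
    elif dialect == "vcf_min":
        records, errors = _read_vcf_min(path, on_error)
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")
    return (records, errors) if on_error == "collect" else records


def _read_vcf_min(path, on_error):
    import pysam

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records, errors = [], []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                info = rec.info
                rf = info.get("RF")
                imp = info.get("IMPACT")
                records.append(VariantCall(
                    participant_id=str(info["PID"]),
                    sample_id=str(info["SID"]),
                    source=Source(str(info["SRC"])),
                    collection_day=int(info["DAY"]),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(info.get("GENE", ".")),
                    ta=int(info["TA"]),
                    tr=int(info["TR"]),
                    to=int(info["TO"]),
                    rf_score=None if rf is None else float(rf),
                    impact=None if imp is None else Impact(str(imp)),
                ))
            except (InvariantError, ValueError, KeyError, TypeError) as exc:
                err = RowError(i, str(exc))
                if on_error == "collect":
                    errors.append(err)
                else:
                    raise err from exc
    return records, errors


def write_variant_table(calls: Iterable[VariantCall], path) -> None:
    """Write calls as TSV readable by :func:`read_variant_table`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for c in calls:
            w.writerow([
                c.participant_id, c.sample_id, c.source.value, c.collection_day,
                c.chrom, c.pos, c.ref, c.alt, c.gene, c.ta, c.tr, c.to,
                "" if c.rf_score is None else repr(c.rf_score),
                "" if c.impact is None else c.impact.value,
            ])


# ---------------------------------------------------------------------------
# BED target regions

def read_target_bed(path) -> list[TargetRegion]:
    """Read a BED3+ file of panel target regions, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            gene = parts[3] if len(parts) > 3 else "."
            regions.append(TargetRegion(chrom, start, end, gene))
    return regions


def write_target_bed(regions: Iterable[TargetRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


# ---------------------------------------------------------------------------
# ddPCR and clinical tables (CSV)

DDPCR_COLUMNS = [
    "participant_id", "chrom", "pos", "ref", "alt",
    "fam_droplets", "fluorescence_ratio", "total_droplets",
]


def _parse_ddpcr_row(row: dict) -> DdpcrAssay:
    total = row.get("total_droplets")
    return DdpcrAssay(
        key=VariantKey(str(row["chrom"]), _as_int(row["pos"], "pos"),
                       str(row["ref"]), str(row["alt"])),
        participant_id=str(row["participant_id"]),
        fam_droplets=_as_int(row["fam_droplets"], "fam_droplets"),
        fluorescence_ratio=float(row["fluorescence_ratio"]),
        total_droplets=None if total in (None, "", "NA") else _as_int(total, "total_droplets"),
    )


def read_ddpcr_table(path, on_error: str = "raise"):
    """Read a ddPCR results CSV into :class:`DdpcrAssay` records."""
    records, errors = _read_rows(
        path, _parse_ddpcr_row, DDPCR_COLUMNS[:7], {"total_droplets"}, ",", on_error)
    return (records, errors) if on_error == "collect" else records


def write_ddpcr_table(assays: Iterable[DdpcrAssay], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(DDPCR_COLUMNS)
        for a in assays:
            w.writerow([
                a.participant_id, a.key.chrom, a.key.pos, a.key.ref, a.key.alt,
                a.fam_droplets, repr(a.fluorescence_ratio),
                "" if a.total_droplets is None else a.total_droplets,
            ])


CLINICAL_COLUMNS = [
    "participant_id", "arm", "pcr", "age_group", "tumour_stage", "node_status",
    "capecitabine", "followup_day", "event", "event_day",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_clinical_row(row: dict) -> ParticipantRecord:
    event = _BOOL[str(row["event"]).strip().lower()]
    ed = row.get("event_day")
    return ParticipantRecord(
        participant_id=str(row["participant_id"]),
        arm=Arm(row["arm"]),
        pcr=Pcr(row["pcr"]),
        age_group=str(row["age_group"]),
        tumour_stage=str(row["tumour_stage"]),
        node_status=NodeStatus(row["node_status"]),
        capecitabine=_BOOL[str(row["capecitabine"]).strip().lower()],
        followup_day=_as_int(row["followup_day"], "followup_day"),
        event=event,
        event_day=None if ed in (None, "", "NA") else _as_int(ed, "event_day"),
    )


def read_clinical_table(path, on_error: str = "raise"):
    """Read the clinical covariate/follow-up CSV into :class:`ParticipantRecord`s."""
    records, errors = _read_rows(
        path, _parse_clinical_row, CLINICAL_COLUMNS[:9], {"event_day"}, ",", on_error)
    return (records, errors) if on_error == "collect" else records


def write_clinical_table(records: Iterable[ParticipantRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CLINICAL_COLUMNS)
        for r in records:
            w.writerow([
                r.participant_id, r.arm.value, r.pcr.value, r.age_group,
                r.tumour_stage, r.node_status.value, str(r.capecitabine).lower(),
                r.followup_day, str(r.event).lower(),
                "" if r.event_day is None else r.event_day,
            ])


# ---------------------------------------------------------------------------
# Audit report

AUDIT_COLUMNS = [
    "record_type", "step_index", "step_name", "n_in", "n_removed", "n_added",
    "participant_id", "chrom", "pos", "ref", "alt", "fate",
]


def write_audit_report(callset, path) -> None:
    """Write a FilteredCallSet's ledger and per-variant fates as a single TSV.

    Rows with ``record_type=step`` carry the per-step bookkeeping counts; rows
    with ``record_type=variant`` carry one fate per input variant call.
    Re-reading with :func:`read_audit_report` reproduces the counts exactly.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(AUDIT_COLUMNS)
        for i, step in enumerate(callset.ledger, start=1):
            w.writerow(["step", i, step.name, step.n_in, step.n_removed,
                        step.n_added, "", "", "", "", "", ""])
        for (pid, key), fate in sorted(callset.fates.items(), key=lambda kv: str(kv[0])):
            w.writerow(["variant", "", "", "", "", "", pid,
                        key.chrom, key.pos, key.ref, key.alt, fate])


def read_audit_report(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an audit TSV back as (step table, variant-fate table)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AUDIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing audit column(s): {', '.join(missing)}")
    steps = df[df.record_type == "step"].copy()
    for col in ("step_index", "n_in", "n_removed", "n_added"):
        steps[col] = steps[col].astype(int)
    variants = df[df.record_type == "variant"].copy()
    return steps.reset_index(drop=True), variants.reset_index(drop=True)
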