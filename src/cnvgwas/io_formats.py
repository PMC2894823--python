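"""Readers and writers for every external format the toolkit touches.

Canonical interchange formats (all plain text, UTF-8, 1-based closed
genomic coordinates unless stated otherwise):

* **Generic CNV CSV** — header ``subject_id,chromosome,start,end,state,n_snps``,
  one CNV call per row.  ``start``/``end`` are base-pair positions, or marker
  ids when a SNP map is supplied to the reader.  ``state`` is either an
  unsigned copy number (0, 1, 3, 4; 2 is rejected as copy-neutral) or an
  explicitly signed dose (−2, −1, +1, +2).  Internally every state is held on
  the signed-dose scale (CN0→−2, CN1→−1, CN3→+1, CN4→+2) so that one numeric
  column serves the additive regression model; the writer always emits
  explicit signs, making write→read the identity.
* **Segment summary** — a tolerant adapter for genotyping-console style
  per-segment exports (tab/comma/semicolon delimited, header synonyms listed
  in ``SEGMENT_SUMMARY_SYNONYMS``); the copy-number column is interpreted on
  the 0–4 scale.
* **Phenotype CSV** — ``subject_id`` first, then numeric columns; blank cells
  are missing, any non-numeric cell is a validation error.
* **Genotype calls** — markers × subjects matrix; codes AA/AB/BB map to
  additive doses 0/1/2, ``NoCall``/``NC``/``-1`` to missing.
* **Catalog** — BED-like 4-column ``chrom,start,end,trait``; BED files
  (0-based half-open) are converted to internal 1-based closed coordinates.

Parsers never silently drop a data row: every rejected row either raises with
its line number or is skipped with an explicit warning carrying it.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MissingMetadataWarning,
    NeutralStateWarning,
    ResolutionError,
    RowError,
    ValidationError,
)

__all__ = [
    "SnpMarker",
    "CnvCall",
    "PhenotypeTable",
    "GenotypeTable",
    "CatalogRegion",
    "ConsistencyReport",
    "read_generic_cnv_csv",
    "write_generic_cnv_csv",
    "read_segment_summary",
    "write_segment_summary",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotype_calls",
    "write_genotype_calls",
    "read_snp_map",
    "write_snp_map",
    "read_catalog",
    "validate_subject_consistency",
    "write_results_csv",
    "read_results_csv",
    "write_results_excel",
    "write_regions_csv",
    "read_regions_csv",
    "write_regions_bed",
    "chromosome_sort_key",
    "CHROMOSOME_ORDER",
]

#: Natural ordering of human chromosomes used for sorting and plot layout.
CHROMOSOME_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOME_ORDER)}


def chromosome_sort_key(chromosome: str):
    """Sort key placing chromosomes in natural order 1..22, X, Y, then others."""
    c = str(chromosome)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (_CHROM_RANK.get(c, len(CHROMOSOME_ORDER)), c)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMarker:
    """A SNP-array marker: id, chromosome and 1-based bp position."""

    marker_id: str
    chromosome: str
    position: int

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position must be >= 1, got {self.position}"
            )


#: copy-number → signed dose (deviation from the diploid state, halved sign-wise)
CN_TO_DOSE = {0: -2, 1: -1, 3: +1, 4: +2}
DOSE_TO_CN = {v: k for k, v in CN_TO_DOSE.items()}

_VALID_DOSES = frozenset({-2, -1, 1, 2})


class _NeutralState(ValueError):
    """Internal: CN=2 encountered; the row is copy-neutral, not a CNV."""


def normalize_state(raw) -> int:
    """Map a raw state token to the internal signed-dose scale.

    Unsigned integers are copy numbers (0,1,3,4); explicitly signed tokens
    (``+1``, ``-2``) are already doses; ``loss``/``gain`` map to −1/+1.
    CN=2 raises :class:`_NeutralState` (callers skip the row with a warning).
    """
    s = str(raw).strip()
    low = s.lower()
    if low in ("loss", "deletion", "del"):
        return -1
    if low in ("gain", "amplification", "amp", "dup", "duplication"):
        return +1
    signed = s.startswith(("+", "-"))
    try:
        value = int(s)
    except ValueError:
        raise FormatError(f"unrecognized CNV state {raw!r}") from None
    if signed:
        if value not in _VALID_DOSES:
            raise FormatError(f"signed state must be in -2,-1,+1,+2, got {raw!r}")
        return value
    if value == 2:
        raise _NeutralState(raw)
    if value not in CN_TO_DOSE:
        raise FormatError(f"copy number must be in 0,1,2,3,4, got {raw!r}")
    return CN_TO_DOSE[value]


@dataclass
class CnvCall:
    """One subject's CNV segment on a single chromosome.

    ``state`` is the normalized signed dose in {−2, −1, +1, +2} (never 0: a
    call is always a gain or a loss).  ``n_snps`` may be ``None`` when the
    source file did not carry a marker count; such calls are exempt from the
    minimum-SNP filter (fail-open on metadata).
    """

    subject_id: str
    chromosome: str
    start_pos: int
    end_pos: int
    state: int
    n_snps: Optional[int] = None
    start_marker: Optional[str] = None
    end_marker: Optional[str] = None

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValidationError(
                f"CNV call {self.subject_id} {self.chromosome}:"
                f"{self.start_pos}-{self.end_pos}: start > end"
            )
        if self.state not in _VALID_DOSES:
            raise ValidationError(f"CNV state must be a nonzero signed dose, got {self.state}")
        if self.n_snps is not None and self.n_snps < 1:
            raise ValidationError(f"n_snps must be >= 1, got {self.n_snps}")

    @property
    def length(self) -> int:
        """Closed-interval length in bp."""
        return self.end_pos - self.start_pos + 1


class PhenotypeTable:
    """Subjects × numeric phenotypes, missing values held as NaN (never zero)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate subject ids: {dups}")
        if len(set(frame.columns)) != len(frame.columns):
            raise ValidationError("duplicate phenotype column names")
        self.frame = frame.astype(float)
        self.frame.index = self.frame.index.astype(str)
        self.frame.index.name = "subject_id"

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self):
        return self.frame.shape

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise ConfigColumnError(name, self.columns)
        return self.frame[name]

    def subset(self, subject_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.frame.loc[list(subject_ids)])

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, PhenotypeTable) and self.frame.equals(other.frame)


def ConfigColumnError(name, available):  # small helper, keeps message uniform
    from .errors import ConfigError

    return ConfigError(f"unknown phenotype column {name!r}; available: {sorted(available)}")


@dataclass
class GenotypeTable:
    """SNP genotype doses: markers × subjects, additive coding 0/1/2, NaN missing."""

    frame: pd.DataFrame

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.columns)

    def doses(self, marker_id: str) -> pd.Series:
        return self.frame.loc[marker_id]


@dataclass(frozen=True)
class CatalogRegion:
    """A published association region (1-based closed) with its trait label."""

    chromosome: str
    start_pos: int
    end_pos: int
    trait: str

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValidationError(
                f"catalog region {self.chromosome}:{self.start_pos}-{self.end_pos}: start > end"
            )


@dataclass
class ConsistencyReport:
    """Subjects present in only one of two inputs, plus the usable intersection."""

    call_only: set
    pheno_only: set
    shared: set

    @property
    def consistent(self) -> bool:
        return not self.call_only and not self.pheno_only


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    """Pick the delimiter (comma/tab/semicolon) with most hits in the header line."""
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                counts = {d: line.count(d) for d in (",", "\t", ";")}
                best = max(counts, key=counts.get)
                return best if counts[best] > 0 else ","
    return ","


def _parse_position(token: str, marker_index, which: str, line: int):
    """Return (position, marker_id) for a start/end token (bp or marker id)."""
    token = token.strip()
    try:
        return int(token), None
    except ValueError:
        pass
    if marker_index is None:
        raise RowError(f"non-numeric {which} position {token!r}", line)
    if token not in marker_index:
        raise ResolutionError(f"line {line}: unknown marker id {token!r} in {which} column")
    return marker_index[token].position, token


def _parse_int(token: str, name: str, line: int) -> int:
    try:
        return int(str(token).strip())
    except (TypeError, ValueError):
        raise RowError(f"non-integer {name} {token!r}", line) from None


# ---------------------------------------------------------------------------
# CNV call readers / writers
# ---------------------------------------------------------------------------

GENERIC_CNV_COLUMNS = ["subject_id", "chromosome", "start", "end", "state", "n_snps"]


def read_generic_cnv_csv(
    path, snp_map: Optional[Sequence[SnpMarker]] = None
) -> list[CnvCall]:
    """Read the canonical generic CNV CSV into a list of :class:`CnvCall`.

    When ``snp_map`` is given, non-numeric ``start``/``end`` tokens are
    resolved as marker ids against it.  Copy-neutral rows (state 2) are
    skipped with a :class:`NeutralStateWarning`; structural problems raise.
    """
    path = Path(path)
    marker_index = {m.marker_id: m for m in snp_map} if snp_map is not None else None
    delim = _sniff_delimiter(path)
    calls: list[CnvCall] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected header {GENERIC_CNV_COLUMNS}")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in GENERIC_CNV_COLUMNS[:5] if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        has_n_snps = "n_snps" in header
        if not has_n_snps:
            warnings.warn(
                f"{path}: no n_snps column; marker counts imputed as missing "
                "(calls exempt from the min-SNP filter)",
                MissingMetadataWarning,
                stacklevel=2,
            )
        for row in reader:
            line = reader.line_num
            start, start_marker = _parse_position(row["start"], marker_index, "start", line)
            end, end_marker = _parse_position(row["end"], marker_index, "end", line)
            try:
                state = normalize_state(row["state"])
            except _NeutralState:
                warnings.warn(
                    f"{path} line {line}: neutral state (copy number 2) is not a CNV; "
                    "row rejected",
                    NeutralStateWarning,
                    stacklevel=2,
                )
                continue
            n_snps = None
            if has_n_snps and str(row.get("n_snps", "")).strip() not in ("", "NA"):
                n_snps = _parse_int(row["n_snps"], "n_snps", line)
            try:
                calls.append(
                    CnvCall(
                        subject_id=str(row["subject_id"]).strip(),
                        chromosome=str(row["chromosome"]).strip(),
                        start_pos=start,
                        end_pos=end,
                        state=state,
                        n_snps=n_snps,
                        start_marker=start_marker,
                        end_marker=end_marker,
                    )
                )
            except ValidationError as exc:
                raise RowError(str(exc), line) from None
    return calls


def write_generic_cnv_csv(calls: Iterable[CnvCall], path) -> Path:
    """Write calls in the generic dialect; states carry explicit signs."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENERIC_CNV_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.subject_id,
                    c.chromosome,
                    c.start_pos,
                    c.end_pos,
                    f"{c.state:+d}",
                    "" if c.n_snps is None else c.n_snps,
                ]
            )
    return path


#: Accepted header synonyms for the per-segment export dialect (lower-cased,
#: spaces/underscores interchangeable).
SEGMENT_SUMMARY_SYNONYMS = {
    "subject_id": ["sample", "sample id", "sample name", "subject", "subject id"],
    "chromosome": ["chromosome", "chr", "chrom"],
    "start": ["start", "start position", "start pos", "min position"],
    "end": ["end", "end position", "end pos", "max position"],
    "state": ["state", "cn state", "copy number", "copy number state", "cn"],
    "n_snps": ["n_snps", "marker count", "markercount", "num markers", "probe count", "markers"],
}


def _normalize_header_token(token: str) -> str:
    return token.strip().lower().replace("_", " ")


def read_segment_summary(path) -> list[CnvCall]:
    """Tolerant reader for per-segment copy-number summary exports.

    Same contract as :func:`read_generic_cnv_csv`; the state column is a copy
    number on the 0–4 scale (2 → row rejected with a neutral-state warning).
    A missing marker-count column imputes ``n_snps`` as missing with a warning.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        normalized = [_normalize_header_token(h) for h in raw_header]
        col_of = {}
        for canonical, synonyms in SEGMENT_SUMMARY_SYNONYMS.items():
            for i, h in enumerate(normalized):
                if h in synonyms or h == canonical:
                    col_of[canonical] = i
                    break
        missing = [c for c in ("subject_id", "chromosome", "start", "end", "state") if c not in col_of]
        if missing:
            raise FormatError(
                f"{path}: unrecognized header {raw_header}; could not find column(s) "
                + ", ".join(f"{c} (accepted: {SEGMENT_SUMMARY_SYNONYMS[c]})" for c in missing)
            )
        if "n_snps" not in col_of:
            warnings.warn(
                f"{path}: no marker-count column; n_snps imputed as missing",
                MissingMetadataWarning,
                stacklevel=2,
            )
        calls: list[CnvCall] = []
        for line, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(raw_header):
                raise RowError(f"expected {len(raw_header)} fields, got {len(row)}", line)
            try:
                state = normalize_state(row[col_of["state"]])
            except _NeutralState:
                warnings.warn(
                    f"{path} line {line}: neutral state (copy number 2) is not a CNV; "
                    "row rejected",
                    NeutralStateWarning,
                    stacklevel=2,
                )
                continue
            n_snps = None
            if "n_snps" in col_of and row[col_of["n_snps"]].strip():
                n_snps = _parse_int(row[col_of["n_snps"]], "marker count", line)
            try:
                calls.append(
                    CnvCall(
                        subject_id=row[col_of["subject_id"]].strip(),
                        chromosome=row[col_of["chromosome"]].strip(),
                        start_pos=_parse_int(row[col_of["start"]], "start", line),
                        end_pos=_parse_int(row[col_of["end"]], "end", line),
                        state=state,
                        n_snps=n_snps,
                    )
                )
            except ValidationError as exc:
                raise RowError(str(exc), line) from None
    return calls


def write_segment_summary(calls: Iterable[CnvCall], path) -> Path:
    """Write calls in the tab-delimited segment-summary dialect (CN 0–4 states)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Sample", "Chromosome", "Start Position", "End Position",
                         "Copy Number State", "Marker Count"])
        for c in calls:
            writer.writerow(
                [
                    c.subject_id,
                    c.chromosome,
                    c.start_pos,
                    c.end_pos,
                    DOSE_TO_CN[c.state],
                    "" if c.n_snps is None else c.n_snps,
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV (``subject_id`` first, numeric columns after).

    Blank cells become NaN (missing); any non-numeric cell raises a
    :class:`ValidationError` naming the subject and column; duplicate subject
    ids raise.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, encoding="utf-8")
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a subject_id column plus at least one phenotype")
    subj_col = raw.columns[0]
    subjects = raw[subj_col].astype(str).str.strip()
    if subjects.duplicated().any():
        dups = subjects[subjects.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate subject id(s) {dups}")
    data = {}
    for col in raw.columns[1:]:
        cells = raw[col].astype(str).str.strip()
        blank = (cells == "") | cells.str.upper().isin({"NA", "NAN"})
        values = np.empty(len(cells), dtype=float)
        # python float() parsing keeps write->read lossless to the last ulp
        for i, (cell, is_blank) in enumerate(zip(cells, blank)):
            if is_blank:
                values[i] = np.nan
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} in column {col!r} "
                    f"for subject {subjects.iloc[i]!r} (row {i + 2})"
                ) from None
        data[col] = values
    frame = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

GENOTYPE_CODE_TO_DOSE = {
    "AA": 0.0, "AB": 1.0, "BA": 1.0, "BB": 2.0,
    "0": 0.0, "1": 1.0, "2": 2.0,
    "NOCALL": math.nan, "NC": math.nan, "NN": math.nan, "-1": math.nan, "": math.nan,
    "NA": math.nan,
}

_DOSE_TO_CODE = {0.0: "AA", 1.0: "AB", 2.0: "BB"}


def read_genotype_calls(path) -> GenotypeTable:
    """Read a markers × subjects genotype call matrix into additive doses."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty genotype file") from None
        subjects = [h.strip() for h in header[1:]]
        if not subjects:
            raise FormatError(f"{path}: header must list subject columns after the marker id")
        markers, rows = [], []
        for line, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path} line {line}: ragged row, expected {len(header)} fields, got {len(row)}"
                )
            marker = row[0].strip()
            doses = []
            for subject, cell in zip(subjects, row[1:]):
                code = cell.strip().upper()
                if code not in GENOTYPE_CODE_TO_DOSE:
                    raise FormatError(
                        f"{path} line {line}: unknown genotype code {cell!r} "
                        f"(marker {marker}, subject {subject})"
                    )
                doses.append(GENOTYPE_CODE_TO_DOSE[code])
            markers.append(marker)
            rows.append(doses)
    frame = pd.DataFrame(rows, index=pd.Index(markers, name="marker_id"), columns=subjects)
    return GenotypeTable(frame)


def write_genotype_calls(genotypes: GenotypeTable, path) -> Path:
    """Write doses back as AA/AB/BB/NoCall codes (tab-delimited)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["probeset_id", *genotypes.subject_ids])
        for marker, row in genotypes.frame.iterrows():
            writer.writerow(
                [marker]
                + ["NoCall" if math.isnan(v) else _DOSE_TO_CODE[float(v)] for v in row]
            )
    return path


# ---------------------------------------------------------------------------
# SNP map and catalog
# ---------------------------------------------------------------------------


def read_snp_map(path) -> list[SnpMarker]:
    """Read a SNP map CSV with header ``marker_id,chromosome,position``."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    markers = []
    seen = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"marker_id", "chromosome", "position"}
        if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
            raise FormatError(f"{path}: expected header with columns {sorted(required)}")
        for row in reader:
            mid = row["marker_id"].strip()
            if mid in seen:
                raise ValidationError(f"{path}: duplicate marker id {mid!r}")
            seen.add(mid)
            markers.append(
                SnpMarker(mid, row["chromosome"].strip(),
                          _parse_int(row["position"], "position", reader.line_num))
            )
    markers.sort(key=lambda m: (chromosome_sort_key(m.chromosome), m.position))
    return markers


def write_snp_map(markers: Iterable[SnpMarker], path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker_id", "chromosome", "position"])
        for m in markers:
            writer.writerow([m.marker_id, m.chromosome, m.position])
    return path


def read_catalog(path, coords: Optional[str] = None) -> list[CatalogRegion]:
    """Read a known-association catalog (``chrom,start,end,trait``).

    ``coords`` is ``"bed"`` (0-based half-open) or ``"closed"`` (1-based
    closed); default is BED semantics when the filename ends in ``.bed``,
    closed otherwise.
    """
    path = Path(path)
    if coords is None:
        coords = "bed" if path.suffix.lower() == ".bed" else "closed"
    if coords not in ("bed", "closed"):
        raise FormatError(f"coords must be 'bed' or 'closed', got {coords!r}")
    delim = "\t" if path.suffix.lower() == ".bed" else _sniff_delimiter(path)
    regions = []
    with path.open(newline="", encoding="utf-8") as fh:
        for line, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or row[0].startswith("#"):
                continue
            if line == 1 and row[0].strip().lower() in ("chrom", "chromosome"):
                continue
            if len(row) < 4:
                raise RowError(f"expected 4 columns chrom,start,end,trait, got {len(row)}", line)
            start = _parse_int(row[1], "start", line)
            end = _parse_int(row[2], "end", line)
            if coords == "bed":
                start += 1  # half-open end equals the closed end coordinate
            regions.append(
                CatalogRegion(row[0].strip().removeprefix("chr"), start, end, row[3].strip())
            )
    return regions


# ---------------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------------


def validate_subject_consistency(
    calls: Sequence[CnvCall], phenos: PhenotypeTable
) -> ConsistencyReport:
    """Report subjects present in only one input; fatal if none are shared."""
    call_subjects = {c.subject_id for c in calls}
    pheno_subjects = set(phenos.subject_ids)
    shared = call_subjects & pheno_subjects
    if not shared:
        raise ValidationError(
            "no subjects shared between the CNV calls and the phenotype table; "
            "check that subject ids use the same vocabulary"
        )
    return ConsistencyReport(
        call_only=call_subjects - pheno_subjects,
        pheno_only=pheno_subjects - call_subjects,
        shared=shared,
    )


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "region_id", "chromosome", "start", "end", "frequency", "n",
    "beta", "se", "t_stat", "p_value", "df", "significant", "catalog_hit",
    "covariate_betas",
]


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_results_csv(results, path) -> Path:
    """Write association results; floats serialized losslessly via ``repr``.

    An empty result list writes a header-only file.  Covariate coefficient
    estimates travel in a JSON-encoded column so that read-back reproduces
    every field.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.region_id, r.chromosome, r.start_pos, r.end_pos,
                    _fmt_float(r.frequency), r.n,
                    _fmt_float(r.beta), _fmt_float(r.se), _fmt_float(r.t_stat),
                    _fmt_float(r.p_value), r.df,
                    "true" if r.significant else "false",
                    "true" if r.catalog_hit else "false",
                    json.dumps(r.covariate_betas),
                ]
            )
    return path


def read_results_csv(path):
    """Read back a results CSV into :class:`~cnvgwas.association.AssociationResult`s."""
    from .association import AssociationResult  # local import avoids a cycle

    path = Path(path)
    results = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty results file")
        missing = [c for c in RESULTS_COLUMNS[:12] if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing results column(s) {missing}")
        for row in reader:
            results.append(
                AssociationResult(
                    region_id=row["region_id"],
                    chromosome=row["chromosome"],
                    start_pos=int(row["start"]),
                    end_pos=int(row["end"]),
                    frequency=float(row["frequency"]),
                    n=int(row["n"]),
                    beta=float(row["beta"]),
                    se=float(row["se"]),
                    t_stat=float(row["t_stat"]),
                    p_value=float(row["p_value"]),
                    df=int(row["df"]),
                    significant=row["significant"] == "true",
                    catalog_hit=row.get("catalog_hit") == "true",
                    covariate_betas=json.loads(row.get("covariate_betas") or "{}"),
                )
            )
    return results


def write_results_excel(results, path) -> Path:
    """Optional Excel export of the results table (requires openpyxl)."""
    path = Path(path)
    rows = [
        {
            "region_id": r.region_id, "chromosome": r.chromosome,
            "start": r.start_pos, "end": r.end_pos, "frequency": r.frequency,
            "n": r.n, "beta": r.beta, "se": r.se, "t_stat": r.t_stat,
            "p_value": r.p_value, "df": r.df, "significant": r.significant,
            "catalog_hit": r.catalog_hit,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=RESULTS_COLUMNS[:13]).to_excel(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Region persistence (reuse of detected regions across analyses)
# ---------------------------------------------------------------------------

REGIONS_COLUMNS = [
    "region_id", "chromosome", "start", "end",
    "n_carriers", "n_subjects", "frequency", "sign", "carriers",
]


def write_regions_csv(regions, path) -> Path:
    """Persist detected regions so association runs can reuse them."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGIONS_COLUMNS)
        for r in regions:
            writer.writerow(
                [
                    r.region_id, r.chromosome, r.start_pos, r.end_pos,
                    r.n_carriers, r.n_subjects, _fmt_float(r.frequency),
                    r.sign or "",
                    ";".join(sorted(r.carrier_ids)),
                ]
            )
    return path


def read_regions_csv(path):
    """Read a saved regions CSV back into :class:`~cnvgwas.cnvr_detection.SubCnvr`s.

    Merged-region member structure is not persisted; a reloaded region behaves
    as a single detected region with the saved span and carrier set, which is
    all the association step needs.
    """
    from .cnvr_detection import SubCnvr  # local import avoids a cycle

    path = Path(path)
    regions = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty regions file")
        missing = [c for c in REGIONS_COLUMNS[:7] if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing regions column(s) {missing}")
        for row in reader:
            carriers = frozenset(filter(None, (row.get("carriers") or "").split(";")))
            regions.append(
                SubCnvr(
                    chromosome=row["chromosome"],
                    start_pos=int(row["start"]),
                    end_pos=int(row["end"]),
                    n_subjects=int(row["n_subjects"]),
                    carrier_ids=carriers if carriers else frozenset(),
                    n_carriers=int(row["n_carriers"]),
                    sign=row.get("sign") or None,
                )
            )
    return regions


def write_regions_bed(regions, path) -> Path:
    """Export region spans as BED (0-based half-open) for genome-browser use."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_pos - 1}\t{r.end_pos}\t{r.region_id}\n")
    return path
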