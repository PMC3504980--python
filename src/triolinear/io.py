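"""Trio file format, validation, and study configuration loading.

The canonical on-disk format is a minimal tab-separated dialect with
header ``family_id  mother_locus1  father_locus1  child_locus1
mother_locus2``, genotype values in {0, 1, 2, NA} (NA case-insensitive,
the only missing code), UTF-8, and ``#`` comment lines ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .cell_table import MISSING
from .em_missing import IncompleteFamily, compatible_cells
from .exceptions import DataError, MendelianError

HEADER = ("family_id", "mother_locus1", "father_locus1", "child_locus1", "mother_locus2")


@dataclass
class ValidationReport:
    """Row-level problems found while reading a trio file."""

    n_rows: int = 0
    n_valid: int = 0
    class_counts: dict = field(default_factory=dict)
    mendelian_errors: list = field(default_factory=list)  # (line_no, family_id, message)

    @property
    def ok(self) -> bool:
        return not self.mendelian_errors


def _parse_genotype(token: str, line_no: int, col: str) -> int:
    token = token.strip()
    if token.upper() == "NA":
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise DataError(
        f"line {line_no}: column {col!r} has value {token!r}; expected 0, 1, 2 or NA"
    )


def read_trio_file(path) -> tuple[list[IncompleteFamily], ValidationReport]:
    """Read and validate a trio TSV.

    Mendelian-inconsistent rows are collected in the report and excluded
    from the returned family list, never silently dropped.  A duplicate
    family_id or a malformed header/value is an error.
    """
    path = Path(path)
    report = ValidationReport()
    families: list[IncompleteFamily] = []
    seen: set[str] = set()
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(f.strip() for f in fields) != HEADER:
                    raise DataError(
                        f"line {line_no}: header must be exactly {' '.join(HEADER)} "
                        "(tab-separated)"
                    )
                header_seen = True
                continue
            if len(fields) != 5:
                raise DataError(f"line {line_no}: expected 5 tab-separated fields, got {len(fields)}")
            fid = fields[0].strip()
            if not fid:
                raise DataError(f"line {line_no}: empty family_id")
            if fid in seen:
                raise DataError(f"line {line_no}: duplicate family_id {fid!r}")
            seen.add(fid)
            report.n_rows += 1
            m = _parse_genotype(fields[1], line_no, HEADER[1])
            f = _parse_genotype(fields[2], line_no, HEADER[2])
            c = _parse_genotype(fields[3], line_no, HEADER[3])
            m2 = _parse_genotype(fields[4], line_no, HEADER[4])
            if c == MISSING:
                report.mendelian_errors.append((line_no, fid, "case genotype is missing"))
                continue
            fam = IncompleteFamily(m=m, f=f, c=c, m2=m2, family_id=fid)
            try:
                compatible_cells(fam)
            except MendelianError as err:
                report.mendelian_errors.append((line_no, fid, str(err)))
                continue
            report.n_valid += 1
            cls = fam.completeness_class
            report.class_counts[cls] = report.class_counts.get(cls, 0) + 1
            families.append(fam)
    if not header_seen:
        raise DataError(f"{path}: no families (empty file)")
    if report.n_rows == 0:
        raise DataError(f"{path}: no families")
    return families, report


def write_trio_file(families, path) -> None:
    """Write families in the canonical TSV dialect (round-trips with read)."""

    def fmt(v: int) -> str:
        return "NA" if v == MISSING else str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(HEADER) + "\n")
        for fam in families:
            fh.write(
                f"{fam.family_id}\t{fmt(fam.m)}\t{fmt(fam.f)}\t{fmt(fam.c)}\t{fmt(fam.m2)}\n"
            )


def read_counts_table(path) -> "np.ndarray":
    """Convert a pre-tabulated 4-column (M, F, C, M2) + count TSV to cell counts."""
    import numpy as np

    from .cell_table import N_CELLS, cell_index, config_of

    counts = np.zeros(N_CELLS)
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("m\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise DataError(f"line {line_no}: expected M F C M2 count")
            m, f, c, k = (int(v) for v in parts[:4])
            counts[cell_index(config_of(m, f, c), k)] += float(parts[4])
    return counts


def load_study_config(path) -> dict:
    """Load a YAML or JSON study configuration."""
    import json

    import yaml

    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
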