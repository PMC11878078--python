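"""Readers and writers for the package's plain-text table dialects.

Cohort and catalog tables are UTF-8 TSV; growth curves are long-format
CSV; resistance matrices are TSV grids with a JSON provenance sidecar.
Writers emit byte-stable output (fixed column order, "\\n" line endings)
so that write -> load is the identity on validated objects.

The packaged fixtures transcribe the study's published cohort and
Pf-phage catalog tables (75 isolates from 25 patients; 12 Pf phages)
and are guarded by a SHA-256 manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import Cohort, Isolate, PfPhage, annotate_system
from .errors import ChecksumError, InputError, ParseError

COHORT_COLUMNS = [
    "isolate_id",
    "patient_id",
    "st",
    "pf_isolate_names",
    "pf_catalog_ids",
    "n_genome_systems",
    "genome_system_names",
]
CATALOG_COLUMNS = [
    "pf_id",
    "n_isolates",
    "n_patients",
    "st_list",
    "genbank",
    "attb_site",
    "genome_size",
    "n_cds",
    "n_core_cds",
    "n_accessory_cds",
    "complete_systems",
    "incomplete_systems",
]
SPOT_COLUMNS = ["isolate_id", "phage_id", "rep1", "rep2", "rep3"]
CURVE_COLUMNS = ["isolate_id", "phage_id", "condition", "replicate_id", "time_h", "od600"]


def _split(cell: str) -> tuple[str, ...]:
    """Parse a ';'-separated multi-value cell; 'ND' and '' mean empty."""
    cell = cell.strip()
    if cell in ("", "ND"):
        return ()
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def _read_rows(path: str | Path, columns: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t", restval="")
        if reader.fieldnames is None or list(reader.fieldnames) != list(columns):
            raise ParseError(
                f"{path}: header {reader.fieldnames} does not match expected "
                f"columns {list(columns)}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if None in row:
                raise ParseError(f"{path}: line {lineno}: too many fields")
            row["__line__"] = str(lineno)
            rows.append(row)
        return rows


# -- catalog --------------------------------------------------------------


def read_catalog_table(path: str | Path) -> tuple[PfPhage, ...]:
    """Read a Pf-phage catalog TSV into validated catalog entries."""
    phages = []
    for row in _read_rows(path, CATALOG_COLUMNS):
        line = row.pop("__line__")
        try:
            systems = [annotate_system(n) for n in _split(row["complete_systems"])]
            systems += [
                annotate_system(n, complete=False)
                for n in _split(row["incomplete_systems"])
            ]
            phages.append(
                PfPhage(
                    id=row["pf_id"],
                    n_isolates=int(row["n_isolates"]),
                    n_patients=int(row["n_patients"]),
                    st_list=row["st_list"],
                    genbank=row["genbank"],
                    attb_site=row["attb_site"],
                    genome_size=int(row["genome_size"]),
                    n_cds=int(row["n_cds"]),
                    n_core_cds=int(row["n_core_cds"]),
                    n_accessory_cds=int(row["n_accessory_cds"]),
                    systems=tuple(systems),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    return tuple(phages)


def write_catalog_table(catalog: Iterable[PfPhage], path: str | Path) -> None:
    lines = ["\t".join(CATALOG_COLUMNS)]
    for p in catalog:
        complete = ";".join(s.name for s in p.systems if s.complete)
        incomplete = ";".join(s.name for s in p.systems if not s.complete)
        lines.append(
            "\t".join(
                [
                    p.id,
                    str(p.n_isolates),
                    str(p.n_patients),
                    p.st_list,
                    p.genbank,
                    p.attb_site,
                    str(p.genome_size),
                    str(p.n_cds),
                    str(p.n_core_cds),
                    str(p.n_accessory_cds),
                    complete,
                    incomplete,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# -- cohort ---------------------------------------------------------------


def load_cohort_table(
    path: str | Path, catalog: Sequence[PfPhage] | str | Path | None = None
) -> Cohort:
    """Read a cohort TSV and return a validated :class:`Cohort`.

    ``catalog`` may be a list of catalog entries, a path to a catalog
    TSV, or ``None`` to use the packaged Pf-phage catalog. Carriage
    cells holding ``ND`` or nothing mean non-carrier; multiple phages
    are ';'-separated.
    """
    if catalog is None:
        catalog = load_table2_catalog()
    elif isinstance(catalog, (str, Path)):
        catalog = read_catalog_table(catalog)
    isolates = []
    for row in _read_rows(path, COHORT_COLUMNS):
        line = row.pop("__line__")
        try:
            isolates.append(
                Isolate(
                    id=row["isolate_id"],
                    patient_id=row["patient_id"],
                    st=row["st"],
                    pf_isolate_names=_split(row["pf_isolate_names"]),
                    pf_ids=_split(row["pf_catalog_ids"]),
                    n_genome_systems=int(row["n_genome_systems"] or 0),
                    genome_system_names=frozenset(_split(row["genome_system_names"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    try:
        return Cohort(isolates=tuple(isolates), catalog=tuple(catalog))
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_cohort_table(cohort: Cohort, path: str | Path) -> None:
    lines = ["\t".join(COHORT_COLUMNS)]
    for iso in cohort.isolates:
        lines.append(
            "\t".join(
                [
                    iso.id,
                    iso.patient_id,
                    iso.st,
                    ";".join(iso.pf_isolate_names) or "ND",
                    ";".join(iso.pf_ids),
                    str(iso.n_genome_systems),
                    ";".join(sorted(iso.genome_system_names)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# -- spots and curves -----------------------------------------------------


def read_spot_table(path: str | Path) -> dict[tuple[str, str], tuple[str, str, str]]:
    """Spot-grade TSV -> {(isolate_id, phage_id): (rep1, rep2, rep3)}."""
    out: dict[tuple[str, str], tuple[str, str, str]] = {}
    for row in _read_rows(path, SPOT_COLUMNS):
        line = row.pop("__line__")
        key = (row["isolate_id"], row["phage_id"])
        if key in out:
            raise ParseError(f"{path}: line {line}: duplicate spot row for {key}")
        grades = (row["rep1"], row["rep2"], row["rep3"])
        if any(g not in ("clear", "turbid", "none") for g in grades):
            raise ParseError(f"{path}: line {line}: invalid spot grade in {grades}")
        out[key] = grades
    return out


def write_spot_table(
    spots: Mapping[tuple[str, str], Sequence[str]], path: str | Path
) -> None:
    lines = ["\t".join(SPOT_COLUMNS)]
    for (iso, phage), grades in spots.items():
        lines.append("\t".join([iso, phage, *grades]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_curve_table(path: str | Path) -> pd.DataFrame:
    """Long-format growth-curve CSV -> DataFrame with the canonical columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != CURVE_COLUMNS:
        raise ParseError(
            f"{path}: columns {list(df.columns)} do not match {CURVE_COLUMNS}"
        )
    return df


def write_curve_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, CURVE_COLUMNS].to_csv(path, index=False, lineterminator="\n")


# -- packaged fixtures ----------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("pfresist.data") / name)


def fixture_paths() -> dict[str, Path]:
    return {
        "table1_cohort.tsv": _data_path("table1_cohort.tsv"),
        "table2_catalog.tsv": _data_path("table2_catalog.tsv"),
    }


def verify_fixture_checksums() -> None:
    """Compare packaged fixtures against the recorded SHA-256 manifest."""
    manifest = json.loads(_data_path("MANIFEST.json").read_text())
    for name, expected in manifest.items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise ChecksumError(
                f"fixture {name} checksum mismatch: expected {expected}, got {digest}"
            )


def load_table2_catalog() -> tuple[PfPhage, ...]:
    """The packaged 12-phage Pf catalog."""
    return read_catalog_table(_data_path("table2_catalog.tsv"))


def load_table1_cohort() -> Cohort:
    """The packaged 75-isolate, 25-patient cohort with the Pf catalog attached."""
    return load_cohort_table(_data_path("table1_cohort.tsv"), load_table2_catalog())
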