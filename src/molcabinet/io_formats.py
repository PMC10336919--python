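"""Import and export of compound tables: CSV, XLSX, SDF, and an HTML grid.

Imports are append-only with a first-instance-wins duplicate policy: a row
whose ID already exists in the project, or appeared earlier in the same file,
is skipped and reported rather than merged or overwritten. Rows whose SMILES
fails to parse are likewise skipped and reported. Every import returns an
:class:`ImportReport` so nothing is dropped silently.

CSV and XLSX files must carry a header row; the caller maps which columns
hold the molecule ID and the SMILES, and every other column becomes a
property column. Empty cells import as *absent* properties, distinguishing
"no data" from the empty string.
"""

from __future__ import annotations

import csv
import html
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import try_mol
from .errors import MolCabinetError
from .project import Project

#: CSV separators offered by the import dialog.
SEPARATORS = {"comma": ",", "semicolon": ";", "tab": "\t"}

#: Sentinel for taking the SDF record ID from the molecule title line.
MOLECULE_TITLE = "molecule title"


@dataclass
class ImportReport:
    """Outcome of one ingest: counts plus the skipped-record listings.

    Invariant: ``n_imported == n_read - len(duplicates) - len(invalid_structures)``.
    """

    n_read: int = 0
    n_imported: int = 0
    duplicates: list[tuple[str, int]] = field(default_factory=list)  # (id, row number)
    invalid_structures: list[tuple[int, str]] = field(default_factory=list)  # (row number, reason)

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_imported": self.n_imported,
            "duplicates": [list(t) for t in self.duplicates],
            "invalid_structures": [list(t) for t in self.invalid_structures],
        }


@dataclass
class TableMapping:
    """Which header columns hold the molecule ID and the SMILES.

    ``separator`` applies to CSV only and may be given as a literal
    character or as one of ``comma``/``semicolon``/``tab``.
    """

    id_field: str
    smiles_field: str
    separator: str = ","

    def __post_init__(self):
        if self.id_field == self.smiles_field:
            raise MolCabinetError("id_field and smiles_field must differ")
        self.separator = SEPARATORS.get(self.separator, self.separator)
        if self.separator not in SEPARATORS.values():
            raise MolCabinetError(
                f"unsupported CSV separator {self.separator!r}; use comma, semicolon, or tab"
            )


def _read_table(path: Path, fmt: str, mapping: TableMapping) -> pd.DataFrame:
    if fmt == "csv":
        df = pd.read_csv(path, sep=mapping.separator, dtype=str, keep_default_na=False)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0, dtype=str, engine="openpyxl")
        df = df.fillna("")
    else:
        raise MolCabinetError(f"unsupported table format: {fmt!r}")
    df.columns = [str(c) for c in df.columns]
    return df


def _ingest_row(
    project: Project,
    report: ImportReport,
    row_no: int,
    entry_id: str,
    smiles: str,
    properties: dict[str, str],
) -> None:
    """Shared duplicate/invalid policy for every ingest path."""
    if not entry_id:
        report.invalid_structures.append((row_no, "missing ID"))
        return
    if entry_id in project:
        report.duplicates.append((entry_id, row_no))
        return
    mol = try_mol(smiles)
    if mol is None:
        report.invalid_structures.append((row_no, f"invalid SMILES: {smiles!r}"))
        return
    entry = project.add_molecule(entry_id, smiles)
    for name, value in properties.items():
        project.set_property(entry.id, name, value)
    report.n_imported += 1


def import_table(project: Project, path: str | os.PathLike, fmt: str, mapping: TableMapping) -> ImportReport:
    """Import a CSV or XLSX compound table into ``project``.

    Works on empty and non-empty projects alike (rows append). Non-mapped
    header columns become property columns in file order. Row numbers in the
    report are 1-based over data rows (the header is row 0).
    """
    path = Path(path)
    df = _read_table(path, fmt, mapping)
    for col in (mapping.id_field, mapping.smiles_field):
        if col not in df.columns:
            raise MolCabinetError(f"mapped column {col!r} not found in {path.name}")
    property_columns = [c for c in df.columns if c not in (mapping.id_field, mapping.smiles_field)]

    report = ImportReport()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        record = dict(zip(df.columns, row))
        report.n_read += 1
        props = {c: str(record[c]) for c in property_columns if str(record[c]) != ""}
        _ingest_row(project, report, i, str(record[mapping.id_field]).strip(),
                    str(record[mapping.smiles_field]).strip(), props)
    return report


def import_sdf(project: Project, path: str | os.PathLike, id_source: str = MOLECULE_TITLE) -> ImportReport:
    """Import a V2000 SDF; structures come from the connection table.

    ``id_source`` selects where the molecule ID comes from: the literal
    string ``"molecule title"`` for the title line, otherwise the name of an
    SDF data field. Every data field becomes a property column.
    """
    path = Path(path)
    if not path.is_file():
        raise MolCabinetError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    report = ImportReport()
    for i, mol in enumerate(supplier, start=1):
        report.n_read += 1
        if mol is None:
            report.invalid_structures.append((i, "malformed SDF record"))
            continue
        # GetProp (not GetPropsAsDict) keeps field values as verbatim strings
        props = {k: mol.GetProp(k) for k in mol.GetPropNames() if not k.startswith("_")}
        if id_source == MOLECULE_TITLE:
            entry_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        else:
            entry_id = props.pop(id_source, "")
        if not entry_id.strip():
            report.invalid_structures.append((i, "missing ID"))
            continue
        smiles = Chem.MolToSmiles(mol)
        _ingest_row(project, report, i, entry_id.strip(), smiles, props)
    return report


def export_table(project: Project, path: str | os.PathLike, fmt: str, separator: str = ",") -> None:
    """Write the project as CSV or XLSX: columns ID, SMILES, then schema.

    The SMILES column carries the canonical form. CSV quoting protects
    property values containing the separator.
    """
    path = Path(path)
    separator = SEPARATORS.get(separator, separator)
    header = ["ID", "SMILES", *project.schema]
    rows = [
        [e.id, e.smiles_canonical, *[e.properties.get(c, "") for c in project.schema]]
        for e in project.entries
    ]
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=separator, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(header)
            writer.writerows(rows)
    elif fmt == "xlsx":
        pd.DataFrame(rows, columns=header).to_excel(path, index=False, engine="openpyxl")
    else:
        raise MolCabinetError(f"unsupported table format: {fmt!r}")


def export_sdf(project: Project, path: str | os.PathLike) -> list[tuple[str, str]]:
    """Write one V2000 record per entry: ID as title, properties as fields.

    Entries whose canonical SMILES cannot be rendered are skipped; the
    returned list holds ``(id, reason)`` for each skipped entry.
    """
    path = Path(path)
    failures: list[tuple[str, str]] = []
    writer = Chem.SDWriter(str(path))
    try:
        for e in project.entries:
            mol = try_mol(e.smiles_canonical)
            if mol is None:
                failures.append((e.id, "structure could not be rendered"))
                continue
            mol.SetProp("_Name", e.id)
            for name in project.schema:
                if name in e.properties:
                    mol.SetProp(name, e.properties[name])
            writer.write(mol)
    finally:
        writer.close()
    return failures


# ---------------------------------------------------------------------------
# HTML grid report
# ---------------------------------------------------------------------------

_HIGHLIGHT_CSS = {"none": "#ffffff", "green": "#c8e6c9", "yellow": "#fff9c4", "red": "#ffcdd2"}


def _depict_svg(smiles: str, size: int = 180) -> str | None:
    try:
        from rdkit.Chem.Draw import rdMolDraw2D
    except ImportError:  # depiction backend unavailable
        return None
    mol = try_mol(smiles)
    if mol is None:
        return None
    drawer = rdMolDraw2D.MolDraw2DSVG(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def grid_report(project: Project, path: str | os.PathLike, depict: bool = True) -> None:
    """Write a self-contained HTML grid, one cell per molecule.

    Each cell shows the ID, a 2-D depiction (inline SVG) when the drawing
    backend is available — the SMILES string otherwise — and the row's
    highlight colour as the cell background.
    """
    cells = []
    for e in project.entries:
        svg = _depict_svg(e.smiles_canonical) if depict else None
        body = svg if svg else f"<code>{html.escape(e.smiles_canonical)}</code>"
        color = _HIGHLIGHT_CSS.get(e.highlight, "#ffffff")
        cells.append(
            f'<div class="mol-cell" data-id="{html.escape(e.id)}" '
            f'data-highlight="{e.highlight}" style="background:{color}">'
            f"<div class='mol-id'>{html.escape(e.id)}</div>{body}</div>"
        )
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(project.name)} — grid</title>"
        "<style>.mol-grid{display:flex;flex-wrap:wrap;gap:8px;font-family:sans-serif}"
        ".mol-cell{border:1px solid #ccc;padding:6px;width:200px;text-align:center}"
        ".mol-id{font-weight:bold;margin-bottom:4px}</style></head>\n"
        f"<body><h1>{html.escape(project.name)}</h1>\n<div class='mol-grid'>\n"
        + "\n".join(cells)
        + "\n</div></body></html>\n"
    )
    Path(path).write_text(doc, encoding="utf-8")
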