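"""In-memory project model and folder-based persistence.

A *project* is an ordered collection of molecule entries plus a property
schema, stored on disk as a plain folder::

    <project>/
        project.json        # name, schema, ordered entries
        attachments/<id>/   # files attached to individual molecules
        lock.json           # single-writer lock record

The folder layout is deliberately diff-able and sync-service friendly: the
table is one UTF-8 JSON file and attachments are ordinary files, so a project
can be shared by dropping the folder into any file-synchronisation service.
When several users open the same folder, only the first holds the read/write
lock; later openers are handed a read-only session together with the lock
owner's identity.
"""

from __future__ import annotations

import datetime as _dt
import getpass
import json
import os
import shutil
import socket
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

from .chem import canonical_smiles
from .errors import (
    DuplicateIdError,
    LockError,
    MolCabinetError,
    ProjectExistsError,
    ProjectLoadError,
    ReadOnlyError,
    UnknownColumnError,
    UnknownIdError,
)

PROJECT_FILE = "project.json"
LOCK_FILE = "lock.json"
ATTACHMENTS_DIR = "attachments"

#: Column names that can never be user property columns: the entry key, the
#: structure column, and the attachment-indicator column.
RESERVED_COLUMNS = ("ID", "SMILES", "#")

HIGHLIGHT_COLORS = ("none", "green", "yellow", "red")

READ_WRITE = "read_write"
READ_ONLY = "read_only"

#: Locks older than this are considered abandoned and may be stolen
#: explicitly; crashes never release the lock file on their own.
DEFAULT_LOCK_TTL_HOURS = 24.0


def default_identity() -> str:
    return f"{getpass.getuser()}@{socket.gethostname()}"


@dataclass
class MoleculeEntry:
    """One compound row: identity, structure, and free-form properties.

    ``smiles_input`` is kept verbatim as the user supplied it;
    ``smiles_canonical`` is the unique spelling used for all matching and
    de-duplication. Property values are uniformly strings — numeric
    interpretation happens at query/sort time.
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    properties: dict[str, str] = field(default_factory=dict)
    highlight: str = "none"
    attachments: list[str] = field(default_factory=list)

    @property
    def has_attachments(self) -> bool:
        """The paperclip indicator shown in the "#" column."""
        return bool(self.attachments)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "smiles_input": self.smiles_input,
            "smiles_canonical": self.smiles_canonical,
            "properties": dict(self.properties),
            "highlight": self.highlight,
            "attachments": list(self.attachments),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeEntry":
        return cls(
            id=d["id"],
            smiles_input=d["smiles_input"],
            smiles_canonical=d["smiles_canonical"],
            properties=dict(d.get("properties", {})),
            highlight=d.get("highlight", "none"),
            attachments=list(d.get("attachments", [])),
        )

    def copy(self) -> "MoleculeEntry":
        return MoleculeEntry.from_dict(self.to_dict())


@dataclass
class LockState:
    owner: str
    acquired_at: str  # ISO-8601, UTC
    mode: str = READ_WRITE
    pid: int = 0

    def age_hours(self) -> float:
        then = _dt.datetime.fromisoformat(self.acquired_at)
        now = _dt.datetime.now(_dt.timezone.utc)
        return (now - then).total_seconds() / 3600.0


class Project:
    """Ordered molecule entries plus a property schema.

    ``schema`` is the ordered list of user property columns; the reserved
    columns ``ID``, ``SMILES`` and ``#`` are implicit and never appear in it.
    ``mode`` records the session access level (:data:`READ_WRITE` or
    :data:`READ_ONLY`); in-memory projects that were never opened from disk
    are writable.
    """

    def __init__(self, name: str, path: Path | None = None):
        self.name = name
        self.path = Path(path) if path is not None else None
        self.entries: list[MoleculeEntry] = []
        self.schema: list[str] = []
        self.mode: str = READ_WRITE
        self.lock_owner: str | None = None
        # Columns written by the descriptor calculator; these may be
        # recomputed (overwritten) freely, unlike user-created columns.
        self.descriptor_columns: set[str] = set()
        self._by_id: dict[str, MoleculeEntry] = {}

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def get(self, entry_id: str) -> MoleculeEntry:
        try:
            return self._by_id[entry_id]
        except KeyError:
            raise UnknownIdError(entry_id) from None

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def _require_writable(self) -> None:
        if self.mode != READ_WRITE:
            raise ReadOnlyError(
                f"project opened read-only (lock held by {self.lock_owner or 'another user'})"
            )

    def _ensure_column(self, name: str) -> None:
        if name in RESERVED_COLUMNS:
            raise MolCabinetError(f"column name {name!r} is reserved")
        if not name:
            raise MolCabinetError("property name must be non-empty")
        if name not in self.schema:
            self.schema.append(name)

    # -- mutation ----------------------------------------------------------

    def add_molecule(self, entry_id: str, smiles: str, properties: dict[str, str] | None = None) -> MoleculeEntry:
        """Append a compound; new property names extend the schema."""
        self._require_writable()
        if not entry_id:
            raise MolCabinetError("molecule ID must be non-empty")
        if entry_id in self._by_id:
            raise DuplicateIdError(entry_id)
        canonical = canonical_smiles(smiles)  # raises InvalidSmilesError
        entry = MoleculeEntry(id=entry_id, smiles_input=smiles, smiles_canonical=canonical)
        for name, value in (properties or {}).items():
            self._ensure_column(name)
            entry.properties[name] = str(value)
        self.entries.append(entry)
        self._by_id[entry_id] = entry
        return entry

    def set_property(self, entry_id: str, name: str, value: str) -> None:
        """Set (or overwrite, edit-in-place) a property value."""
        self._require_writable()
        entry = self.get(entry_id)
        self._ensure_column(name)
        entry.properties[name] = str(value)

    def set_highlight(self, entry_id: str, color: str) -> None:
        """Highlight a row green/yellow/red, or ``none`` to clear it."""
        self._require_writable()
        if color not in HIGHLIGHT_COLORS:
            raise MolCabinetError(
                f"unknown highlight color {color!r}; choose from {', '.join(HIGHLIGHT_COLORS)}"
            )
        self.get(entry_id).highlight = color

    def _rebuild_index(self) -> None:
        self._by_id = {e.id: e for e in self.entries}

    # -- sorting -----------------------------------------------------------

    def sort_entries(self, column: str, descending: bool = False, numeric: bool = False) -> "Project":
        """Return a re-ordered *view* project; the source is untouched.

        With ``numeric`` set, cell values are parsed as decimal numbers and
        entries whose value is missing or unparsable are placed last in
        stable input order; the same placement applies to missing cells in
        lexicographic mode.
        """
        if column not in ("ID", "SMILES") and column not in self.schema:
            raise UnknownColumnError(column)

        def cell(e: MoleculeEntry) -> str | None:
            if column == "ID":
                return e.id
            if column == "SMILES":
                return e.smiles_canonical
            return e.properties.get(column)

        keyed: list[tuple[object, MoleculeEntry]] = []
        unsortable: list[MoleculeEntry] = []
        for e in self.entries:
            v = cell(e)
            if v is None:
                unsortable.append(e)
                continue
            if numeric:
                try:
                    keyed.append((float(v), e))
                except ValueError:
                    unsortable.append(e)
            else:
                keyed.append((v, e))
        keyed.sort(key=lambda kv: kv[0], reverse=descending)

        view = Project(self.name, path=None)
        view.schema = list(self.schema)
        view.descriptor_columns = set(self.descriptor_columns)
        view.entries = [e for _, e in keyed] + unsortable
        view._rebuild_index()
        return view

    # -- attachments (the Chemical Notebook) -------------------------------

    def _attachments_dir(self, entry_id: str) -> Path:
        if self.path is None:
            raise MolCabinetError("project must be saved to a folder before attaching files")
        return self.path / ATTACHMENTS_DIR / entry_id

    def attach_file(self, entry_id: str, source_path: str | os.PathLike) -> str:
        """Copy a file under ``attachments/<id>/`` and record its name.

        Name collisions are resolved by suffixing ``_1``, ``_2``, … before
        the extension — an existing attachment is never overwritten.
        Returns the stored file name.
        """
        self._require_writable()
        entry = self.get(entry_id)
        src = Path(source_path)
        if not src.is_file():
            raise MolCabinetError(f"attachment source not readable: {src}")
        dest_dir = self._attachments_dir(entry_id)
        dest_dir.mkdir(parents=True, exist_ok=True)
        name = src.name
        stem, ext = os.path.splitext(name)
        counter = 1
        while name in entry.attachments or (dest_dir / name).exists():
            name = f"{stem}_{counter}{ext}"
            counter += 1
        shutil.copyfile(src, dest_dir / name)
        entry.attachments.append(name)
        return name

    def list_attachments(self, entry_id: str) -> list[str]:
        return list(self.get(entry_id).attachments)

    def attachment_path(self, entry_id: str, name: str) -> Path:
        """Filesystem path of a stored attachment (the "open" action)."""
        entry = self.get(entry_id)
        if name not in entry.attachments:
            raise MolCabinetError(f"no attachment {name!r} on molecule {entry_id!r}")
        return self._attachments_dir(entry_id) / name

    def delete_attachment(self, entry_id: str, name: str) -> None:
        self._require_writable()
        path = self.attachment_path(entry_id, name)
        if path.exists():
            path.unlink()
        self.get(entry_id).attachments.remove(name)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "molcabinet-project/1",
            "name": self.name,
            "schema": list(self.schema),
            "descriptor_columns": sorted(self.descriptor_columns),
            "entries": [e.to_dict() for e in self.entries],
        }

    @classmethod
    def from_dict(cls, d: dict, path: Path | None = None) -> "Project":
        p = cls(d["name"], path=path)
        p.schema = list(d.get("schema", []))
        p.descriptor_columns = set(d.get("descriptor_columns", []))
        p.entries = [MoleculeEntry.from_dict(e) for e in d.get("entries", [])]
        p._rebuild_index()
        return p

    def copy(self, name: str | None = None) -> "Project":
        """Deep copy detached from disk (used by the query engine)."""
        clone = Project.from_dict(self.to_dict(), path=None)
        if name is not None:
            clone.name = name
        return clone


# ---------------------------------------------------------------------------
# folder persistence and the single-writer lock
# ---------------------------------------------------------------------------


def is_project_folder(path: str | os.PathLike) -> bool:
    return (Path(path) / PROJECT_FILE).is_file()


def _write_json_atomic(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=1, ensure_ascii=False), encoding="utf-8")
    os.replace(tmp, path)


def create_project(path: str | os.PathLike, name: str, identity: str | None = None) -> Project:
    """Create and persist an empty project at ``path``.

    The caller becomes the lock owner in read/write mode. Refuses to create
    over an existing project folder.
    """
    folder = Path(path)
    if is_project_folder(folder):
        raise ProjectExistsError(f"{folder} already contains a project")
    folder.mkdir(parents=True, exist_ok=True)
    (folder / ATTACHMENTS_DIR).mkdir(exist_ok=True)
    project = Project(name, path=folder)
    _write_json_atomic(folder / PROJECT_FILE, project.to_dict())
    identity = identity or default_identity()
    _acquire_lock(folder, identity)
    project.mode = READ_WRITE
    project.lock_owner = identity
    return project


def _acquire_lock(folder: Path, identity: str) -> LockState:
    """Atomically create the lock record; raises LockError if already held.

    Atomicity relies on O_EXCL file creation, which is also honoured by the
    file-synchronisation services the folder may live on.
    """
    state = LockState(
        owner=identity,
        acquired_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        mode=READ_WRITE,
        pid=os.getpid(),
    )
    lock_path = folder / LOCK_FILE
    try:
        fd = os.open(lock_path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
    except FileExistsError:
        raise LockError(f"lock already held on {folder}") from None
    with os.fdopen(fd, "w", encoding="utf-8") as fh:
        json.dump(state.__dict__, fh)
    return state


def read_lock(path: str | os.PathLike) -> LockState | None:
    """Current lock record, or ``None`` if the project is unlocked."""
    lock_path = Path(path) / LOCK_FILE
    if not lock_path.exists():
        return None
    try:
        d = json.loads(lock_path.read_text(encoding="utf-8"))
        return LockState(
            owner=d["owner"],
            acquired_at=d["acquired_at"],
            mode=d.get("mode", READ_WRITE),
            pid=d.get("pid", 0),
        )
    except (json.JSONDecodeError, KeyError):
        # A half-written lock file counts as held by an unknown owner.
        return LockState(owner="<unknown>", acquired_at=_dt.datetime.now(_dt.timezone.utc).isoformat())


def release_lock(path: str | os.PathLike, identity: str) -> None:
    """Release the read/write lock if held by ``identity``."""
    state = read_lock(path)
    if state is None:
        return
    if state.owner != identity:
        raise LockError(f"lock on {path} is held by {state.owner}, not {identity}")
    (Path(path) / LOCK_FILE).unlink(missing_ok=True)


def break_lock(path: str | os.PathLike) -> None:
    """Forcibly remove the lock record (the explicit steal action)."""
    (Path(path) / LOCK_FILE).unlink(missing_ok=True)


def load_project_table(path: str | os.PathLike) -> Project:
    """Read ``project.json`` without touching the lock."""
    folder = Path(path)
    table = folder / PROJECT_FILE
    if not table.is_file():
        raise ProjectLoadError(f"missing project table file: {table}")
    try:
        data = json.loads(table.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ProjectLoadError(f"corrupt project table file: {table} ({exc})") from exc
    if not isinstance(data, dict) or "name" not in data:
        raise ProjectLoadError(f"corrupt project table file: {table} (not a project table)")
    return Project.from_dict(data, path=folder)


def open_project(
    path: str | os.PathLike,
    identity: str | None = None,
    *,
    read_only: bool = False,
    lock_ttl_hours: float = DEFAULT_LOCK_TTL_HOURS,
    steal: bool = False,
) -> tuple[Project, str]:
    """Open a project folder, arbitrating the single read/write slot.

    The first opener gets :data:`READ_WRITE` and the lock records them as
    owner; while the lock is live, every later opener gets :data:`READ_ONLY`
    and ``project.lock_owner`` names the active writer (the notification
    content). A lock older than ``lock_ttl_hours`` is stale and may be
    force-broken by passing ``steal=True``; this never happens implicitly.

    Returns ``(project, mode)``.
    """
    folder = Path(path)
    identity = identity or default_identity()
    project = load_project_table(folder)

    if read_only:
        state = read_lock(folder)
        project.mode = READ_ONLY
        project.lock_owner = state.owner if state else None
        return project, READ_ONLY

    state = read_lock(folder)
    if state is not None and steal and state.age_hours() > lock_ttl_hours:
        break_lock(folder)
        state = None
    if state is None:
        try:
            _acquire_lock(folder, identity)
        except LockError:
            state = read_lock(folder)  # lost the race to a concurrent opener
        else:
            project.mode = READ_WRITE
            project.lock_owner = identity
            return project, READ_WRITE
    project.mode = READ_ONLY
    project.lock_owner = state.owner if state else None
    return project, READ_ONLY


def save_project(project: Project, path: str | os.PathLike | None = None) -> None:
    """Persist the in-memory state; ``load(save(P))`` reproduces ``P``.

    Requires a read/write session. ``path`` may be given for a project not
    yet bound to a folder.
    """
    if project.mode != READ_WRITE:
        raise ReadOnlyError("cannot save: session is read-only")
    if path is not None:
        project.path = Path(path)
    if project.path is None:
        raise MolCabinetError("project has no folder; pass a path to save to")
    project.path.mkdir(parents=True, exist_ok=True)
    (project.path / ATTACHMENTS_DIR).mkdir(exist_ok=True)
    _write_json_atomic(project.path / PROJECT_FILE, project.to_dict())


def close_project(project: Project, identity: str | None = None) -> None:
    """Release the read/write lock held by this session, if any."""
    if project.mode == READ_WRITE and project.path is not None:
        release_lock(project.path, identity or project.lock_owner or default_identity())
        project.mode = READ_ONLY


@contextmanager
def project_session(path: str | os.PathLike, identity: str | None = None, **open_kwargs):
    """Open read/write, yield the project, save and release on clean exit."""
    identity = identity or default_identity()
    project, mode = open_project(path, identity, **open_kwargs)
    try:
        yield project
        if mode == READ_WRITE:
            save_project(project)
    finally:
        if mode == READ_WRITE:
            close_project(project, identity)
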