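"""Exception hierarchy.

User-facing errors derive from :class:`MolCabinetError` so callers (and the
CLI) can separate expected rejections — duplicate IDs, bad SMILES, read-only
sessions — from genuine bugs or I/O faults.
"""


class MolCabinetError(Exception):
    """Base class for all expected, user-correctable errors."""


class InvalidSmilesError(MolCabinetError):
    """A SMILES string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DuplicateIdError(MolCabinetError):
    def __init__(self, entry_id: str):
        self.entry_id = entry_id
        super().__init__(f"duplicate molecule ID: {entry_id!r}")


class UnknownIdError(MolCabinetError):
    def __init__(self, entry_id: str):
        self.entry_id = entry_id
        super().__init__(f"no molecule with ID {entry_id!r}")


class UnknownColumnError(MolCabinetError):
    def __init__(self, column: str):
        self.column = column
        super().__init__(f"unknown column: {column!r}")


class ProjectExistsError(MolCabinetError):
    """The target folder already holds a project."""


class ProjectLoadError(MolCabinetError):
    """The project table file is missing or corrupt; message names the file."""


class ReadOnlyError(MolCabinetError):
    """A mutating operation was attempted in a read-only session."""


class LockError(MolCabinetError):
    """Lock acquisition or release failed."""
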