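"""CAS registry number resolution to structures and IUPAC names.

A CAS number has the form ``dd…d-dd-d`` (2–7 digits, 2 digits, 1 check
digit).  The check digit is the position-weighted digit sum modulo 10:
counting the digits that precede the check digit from right to left as
positions 1, 2, 3, …, the check digit must equal Σ position·digit mod 10.
Validation happens before any network traffic.

Resolution goes through a :class:`ResolverClient`; two implementations are
provided.  :class:`FixtureResolverClient` replays a recorded CAS→(SMILES,
IUPAC name) map from memory or a JSON file and is fully deterministic and
offline.  :class:`PubChemClient` queries the PubChem PUG REST service over
HTTP with polite rate limiting and retries; it is only ever used when a
caller constructs it explicitly.
"""

from __future__ import annotations

import json
import os
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .chem import try_mol
from .io_formats import ImportReport
from .project import Project

CAS_PATTERN = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

RESOLVED = "resolved"
NOT_FOUND = "not_found"
INVALID_CAS = "invalid_cas"
NETWORK_ERROR = "network_error"

#: Name of the property column that receives the IUPAC name on CAS import.
IUPAC_NAME_COLUMN = "IUPAC name"


@dataclass
class CasRecord:
    cas: str
    smiles: str | None = None
    iupac_name: str | None = None
    status: str = NOT_FOUND
    note: str = ""

    @property
    def resolved(self) -> bool:
        return self.status == RESOLVED


class ResolverTransportError(Exception):
    """Transport-level failure talking to the resolution service."""


def validate_cas(cas: str) -> bool:
    """True iff ``cas`` is well-formed and its check digit verifies."""
    if not isinstance(cas, str):
        return False
    m = CAS_PATTERN.match(cas.strip())
    if not m:
        return False
    digits = m.group(1) + m.group(2)  # digits preceding the check digit
    check = int(m.group(3))
    total = sum(pos * int(d) for pos, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


class FixtureResolverClient:
    """Deterministic resolver replaying a recorded CAS→structure map.

    ``mapping`` is ``{cas: [smiles, iupac_name]}``, given directly or as a
    JSON file path. ``n_lookups`` counts the lookups actually issued, which
    makes cache behaviour observable.
    """

    def __init__(self, mapping: dict | str | os.PathLike):
        if not isinstance(mapping, dict):
            mapping = json.loads(Path(mapping).read_text(encoding="utf-8"))
        self._map = {k: tuple(v) for k, v in mapping.items()}
        self.n_lookups = 0

    def lookup(self, cas: str) -> tuple[str, str] | None:
        self.n_lookups += 1
        return self._map.get(cas)


class PubChemClient:
    """Live client for a PubChem-PUG-style REST endpoint.

    Requests the canonical SMILES and IUPAC name by compound name (CAS
    numbers are registered as synonyms). When one CAS maps to several
    records, the first returned record is taken. At least ``min_interval``
    seconds elapse between requests; transient failures are retried with
    exponential backoff before raising :class:`ResolverTransportError`.
    """

    BASE = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"

    def __init__(self, min_interval: float = 0.2, retries: int = 3, timeout: float = 15.0):
        self.min_interval = min_interval
        self.retries = retries
        self.timeout = timeout
        self._last_request = 0.0

    def _get(self, url: str) -> bytes:
        delay = 0.5
        for attempt in range(self.retries + 1):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            try:
                self._last_request = time.monotonic()
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise
                if attempt == self.retries:
                    raise ResolverTransportError(str(exc)) from exc
            except (urllib.error.URLError, OSError) as exc:
                if attempt == self.retries:
                    raise ResolverTransportError(str(exc)) from exc
            time.sleep(delay)
            delay *= 2
        raise ResolverTransportError("unreachable")

    def lookup(self, cas: str) -> tuple[str, str] | None:
        url = (
            f"{self.BASE}/compound/name/{urllib.parse.quote(cas)}"
            "/property/CanonicalSMILES,IUPACName/JSON"
        )
        try:
            payload = json.loads(self._get(url))
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                return None
            raise ResolverTransportError(str(exc)) from exc
        props = payload.get("PropertyTable", {}).get("Properties", [])
        if not props:
            return None
        first = props[0]  # first record wins on multi-record CAS numbers
        smiles = first.get("CanonicalSMILES") or first.get("SMILES")
        if not smiles:
            return None
        return smiles, first.get("IUPACName", "")


def resolve_cas(cas: str, client, cache: dict[str, CasRecord] | None = None) -> CasRecord:
    """Resolve one CAS number through ``client``.

    Malformed numbers are rejected without any client call. Results
    (including not-found) are cached per CAS; transport failures are not
    cached, so a later retry can succeed. Never raises for resolution
    problems — the status field carries the outcome.
    """
    cas = cas.strip()
    if not validate_cas(cas):
        return CasRecord(cas=cas, status=INVALID_CAS, note="malformed CAS number")
    if cache is not None and cas in cache:
        return cache[cas]
    try:
        hit = client.lookup(cas)
    except ResolverTransportError as exc:
        return CasRecord(cas=cas, status=NETWORK_ERROR, note=str(exc))
    if hit is None:
        record = CasRecord(cas=cas, status=NOT_FOUND)
    else:
        smiles, iupac = hit
        if try_mol(smiles) is None:
            record = CasRecord(cas=cas, status=NOT_FOUND, note=f"service returned unparsable structure {smiles!r}")
        else:
            record = CasRecord(cas=cas, smiles=smiles, iupac_name=iupac, status=RESOLVED)
    if cache is not None:
        cache[cas] = record
    return record


def resolve_cas_list(path: str | os.PathLike, client) -> list[CasRecord]:
    """Resolve a plain-text file of CAS numbers, one per line.

    Blank lines are ignored; order is preserved; duplicate numbers are
    served from an in-call cache so each distinct CAS costs one lookup.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    cache: dict[str, CasRecord] = {}
    return [resolve_cas(line, client, cache) for line in lines if line.strip()]


def status_counts(records: list[CasRecord]) -> dict[str, int]:
    counts = {RESOLVED: 0, NOT_FOUND: 0, INVALID_CAS: 0, NETWORK_ERROR: 0}
    for r in records:
        counts[r.status] = counts.get(r.status, 0) + 1
    return counts


def import_cas(project: Project, records: list[CasRecord]) -> ImportReport:
    """Turn resolved records into project entries.

    The entry ID is the CAS number itself; the IUPAC name is stored in the
    ``IUPAC name`` property column. Unresolved records are counted under
    ``invalid_structures`` with their status as reason; the duplicate policy
    matches file imports (first instance wins, later ones reported).
    """
    report = ImportReport()
    for i, rec in enumerate(records, start=1):
        report.n_read += 1
        if not rec.resolved:
            report.invalid_structures.append((i, rec.status))
            continue
        if rec.cas in project:
            report.duplicates.append((rec.cas, i))
            continue
        project.add_molecule(rec.cas, rec.smiles)
        if rec.iupac_name:
            project.set_property(rec.cas, IUPAC_NAME_COLUMN, rec.iupac_name)
        report.n_imported += 1
    return report
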