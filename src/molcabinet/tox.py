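"""Per-endpoint consensus toxicity scoring on a 0–100 scale.

Four endpoints are supported: mutagenicity, carcinogenicity, estrogenicity
and hepatotoxicity.  Each endpoint is scored by an *ensemble* of
fingerprint-based probabilistic classifiers; the consensus score is the
arithmetic mean of the member probabilities scaled to 0–100 and rounded
half-up to an integer.  Scoring is entirely local — no network access.

The bundled training harness fits placeholder ensembles: logistic models
over Morgan fingerprints, each trained on a bootstrap resample of a
labelled (SMILES, 0/1) dataset.  Training is fully deterministic given the
dataset, the member count, and the seed, so ensembles can be rebuilt
reproducibly instead of being shipped as opaque binaries.  The placeholder
models carry no toxicological validity; they exist to exercise the scoring
contract end to end on data with a planted structure–label signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .chem import mol_from_smiles, try_mol
from .errors import MolCabinetError
from .project import Project
from .query import FP_BITS, FP_RADIUS, _fp_generator

ENDPOINTS = ("mutagenicity", "carcinogenicity", "estrogenicity", "hepatotoxicity")

TOX_COLUMNS = {
    "mutagenicity": "Tox_Mutagenicity",
    "carcinogenicity": "Tox_Carcinogenicity",
    "estrogenicity": "Tox_Estrogenicity",
    "hepatotoxicity": "Tox_Hepatotoxicity",
}


@dataclass(frozen=True)
class ToxScore:
    endpoint: str
    score: int  # 0–100

    def __post_init__(self):
        if not 0 <= self.score <= 100:
            raise MolCabinetError(f"toxicity score out of range: {self.score}")


@dataclass
class EndpointEnsemble:
    """Non-empty list of probabilistic classifiers plus training metadata."""

    endpoint: str
    models: list = field(default_factory=list)
    seed: int = 0
    fp_radius: int = FP_RADIUS
    fp_bits: int = FP_BITS

    def member_probabilities(self, smiles: str) -> list[float]:
        x = _features([smiles])
        return [float(m.predict_proba(x)[0, 1]) for m in self.models]


def _features(smiles_list: list[str]) -> np.ndarray:
    rows = []
    for smi in smiles_list:
        fp = _fp_generator.GetFingerprint(mol_from_smiles(smi))
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
    return np.asarray(rows, dtype=np.float64)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def consensus_score(smiles: str, ensemble: EndpointEnsemble) -> ToxScore:
    """Mean member probability × 100, rounded half-up.

    Deterministic for frozen models; a consensus of m identical models
    equals the single-model score.
    """
    if not ensemble.models:
        raise MolCabinetError("ensemble has no models")
    probs = ensemble.member_probabilities(smiles)
    return ToxScore(endpoint=ensemble.endpoint, score=_round_half_up(100.0 * sum(probs) / len(probs)))


def train_placeholder_ensemble(
    dataset: list[tuple[str, int]], n_models: int = 5, seed: int = 0, endpoint: str = "mutagenicity"
) -> EndpointEnsemble:
    """Fit ``n_models`` bootstrap-resampled logistic models on the dataset.

    The dataset must contain both classes. Resampling is driven by ``seed``;
    each bootstrap is redrawn until it contains both classes so every member
    yields calibrated two-class probabilities. Fully reproducible given
    ``(dataset, n_models, seed)``.
    """
    if n_models < 1:
        raise MolCabinetError("n_models must be >= 1")
    labels = np.asarray([int(lbl) for _, lbl in dataset])
    if len(set(labels.tolist())) < 2:
        raise MolCabinetError("training dataset must contain both classes")
    x = _features([smi for smi, _ in dataset])
    rng = np.random.default_rng(seed)
    n = len(dataset)
    models = []
    for _ in range(n_models):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(set(labels[idx].tolist())) == 2:
                break
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(x[idx], labels[idx])
        models.append(clf)
    return EndpointEnsemble(endpoint=endpoint, models=models, seed=seed)


def default_ensembles(seed: int = 2023, n_models: int = 5, n_train: int = 200) -> dict[str, EndpointEnsemble]:
    """Deterministically rebuild one placeholder ensemble per endpoint.

    Each endpoint trains on its own seeded synthetic dataset (planted
    nitro-group signal), so rebuilt ensembles score identically across
    processes without any serialized model files.
    """
    from .fixtures import generate_tox_dataset

    ensembles = {}
    for k, endpoint in enumerate(ENDPOINTS):
        data = generate_tox_dataset(n_train, seed=seed + 101 * k)
        ensembles[endpoint] = train_placeholder_ensemble(
            data, n_models=n_models, seed=seed + 13 * k, endpoint=endpoint
        )
    return ensembles


def predict_project(
    project: Project, endpoints, ensembles: dict[str, EndpointEnsemble]
) -> list[tuple[str, str]]:
    """Score every entry for the requested endpoints into ``Tox_*`` columns.

    All computation is local. Per-entry SMILES failures leave the cell
    absent and are returned as ``(id, reason)`` pairs; they never abort the
    batch. Unknown endpoint names raise.
    """
    if project.mode != "read_write":
        raise MolCabinetError("toxicity prediction requires a read/write session")
    endpoints = tuple(endpoints)
    unknown = [e for e in endpoints if e not in ENDPOINTS]
    if unknown:
        raise MolCabinetError(f"unknown endpoints: {', '.join(unknown)}")
    missing = [e for e in endpoints if e not in ensembles]
    if missing:
        raise MolCabinetError(f"no ensemble supplied for: {', '.join(missing)}")
    failures: list[tuple[str, str]] = []
    for entry in project.entries:
        if try_mol(entry.smiles_canonical) is None:
            failures.append((entry.id, f"invalid SMILES: {entry.smiles_canonical!r}"))
            continue
        for endpoint in endpoints:
            score = consensus_score(entry.smiles_canonical, ensembles[endpoint])
            project.set_property(entry.id, TOX_COLUMNS[endpoint], str(score.score))
    return failures
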