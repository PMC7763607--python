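"""Synthetic compound datasets with planted fragment effects.

Molecules are assembled by concatenating chemically valid SMILES building
blocks (chain extenders plus terminal groups), which guarantees parseable,
drug-like structures without a valence-repair pass.  The grammar covers
the moiety classes whose influence on blood-brain barrier permeability is
chemically interpretable: alkyl chains, aromatic rings, ethers, amines,
amides, carboxylic acids, halogens, nitriles and sulfur groups.

The endpoint is constructed from ground truth: a linear combination of
the occurrence counts of a small set of *active* fragments (canonical
level-1 fragment keys with signed coefficients in log units), optionally
passed through a mild squashing nonlinearity, plus Gaussian noise, clipped
to a realistic LogBB span.  Because the planted coefficients are returned
alongside the data, every downstream stage — selection, double-CV
training, the guarded predictor, and fragment-contribution recovery — can
be tested against known truth without any download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .fragments import enumerate_fragments
from .molgraph import CompoundRecord, parse_structure

# chain tokens concatenate head-to-tail into valid SMILES; terminal tokens
# close the molecule
CHAIN_TOKENS = (
    "C", "CC", "CCC", "CO", "CN", "CC(C)", "c1ccccc1", "C(=O)N", "CS",
    "c1ccc(F)cc1", "C(C)O",
)
TERMINAL_TOKENS = (
    "C", "CC", "O", "N", "F", "Cl", "C(F)(F)F", "C(=O)O", "C#N", "N(C)C",
    "OC", "C(=O)N",
)

# planted effects: canonical level-1 fragment keys -> log-unit coefficient.
# Signs follow the known structure-permeability trends: carbon richness,
# fluorine and aromatic character raise LogBB; oxygens, carbonyls and
# amines lower it.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "L1|path|C": 0.10,
    "L1|path|O": -0.40,
    "L1|path|N": -0.30,
    "L1|path|F": 0.25,
    "L1|path|Cl": 0.20,
    "L1|path|C=O": -0.35,
    "L1|path|C:C": 0.05,
}
DEFAULT_INTERCEPT = -0.7

NONLINEARITIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda z: z,
    # mild saturation towards the ends of the LogBB scale
    "tanh": lambda z: 2.4 * np.tanh(z / 2.4),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic generator."""

    n_compounds: int = 500
    chain_tokens: tuple[str, ...] = CHAIN_TOKENS
    terminal_tokens: tuple[str, ...] = TERMINAL_TOKENS
    min_chain: int = 1
    max_chain: int = 5
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float = DEFAULT_INTERCEPT
    nonlinearity: str = "identity"
    noise_sd: float = 0.3
    clip_range: tuple[float, float] = (-2.2, 1.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


def _random_smiles(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    n_chain = int(rng.integers(spec.min_chain, spec.max_chain + 1))
    parts = [
        spec.chain_tokens[rng.integers(len(spec.chain_tokens))]
        for _ in range(n_chain)
    ]
    parts.append(spec.terminal_tokens[rng.integers(len(spec.terminal_tokens))])
    return "".join(parts)


def generate_dataset(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[list[CompoundRecord], dict[str, float]]:
    """Generate compounds with a planted fragment-effect endpoint.

    Returns the records (id, graph, LogBB) and the ground-truth coefficient
    map used to construct the endpoint.  Deterministic given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    squash = NONLINEARITIES[spec.nonlinearity]
    records: list[CompoundRecord] = []
    attempts = 0
    while len(records) < spec.n_compounds:
        attempts += 1
        if attempts > 50 * spec.n_compounds:
            raise RuntimeError("grammar failed to produce valid structures")
        smi = _random_smiles(rng, spec)
        try:
            graph = parse_structure(smi, "smiles", f"syn{len(records):04d}")
        except Exception as exc:
            raise ValueError(f"invalid grammar output {smi!r}: {exc}") from exc
        counts = enumerate_fragments(graph, max_atoms=2, levels=(1,))
        linear = spec.intercept + sum(
            coef * counts.get(key, 0) for key, coef in spec.coefficients.items()
        )
        value = float(squash(np.asarray(linear)))
        value += float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else 0.0
        value = float(np.clip(value, *spec.clip_range))
        records.append(
            CompoundRecord(f"syn{len(records):04d}", graph, value, smiles=smi)
        )
    return records, dict(spec.coefficients)


def write_dataset_csv(
    records: Sequence[CompoundRecord],
    path: str | Path,
    coefficients: Mapping[str, float] | None = None,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write the standard id/smiles/logbb CSV plus an optional ground-truth
    sidecar (fragment key, coefficient)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "logbb"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles, rec.logbb])
    if coefficients is not None and sidecar_path is not None:
        with open(sidecar_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fragment_key", "coefficient"])
            for key, coef in coefficients.items():
                writer.writerow([key, coef])


@dataclass(frozen=True)
class ToyFixture:
    """A hand-checked molecule with its manually enumerated fragment counts."""

    name: str
    smiles: str
    max_atoms: int
    level: int
    expected_counts: Mapping[str, int]


def make_toy_fixtures() -> list[ToyFixture]:
    """Micro-fixtures with fragment counts enumerated by hand.

    Counts are complete level-1 maps at the stated ``max_atoms`` for each
    molecule; they anchor the enumeration oracle tests.
    """
    return [
        ToyFixture("methane", "C", 3, 1, {"L1|path|C": 1}),
        ToyFixture("ethane", "CC", 3, 1,
                   {"L1|path|C": 2, "L1|path|C-C": 1}),
        ToyFixture("propane", "CCC", 3, 1,
                   {"L1|path|C": 3, "L1|path|C-C": 2, "L1|path|C-C-C": 1}),
        ToyFixture("butane", "CCCC", 4, 1,
                   {"L1|path|C": 4, "L1|path|C-C": 3, "L1|path|C-C-C": 2,
                    "L1|path|C-C-C-C": 1}),
        ToyFixture("isobutane", "CC(C)C", 4, 1,
                   {"L1|path|C": 4, "L1|path|C-C": 3, "L1|path|C-C-C": 3,
                    "L1|branch|C(-C,-C,-C)": 1}),
        ToyFixture("neopentane", "CC(C)(C)C", 4, 1,
                   {"L1|path|C": 5, "L1|path|C-C": 4, "L1|path|C-C-C": 6,
                    "L1|branch|C(-C,-C,-C)": 4}),
        ToyFixture("cyclohexane", "C1CCCCC1", 6, 1,
                   {"L1|path|C": 6, "L1|path|C-C": 6, "L1|path|C-C-C": 6,
                    "L1|path|C-C-C-C": 6, "L1|path|C-C-C-C-C": 6,
                    "L1|cycle|C-C-C-C-C-C-": 1}),
        ToyFixture("benzene", "c1ccccc1", 6, 1,
                   {"L1|path|C": 6, "L1|path|C:C": 6, "L1|path|C:C:C": 6,
                    "L1|path|C:C:C:C": 6, "L1|path|C:C:C:C:C": 6,
                    "L1|cycle|C:C:C:C:C:C:": 1}),
        ToyFixture("ethanol", "CCO", 3, 1,
                   {"L1|path|C": 2, "L1|path|O": 1, "L1|path|C-C": 1,
                    "L1|path|C-O": 1, "L1|path|C-C-O": 1}),
        ToyFixture("dimethyl_ether", "COC", 3, 1,
                   {"L1|path|C": 2, "L1|path|O": 1, "L1|path|C-O": 2,
                    "L1|path|C-O-C": 1}),
        ToyFixture("acetic_acid", "CC(=O)O", 4, 1,
                   {"L1|path|C": 2, "L1|path|O": 2, "L1|path|C-C": 1,
                    "L1|path|C=O": 1, "L1|path|C-O": 1, "L1|path|C-C=O": 1,
                    "L1|path|C-C-O": 1, "L1|path|O-C=O": 1,
                    "L1|branch|C(-C,-O,=O)": 1}),
        ToyFixture("ethylamine", "CCN", 3, 1,
                   {"L1|path|C": 2, "L1|path|N": 1, "L1|path|C-C": 1,
                    "L1|path|C-N": 1, "L1|path|C-C-N": 1}),
        ToyFixture("toluene", "Cc1ccccc1", 3, 1,
                   {"L1|path|C": 7, "L1|path|C-C": 1, "L1|path|C:C": 6,
                    "L1|path|C-C:C": 2, "L1|path|C:C:C": 6}),
        ToyFixture("pyridine", "c1ccncc1", 3, 1,
                   {"L1|path|C": 5, "L1|path|N": 1, "L1|path|C:C": 4,
                    "L1|path|C:N": 2, "L1|path|C:C:C": 3,
                    "L1|path|C:C:N": 2, "L1|path|C:N:C": 1}),
        ToyFixture("chlorobenzene", "Clc1ccccc1", 3, 1,
                   {"L1|path|C": 6, "L1|path|Cl": 1, "L1|path|C-Cl": 1,
                    "L1|path|C:C": 6, "L1|path|C:C-Cl": 2,
                    "L1|path|C:C:C": 6}),
    ]
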