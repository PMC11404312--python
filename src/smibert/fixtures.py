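"""Synthetic SMILES corpora and multitask label tables.

Everything in this package is testable offline: molecules are assembled
from valence-safe fragments (alkyl/heteroatom chains, benzene rings,
cycloalkane rings, terminal halogens), validated with RDKit and
deduplicated by canonical form, so every corpus is a set of real, parseable
molecules. Labels are deterministic functions of the molecule's *token
statistics* (e.g., the count of "O" tokens, or the presence of aromatic
"c") plus optional Gaussian noise — the tokenizer itself can recover the
ground truth, which makes learnability checks self-contained.

These corpora emulate the shape of chemical datasets (variable length,
rings, branches, heteroatoms, missing labels) but not drug-likeness or any
realistic property distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from rdkit import Chem

from .chem_text import TokenSequence, tokenize
from .datasets import MoleculeRecord, TaskTable

__all__ = [
    "FixtureSpec",
    "LabelRule",
    "generate_corpus",
    "generate_task_table",
    "token_count_rule",
    "contains_token_rule",
]

_CHAIN_ATOMS = ("C", "N", "O", "S")
_HALOGENS = ("F", "Cl", "Br")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic corpus."""

    n_molecules: int = 100
    min_heavy_atoms: int = 3
    max_heavy_atoms: int = 18
    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br")
    aromatic: bool = True
    seed: int = 0
    max_attempts_per_molecule: int = 200


@dataclass(frozen=True)
class LabelRule:
    """A deterministic map from token statistics to a label.

    ``func`` receives the molecule's :class:`TokenSequence`; regression
    rules may add Gaussian noise of the stated sigma, classification rules
    are thresholded to {0, 1}.
    """

    name: str
    kind: str  # "classification" | "regression"
    func: Callable[[TokenSequence], float]
    noise_sigma: float = 0.0


def token_count_rule(token: str, name: str | None = None,
                     scale: float = 1.0, offset: float = 0.0,
                     noise_sigma: float = 0.0) -> LabelRule:
    """Regression rule: offset + scale * (count of ``token``) + noise."""
    return LabelRule(
        name=name or f"count_{token}",
        kind="regression",
        func=lambda seq: offset + scale * sum(t == token for t in seq.tokens),
        noise_sigma=noise_sigma,
    )


def contains_token_rule(token: str, name: str | None = None) -> LabelRule:
    """Classification rule: 1 if the token occurs, else 0."""
    return LabelRule(
        name=name or f"has_{token}",
        kind="classification",
        func=lambda seq: float(any(t == token for t in seq.tokens)),
    )


# Chain fragments with sampling weights chosen to mimic the composition of
# drug-like molecules: carbon dominates the heavy-atom count (~70-75% in
# typical libraries), heteroatoms appear mostly inside stereotyped
# functional groups (carbonyl, ester, amide, ether, amine), and rings —
# especially aromatic ones — occur in the large majority of structures.
_FRAGMENTS: tuple[tuple[str, float], ...] = (
    ("C", 6.0), ("CC", 5.0), ("CCC", 3.0), ("C(C)C", 2.0),
    ("O", 1.5), ("N", 1.5), ("S", 0.5),
    ("C(=O)", 1.0), ("C(=O)O", 1.0), ("C(=O)N", 1.0), ("OC", 1.0),
)
_RING_PREFIXES: tuple[tuple[str, float, int], ...] = (
    ("c1ccccc1", 0.5, 6),    # benzene
    ("C1CCCCC1", 0.1, 6),    # cyclohexane
    ("C1CCCC1", 0.05, 5),    # cyclopentane
)


def _heavy_atoms(fragment: str) -> int:
    return sum(ch in "CNOScnos" for ch in fragment)


def _candidate(rng: np.random.Generator, spec: FixtureSpec) -> str:
    allowed = set(spec.elements)
    frags = [(f, w) for f, w in _FRAGMENTS
             if all(ch not in "NOS" or ch in allowed for ch in f)]
    if "C" not in allowed:
        frags = [(f, w) for f, w in frags if "C" not in f]
    if not frags:
        frags = [("C", 1.0)]
    names = [f for f, _ in frags]
    weights = np.array([w for _, w in frags])
    weights = weights / weights.sum()
    halos = tuple(e for e in spec.elements if e in _HALOGENS)

    size = int(rng.integers(spec.min_heavy_atoms, spec.max_heavy_atoms + 1))
    parts: list[str] = []
    count = 0
    u = rng.random()
    if "C" in allowed and size >= 6:
        acc = 0.0
        for ring, prob, natoms in _RING_PREFIXES:
            if ring.startswith("c") and not spec.aromatic:
                continue
            acc += prob
            if u < acc:
                parts.append(ring)
                count += natoms
                break
    while count < size:
        f = str(rng.choice(names, p=weights))
        if _heavy_atoms(f) > size - count:
            f = min(names, key=_heavy_atoms)  # smallest fragment fits last
        parts.append(f)
        count += _heavy_atoms(f)
    if halos and rng.random() < 0.2:
        parts.append(str(rng.choice(halos)))
    return "".join(parts)


def generate_corpus(spec: FixtureSpec) -> list[str]:
    """Draw ``n_molecules`` valid SMILES, unique by canonical form.

    Deterministic under ``spec.seed``. If the spec cannot reach the
    requested count (tiny element sets / size ranges), the partial corpus
    is returned with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts_left = spec.max_attempts_per_molecule * spec.n_molecules
    while len(out) < spec.n_molecules and attempts_left > 0:
        attempts_left -= 1
        smi = _candidate(rng, spec)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        cano = Chem.MolToSmiles(mol)
        if cano in seen:
            continue
        seen.add(cano)
        out.append(smi)
    if len(out) < spec.n_molecules:
        warnings.warn(
            f"could only generate {len(out)} of {spec.n_molecules} unique "
            "molecules for this spec", stacklevel=2,
        )
    return out


def generate_task_table(corpus: list[str], label_rules: list[LabelRule],
                        seed: int = 0, blank_fraction: float = 0.0,
                        source: str | None = "fixture") -> TaskTable:
    """Label a corpus with deterministic token-statistic rules.

    ``blank_fraction`` of cells are independently marked unobserved to
    exercise missing-label handling. Reproducible under ``seed``.
    """
    if not 0.0 <= blank_fraction < 1.0:
        raise ValueError("blank_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    for smi in corpus:
        seq = tokenize(smi)
        labels = np.zeros(len(label_rules))
        observed = np.ones(len(label_rules), dtype=bool)
        for j, rule in enumerate(label_rules):
            val = float(rule.func(seq))
            if rule.kind == "regression":
                if rule.noise_sigma > 0:
                    val += rng.normal(0.0, rule.noise_sigma)
            else:
                val = 1.0 if val >= 0.5 else 0.0
            labels[j] = val
            if blank_fraction > 0 and rng.random() < blank_fraction:
                observed[j] = False
        records.append(MoleculeRecord(smi, labels, observed, source=source))
    return TaskTable([r.name for r in label_rules],
                     [r.kind for r in label_rules], records)
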