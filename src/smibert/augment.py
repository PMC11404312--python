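"""SMILES enumeration as data augmentation.

A molecule has many valid SMILES renderings, obtained by starting the
depth-first traversal from different atoms in different orders. Enumerating
these and training on all of them multiplies the effective dataset size and
forces the model to learn order-invariant structure; at prediction time the
per-rendering predictions are averaged (see :mod:`smibert.inference`).

Enumeration draws random atom orderings with RDKit and keeps only renderings
not seen before for this molecule; after ``retry_cap`` consecutive duplicate
draws for a slot the search stops and fewer variants are returned. The
canonical SMILES is always kept as variant #1 so that a request for a single
variant degrades gracefully to no augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions

__all__ = ["EnumerationResult", "enumerate_smiles", "augment_dataset", "canonical"]


class SmilesParseError(ValueError):
    """The input string is not a valid SMILES."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical(smiles: str) -> str:
    """RDKit canonical SMILES; the equivalence oracle for enumeration."""
    return Chem.MolToSmiles(_mol(smiles))


@dataclass(frozen=True)
class EnumerationResult:
    canonical: str
    variants: tuple[str, ...]
    requested: int
    attempts: int


def enumerate_smiles(smiles: str, n: int, seed: int,
                     retry_cap: int = 100) -> EnumerationResult:
    """Generate up to ``n`` distinct SMILES renderings of one molecule.

    The canonical form is variant #1; further slots draw random-atom-order
    renderings, retrying on duplicates up to ``retry_cap`` consecutive times
    per slot before giving up (small molecules may have fewer than ``n``
    distinct renderings).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = _mol(smiles)
    cano = Chem.MolToSmiles(mol)
    rng = np.random.default_rng(seed)
    variants: list[str] = [cano]
    seen = {cano}
    attempts = 0
    while len(variants) < n:
        failures = 0
        while failures < retry_cap:
            attempts += 1
            order = rng.permutation(mol.GetNumAtoms()).tolist()
            shuffled = Chem.RenumberAtoms(mol, order)
            cand = Chem.MolToSmiles(shuffled, canonical=False)
            if cand in seen:
                failures += 1
                continue
            seen.add(cand)
            variants.append(cand)
            break
        else:
            break  # retry cap exhausted for this slot
    return EnumerationResult(
        canonical=cano, variants=tuple(variants), requested=n, attempts=attempts
    )


def augment_dataset(records, factor: int = 20, seed: int = 0,
                    retry_cap: int = 100) -> list:
    """Expand each record into up to ``factor`` enumerated copies.

    Labels, observed-masks and split assignment are copied verbatim onto
    every variant; the output order is a deterministic shuffle under
    ``seed``. Parse errors are re-raised with the offending record's index.
    """
    from .datasets import MoleculeRecord  # local import avoids a cycle

    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[MoleculeRecord] = []
    for idx, rec in enumerate(records):
        try:
            enum = enumerate_smiles(rec.smiles, n=factor,
                                    seed=int(rng.integers(2**31)),
                                    retry_cap=retry_cap)
        except SmilesParseError as exc:
            raise SmilesParseError(f"record {idx}: {exc}") from exc
        for var in enum.variants:
            out.append(MoleculeRecord(
                smiles=var,
                labels=rec.labels.copy(),
                observed=rec.observed.copy(),
                split=rec.split,
                source=rec.source,
            ))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]
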