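"""Deterministic synthetic drug-like molecule and planted-property generator.

Molecules are assembled from a weighted fragment grammar of chemically valid
pieces (alkyl chains, benzene, pyridine, cyclohexane, halogens, nitro,
hydroxyl, amide, ...) joined by single bonds, so every emitted SMILES parses
by construction and no rejection loop is needed.  Labels are *planted*:
classification labels indicate the presence of a chosen motif (optionally
flipped at a known rate), regression targets are a linear function of the
motif occurrence count plus Gaussian noise.  Ground-truth motif matching uses
the toolkit's substructure search, independent of the hashed-identifier code
the rest of the package tests.

Defaults emulate small drug-like molecules: 2-4 fragments per molecule,
roughly 5-25 heavy atoms, with a mix of rings, heteroatoms and common
functional groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .graph import mol_from_smiles

#: (fragment SMILES, sampling weight); every fragment joins via its first atom
DEFAULT_FRAGMENTS: tuple[tuple[str, float], ...] = (
    ("CC", 0.14),  # ethyl
    ("CCC", 0.12),  # propyl
    ("CCCC", 0.08),  # butyl
    ("c1ccccc1", 0.14),  # benzene
    ("c1ccncc1", 0.08),  # pyridine
    ("C1CCCCC1", 0.07),  # cyclohexane
    ("F", 0.05),
    ("Cl", 0.05),
    ("Br", 0.03),
    ("[N+](=O)[O-]", 0.06),  # nitro
    ("O", 0.07),  # hydroxyl
    ("C(N)=O", 0.06),  # amide
    ("OC", 0.05),  # methoxy
    ("N", 0.05),  # amine (splice point)
)


@dataclass
class GeneratorSpec:
    n_molecules: int = 1000
    seed: int = 0
    fragments: tuple[tuple[str, float], ...] = DEFAULT_FRAGMENTS
    min_fragments: int = 2
    max_fragments: int = 4

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.min_fragments < 1 or self.max_fragments < self.min_fragments:
            raise ValueError("fragment count bounds are inconsistent")
        for frag, weight in self.fragments:
            if weight < 0:
                raise ValueError(f"negative weight for fragment {frag!r}")
            if Chem.MolFromSmiles(frag, sanitize=False) is None:
                raise ValueError(f"grammar fragment does not parse: {frag!r}")


@dataclass
class PlantedTask:
    task: str  # "classification" | "regression"
    motif: str = "c1ccncc1"  # pyridine ring; ~23% presence under the default grammar
    effect_size: float = 1.0
    noise: float = 0.0  # label-flip rate / Gaussian sd

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "classification" and not 0.0 <= self.noise < 0.5:
            raise ValueError("classification flip rate must be in [0, 0.5)")
        if self.task == "regression" and self.noise < 0:
            raise ValueError("regression noise sd must be >= 0")
        if Chem.MolFromSmarts(self.motif) is None:
            raise ValueError(f"motif does not parse: {self.motif!r}")


def _can_accept_bond(atom: Chem.Atom) -> bool:
    """Whether one more single bond keeps the atom at or below its
    charge-adjusted default valence (e.g. the nitro N+, valence cap 4)."""
    if atom.GetTotalNumHs() > 0:
        return True
    cap = Chem.GetPeriodicTable().GetDefaultValence(atom.GetAtomicNum())
    cap += atom.GetFormalCharge() if atom.GetAtomicNum() in (5, 7) else 0
    return atom.GetExplicitValence() + atom.GetTotalNumHs() < cap


def _attachment_atom(mol: Chem.Mol) -> int:
    """First atom able to accept one more single bond."""
    for atom in mol.GetAtoms():
        if _can_accept_bond(atom):
            return atom.GetIdx()
    raise ValueError("fragment has no attachment point")


def _assemble(fragment_mols: list[Chem.Mol], rng: np.random.Generator) -> str:
    """Join fragments with single bonds at hydrogen-bearing atoms.

    Each new fragment bonds its own attachment atom to a randomly chosen
    hydrogen-bearing atom of the growing molecule, so valences are respected
    by construction and the result always sanitizes.
    """
    grown = Chem.RWMol(fragment_mols[0])
    for frag in fragment_mols[1:]:
        sites = [a.GetIdx() for a in grown.GetAtoms() if a.GetTotalNumHs() > 0]
        if not sites:
            break  # fully substituted; emit what we have
        site = int(rng.choice(sites))
        offset = grown.GetNumAtoms()
        attach = offset + _attachment_atom(frag)
        grown = Chem.RWMol(Chem.CombineMols(grown, frag))
        grown.AddBond(site, attach, Chem.BondType.SINGLE)
        Chem.SanitizeMol(grown)
    return Chem.MolToSmiles(grown)


def gen_molecules(spec: GeneratorSpec) -> list[str]:
    """Sample ``n_molecules`` fragment-assembled SMILES; deterministic in
    ``spec.seed``; duplicates allowed."""
    rng = np.random.default_rng(spec.seed)
    frag_mols = [Chem.MolFromSmiles(f) for f, _ in spec.fragments]
    if any(m is None for m in frag_mols):
        raise ValueError("grammar fragment failed to sanitize")
    weights = np.asarray([w for _, w in spec.fragments], dtype=np.float64)
    weights = weights / weights.sum()
    # the leading (backbone) fragment must be multi-atom and still offer
    # hydrogen-bearing attachment sites for later substituents
    backbone_ok = np.asarray(
        [
            m.GetNumAtoms() > 1 and any(a.GetTotalNumHs() > 0 for a in m.GetAtoms())
            for m in frag_mols
        ]
    )
    backbone_weights = weights * backbone_ok
    backbone_weights = backbone_weights / backbone_weights.sum()
    out = []
    for _ in range(spec.n_molecules):
        k = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        idx = [int(rng.choice(len(frag_mols), p=backbone_weights))]
        idx += [int(i) for i in rng.choice(len(frag_mols), size=k - 1, p=weights)]
        smi = _assemble([frag_mols[i] for i in idx], rng)
        mol_from_smiles(smi)  # grammar guarantee: every draw parses
        out.append(smi)
    return out


def count_motif(smiles: str, motif: str) -> int:
    """Occurrences of ``motif`` (SMARTS/SMILES) by toolkit substructure search."""
    mol = mol_from_smiles(smiles)
    patt = Chem.MolFromSmarts(motif)
    return len(mol.GetSubstructMatches(patt))


def plant_property(
    smiles_list: list[str], task: PlantedTask, seed: int = 0
) -> list[tuple[str, float]]:
    """Label molecules with a planted structure-property relationship.

    classification: label = motif presence, flipped with rate ``noise``;
    regression: target = effect_size * motif count + N(0, noise^2).
    """
    if not smiles_list:
        raise ValueError("empty SMILES list")
    rng = np.random.default_rng(seed)
    rows = []
    for smi in smiles_list:
        count = count_motif(smi, task.motif)
        if task.task == "classification":
            label = float(count > 0)
            if task.noise > 0 and rng.random() < task.noise:
                label = 1.0 - label
        else:
            label = task.effect_size * count + (
                rng.normal(0.0, task.noise) if task.noise > 0 else 0.0
            )
        rows.append((smi, label))
    return rows


def write_dataset_csv(rows: list[tuple[str, float]], path) -> None:
    """Write a labeled dataset as ``smiles,label`` CSV (header included)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "label"])
        for smi, label in rows:
            writer.writerow([smi, label])


def read_dataset_csv(path) -> tuple[list[str], np.ndarray]:
    """Read a ``smiles,label`` CSV into (smiles list, label array)."""
    smiles, labels = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with a 'smiles' column")
        label_col = next(
            (c for c in reader.fieldnames if c != "smiles"), None
        )
        if label_col is None:
            raise ValueError(f"{path}: no label column found")
        for row in reader:
            smiles.append(row["smiles"])
            labels.append(float(row[label_col]))
    return smiles, np.asarray(labels)


def write_smi(smiles_list: list[str], path) -> None:
    Path(path).write_text("".join(s + "\n" for s in smiles_list))
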