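"""SMILES parsing and molecular-sentence generation.

A molecule is read as a hydrogen-suppressed graph and converted into a
*molecular sentence*: the ordered, deduplicated list of 32-bit hashed
identifiers of its atom-centered circular substructures (the extended-
connectivity / Morgan enumeration), one identifier per (atom, radius)
environment.  Sentences are the "words" fed to the downstream vocabulary,
encoder and property models.

Generation proceeds in three stages:

1. every heavy atom receives a radius-0 identifier hashed from five atomic
   invariants (atomic number, heavy-atom degree, attached hydrogens, formal
   charge, ring membership);
2. identifiers are iteratively expanded: at radius t an atom's identifier is
   hashed from its radius-(t-1) identifier plus the sorted (bond-order,
   neighbor-identifier) pairs of its immediate neighbors, and the environment
   is kept only if its bond neighborhood actually grew;
3. duplicate environments are removed — first environments of radius >= 1
   covering an identical bond set (keep the smaller radius, then the smaller
   canonical atom rank), then repeated identifier values (keep the first in
   sentence order) — and the survivors are sorted by (canonical atom rank,
   radius).

Parsing keeps the bonding pattern exactly as written: RDKit's structural
normalization pass (which e.g. rewrites ``N(=O)=O`` into the charge-separated
``[N+](=O)[O-]``) is disabled, while ring perception and aromaticity
perception are kept, so any two SMILES spellings of the same drawn structure
produce the same graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

from .hashing import hash_invariants

RDLogger.DisableLog("rdApp.*")

#: bond-order codes used inside the radius>=1 hash tuples
BOND_ORDER_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


class EmptyMoleculeError(ValueError):
    """Raised when a molecule contains no heavy (non-hydrogen) atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """Invariant properties of one heavy atom."""

    atomic_number: int
    formal_charge: int
    n_heavy_neighbors: int
    n_hydrogens: int
    in_ring: bool


@dataclass(frozen=True)
class BondRecord:
    """A typed bond between two heavy atoms (indices into ``atoms``)."""

    endpoints: tuple[int, int]
    order: str  # "single" | "double" | "triple" | "aromatic"
    order_code: int


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with a canonical atom ranking."""

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    canonical_order: list[int]  # canonical rank of each atom index
    smiles: str = ""
    # adjacency: atom index -> list of (neighbor atom index, bond index)
    neighbors: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class SubstructureEnvironment:
    """An atom-centered circular substructure and its hashed identifier."""

    center: int
    radius: int
    bond_set: frozenset[int]
    identifier: int


@dataclass
class MolecularSentence:
    """Ordered, deduplicated identifier list with (atom rank, radius) provenance."""

    tokens: list[int]
    provenance: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.tokens)

    def as_text(self) -> str:
        """Corpus dialect: space-separated unsigned decimal identifiers."""
        return " ".join(str(t) for t in self.tokens)


_SANITIZE_FLAGS = (
    Chem.SanitizeFlags.SANITIZE_ALL
    ^ Chem.SanitizeFlags.SANITIZE_CLEANUP
    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into an RDKit Mol, perceiving rings/aromaticity but not
    rewriting the drawn bonding pattern.  Raises :class:`SmilesParseError` /
    :class:`EmptyMoleculeError` on bad input."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
        mol = Chem.RemoveHs(mol, sanitize=False, updateExplicitCount=True)
        Chem.SanitizeMol(mol, _SANITIZE_FLAGS)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise SmilesParseError(f"invalid SMILES: {smiles!r} ({exc})") from exc
    if mol.GetNumAtoms() == 0 or all(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        raise EmptyMoleculeError(f"molecule has no heavy atoms: {smiles!r}")
    return mol


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    The graph is hydrogen-suppressed: explicit hydrogens are folded into the
    per-atom hydrogen counts.  ``canonical_order[i]`` is the canonical rank of
    atom ``i`` as produced by the canonical-SMILES algorithm, which is the
    ordering key of the molecular sentence.
    """
    mol = mol_from_smiles(smiles)
    atoms = [
        AtomRecord(
            atomic_number=a.GetAtomicNum(),
            formal_charge=a.GetFormalCharge(),
            n_heavy_neighbors=a.GetDegree(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        code = BOND_ORDER_CODES.get(b.GetBondType())
        if code is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in {smiles!r}"
            )
        bonds.append(
            BondRecord(
                endpoints=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                order={1: "single", 2: "double", 3: "triple", 4: "aromatic"}[code],
                order_code=code,
            )
        )
    ranks = list(Chem.CanonicalRankAtoms(mol))
    neighbors: list[list[tuple[int, int]]] = [[] for _ in atoms]
    for bi, bond in enumerate(bonds):
        i, j = bond.endpoints
        neighbors[i].append((j, bi))
        neighbors[j].append((i, bi))
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        canonical_order=ranks,
        smiles=Chem.MolToSmiles(mol),
        neighbors=neighbors,
    )


def initial_identifiers(graph: MolecularGraph) -> list[SubstructureEnvironment]:
    """Stage 1: one radius-0 environment per heavy atom.

    The identifier hashes the tagged five-invariant tuple, so atoms with
    identical invariants receive identical identifiers.
    """
    if graph.n_atoms == 0:
        raise EmptyMoleculeError("graph has no atoms")
    envs = []
    for idx, atom in enumerate(graph.atoms):
        ident = hash_invariants(
            (
                0,  # radius tag
                atom.atomic_number,
                atom.n_heavy_neighbors,
                atom.n_hydrogens,
                atom.formal_charge,
                int(atom.in_ring),
            )
        )
        envs.append(
            SubstructureEnvironment(
                center=idx, radius=0, bond_set=frozenset(), identifier=ident
            )
        )
    return envs


def _bond_neighborhood(graph: MolecularGraph, center: int, radius: int) -> frozenset[int]:
    """All bonds reachable within ``radius`` breadth-first steps of ``center``."""
    seen_atoms = {center}
    bond_set: set[int] = set()
    frontier = deque([(center, 0)])
    while frontier:
        atom, depth = frontier.popleft()
        if depth == radius:
            continue
        for nbr, bond_idx in graph.neighbors[atom]:
            bond_set.add(bond_idx)
            if nbr not in seen_atoms:
                seen_atoms.add(nbr)
                frontier.append((nbr, depth + 1))
    return frozenset(bond_set)


def expand_identifiers(
    graph: MolecularGraph,
    previous: list[SubstructureEnvironment],
    radius: int | None = None,
) -> list[SubstructureEnvironment]:
    """Stage 2: grow every atom's environment by one bond radius.

    ``previous`` must hold exactly one environment per atom at radius t-1.
    An atom whose bond neighborhood did not grow (isolated atoms, exhausted
    fragments) emits nothing.  The new identifier hashes the atom's previous
    identifier together with the *sorted* (bond-order code, neighbor previous
    identifier) pairs, so the result is independent of input atom order.
    """
    by_center = {env.center: env for env in previous}
    if len(by_center) != graph.n_atoms:
        raise ValueError("previous environments must cover every heavy atom")
    if radius is None:
        radius = max(env.radius for env in previous) + 1
    out = []
    for idx in range(graph.n_atoms):
        prev = by_center[idx]
        bond_set = _bond_neighborhood(graph, idx, radius)
        if bond_set == prev.bond_set:
            continue
        pairs = sorted(
            (graph.bonds[bond_idx].order_code, by_center[nbr].identifier)
            for nbr, bond_idx in graph.neighbors[idx]
        )
        fields = [radius, prev.identifier]
        for code, ident in pairs:
            fields.extend((code, ident))
        out.append(
            SubstructureEnvironment(
                center=idx,
                radius=radius,
                bond_set=bond_set,
                identifier=hash_invariants(fields),
            )
        )
    return out


def _sentence_key(graph: MolecularGraph):
    return lambda env: (graph.canonical_order[env.center], env.radius)


def deduplicate(
    envs: list[SubstructureEnvironment], graph: MolecularGraph
) -> list[SubstructureEnvironment]:
    """Stage 3: drop duplicate and equivalent environments.

    Two rules, applied in order:

    (a) environments of radius >= 1 with identical bond sets describe the same
        substructure; only the one with the smaller radius — then the smaller
        canonical atom rank — survives;
    (b) among survivors, repeated identifier *values* keep their first
        occurrence in sentence order.

    Output preserves sentence order (canonical rank ascending, radius
    ascending).
    """
    key = _sentence_key(graph)
    ordered = sorted(envs, key=key)

    best_for_bonds: dict[frozenset[int], SubstructureEnvironment] = {}
    for env in ordered:
        if env.radius == 0:
            continue
        cur = best_for_bonds.get(env.bond_set)
        if cur is None or (env.radius, graph.canonical_order[env.center]) < (
            cur.radius,
            graph.canonical_order[cur.center],
        ):
            best_for_bonds[env.bond_set] = env

    survivors = [
        env
        for env in ordered
        if env.radius == 0 or best_for_bonds[env.bond_set] is env
    ]

    seen_values: set[int] = set()
    out = []
    for env in survivors:
        if env.identifier in seen_values:
            continue
        seen_values.add(env.identifier)
        out.append(env)
    return out


def enumerate_environments(
    graph: MolecularGraph, max_radius: int = 1
) -> list[SubstructureEnvironment]:
    """All surviving environments up to ``max_radius``, in sentence order."""
    if max_radius < 0:
        raise ValueError("max_radius must be >= 0")
    envs = initial_identifiers(graph)
    all_envs = list(envs)
    for t in range(1, max_radius + 1):
        grown = expand_identifiers(graph, envs, radius=t)
        # atoms whose neighborhood stopped growing carry their last env forward
        by_center = {e.center: e for e in envs}
        by_center.update({e.center: e for e in grown})
        all_envs.extend(grown)
        envs = [by_center[i] for i in range(graph.n_atoms)]
    return deduplicate(all_envs, graph)


def generate_sentence(smiles: str, max_radius: int = 1) -> MolecularSentence:
    """SMILES -> molecular sentence (the full three-stage pipeline).

    Deterministic: any two SMILES spellings of the same molecule yield the
    same token list.
    """
    graph = parse_smiles(smiles)
    envs = enumerate_environments(graph, max_radius=max_radius)
    return MolecularSentence(
        tokens=[e.identifier for e in envs],
        provenance=[(graph.canonical_order[e.center], e.radius) for e in envs],
    )


def read_smi(path) -> list[str]:
    """Read a ``.smi`` file: one record per line, ``SMILES`` or
    ``SMILES<TAB>ID``; ``#`` comment lines and blank lines are ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out
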