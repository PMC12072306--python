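"""Combinatorial library construction around a decorated scaffold.

A scaffold is an ordinary SMILES string in which every diversifiable
position carries a numbered wildcard atom ``[*:i]`` (``i`` = 1..k, in the
order of the declared position names).  Substituent fragments are SMILES
with exactly one unnumbered wildcard ``[*]`` marking the attachment bond;
the special fragment ``[*][H]`` means "leave this position unsubstituted".

Products are assembled with RDKit's ``molzip`` and emitted as canonical
SMILES in odometer order over the declared positions (rightmost position
varies fastest), so two runs over the same inputs are byte-identical.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Fragment meaning "no substituent here" — attaching it restores the
#: implicit hydrogen at the position.
HYDROGEN_FRAGMENT = "[*][H]"


class ScaffoldError(ValueError):
    """Raised for malformed scaffolds or scaffold/position mismatches."""


class FragmentError(ValueError):
    """Raised for malformed substituent fragments."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ScaffoldError(f"could not parse SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form of *smiles*; raises :class:`ScaffoldError` if invalid."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def canonical_fragment(fragment: str) -> str:
    """Canonicalise a one-attachment-point fragment.

    The attachment marker is normalised to a plain ``[*]`` (any atom-map
    number on it is discarded) so that equality of canonical strings is
    equality of fragments.
    """
    mol = Chem.MolFromSmiles(fragment, sanitize=False)
    if mol is None:
        raise FragmentError(f"could not parse fragment SMILES: {fragment!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise FragmentError(
            f"fragment {fragment!r} must contain exactly one attachment "
            f"marker [*], found {len(dummies)}"
        )
    dummies[0].SetAtomMapNum(0)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise FragmentError(f"fragment {fragment!r} failed sanitisation: {exc}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class AttachmentScaffold:
    """A core structure with ordered, labelled substitution positions.

    ``positions[i]`` names the attachment point carried by the wildcard
    atom ``[*:i+1]`` in ``core_smiles``.
    """

    core_smiles: str
    positions: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.positions)

    def map_number(self, position: str) -> int:
        return self.positions.index(position) + 1

    def bare_smiles(self) -> str:
        """Canonical SMILES of the scaffold with every position unsubstituted."""
        return assemble(self, {p: HYDROGEN_FRAGMENT for p in self.positions})


def parse_scaffold(core_smiles: str, positions: Sequence[str]) -> AttachmentScaffold:
    """Validate and build an :class:`AttachmentScaffold`.

    Every position name must correspond to exactly one numbered wildcard
    ``[*:i]`` in the core (``i`` = 1-based index into *positions*), and the
    core must be valid chemistry once all wildcards are hydrogen-capped.
    """
    positions = tuple(positions)
    if len(positions) == 0:
        raise ScaffoldError("a scaffold needs at least one position")
    if len(set(positions)) != len(positions):
        raise ScaffoldError(f"duplicate position names in {positions}")
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        raise ScaffoldError(f"could not parse scaffold SMILES: {core_smiles!r}")
    labels = sorted(
        a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0
    )
    expected = list(range(1, len(positions) + 1))
    if labels != expected:
        raise ScaffoldError(
            f"scaffold labels {labels} do not match the declared positions "
            f"{list(positions)} (expected wildcard labels {expected})"
        )
    scaffold = AttachmentScaffold(core_smiles=core_smiles, positions=positions)
    scaffold.bare_smiles()  # raises if the hydrogen-capped core is invalid
    return scaffold


class SubstituentSet:
    """Per-position substituent libraries.

    Stores, for each position name, an ordered list of canonical fragment
    SMILES.  Duplicate fragments within one position are a configuration
    error; the hydrogen fragment is an ordinary list member.
    """

    def __init__(self, per_position: Mapping[str, Sequence[str]]):
        self._frags: dict[str, list[str]] = {}
        for pos, frags in per_position.items():
            if len(frags) == 0:
                raise FragmentError(f"position {pos!r} has an empty substituent list")
            canon = [canonical_fragment(f) for f in frags]
            if len(set(canon)) != len(canon):
                dupes = {f for f in canon if canon.count(f) > 1}
                raise FragmentError(f"duplicate fragments at {pos!r}: {sorted(dupes)}")
            self._frags[pos] = canon

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self._frags)

    def fragments(self, position: str) -> list[str]:
        return list(self._frags[position])

    def counts(self) -> dict[str, int]:
        return {p: len(f) for p, f in self._frags.items()}

    def with_hydrogen(self) -> "SubstituentSet":
        """Return a copy where every position list starts with ``[*][H]``."""
        h = canonical_fragment(HYDROGEN_FRAGMENT)
        out = {}
        for pos, frags in self._frags.items():
            rest = [f for f in frags if f != h]
            out[pos] = [h] + rest
        return SubstituentSet(out)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SubstituentSet) and self._frags == other._frags

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubstituentSet":
        """Read a two-column CSV ``position,fragment_smiles``."""
        per_position: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "position",
                "fragment_smiles",
            } <= set(reader.fieldnames):
                raise FragmentError(
                    f"{path}: expected columns position,fragment_smiles"
                )
            for row in reader:
                per_position.setdefault(row["position"], []).append(
                    row["fragment_smiles"]
                )
        return cls(per_position)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["position", "fragment_smiles"])
            for pos, frags in self._frags.items():
                for f in frags:
                    writer.writerow([pos, f])

    @classmethod
    def from_files(cls, per_position_paths: Mapping[str, str | Path]) -> "SubstituentSet":
        """Read one SMILES file per position (one fragment per line, ``#`` comments)."""
        per_position = {}
        for pos, path in per_position_paths.items():
            frags = []
            for line in Path(path).read_text().splitlines():
                line = line.split("#", 1)[0].strip()
                if line:
                    frags.append(line.split()[0])
            per_position[pos] = frags
        return cls(per_position)


@dataclass(frozen=True)
class LibraryMolecule:
    """One enumerated product of the combinatorial library."""

    smiles: str
    assignment: tuple[tuple[str, int], ...]
    library_id: int

    def assignment_string(self) -> str:
        return ";".join(f"{p}={i}" for p, i in self.assignment)

    @staticmethod
    def parse_assignment(text: str) -> tuple[tuple[str, int], ...]:
        pairs = []
        for token in text.split(";"):
            pos, idx = token.split("=")
            pairs.append((pos, int(idx)))
        return tuple(pairs)


def count_library(substituents: SubstituentSet) -> int:
    """Size of the full combinatorial library: the product of the
    per-position substituent counts.  Pure arithmetic, no enumeration."""
    counts = substituents.counts()
    if any(c == 0 for c in counts.values()):
        raise FragmentError("every position needs at least one substituent")
    return math.prod(counts.values())


def assemble(scaffold: AttachmentScaffold, fragments: Mapping[str, str]) -> str:
    """Attach one fragment per position and return the canonical product SMILES.

    All positions are joined with ``Chem.molzip`` on matching atom-map
    numbers; the hydrogen fragment attaches an explicit H that is folded
    back into the implicit hydrogen count afterwards.
    """
    missing = set(scaffold.positions) - set(fragments)
    if missing:
        raise ScaffoldError(f"no fragment supplied for positions {sorted(missing)}")

    combo = Chem.MolFromSmiles(scaffold.core_smiles)
    if combo is None:
        raise ScaffoldError(f"could not parse scaffold SMILES: {scaffold.core_smiles!r}")
    for pos in scaffold.positions:
        mapno = scaffold.map_number(pos)
        frag = Chem.MolFromSmiles(fragments[pos], sanitize=False)
        if frag is None:
            raise FragmentError(f"could not parse fragment {fragments[pos]!r}")
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(mapno)
        combo = Chem.CombineMols(combo, frag)

    try:
        product = Chem.molzip(combo)
        product = Chem.RemoveHs(product)
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise FragmentError(f"assembly produced invalid chemistry: {exc}")
    return Chem.MolToSmiles(product)


@dataclass
class RejectionLog:
    """Assembly failures and duplicate products recorded during enumeration."""

    rejected: list[tuple[str, str, str]] = field(default_factory=list)  # assignment, position/frag, reason
    duplicates: list[tuple[str, str]] = field(default_factory=list)  # assignment, smiles

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["kind", "assignment", "detail", "reason"])
            for a, d, r in self.rejected:
                writer.writerow(["rejected", a, d, r])
            for a, s in self.duplicates:
                writer.writerow(["duplicate", a, s, ""])


def enumerate_library(
    scaffold: AttachmentScaffold,
    substituents: SubstituentSet,
    *,
    start_id: int = 0,
    log: RejectionLog | None = None,
    track_duplicates: bool = False,
) -> Iterator[LibraryMolecule]:
    """Yield every combinatorial product in deterministic odometer order.

    The assignment odometer runs over the scaffold's declared position
    order with the rightmost position varying fastest.  Chemically invalid
    combinations are recorded in *log* and skipped without stopping the
    stream.  Memory use is constant unless *track_duplicates* is set, which
    keeps a seen-SMILES set to flag assignments that collapse to the same
    product.
    """
    if set(scaffold.positions) != set(substituents.positions):
        raise ScaffoldError(
            f"scaffold positions {scaffold.positions} do not match substituent "
            f"positions {substituents.positions}"
        )
    per_pos = [substituents.fragments(p) for p in scaffold.positions]
    seen: dict[str, str] = {}
    library_id = start_id
    for indices in itertools.product(*(range(len(f)) for f in per_pos)):
        assignment = tuple(zip(scaffold.positions, indices))
        frags = {p: per_pos[j][i] for j, (p, i) in enumerate(assignment)}
        try:
            smiles = assemble(scaffold, frags)
        except (FragmentError, ScaffoldError) as exc:
            if log is not None:
                mol = LibraryMolecule("", assignment, -1)
                log.rejected.append((mol.assignment_string(), str(frags), str(exc)))
            continue
        mol = LibraryMolecule(smiles=smiles, assignment=assignment, library_id=library_id)
        library_id += 1
        if track_duplicates:
            if smiles in seen and log is not None:
                log.duplicates.append((mol.assignment_string(), smiles))
            seen.setdefault(smiles, mol.assignment_string())
        yield mol


def write_smi(path: str | Path, molecules: Iterable[LibraryMolecule]) -> int:
    """Write a tab-separated ``.smi`` file: smiles, id, assignment. Returns count."""
    n = 0
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.smiles}\t{mol.library_id}\t{mol.assignment_string()}\n")
            n += 1
    return n


def read_smi(path: str | Path) -> Iterator[LibraryMolecule]:
    """Stream molecules back from a ``.smi`` file written by :func:`write_smi`."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            smiles, lib_id, assignment = line.split("\t")
            yield LibraryMolecule(
                smiles=smiles,
                assignment=LibraryMolecule.parse_assignment(assignment),
                library_id=int(lib_id),
            )
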