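"""SAR-driven structural simplification.

From the best-predicted slice of the library, count how often each
substituent appears at each position; substituents over-represented among
the most active compounds are "privileged".  New low-decoration candidates
are then generated that carry only privileged substituents (hydrogen
everywhere else), trading some predicted potency for much shorter synthetic
routes.  A graph-complexity score quantifies the simplification.
"""

from __future__ import annotations

import csv
import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem

from simplihit.enumeration import (
    AttachmentScaffold,
    FragmentError,
    HYDROGEN_FRAGMENT,
    LibraryMolecule,
    RejectionLog,
    assemble,
    canonical_fragment,
)
from simplihit.qsar import PredictionRecord


class SimplificationError(ValueError):
    pass


def select_top_set(
    records: Sequence[PredictionRecord], n: int = 4000, threshold: float = 7.0
) -> list[PredictionRecord]:
    """The top-*n* records by mean predicted pIC50 among those above *threshold*.

    Extrapolating compounds are kept (the flag is carried, not filtered on):
    range-based extrapolation shows no activity bias on this kind of library,
    so removing them would only lose information.  Ties in mean break by
    molecule id for determinism.
    """
    if not records:
        raise SimplificationError("no predictions to select from")
    above = [r for r in records if r.mean_pic50 > threshold]
    if not above:
        best = max(r.mean_pic50 for r in records)
        raise SimplificationError(
            f"no compound exceeds the activity threshold {threshold} "
            f"(best mean pIC50 = {best:.2f})"
        )
    above.sort(key=lambda r: (-r.mean_pic50, r.molecule_id))
    return above[:n]


@dataclass
class FrequencyTable:
    """Per-position substituent counts within the top set."""

    counts: dict[str, Counter]  # position -> fragment smiles -> count
    top_set_size: int
    threshold: float
    n_requested: int

    def fractions(self, position: str) -> dict[str, float]:
        return {f: c / self.top_set_size for f, c in self.counts[position].items()}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["position", "substituent", "count", "fraction"])
            for pos, counter in self.counts.items():
                for frag, c in counter.most_common():
                    writer.writerow([pos, frag, c, f"{c / self.top_set_size:.6f}"])


def substituent_frequencies(
    top_set: Sequence[LibraryMolecule],
    substituents,
    *,
    threshold: float = 7.0,
    n_requested: int = 4000,
) -> FrequencyTable:
    """Exact per-(position, substituent) counts over the top set.

    Molecules must carry their assignment vectors — frequencies are
    attributed by provenance, not by re-parsing structures.
    """
    if not top_set:
        raise SimplificationError("empty top set")
    counts: dict[str, Counter] = {}
    for mol in top_set:
        if not mol.assignment:
            raise SimplificationError(
                f"molecule {mol.library_id} lacks an assignment vector"
            )
        for pos, idx in mol.assignment:
            frag = substituents.fragments(pos)[idx]
            counts.setdefault(pos, Counter())[frag] += 1
    return FrequencyTable(
        counts=counts,
        top_set_size=len(top_set),
        threshold=threshold,
        n_requested=n_requested,
    )


def privileged_substituents(
    freq: FrequencyTable,
    *,
    top_k: int | Mapping[str, int] | None = None,
    min_fraction: float | None = None,
) -> dict[str, list[str]]:
    """Per-position privileged substituent lists.

    Either keep the *top_k* most frequent substituents per position (an int
    applies everywhere, a mapping sets k per position) or keep those whose
    fraction reaches *min_fraction*.  The hydrogen fragment never counts as
    privileged: it marks the absence of a substituent, which is the
    simplification target itself.  Ties in count break by fragment SMILES.
    """
    if (top_k is None) == (min_fraction is None):
        raise SimplificationError("specify exactly one of top_k or min_fraction")
    hydrogen = canonical_fragment(HYDROGEN_FRAGMENT)
    out: dict[str, list[str]] = {}
    for pos, counter in freq.counts.items():
        ranked = sorted(
            ((f, c) for f, c in counter.items() if f != hydrogen),
            key=lambda fc: (-fc[1], fc[0]),
        )
        if top_k is not None:
            k = top_k[pos] if isinstance(top_k, Mapping) else top_k
            chosen = [f for f, _ in ranked[:k]]
        else:
            cutoff = min_fraction * freq.top_set_size
            chosen = [f for f, c in ranked if c >= cutoff]
        out[pos] = chosen
    return out


@dataclass
class SimplifiedCandidate:
    """A low-decoration structure built purely from privileged substituents."""

    smiles: str
    occupied_positions: tuple[tuple[str, str], ...]  # (position, fragment smiles)
    predictions: dict[str, float] = field(default_factory=dict)
    mean_pic50: float = float("nan")
    extrapolated: dict[str, bool] = field(default_factory=dict)
    pareto_value: int = -1
    complexity: float = float("nan")
    rank_combinatorial: int = -1

    @property
    def candidate_id(self) -> str:
        return "|".join(f"{p}:{f}" for p, f in self.occupied_positions)


def generate_simplified(
    scaffold: AttachmentScaffold,
    privileged: Mapping[str, Sequence[str]],
    *,
    max_decorations: int = 2,
    min_decorations: int = 1,
    anchor: str | None = None,
    log: RejectionLog | None = None,
) -> list[SimplifiedCandidate]:
    """All structures bearing min..max_decorations privileged substituents.

    Substituents occupy distinct positions; every other position is
    hydrogen.  With an *anchor* position set, every multi-decoration
    structure must occupy the anchor (single-decoration structures are
    unconstrained).  Products are canonicalised and de-duplicated; invalid
    chemistry is logged and skipped.
    """
    active = [p for p in scaffold.positions if privileged.get(p)]
    if not active:
        raise SimplificationError("no position has any privileged substituent")
    if anchor is not None and anchor not in scaffold.positions:
        raise SimplificationError(f"anchor {anchor!r} is not a scaffold position")
    if not 1 <= min_decorations <= max_decorations:
        raise SimplificationError("need 1 <= min_decorations <= max_decorations")
    candidates: list[SimplifiedCandidate] = []
    seen: set[str] = set()
    for n_dec in range(min_decorations, max_decorations + 1):
        for pos_combo in itertools.combinations(active, n_dec):
            if anchor is not None and n_dec > 1 and anchor not in pos_combo:
                continue
            for frag_combo in itertools.product(*(privileged[p] for p in pos_combo)):
                occupied = tuple(zip(pos_combo, frag_combo))
                frags = {p: HYDROGEN_FRAGMENT for p in scaffold.positions}
                frags.update(dict(occupied))
                try:
                    smiles = assemble(scaffold, frags)
                except FragmentError as exc:
                    if log is not None:
                        log.rejected.append(
                            (";".join(f"{p}={f}" for p, f in occupied), str(frags), str(exc))
                        )
                    continue
                if smiles in seen:
                    if log is not None:
                        log.duplicates.append(
                            (";".join(f"{p}={f}" for p, f in occupied), smiles)
                        )
                    continue
                seen.add(smiles)
                candidates.append(
                    SimplifiedCandidate(smiles=smiles, occupied_positions=occupied)
                )
    if not candidates:
        raise SimplificationError("every simplified combination failed assembly")
    return candidates


def complexity_score(smiles: str) -> float:
    """Graph-complexity index of a molecule.

    score = heavy atoms + 2 x rings (SSSR) + distinct non-carbon heavy
    elements + atoms with more than two heavy-atom neighbours.

    A deliberately simple, fully documented proxy for molecular-complexity
    parameters used in desktop cheminformatics tools: it grows with size,
    ring count, heteroatom diversity and branching, and is strictly
    monotone under adding a heavy atom at a terminal position.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SimplificationError(f"invalid SMILES: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    rings = mol.GetRingInfo().NumRings()
    hetero_elements = len(
        {a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)}
    )
    branched = sum(1 for a in mol.GetAtoms() if a.GetDegree() > 2)
    return float(heavy + 2 * rings + hetero_elements + branched)


def write_candidates_csv(path: str | Path, candidates: Sequence[SimplifiedCandidate]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "candidate_id",
                "smiles",
                "occupied_positions",
                "predictions",
                "mean_pic50",
                "pareto_value",
                "complexity",
                "rank_combinatorial",
            ]
        )
        for c in candidates:
            writer.writerow(
                [
                    c.candidate_id,
                    c.smiles,
                    ";".join(f"{p}={f}" for p, f in c.occupied_positions),
                    ";".join(f"{t}={v:.4f}" for t, v in sorted(c.predictions.items())),
                    f"{c.mean_pic50:.4f}",
                    c.pareto_value,
                    f"{c.complexity:.1f}",
                    c.rank_combinatorial,
                ]
            )
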