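"""Crosslinking-MS distance-restraint validation against a model.

A chemical crosslinker of known spacer length bounds the distance between
the linked residues; for DSS the conventional compatibility bound is a
Cα–Cα distance of 30 Å.  Identified residue pairs come in as a delimited
table naming proteins and residue numbers; in a homo-oligomer a protein
name maps to several chains, so each pair is evaluated either as the
minimum over all allowed chain assignments or on a fixed chain pair.

Pairs touching residues absent from the model are reported ``unmapped``,
never ``violated`` — an unbuilt loop is missing evidence, not a clash.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Structure

__all__ = [
    "CrosslinkPair",
    "CrosslinkResult",
    "CrosslinkSummary",
    "parse_crosslink_table",
    "evaluate_crosslinks",
    "crosslink_report",
]

_COLUMN_ALIASES = {
    "protein1": "protein_1", "protein 1": "protein_1",
    "residue1": "residue_1", "residue 1": "residue_1",
    "protein2": "protein_2", "protein 2": "protein_2",
    "residue2": "residue_2", "residue 2": "residue_2",
    "annotation": "annotation", "peptide": "annotation",
}


@dataclass(frozen=True)
class CrosslinkPair:
    protein_1: str
    residue_1: int
    protein_2: str
    residue_2: int
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.residue_1 < 1 or self.residue_2 < 1:
            raise ValueError(
                f"residue numbers must be positive: {self.residue_1}, {self.residue_2}"
            )

    def is_intermolecular(self) -> bool:
        return self.protein_1 != self.protein_2


@dataclass(frozen=True)
class CrosslinkResult:
    pair: CrosslinkPair
    status: Literal["satisfied", "violated", "unmapped"]
    distance: float | None
    best_chain_pair: tuple[str, str] | None
    candidate_distances: tuple[tuple[tuple[str, str], float], ...]
    cutoff: float
    atom: str


@dataclass(frozen=True)
class CrosslinkSummary:
    n_pairs: int
    satisfied: int
    violated: int
    unmapped: int
    max_distance: float | None
    violating_pairs: tuple[CrosslinkPair, ...]


def parse_crosslink_table(
    path: str | Path,
    protein_chain_map: Mapping[str, Sequence[str]] | None = None,
) -> list[CrosslinkPair]:
    """Read a crosslink CSV with Protein1/Residue1/Protein2/Residue2 columns.

    An optional Annotation column is carried through.  When a protein→chain
    map is given, protein names not present in the map are rejected up
    front, so typos fail at parse time rather than as silent unmapped rows.
    """
    df = pd.read_csv(path)
    if df.empty and len(df.columns) <= 1:
        return []
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    required = {"protein_1", "residue_1", "protein_2", "residue_2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    pairs: list[CrosslinkPair] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            pair = CrosslinkPair(
                protein_1=str(row["protein_1"]).strip(),
                residue_1=int(row["residue_1"]),
                protein_2=str(row["protein_2"]).strip(),
                residue_2=int(row["residue_2"]),
                annotation=str(row.get("annotation", "") or ""),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {line}: {exc}") from exc
        if protein_chain_map is not None:
            for prot in (pair.protein_1, pair.protein_2):
                if prot not in protein_chain_map:
                    raise ValueError(
                        f"{path}: line {line}: protein {prot!r} not in chain map"
                    )
        pairs.append(pair)
    return pairs


def _atom_lookup(model: Structure, atom: str) -> dict[tuple[str, int], np.ndarray]:
    return {
        (a.chain, a.residue_number): a.xyz
        for a in model.atoms
        if a.atom_name == atom
    }


def evaluate_crosslinks(
    model: Structure,
    pairs: Sequence[CrosslinkPair],
    protein_chain_map: Mapping[str, Sequence[str]],
    cutoff: float = 30.0,
    atom: Literal["CA", "NZ"] = "CA",
    ambiguity: Literal["min_over_chains", "fixed_chains"] = "min_over_chains",
    fixed_chains: Mapping[str, str] | None = None,
) -> list[CrosslinkResult]:
    """Measure and classify each crosslink pair on a model.

    ``min_over_chains`` takes, per pair, the minimum distance over every
    allowed chain assignment (distinct chains for the two sides when they
    name the same residue of the same protein); ``fixed_chains`` restricts
    each protein to one stated chain.
    """
    coords = _atom_lookup(model, atom)
    if not coords:
        raise ValueError(f"model has no {atom!r} atoms")
    if ambiguity == "fixed_chains" and not fixed_chains:
        raise ValueError("fixed_chains ambiguity requires a protein→chain mapping")

    results: list[CrosslinkResult] = []
    for pair in pairs:
        if ambiguity == "fixed_chains":
            chains_1 = [fixed_chains[pair.protein_1]]
            chains_2 = [fixed_chains[pair.protein_2]]
        else:
            chains_1 = list(protein_chain_map[pair.protein_1])
            chains_2 = list(protein_chain_map[pair.protein_2])
        candidates: list[tuple[tuple[str, str], float]] = []
        for c1 in chains_1:
            p1 = coords.get((c1, pair.residue_1))
            if p1 is None:
                continue
            for c2 in chains_2:
                if (
                    c1 == c2
                    and pair.protein_1 == pair.protein_2
                    and pair.residue_1 == pair.residue_2
                ):
                    # a residue crosslinked to itself on one chain: distance 0
                    candidates.append(((c1, c2), 0.0))
                    continue
                p2 = coords.get((c2, pair.residue_2))
                if p2 is None:
                    continue
                candidates.append(((c1, c2), float(np.linalg.norm(p1 - p2))))
        if not candidates:
            results.append(
                CrosslinkResult(
                    pair=pair, status="unmapped", distance=None,
                    best_chain_pair=None, candidate_distances=(),
                    cutoff=cutoff, atom=atom,
                )
            )
            continue
        best_chains, best_d = min(candidates, key=lambda cd: cd[1])
        status = "satisfied" if best_d <= cutoff else "violated"
        results.append(
            CrosslinkResult(
                pair=pair, status=status, distance=best_d,
                best_chain_pair=best_chains,
                candidate_distances=tuple(candidates),
                cutoff=cutoff, atom=atom,
            )
        )
    return results


def crosslink_report(results: Sequence[CrosslinkResult]) -> CrosslinkSummary:
    """Counts by status, the largest mapped distance, and the violators."""
    mapped = [r for r in results if r.distance is not None]
    return CrosslinkSummary(
        n_pairs=len(results),
        satisfied=sum(r.status == "satisfied" for r in results),
        violated=sum(r.status == "violated" for r in results),
        unmapped=sum(r.status == "unmapped" for r in results),
        max_distance=max((r.distance for r in mapped), default=None),
        violating_pairs=tuple(r.pair for r in results if r.status == "violated"),
    )
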