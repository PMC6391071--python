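"""Coordinate I/O and tier/domain selection.

Reads mmCIF/PDB coordinate files into a flat, author-numbered atom list and
turns structured tier definitions (ordered per-subunit residue intervals)
into ordered atom selections and center-of-mass series — the substrate for
all downstream geometry.

Conventions:

* author chain IDs and author residue numbering throughout (matching what
  deposited models print);
* first model only; alternate locations resolved to the highest-occupancy
  conformer (ties broken toward altloc ``A``);
* centers of mass are computed over non-hydrogen atoms with atomic average
  masses by default; uniform weighting is selectable because published
  "center of gravity" analyses rarely state the convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
import yaml

logger = logging.getLogger("ringtier")

__all__ = [
    "AtomRecord",
    "DomainSpec",
    "TierSpec",
    "Structure",
    "load_structure",
    "select_domain",
    "center_of_mass",
    "tier_coms",
    "write_pdb",
    "load_tier_config",
    "default_tier_config_path",
    "element_mass",
]


# --------------------------------------------------------------------------
# elements
# --------------------------------------------------------------------------

def element_mass(symbol: str) -> float:
    """Average atomic mass (Da) of an element symbol; raises on unknowns."""
    el = gemmi.Element(symbol)
    if el.name == "X" or el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return float(el.weight)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom with author chain/residue identifiers and a position in Å."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", tuple(float(x) for x in self.position)
        )
        if len(self.position) != 3 or not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.key()}")
        element_mass(self.element)  # rejects unknown elements

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.atom_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def mass(self) -> float:
        return element_mass(self.element)


@dataclass(frozen=True)
class DomainSpec:
    """A labelled inclusive residue interval on one chain."""

    label: str
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"domain {self.label!r}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class TierSpec:
    """An ordered series of domains forming one ring/spiral layer.

    The order is the spiral order (bottom to top) and is always explicit:
    it is never inferred from chain IDs, because deposited models name
    chains in ring-adjacency order, not staircase order.
    """

    name: str
    domains: tuple[DomainSpec, ...]

    def __init__(self, name: str, domains: Sequence[DomainSpec]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "domains", tuple(domains))
        if len(self.domains) < 3:
            raise ValueError(
                f"tier {name!r} has {len(self.domains)} domains; "
                "plane/helix fits need at least 3"
            )


@dataclass
class Structure:
    """A flat atom collection plus provenance."""

    atoms: list[AtomRecord]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate (chain, residue, atom) triple: {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def positions(self, atoms: Iterable[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else list(atoms)
        return np.array([a.position for a in src], dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            by_name[atom.name] = atom
    return list(by_name.values())


def load_structure(path: str | Path, format: Literal["mmcif", "pdb", "auto"] = "auto") -> Structure:
    """Read all ATOM/HETATM records of the first model of a coordinate file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        st = gemmi.read_structure(str(path))
    elif format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown format {format!r}")
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models; using model 1 only", path.name, len(st))

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in _resolve_altlocs(residue):
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: zero atoms in model 1")
    return Structure(atoms=atoms, source=f"{path}:{format}")


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a Structure to a PDB file (3-decimal coordinate precision)."""
    # group atoms by chain, then by residue, building each gemmi object
    # completely before inserting it (insertion copies/invalidates refs)
    by_chain: dict[str, dict[int, list[AtomRecord]]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain, {}).setdefault(a.residue_number, []).append(a)

    st = gemmi.Structure()
    st.name = "ringtier"
    model = gemmi.Model("1")
    for chain_name, residues in by_chain.items():
        ch = gemmi.Chain(chain_name)
        for resnum in sorted(residues):
            group = residues[resnum]
            r = gemmi.Residue()
            r.name = group[0].residue_name
            r.seqid = gemmi.SeqId(resnum, " ")
            for a in group:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                r.add_atom(at)
            ch.add_residue(r)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# --------------------------------------------------------------------------
# selection and centers of mass
# --------------------------------------------------------------------------

def select_domain(
    structure: Structure,
    spec: DomainSpec,
    atom_filter: Literal["all", "ca_only"] = "all",
) -> list[AtomRecord]:
    """Atoms of ``spec.chain`` with residue number in [start, end], in residue order.

    An empty selection is valid (the interval may be entirely unmodelled);
    a missing chain is an error because it signals a mis-written config.
    """
    if spec.chain not in structure.chains:
        raise KeyError(f"chain {spec.chain!r} not present in {structure.source}")
    out = [
        a
        for a in structure.atoms
        if a.chain == spec.chain and spec.start <= a.residue_number <= spec.end
    ]
    if atom_filter == "ca_only":
        out = [a for a in out if a.atom_name == "CA"]
    out.sort(key=lambda a: a.residue_number)
    return out


def center_of_mass(
    atoms: Sequence[AtomRecord],
    weighting: Literal["atomic_mass", "uniform"] = "atomic_mass",
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Weighted mean position of a selection (Å).

    Default weights are element average masses over non-hydrogen atoms;
    ``uniform`` weights every retained atom equally.
    """
    sel = list(atoms)
    if not include_hydrogens:
        sel = [a for a in sel if a.element not in ("H", "D")]
    if not sel:
        raise ValueError("center_of_mass of an empty selection")
    pos = np.array([a.position for a in sel], dtype=float)
    if weighting == "atomic_mass":
        w = np.array([a.mass for a in sel], dtype=float)
    elif weighting == "uniform":
        w = np.ones(len(sel))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def tier_coms(
    structure: Structure,
    tier: TierSpec,
    weighting: Literal["atomic_mass", "uniform"] = "atomic_mass",
    atom_filter: Literal["all", "ca_only"] = "all",
) -> np.ndarray:
    """Ordered (n_domains, 3) COM series for a tier.

    Domains with partially unmodelled intervals contribute the COM of their
    modelled atoms; the modelled residue fraction is logged so partially
    built models are visible in reports.
    """
    coms = []
    for spec in tier.domains:
        atoms = select_domain(structure, spec, atom_filter=atom_filter)
        if not atoms:
            raise ValueError(
                f"tier {tier.name!r}: domain {spec.label!r} has no modelled atoms"
            )
        n_expected = spec.end - spec.start + 1
        n_modelled = len({a.residue_number for a in atoms})
        if n_modelled < n_expected:
            logger.info(
                "tier %s domain %s: %d/%d residues modelled",
                tier.name, spec.label, n_modelled, n_expected,
            )
        coms.append(center_of_mass(atoms, weighting=weighting))
    return np.array(coms)


# --------------------------------------------------------------------------
# tier configuration files
# --------------------------------------------------------------------------

def load_tier_config(path: str | Path) -> dict[str, TierSpec]:
    """Parse a YAML tier config into named TierSpecs.

    Schema::

        tiers:
          - name: CTD
            domains:
              - {label: CTD_A, chain: A, start: 203, end: 471}
              ...

    Domain order in the file is the spiral order and is preserved.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "tiers" not in doc:
        raise ValueError(f"{path}: tier config must contain a 'tiers' list")
    tiers: dict[str, TierSpec] = {}
    for entry in doc["tiers"]:
        domains = [
            DomainSpec(
                label=str(d["label"]),
                chain=str(d["chain"]),
                start=int(d["start"]),
                end=int(d["end"]),
            )
            for d in entry["domains"]
        ]
        spec = TierSpec(name=str(entry["name"]), domains=domains)
        tiers[spec.name] = spec
    return tiers


def default_tier_config_path() -> Path:
    """Path of the shipped tier config for the deposited helicase-loader model."""
    return Path(__file__).parent / "data" / "tiers_6bbm.yaml"
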