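"""Reading atomic structures and assembling multi-conformation ensembles.

A conformational ensemble is the basic input of the rigid-domain pipeline:
M >= 2 snapshots of the same protein, reduced to one representative atom
per residue (C-alpha by default) on a common residue index.  Structures are
read with gemmi (PDB and mmCIF); residue correspondence defaults to identity
on author numbering, with an optional explicit mapping table for ensembles
that were aligned externally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: (chain id, author residue number, insertion code)
ResidueId = tuple[str, int, str]


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from a structure."""


@dataclass(frozen=True)
class ConformationEnsemble:
    """M conformations x N residues of representative-atom coordinates (Å).

    Attributes
    ----------
    coords : (M, N, 3) float array
    residue_ids : list of (chain, author number, insertion code), length N
    source_labels : list of M provenance strings
    """

    coords: np.ndarray
    residue_ids: list[ResidueId]
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, N, 3)")
        if coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least two conformations")
        if coords.shape[1] < 3:
            raise ValueError("an ensemble needs at least three residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.residue_ids) != coords.shape[1]:
            raise ValueError("residue_ids length does not match coords")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("residue_ids must be unique")
        object.__setattr__(self, "coords", coords)

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the first altloc identifier
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def load_conformation(
    path: str | Path,
    chain: str,
    atom_name: str = "CA",
) -> list[tuple[ResidueId, np.ndarray]]:
    """Extract one representative-atom coordinate per residue of a chain.

    Only polymer residues are considered (waters and heteroatoms are
    skipped).  Residues lacking the representative atom are omitted with a
    warning; alternate locations resolve to the highest-occupancy copy.

    Returns a list of ``(residue_id, xyz)`` in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise FormatError(f"{path} contains no models")
    model = structure[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        available = ", ".join(ch.name for ch in model) or "(none)"
        raise ChainNotFoundError(
            f"chain {chain!r} not in {path.name}; available: {available}"
        )

    out: list[tuple[ResidueId, np.ndarray]] = []
    for residue in chain_obj:
        if residue.is_water():
            continue
        info = gemmi.find_tabulated_residue(residue.name)
        if info is not None and not (info.is_amino_acid() or info.is_nucleic_acid()):
            continue
        atoms = [a for a in residue if a.name == atom_name]
        if not atoms:
            logger.warning(
                "%s %s%d%s has no %s atom; residue skipped",
                path.name, chain, residue.seqid.num,
                residue.seqid.icode.strip(), atom_name,
            )
            continue
        atom = _pick_altloc(atoms)
        rid: ResidueId = (chain, residue.seqid.num, residue.seqid.icode.strip())
        out.append((rid, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    return out


def read_mapping_table(path: str | Path) -> list[tuple[str, ...]]:
    """Read a residue-correspondence TSV: one column per conformation,
    author residue identifiers as ``chain:number[icode]``, '-' for a gap.
    Rows with any gap are dropped."""
    rows: list[tuple[str, ...]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(tuple(line.split("\t")))
    return rows


def _parse_mapping_token(token: str) -> ResidueId:
    chain, _, rest = token.partition(":")
    num = ""
    icode = ""
    for ch in rest:
        if ch.isdigit() or (ch == "-" and not num):
            num += ch
        else:
            icode += ch
    return (chain, int(num), icode)


def build_ensemble(
    conformations: Sequence[Sequence[tuple[ResidueId, np.ndarray]]],
    mapping: Sequence[tuple[str, ...]] | None = None,
    source_labels: Sequence[str] | None = None,
) -> ConformationEnsemble:
    """Assemble conformations onto a common residue index.

    Without a mapping, correspondence is identity on
    (chain, author number, insertion code): the ensemble is restricted to
    the intersection of residue ids, ordered as in the first conformation.
    With a mapping table, row i pairs up the listed residue of each
    conformation; '-' rows are skipped by :func:`read_mapping_table`.
    """
    if len(conformations) < 2:
        raise ValueError("need at least two conformations")
    dicts = [
        {rid: np.asarray(xyz, dtype=float) for rid, xyz in conf}
        for conf in conformations
    ]

    if mapping is None:
        common = set(dicts[0])
        for d in dicts[1:]:
            common &= set(d)
        order = [rid for rid, _ in conformations[0] if rid in common]
        n_dropped = max(len(d) for d in dicts) - len(order)
        if n_dropped > 0:
            logger.info("dropped %d residues absent from some conformation",
                        n_dropped)
        rows = [tuple([rid] * len(dicts)) for rid in order]
        residue_ids = order
    else:
        rows = []
        for row in mapping:
            if "-" in row:
                continue
            rows.append(tuple(_parse_mapping_token(tok) for tok in row))
        residue_ids = [row[0] for row in rows]

    if len(rows) < 3:
        raise ValueError("insufficient shared residues (need at least 3)")

    coords = np.empty((len(dicts), len(rows), 3))
    for m, d in enumerate(dicts):
        for n, row in enumerate(rows):
            try:
                coords[m, n] = d[row[m]]
            except KeyError:
                raise ValueError(
                    f"mapping names residue {row[m]} absent from "
                    f"conformation {m}"
                ) from None
    labels = list(source_labels) if source_labels else [
        f"conformation_{m}" for m in range(len(dicts))
    ]
    return ConformationEnsemble(coords, residue_ids, labels)


def load_ensemble(
    specs: Sequence[tuple[str | Path, str]],
    atom_name: str = "CA",
    mapping: Sequence[tuple[str, ...]] | None = None,
) -> ConformationEnsemble:
    """Convenience wrapper: load ``(path, chain)`` pairs and assemble them."""
    confs = [load_conformation(p, c, atom_name) for p, c in specs]
    labels = [f"{Path(p).name}:{c}" for p, c in specs]
    return build_ensemble(confs, mapping=mapping, source_labels=labels)


def load_multimodel_ensemble(
    path: str | Path, chain: str = "A", atom_name: str = "CA"
) -> ConformationEnsemble:
    """Load every model of a multi-model PDB/mmCIF as one conformation."""
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    structure.setup_entities()
    confs = []
    for model in structure:
        chain_obj = model.find_chain(chain)
        if chain_obj is None:
            raise ChainNotFoundError(f"chain {chain!r} missing in a model")
        conf = []
        for residue in chain_obj:
            atoms = [a for a in residue if a.name == atom_name]
            if not atoms:
                continue
            atom = _pick_altloc(atoms)
            rid = (chain, residue.seqid.num, residue.seqid.icode.strip())
            conf.append((rid, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
        confs.append(conf)
    labels = [f"{path.name}#model{i + 1}" for i in range(len(confs))]
    return build_ensemble(confs, source_labels=labels)


def write_conformation_pdb(
    path: str | Path,
    ensemble: ConformationEnsemble,
    conformation: int = 0,
    atom_name: str = "CA",
) -> None:
    """Write one conformation of the ensemble as a minimal PDB file."""
    _write_models_pdb(path, ensemble, [conformation], atom_name)


def write_multimodel_pdb(
    path: str | Path, ensemble: ConformationEnsemble, atom_name: str = "CA"
) -> None:
    """Write all conformations as models of a single PDB file."""
    _write_models_pdb(path, ensemble, range(ensemble.n_conformations),
                      atom_name)


def _write_models_pdb(path, ensemble, model_indices, atom_name) -> None:
    structure = gemmi.Structure()
    structure.name = "rigidseg-ensemble"
    for k, m in enumerate(model_indices):
        model = gemmi.Model(k + 1)
        chains: dict[str, gemmi.Chain] = {}
        for n, (chain_id, num, icode) in enumerate(ensemble.residue_ids):
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(num, icode or " ")
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.occ = 1.0
            x, y, z = ensemble.coords[m, n]
            atom.pos = gemmi.Position(x, y, z)
            residue.add_atom(atom)
            chains[chain_id].add_residue(residue)
        for ch in chains.values():
            model.add_chain(ch)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
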