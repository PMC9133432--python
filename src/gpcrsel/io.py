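"""Readers and writers for the external formats the pipeline touches.

Formats handled: aligned FASTA (ortholog families), Newick gene trees,
PDB coordinate files (heavy atoms), TSV coupling-profile tables, TSV
GPCRdb generic-number maps, TSV species-lineage tables and tab-separated
edge tables (Cytoscape import dialect).

Conventions
-----------
* Coordinates are in Angstrom; residue indexing follows PDB author
  numbering; alignment columns are 1-based in all outputs.
* Species are extracted from FASTA/Newick labels with a configurable
  regular expression whose first capture group is the species token; the
  default matches UniProt "..._SPECIES" mnemonics.
* GPCRdb generic numbers are always supplied as an input map (they are
  never computed here).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .tree import GeneTree, LeafInfo, TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALLOWED_ALPHABET = frozenset(AMINO_ACIDS + GAP + "X")

#: Default species extractor: trailing UniProt mnemonic ("ADRB2_HUMAN" -> "HUMAN").
DEFAULT_SPECIES_PATTERN = r"_([A-Za-z0-9]+)$"

#: Controlled vocabulary for the 11 Galpha subtypes of the coupling screens.
G_PROTEIN_SUBTYPES = ("Gs", "Gi1", "Gi3", "Go", "Gz",
                      "Gq", "G11", "G14", "G16", "G12", "G13")

COUPLING_SOURCES = ("datasetA", "datasetB", "merged")

GENERIC_NUMBER_RE = re.compile(r"^\d{1,2}x\d{2,3}$")


# ---------------------------------------------------------------------------
# Aligned families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    species: str
    residues: str


class AlignedFamily:
    """An MSA of one receptor's orthologs; the unit of conservation analysis.

    Invariants enforced: equal-length rows, alphabet restricted to the 20
    amino acids plus ``-`` and ``X``, unique sequence ids, valid target index.
    """

    def __init__(self, family_id: str, sequences: Sequence[SequenceRecord],
                 target_index: int) -> None:
        if not sequences:
            raise ValueError(f"family {family_id!r}: no sequences")
        length = len(sequences[0].residues)
        if length < 1:
            raise ValueError(f"family {family_id!r}: zero-length alignment")
        for rec in sequences:
            if len(rec.residues) != length:
                raise ValueError(
                    f"ragged alignment in family {family_id!r}: record "
                    f"{rec.seq_id!r} has length {len(rec.residues)}, "
                    f"expected {length}")
            bad = set(rec.residues) - _ALLOWED_ALPHABET
            if bad:
                raise ValueError(
                    f"family {family_id!r}: record {rec.seq_id!r} contains "
                    f"invalid symbols {sorted(bad)}")
        ids = [rec.seq_id for rec in sequences]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"family {family_id!r}: duplicate seq_ids {dupes}")
        if not 0 <= target_index < len(sequences):
            raise ValueError(f"family {family_id!r}: target_index "
                             f"{target_index} out of range")
        self.family_id = family_id
        self.sequences = list(sequences)
        self.target_index = target_index

    # -- basic access ---------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequences[0].residues)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def target(self) -> SequenceRecord:
        return self.sequences[self.target_index]

    def seq_ids(self) -> list[str]:
        return [rec.seq_id for rec in self.sequences]

    def column(self, col: int) -> list[str]:
        """Residues of 1-based column ``col``, gaps included."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return [rec.residues[col - 1] for rec in self.sequences]

    def ungapped(self, seq_id: str) -> str:
        for rec in self.sequences:
            if rec.seq_id == seq_id:
                return rec.residues.replace(GAP, "")
        raise KeyError(f"sequence {seq_id!r} not in family {self.family_id!r}")

    def subset(self, seq_ids: Iterable[str]) -> "AlignedFamily":
        """Row subset (original order), keeping the target if selected."""
        wanted = set(seq_ids)
        kept = [rec for rec in self.sequences if rec.seq_id in wanted]
        target_id = self.target.seq_id
        if target_id not in wanted:
            raise ValueError(
                f"family {self.family_id!r}: subset must retain the target "
                f"sequence {target_id!r}")
        new_index = [rec.seq_id for rec in kept].index(target_id)
        return AlignedFamily(self.family_id, kept, new_index)


def make_species_parser(pattern: str = DEFAULT_SPECIES_PATTERN):
    """Return a callable mapping a sequence label to its species token."""
    rx = re.compile(pattern)

    def parse(label: str) -> str:
        m = rx.search(label)
        if m is None or not m.group(1):
            raise ValueError(
                f"cannot parse species from label {label!r} with pattern "
                f"{pattern!r}")
        return m.group(1).upper()

    return parse


def read_fasta_msa(path: str | Path,
                   species_pattern: str = DEFAULT_SPECIES_PATTERN,
                   family_id: str | None = None,
                   target_id: str | None = None,
                   human_species: str = "HUMAN") -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`.

    The target row is ``target_id`` if given, else the unique row whose
    parsed species equals ``human_species``, else row 0.
    """
    path = Path(path)
    parse_species = make_species_parser(species_pattern)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, parse_species(rec.id),
                                      str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    if family_id is None:
        family_id = path.stem
    ids = [r.seq_id for r in records]
    if target_id is not None:
        if target_id not in ids:
            raise ValueError(f"{path}: target {target_id!r} not present")
        target_index = ids.index(target_id)
    else:
        humans = [i for i, r in enumerate(records)
                  if r.species == human_species.upper()]
        target_index = humans[0] if len(humans) == 1 else 0
    return AlignedFamily(family_id, records, target_index)


def write_fasta_msa(family: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in family.sequences:
            fh.write(f">{rec.seq_id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path,
                species_pattern: str = DEFAULT_SPECIES_PATTERN,
                lineages: Mapping[str, Sequence[str]] | None = None,
                human_species: str = "HUMAN",
                target: str | None = None) -> GeneTree:
    """Read a Newick tree; polytomies are accepted at load time.

    Leaf labels are resolved to (seq_id, species) with the species regex;
    an unresolvable label is a hard error naming the label.  ``lineages``
    maps species to ordered taxonomic rank lists (root to species); absent
    species fall back to a single-rank lineage of the species name.
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    parse_species = make_species_parser(species_pattern)

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            if label is None:
                raise ValueError(f"{path}: unlabeled leaf node")
            return TreeNode(label.replace(" ", "_"))
        return TreeNode(children=[convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    leaf_info: dict[str, LeafInfo] = {}
    bad: list[str] = []
    for name in root.leaf_names():
        try:
            species = parse_species(name)
        except ValueError:
            bad.append(name)
            continue
        lineage = tuple(lineages.get(species, (species,))) if lineages \
            else (species,)
        leaf_info[name] = LeafInfo(name, species,
                                   species == human_species.upper(), lineage)
    if bad:
        raise ValueError(f"{path}: unresolvable leaf names: {bad}")
    return GeneTree(root, leaf_info, target=target)


def read_lineages(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a TSV of ``species<TAB>rank1;rank2;...`` (root to species)."""
    out: dict[str, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        species, _, ranks = line.partition("\t")
        out[species.strip().upper()] = tuple(
            r.strip() for r in ranks.split(";") if r.strip())
    if not out:
        raise ValueError(f"{path}: no lineage rows")
    return out


# ---------------------------------------------------------------------------
# Coupling table
# ---------------------------------------------------------------------------

class CouplingTable:
    """Receptor x Galpha coupling flags from one or more source datasets."""

    def __init__(self, frame: pd.DataFrame,
                 g_protein_vocab: Sequence[str] = G_PROTEIN_SUBTYPES) -> None:
        required = {"receptor", "g_protein", "source", "couples"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"coupling table missing columns {sorted(missing)}")
        frame = frame.copy()
        frame["couples"] = frame["couples"].astype(int).astype(bool)
        bad_g = set(frame["g_protein"]) - set(g_protein_vocab)
        if bad_g:
            raise ValueError(f"unknown G protein names {sorted(bad_g)}; "
                             f"expected one of {list(g_protein_vocab)}")
        bad_src = set(frame["source"]) - set(COUPLING_SOURCES)
        if bad_src:
            raise ValueError(f"unknown sources {sorted(bad_src)}")
        key = frame[["receptor", "g_protein", "source"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (receptor, g_protein, source) rows: "
                             f"{dupes[:5]}")
        self.frame = frame
        self.g_protein_vocab = tuple(g_protein_vocab)

    @property
    def receptors(self) -> list[str]:
        return sorted(self.frame["receptor"].unique())

    @property
    def g_proteins(self) -> list[str]:
        return sorted(self.frame["g_protein"].unique())

    def couplers(self, g_protein: str, policy: str = "union") -> set[str]:
        """Receptors coupling to ``g_protein`` under a source policy.

        ``policy`` is one of ``datasetA``, ``datasetB``, ``union``,
        ``intersection``; rows with source ``merged`` count for every policy.
        """
        sub = self.frame[self.frame["g_protein"] == g_protein]
        if sub.empty:
            raise KeyError(f"no rows for G protein {g_protein!r}")
        merged = set(sub[(sub["source"] == "merged") & sub["couples"]]
                     ["receptor"])
        by_src = {
            s: set(sub[(sub["source"] == s) & sub["couples"]]["receptor"])
            for s in ("datasetA", "datasetB")}
        if policy in ("datasetA", "datasetB"):
            return by_src[policy] | merged
        if policy == "union":
            return by_src["datasetA"] | by_src["datasetB"] | merged
        if policy == "intersection":
            present = [s for s in ("datasetA", "datasetB")
                       if (sub["source"] == s).any()]
            if not present:
                return merged
            inter = set.intersection(*(by_src[s] for s in present))
            return inter | merged
        raise ValueError(f"unknown source policy {policy!r}")

    def noncouplers(self, g_protein: str, policy: str = "union") -> set[str]:
        return set(self.receptors) - self.couplers(g_protein, policy)


def read_coupling_table(path: str | Path) -> CouplingTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return CouplingTable(frame)


# ---------------------------------------------------------------------------
# Generic-number maps
# ---------------------------------------------------------------------------

class GenericNumberMap:
    """Injective residue_index -> GPCRdb generic number map for one receptor."""

    def __init__(self, mapping: Mapping[int, str]) -> None:
        for idx, gn in mapping.items():
            if not GENERIC_NUMBER_RE.match(gn):
                raise ValueError(f"invalid generic number {gn!r} at residue "
                                 f"{idx}")
        values = list(mapping.values())
        if len(values) != len(set(values)):
            dupes = sorted({v for v in values if values.count(v) > 1})
            raise ValueError(f"generic numbers assigned twice: {dupes}")
        self._map = {int(k): v for k, v in mapping.items()}

    def get(self, residue_index: int) -> str | None:
        return self._map.get(residue_index)

    def __getitem__(self, residue_index: int) -> str:
        return self._map[residue_index]

    def __contains__(self, residue_index: int) -> bool:
        return residue_index in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def read_generic_map(path: str | Path) -> GenericNumberMap:
    """Read a TSV of ``residue_index<TAB>generic_number`` rows."""
    mapping: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        idx, _, gn = line.partition("\t")
        mapping[int(idx)] = gn.strip()
    if not mapping:
        raise ValueError(f"{path}: no map rows")
    return GenericNumberMap(mapping)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue with its heavy atoms."""

    chain: str
    index: int
    name: str
    generic_number: str | None
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    @property
    def label(self) -> str:
        """Generic number if mapped, else a chain:index fallback key."""
        return self.generic_number or f"{self.chain}:{self.index}"

    def atom_coord(self, atom_name: str) -> np.ndarray:
        try:
            i = self.atom_names.index(atom_name)
        except ValueError:
            raise KeyError(f"residue {self.chain}:{self.index} has no atom "
                           f"{atom_name!r}") from None
        return self.coords[i]


class StructureModel:
    """Heavy-atom coordinates of one receptor structure or trajectory frame."""

    def __init__(self, structure_id: str, residues: Sequence[Residue],
                 state: str = "active") -> None:
        if state not in ("active", "inactive"):
            raise ValueError(f"state must be active/inactive, got {state!r}")
        gns = [r.generic_number for r in residues if r.generic_number]
        if len(gns) != len(set(gns)):
            dupes = sorted({g for g in gns if gns.count(g) > 1})
            raise ValueError(f"{structure_id}: generic numbers used twice: "
                             f"{dupes}")
        for res in residues:
            if not np.all(np.isfinite(res.coords)):
                raise ValueError(f"{structure_id}: non-finite coordinates in "
                                 f"residue {res.chain}:{res.index}")
        self.structure_id = structure_id
        self.residues = list(residues)
        self.state = state

    @property
    def n_heavy_atoms(self) -> int:
        return sum(len(r.atom_names) for r in self.residues)

    def residue_by_generic(self, generic_number: str) -> Residue:
        for res in self.residues:
            if res.generic_number == generic_number:
                return res
        raise KeyError(f"{self.structure_id}: no residue with generic number "
                       f"{generic_number!r}")

    def roster(self) -> list[tuple[str, int, str, tuple[str, ...]]]:
        """Residue/atom identity used to check frame compatibility."""
        return [(r.chain, r.index, r.name, tuple(r.atom_names))
                for r in self.residues]

    def stacked_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues], axis=0)

    def with_coords(self, flat: np.ndarray, structure_id: str | None = None,
                    state: str | None = None) -> "StructureModel":
        """Copy of this model with coordinates replaced (same roster)."""
        if flat.shape != (self.n_heavy_atoms, 3):
            raise ValueError("coordinate array does not match atom roster")
        residues = []
        offset = 0
        for res in self.residues:
            k = len(res.atom_names)
            residues.append(Residue(res.chain, res.index, res.name,
                                    res.generic_number, list(res.atom_names),
                                    list(res.elements),
                                    np.array(flat[offset:offset + k])))
            offset += k
        return StructureModel(structure_id or self.structure_id, residues,
                              state or self.state)


_HYDROGEN = {"H", "D"}


def _convert_biopdb_model(model, structure_id: str,
                          generic_map: GenericNumberMap | None,
                          state: str) -> StructureModel:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, _icode = res.get_id()
            if hetflag.strip():
                continue  # heteroatoms/waters are not part of the receptor
            names, elements, coords = [], [], []
            for atom in res:
                if atom.is_disordered():
                    # keep the highest-occupancy altloc
                    atom = max(atom.disordered_get_list(),
                               key=lambda a: (a.get_occupancy() or 0.0))
                element = (atom.element or "").upper()
                if element in _HYDROGEN:
                    continue
                names.append(atom.get_name())
                elements.append(element)
                coords.append(np.asarray(atom.get_coord(), dtype=float))
            if not names:
                continue
            gn = generic_map.get(resseq) if generic_map is not None else None
            residues.append(Residue(chain.id, resseq, res.get_resname(),
                                    gn, names, elements, np.array(coords)))
    if not any("CA" in r.atom_names for r in residues):
        raise ValueError(f"{structure_id}: no CA atoms found — "
                         "not a protein structure")
    return StructureModel(structure_id, residues, state)


def read_structure(path: str | Path,
                   generic_map: GenericNumberMap | None = None,
                   state: str = "active",
                   structure_id: str | None = None) -> StructureModel:
    """Read the first model of a PDB file, hydrogens dropped.

    Disordered (altloc) atoms keep the highest-occupancy location; duplicate
    atom records raise a warning inside Bio.PDB and the first is kept.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no coordinate models")
    return _convert_biopdb_model(models[0], structure_id or path.stem,
                                 generic_map, state)


def read_trajectory_frames(path: str | Path,
                           generic_map: GenericNumberMap | None = None,
                           state: str = "active") -> list[StructureModel]:
    """Read every model of a multi-model PDB as one frame each."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    frames = [_convert_biopdb_model(m, f"{path.stem}:model{i}",
                                    generic_map, state)
              for i, m in enumerate(structure)]
    if not frames:
        raise ValueError(f"{path}: no coordinate models")
    return frames


def _pdb_atom_line(serial: int, atom_name: str, res_name: str, chain: str,
                   res_index: int, xyz: np.ndarray, element: str) -> str:
    name = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
    return (f"ATOM  {serial:5d} {name:<4s}{'':1s}{res_name:<3s} {chain:1s}"
            f"{res_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    lines = []
    serial = 0
    for res in model.residues:
        for name, element, xyz in zip(res.atom_names, res.elements,
                                      res.coords):
            serial += 1
            lines.append(_pdb_atom_line(serial, name, res.name, res.chain,
                                        res.index, xyz, element))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multimodel_pdb(models: Sequence[StructureModel],
                         path: str | Path) -> None:
    """Write trajectory frames as a numbered multi-model PDB file."""
    lines = []
    for i, model in enumerate(models, start=1):
        lines.append(f"MODEL     {i:4d}")
        serial = 0
        for res in model.residues:
            for name, element, xyz in zip(res.atom_names, res.elements,
                                          res.coords):
                serial += 1
                lines.append(_pdb_atom_line(serial, name, res.name,
                                            res.chain, res.index, xyz,
                                            element))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------

def write_edge_table(network, path: str | Path,
                     header_comment: str | None = None) -> None:
    """Write a ContactNetwork as a Cytoscape-friendly TSV.

    Columns: source_generic, target_generic, score and, when the network
    carries p-values, p_value.  Rows are sorted lexicographically, so the
    byte output is deterministic for a fixed network.
    """
    if network is None:
        raise ValueError("network must not be None")
    has_p = network.pvalues is not None
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    header = "source_generic\ttarget_generic\tscore"
    if has_p:
        header += "\tp_value"
    lines.append(header)
    for (a, b) in sorted(network.edges):
        row = f"{a}\t{b}\t{network.edges[(a, b)]:.6g}"
        if has_p:
            row += f"\t{network.pvalues[(a, b)]:.6g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
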