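"""Macromolecular structure and score-manifest I/O.

The atomic data model is deliberately array-backed: a :class:`ChainModel`
stores flat per-atom numpy arrays which every downstream module consumes
directly.  PDB is the only required dialect; per-residue predictor
confidence (pLDDT) travels in the B-factor column, following the output
convention of structure predictors.

Chain labelling: assemblies with more than 26 chains use a single-character
62-symbol alphabet ``A-Z 0-9 a-z`` (in that order), which keeps every
record a strictly standard fixed-column PDB ATOM line.  More than 62 chains
is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as biotite_pdb

CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


class StructureError(Exception):
    """Base class for structure I/O failures."""


class StructureParseError(StructureError):
    pass


class StructureValidationError(StructureError):
    pass


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0


@dataclass
class ChainModel:
    """One polypeptide chain, stored as flat per-atom arrays."""

    chain_id: str
    atom_names: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float
    res_ids: np.ndarray  # (n,) int, residue number per atom
    res_names: np.ndarray  # (n,) str
    bfactors: np.ndarray  # (n,) float
    occupancies: np.ndarray  # (n,) float
    elements: np.ndarray | None = None

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.bfactors = np.asarray(self.bfactors, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.elements is None:
            self.elements = np.array(
                [_ELEMENT_OF.get(n, n[:1]) for n in self.atom_names], dtype="U2"
            )

    # -- residue level views -------------------------------------------------

    @property
    def residue_numbers(self) -> np.ndarray:
        """Unique residue numbers in file order."""
        _, idx = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(idx)]

    @property
    def sequence_length(self) -> int:
        return len(self.residue_numbers)

    def residues(self):
        """Yield (residue number, residue name, list of Atom)."""
        for num in self.residue_numbers:
            mask = self.res_ids == num
            atoms = [
                Atom(n, e, c, b, o)
                for n, e, c, b, o in zip(
                    self.atom_names[mask],
                    self.elements[mask],
                    self.coords[mask],
                    self.bfactors[mask],
                    self.occupancies[mask],
                )
            ]
            yield int(num), str(self.res_names[mask][0]), atoms

    def atom_mask(self, name: str) -> np.ndarray:
        return self.atom_names == name

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.atom_mask("CA")]

    def cb_or_ca_coords(self) -> np.ndarray:
        """CB coordinate per residue, CA for glycine."""
        out = []
        for num in self.residue_numbers:
            mask = self.res_ids == num
            names = self.atom_names[mask]
            pick = "CB" if "CB" in names else "CA"
            out.append(self.coords[mask][names == pick][0])
        return np.array(out)

    def com(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, r: np.ndarray, t: np.ndarray | None = None) -> "ChainModel":
        t = np.zeros(3) if t is None else np.asarray(t, float)
        return replace(self, coords=(r @ self.coords.T).T + t)

    def translated(self, t: np.ndarray) -> "ChainModel":
        return replace(self, coords=self.coords + np.asarray(t, float))

    def with_chain_id(self, chain_id: str) -> "ChainModel":
        return replace(self, chain_id=chain_id)

    def per_residue_bfactor(self) -> np.ndarray:
        return np.array(
            [self.bfactors[self.res_ids == num].mean() for num in self.residue_numbers]
        )


@dataclass
class Assembly:
    chains: list[ChainModel]
    symmetry_tag: str | None = None
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, float)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_coords(self) -> np.ndarray:
        return np.vstack([c.coords for c in self.chains])

    def transformed(self, r: np.ndarray, t: np.ndarray | None = None) -> "Assembly":
        return Assembly(
            [c.transformed(r, t) for c in self.chains],
            symmetry_tag=self.symmetry_tag,
            center=(r @ self.center) + (np.zeros(3) if t is None else t),
        )

    def translated(self, t) -> "Assembly":
        return Assembly(
            [c.translated(t) for c in self.chains],
            symmetry_tag=self.symmetry_tag,
            center=self.center + np.asarray(t, float),
        )


@dataclass(frozen=True)
class ManifestRecord:
    model_id: str
    mean_plddt: float
    ptm: float
    iptm: float | None = None


@dataclass
class ScoreManifest:
    records: list[ManifestRecord]

    def __len__(self):
        return len(self.records)

    def get(self, model_id: str) -> ManifestRecord:
        for rec in self.records:
            if rec.model_id == model_id:
                return rec
        raise KeyError(f"no manifest record for model {model_id!r}")


# -- validation ---------------------------------------------------------------


def validate_chain(chain: ChainModel) -> None:
    """Enforce the chain invariants; raise StructureValidationError."""
    nums = chain.res_ids
    boundaries = np.flatnonzero(np.diff(nums) != 0)
    ordered = nums[np.concatenate([[0], boundaries + 1])] if len(nums) else nums
    if len(ordered) and np.any(np.diff(ordered) <= 0):
        raise StructureValidationError(
            f"chain {chain.chain_id}: residue numbers not strictly increasing"
        )
    for num, name, atoms in chain.residues():
        names = {a.name for a in atoms}
        for req in BACKBONE_ATOMS:
            if req not in names:
                raise StructureValidationError(
                    f"chain {chain.chain_id} residue {num} ({name}): missing {req}"
                )
        if name != "GLY" and "CB" not in names:
            raise StructureValidationError(
                f"chain {chain.chain_id} residue {num} ({name}): missing CB"
            )
    if not np.all(np.isfinite(chain.coords)):
        raise StructureValidationError(
            f"chain {chain.chain_id}: non-finite coordinates"
        )


def validate_assembly(assembly: Assembly) -> None:
    if not assembly.chains:
        raise StructureValidationError("assembly has no chains")
    ids = [c.chain_id for c in assembly.chains]
    if len(set(ids)) != len(ids):
        raise StructureValidationError("duplicate chain ids")
    for chain in assembly.chains:
        validate_chain(chain)


# -- biotite conversion -------------------------------------------------------


def to_atom_array(obj: ChainModel | Assembly) -> struc.AtomArray:
    chains = obj.chains if isinstance(obj, Assembly) else [obj]
    n = sum(len(c.coords) for c in chains)
    arr = struc.AtomArray(n)
    arr.coord = np.vstack([c.coords for c in chains])
    arr.chain_id = np.concatenate(
        [np.full(len(c.coords), c.chain_id, dtype="U4") for c in chains]
    )
    arr.res_id = np.concatenate([c.res_ids for c in chains])
    arr.res_name = np.concatenate([c.res_names for c in chains])
    arr.atom_name = np.concatenate([c.atom_names for c in chains])
    arr.element = np.concatenate([c.elements for c in chains])
    arr.set_annotation(
        "b_factor", np.concatenate([c.bfactors for c in chains])
    )
    arr.set_annotation(
        "occupancy", np.concatenate([c.occupancies for c in chains])
    )
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def from_atom_array(arr: struc.AtomArray) -> Assembly:
    chains = []
    # preserve file order of chains
    seen = []
    for cid in arr.chain_id:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        mask = arr.chain_id == cid
        chains.append(
            ChainModel(
                chain_id=str(cid),
                atom_names=arr.atom_name[mask],
                coords=arr.coord[mask],
                res_ids=arr.res_id[mask],
                res_names=arr.res_name[mask],
                bfactors=arr.b_factor[mask]
                if "b_factor" in arr.get_annotation_categories()
                else np.zeros(mask.sum()),
                occupancies=arr.occupancy[mask]
                if "occupancy" in arr.get_annotation_categories()
                else np.ones(mask.sum()),
                elements=arr.element[mask],
            )
        )
    return Assembly(chains)


# -- PDB I/O ------------------------------------------------------------------


def _prescan_pdb(path: Path) -> None:
    """Cheap structural scan so malformed ATOM records fail naming the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}, line {lineno}: truncated ATOM record"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}, line {lineno}: unparsable coordinates"
                ) from exc


def read_structure(path, dialect: str = "pdb", validate: bool = True) -> Assembly:
    """Read a (multi-model collapsed to first model) PDB file into an Assembly."""
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    try:
        pdb_file = biotite_pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(
            model=1, extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # pragma: no cover - biotite internal failures
        raise StructureParseError(f"{path}: {exc}") from exc
    assembly = from_atom_array(arr[~arr.hetero])
    if validate:
        validate_assembly(assembly)
    return assembly


def write_assembly(assembly: Assembly, path) -> None:
    """Write standard fixed-column PDB ATOM/TER/END records."""
    if not assembly.chains:
        raise StructureValidationError("refusing to write an empty assembly")
    if assembly.n_chains > len(CHAIN_ALPHABET):
        raise StructureValidationError(
            f"{assembly.n_chains} chains exceed the {len(CHAIN_ALPHABET)}-symbol "
            "chain alphabet"
        )
    arr = to_atom_array(assembly)
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def relabel_chains(assembly: Assembly) -> Assembly:
    """Assign canonical alphabet chain ids in chain order."""
    if assembly.n_chains > len(CHAIN_ALPHABET):
        raise StructureValidationError("too many chains to relabel")
    return Assembly(
        [c.with_chain_id(CHAIN_ALPHABET[i]) for i, c in enumerate(assembly.chains)],
        symmetry_tag=assembly.symmetry_tag,
        center=assembly.center,
    )


# -- score manifest -----------------------------------------------------------


def read_manifest(path) -> ScoreManifest:
    """Read a JSON manifest mapping model id -> {plddt, ptm, iptm}."""
    with open(path) as fh:
        raw = json.load(fh)
    records = []
    for model_id, rec in raw.items():
        records.append(
            _make_record(model_id, rec.get("plddt"), rec.get("ptm"), rec.get("iptm"))
        )
    return ScoreManifest(records)


def write_manifest(manifest: ScoreManifest, path) -> None:
    raw = {}
    for rec in manifest.records:
        entry = {"plddt": rec.mean_plddt, "ptm": rec.ptm}
        if rec.iptm is not None:
            entry["iptm"] = rec.iptm
        raw[rec.model_id] = entry
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)


def manifest_from_models(
    models: dict[str, "ChainModel"], ptm: float = 0.5, iptm: float | None = None
) -> ScoreManifest:
    """Fallback manifest when only PDB files are available: per-model mean
    pLDDT is recovered from the B-factor column (this package's convention;
    predictors do not ship it separately with bare PDBs)."""
    records = [
        ManifestRecord(
            model_id=mid,
            mean_plddt=float(chain.per_residue_bfactor().mean()),
            ptm=ptm,
            iptm=iptm,
        )
        for mid, chain in models.items()
    ]
    return ScoreManifest(records)


def _make_record(model_id, plddt, ptm, iptm) -> ManifestRecord:
    if plddt is None or not 0.0 <= float(plddt) <= 100.0:
        raise StructureValidationError(
            f"model {model_id}: plddt {plddt!r} outside [0, 100]"
        )
    if ptm is None or not 0.0 <= float(ptm) <= 1.0:
        raise StructureValidationError(f"model {model_id}: ptm {ptm!r} outside [0, 1]")
    if iptm is not None and not 0.0 <= float(iptm) <= 1.0:
        raise StructureValidationError(
            f"model {model_id}: iptm {iptm!r} outside [0, 1]"
        )
    return ManifestRecord(
        model_id=str(model_id),
        mean_plddt=float(plddt),
        ptm=float(ptm),
        iptm=None if iptm is None else float(iptm),
    )
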