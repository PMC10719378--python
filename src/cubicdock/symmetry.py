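"""Cubic point-group mathematics and the six-parameter placement model.

A cubic assembly is parametrized by six rigid-body degrees of freedom:
three intrinsic Z-Y-Z Euler angles (psi, theta, phi) rotating the subunit
about its own center of mass, a translation to (x, 0, z), and a rotation
``lam`` about the setup-fold axis, which by convention is the global Z
axis.  Applying every rotation of the point group to the placed subunit
expands the full assembly; the first (identity) copy is the main subunit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import geometry as geo
from .structure_io import (
    Assembly,
    ChainModel,
    relabel_chains,
)

FOLDS = {"T": (2, 3), "O": (2, 3, 4), "I": (2, 3, 5)}
GROUP_ORDER = {"T": 12, "O": 24, "I": 60}

PENALTY_DEPTH = 1.0e9

PARAM_NAMES = ("psi", "theta", "phi", "z", "x", "lam")


class SymmetryError(Exception):
    pass


@dataclass(frozen=True)
class RigidBodyParams:
    """The six docking degrees of freedom (angles in degrees, z/x in A)."""

    psi: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    z: float = 0.0
    x: float = 0.0
    lam: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.psi, self.theta, self.phi, self.z, self.x, self.lam])

    @classmethod
    def from_array(cls, a) -> "RigidBodyParams":
        a = np.asarray(a, float)
        return cls(*[float(v) for v in a])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise SymmetryError(f"non-finite rigid body parameters: {self}")


@dataclass(frozen=True)
class SymmetryGroup:
    kind: str
    rotations: np.ndarray  # (order, 3, 3)
    folds: tuple[int, ...]

    @property
    def order(self) -> int:
        return len(self.rotations)


@dataclass
class SymmetryDefinition:
    kind: str
    setup_fold: int
    params: RigidBodyParams = field(default_factory=RigidBodyParams)
    subsystem_chain_indices: list[int] | None = None

    def __post_init__(self):
        if self.kind not in FOLDS:
            raise SymmetryError(f"unknown symmetry kind {self.kind!r}")
        if self.setup_fold not in FOLDS[self.kind]:
            raise SymmetryError(
                f"fold {self.setup_fold} not available for {self.kind}"
            )

    # -- structured-text serialisation ---------------------------------------

    def to_file(self, path) -> None:
        doc = {
            "format": "cubicdock-symdef-1",
            "kind": self.kind,
            "setup_fold": self.setup_fold,
            "params": {k: float(getattr(self.params, k)) for k in PARAM_NAMES},
            "subsystem_chain_indices": self.subsystem_chain_indices,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SymmetryDefinition":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("format") != "cubicdock-symdef-1":
            raise SymmetryError(f"unrecognised symmetry definition file {path}")
        return cls(
            kind=doc["kind"],
            setup_fold=int(doc["setup_fold"]),
            params=RigidBodyParams(**doc["params"]),
            subsystem_chain_indices=doc.get("subsystem_chain_indices"),
        )


@dataclass
class BoundsSpec:
    intervals: dict[str, tuple[float, float]]
    setup_fold: int
    mode: str
    penalty_depth: float = PENALTY_DEPTH

    def contains(self, params: RigidBodyParams) -> bool:
        return self.n_violations(params) == 0

    def n_violations(self, params: RigidBodyParams) -> int:
        n = 0
        for name in PARAM_NAMES:
            lo, hi = self.intervals[name]
            v = getattr(params, name)
            if v < lo or v > hi:
                n += 1
        return n

    def clip(self, arr: np.ndarray) -> np.ndarray:
        lo = np.array([self.intervals[n][0] for n in PARAM_NAMES])
        hi = np.array([self.intervals[n][1] for n in PARAM_NAMES])
        return np.clip(arr, lo, hi)

    def sample(self, rng: np.random.Generator) -> RigidBodyParams:
        vals = [
            rng.uniform(*self.intervals[name]) for name in PARAM_NAMES
        ]
        return RigidBodyParams.from_array(np.array(vals))


# -- group construction -------------------------------------------------------


def _canonical_axis_sign(a: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Pick the canonical representative of the axis line {+a, -a}."""
    for comp in (a[2], a[1], a[0]):
        if comp > tol:
            return a
        if comp < -tol:
            return -a
    return a


def _sort_rotations(mats: np.ndarray) -> np.ndarray:
    keys = []
    for m in mats:
        axis, angle = geo.rotation_axis_angle(m)
        axis = _canonical_axis_sign(axis)
        keys.append((round(angle, 6),) + tuple(np.round(axis, 6)))
    order = sorted(range(len(mats)), key=lambda i: keys[i])
    return mats[order]


@lru_cache(maxsize=None)
def group_rotations(kind: str) -> SymmetryGroup:
    """The rotation set of the tetrahedral/octahedral/icosahedral group."""
    if kind not in FOLDS:
        raise SymmetryError(f"unknown symmetry kind {kind!r}")
    mats = Rotation.create_group(kind).as_matrix()
    mats = _sort_rotations(np.asarray(mats))
    return SymmetryGroup(kind=kind, rotations=mats, folds=FOLDS[kind])


def fold_axes(group: SymmetryGroup, n: int) -> np.ndarray:
    """Distinct fold-axis lines of order n, canonical representatives.

    Ordered by descending projection on +Z, then lexicographically.
    """
    if n not in group.folds:
        raise SymmetryError(f"fold {n} not in {group.kind} folds {group.folds}")
    target = 360.0 / n
    axes = []
    for m in group.rotations:
        axis, angle = geo.rotation_axis_angle(m)
        if abs(angle - target) < 1e-6:
            axis = _canonical_axis_sign(axis)
            if not any(np.allclose(axis, a, atol=1e-8) for a in axes):
                axes.append(axis)
    axes.sort(key=lambda a: (-round(a[2], 9), -round(a[1], 9), -round(a[0], 9)))
    return np.array(axes)


@lru_cache(maxsize=None)
def setup_frame(kind: str, setup_fold: int):
    """Group rotations conjugated so a setup-fold axis lies on +Z.

    Returns (rotations (order,3,3), reference secondary axis in the new
    frame).  The azimuth is fixed by rotating a deterministic secondary
    fold axis into the XZ half-plane (x > 0).  The identity is first.
    """
    base = group_rotations(kind)
    axes = [a for a in fold_axes(base, setup_fold) if _max_order(base, a) == setup_fold]
    a = axes[0]
    s1 = geo.align_vectors_rotation(a, np.array([0.0, 0.0, 1.0]))
    # secondary axis: the highest other fold order
    other = [f for f in base.folds if f != setup_fold][-1]
    baxes = fold_axes(base, other)
    b = min(
        (s1 @ ax for ax in baxes),
        key=lambda v: (round(-abs(v[2]), 9),) + tuple(np.round(-v, 9)),
    )
    az = math.degrees(math.atan2(b[1], b[0]))
    rz = geo.rot_z(-az)
    s = rz @ s1
    rots = np.einsum("ij,njk,kl->nil", s, base.rotations, s.T)
    # identity first, rest deterministically ordered
    rots = _sort_rotations(rots)
    assert np.allclose(rots[0], np.eye(3), atol=1e-9)
    b_new = rz @ b
    return rots, s @ a, b_new / np.linalg.norm(b_new)


def _max_order(group: SymmetryGroup, axis: np.ndarray) -> int:
    """Highest fold order of group elements sharing this axis line."""
    best = 1
    for m in group.rotations:
        ax, angle = geo.rotation_axis_angle(m)
        if angle < 1e-9:
            continue
        if abs(abs(np.dot(ax, axis)) - 1.0) < 1e-8:
            best = max(best, int(round(360.0 / angle)))
    return best


def setup_rotations(kind: str, setup_fold: int) -> np.ndarray:
    return setup_frame(kind, setup_fold)[0]


@lru_cache(maxsize=None)
def setup_fold_axes(kind: str, setup_fold: int, n: int) -> np.ndarray:
    """Fold axes of order n in the setup frame (setup-fold axis on +Z)."""
    rots, _, _ = setup_frame(kind, setup_fold)
    group = SymmetryGroup(kind=kind, rotations=rots, folds=FOLDS[kind])
    return fold_axes(group, n)


# -- placement ---------------------------------------------------------------


def placement_transform(params: RigidBodyParams, flipped: bool = False):
    """Absolute transform (R, t) of the main subunit: X -> R @ (X - com) + t."""
    params.validate()
    e = geo.euler_to_matrix(params.psi, params.theta, params.phi)
    if flipped:
        e = geo.rot_x(180.0) @ e
    rz = geo.rot_z(params.lam)
    r = rz @ e
    t = rz @ np.array([params.x, 0.0, params.z])
    return r, t


def place_and_expand(
    subunit: ChainModel,
    params: RigidBodyParams,
    sd: SymmetryDefinition,
    flipped: bool = False,
) -> Assembly:
    """Place the subunit by the six parameters and expand through the group."""
    r, t = placement_transform(params, flipped=flipped)
    com = subunit.com()
    placed = (r @ (subunit.coords - com).T).T + t
    rots = setup_rotations(sd.kind, sd.setup_fold)
    chains = []
    for g in rots:
        chains.append(replace(subunit, coords=(g @ placed.T).T))
    assembly = relabel_chains(Assembly(chains, symmetry_tag=sd.kind))
    return assembly


def flip_orientation(params: RigidBodyParams) -> RigidBodyParams:
    """The 180-degree flip of the placed subunit perpendicular to the
    setup-fold axis, expressed back in the six parameters.

    Involution up to group equivalence: flip(flip(p)) regenerates the
    original placement exactly.
    """
    e = geo.euler_to_matrix(params.psi, params.theta, params.phi)
    psi, theta, phi = geo.matrix_to_euler(geo.rot_x(180.0) @ e)
    return replace(params, psi=psi, theta=theta, phi=phi)


# -- bounds ------------------------------------------------------------------


def make_bounds(
    sd: SymmetryDefinition,
    mode: str,
    center: RigidBodyParams | None = None,
) -> BoundsSpec:
    """Parameter intervals maintaining subsystem integrity.

    lam max bounds are +-(360/n)/2 in global mode, halved again in local
    mode.  psi/theta/phi: +-40 deg and x: +-5 A around the center.  z is
    +-5 A around the center locally and [0, 1000] A globally.
    """
    if mode not in ("local", "global"):
        raise SymmetryError(f"unknown bounds mode {mode!r}")
    center = center or sd.params
    n = sd.setup_fold
    half = 360.0 / n / 2.0
    lam_w = half if mode == "global" else half / 2.0
    intervals = {
        "psi": (center.psi - 40.0, center.psi + 40.0),
        "theta": (center.theta - 40.0, center.theta + 40.0),
        "phi": (center.phi - 40.0, center.phi + 40.0),
        "x": (center.x - 5.0, center.x + 5.0),
        "lam": (center.lam - lam_w, center.lam + lam_w),
    }
    if mode == "local":
        intervals["z"] = (center.z - 5.0, center.z + 5.0)
    else:
        intervals["z"] = (0.0, 1000.0)
    return BoundsSpec(intervals=intervals, setup_fold=n, mode=mode)


def square_well_penalty(params: RigidBodyParams, bounds: BoundsSpec) -> float:
    """0 inside the bounds, penalty_depth per violated parameter outside.

    Additivity across violated parameters is a documented convention.
    """
    return bounds.n_violations(params) * bounds.penalty_depth


# -- subsystem ---------------------------------------------------------------


def build_subsystem(
    assembly: Assembly, sd: SymmetryDefinition, cutoff: float = 12.0
) -> Assembly:
    """Main subunit plus every chain with a CB (CA for Gly) within cutoff.

    The returned chain subset carries all interchain interactions of the
    main subunit for scoring ranges up to ``cutoff``.
    """
    main = assembly.chains[0]
    if cutoff <= 0:
        sd.subsystem_chain_indices = [0]
        return Assembly([main], symmetry_tag=assembly.symmetry_tag)
    tree = cKDTree(main.cb_or_ca_coords())
    keep = [0]
    for i, chain in enumerate(assembly.chains[1:], start=1):
        d, _ = tree.query(chain.cb_or_ca_coords(), k=1)
        if np.min(d) <= cutoff:
            keep.append(i)
    if len(keep) == 1:
        warnings.warn("subsystem selection found no partner chains")
    sd.subsystem_chain_indices = keep
    return Assembly(
        [assembly.chains[i] for i in keep], symmetry_tag=assembly.symmetry_tag
    )


def subsystem_rotation_indices(
    subunit: ChainModel,
    params: RigidBodyParams,
    sd: SymmetryDefinition,
    cutoff: float = 12.0,
    margin: float = 2.0,
) -> list[int]:
    """Indices of group elements whose chain copy can interact with the
    main subunit at ``params`` (distance filter on CB clouds)."""
    r, t = placement_transform(params)
    com = subunit.com()
    cb = (r @ (subunit.cb_or_ca_coords() - com).T).T + t
    rots = setup_rotations(sd.kind, sd.setup_fold)
    tree = cKDTree(cb)
    keep = [0]
    for k in range(1, len(rots)):
        d, _ = tree.query((rots[k] @ cb.T).T, k=1)
        if np.min(d) <= cutoff + margin:
            keep.append(k)
    return keep


# -- parameter extraction ----------------------------------------------------


def _chain_group_fit(assembly: Assembly):
    """Pure rotations about the origin mapping chain 0 onto every chain."""
    x0 = assembly.chains[0].ca_coords()
    mats = []
    for chain in assembly.chains:
        xi = chain.ca_coords()
        if xi.shape != x0.shape:
            raise SymmetryError("chains differ in CA count")
        if geo.superposed_rmsd(xi, x0) > 2.0:
            raise SymmetryError(
                f"chain {chain.chain_id} not superposable onto chain 0 (> 2 A)"
            )
        mats.append(geo.rotation_about_origin(x0, xi))
    return np.array(mats)


def _axes_of_angle(mats: np.ndarray, target: float, tol: float = 15.0):
    axes = []
    for m in mats:
        axis, angle = geo.rotation_axis_angle(m)
        if abs(angle - target) < tol:
            axes.append(axis)
            axes.append(-axis)
    return axes


def extract_params(
    assembly: Assembly,
    kind: str,
    setup_fold: int,
    subunit: ChainModel | None = None,
    return_subunit: bool = False,
):
    """Recover the six placement parameters from a full assembly.

    The assembly is centered at the origin, its internal rotation set is
    fitted from chain-to-chain superpositions and aligned onto the standard
    setup frame; the placement of chain 0 then yields (z, x, lam) and, when
    a reference ``subunit`` is supplied, the Euler angles of its residual
    orientation.  Parameters are recovered up to group equivalence.
    """
    if kind not in FOLDS:
        raise SymmetryError(f"unknown symmetry kind {kind!r}")
    if assembly.n_chains != GROUP_ORDER[kind]:
        raise SymmetryError(
            f"{kind} assembly needs {GROUP_ORDER[kind]} chains, got {assembly.n_chains}"
        )
    center = assembly.all_coords().mean(axis=0)
    assembly = assembly.translated(-center)
    mats = _chain_group_fit(assembly)

    rots, _, b_ref = setup_frame(kind, setup_fold)
    c0 = assembly.chains[0].ca_coords().mean(axis=0)
    c0n = c0 / np.linalg.norm(c0)

    n = setup_fold
    n_axes = _axes_of_angle(mats, 360.0 / n)
    if not n_axes:
        raise SymmetryError(f"no {n}-fold rotations found in assembly")
    n_axes.sort(key=lambda a: -float(np.dot(a, c0n)))

    other = [f for f in FOLDS[kind] if f != n][-1]
    m_axes = _axes_of_angle(mats, 360.0 / other)
    ref_angle = math.degrees(
        math.acos(np.clip(b_ref[2], -1.0, 1.0))
    )  # angle between +Z and reference secondary axis

    s_found = None
    for a in n_axes:
        cands = [
            b
            for b in m_axes
            if abs(math.degrees(math.acos(np.clip(np.dot(a, b), -1, 1))) - ref_angle)
            < 10.0
        ]
        cands.sort(key=lambda b: -float(np.dot(b, c0n)))
        for b in cands:
            s = _frame_rotation(a, b, np.array([0.0, 0.0, 1.0]), b_ref)
            if _conjugates_onto(s, mats, rots):
                s_found = s
                break
        if s_found is not None:
            break
    if s_found is None:
        raise SymmetryError("could not align assembly rotations onto the group")

    aligned0 = assembly.chains[0].transformed(s_found)
    c = aligned0.coords.mean(axis=0)
    z = float(c[2])
    x = float(math.hypot(c[0], c[1]))
    lam = float(math.degrees(math.atan2(c[1], c[0]))) if x > 1e-9 else 0.0

    if subunit is not None:
        q = geo.rotation_about_origin(
            subunit.coords - subunit.com(), aligned0.coords - c
        )
        e = geo.rot_z(-lam) @ q
        psi, theta, phi = geo.matrix_to_euler(e)
    else:
        psi = theta = phi = 0.0
        subunit = replace(
            aligned0,
            coords=(geo.rot_z(-lam) @ (aligned0.coords - c).T).T,
        )

    params = RigidBodyParams(psi=psi, theta=theta, phi=phi, z=z, x=x, lam=lam)
    if return_subunit:
        return params, subunit
    return params


def _frame_rotation(a, b, a_ref, b_ref) -> np.ndarray:
    """Rotation mapping the frame spanned by (a, b) onto (a_ref, b_ref)."""

    def frame(u, v):
        u = u / np.linalg.norm(u)
        w1 = v - np.dot(v, u) * u
        w1 /= np.linalg.norm(w1)
        w2 = np.cross(u, w1)
        return np.column_stack([u, w1, w2])

    return frame(a_ref, b_ref) @ frame(a, b).T


def _conjugates_onto(
    s: np.ndarray, mats: np.ndarray, rots: np.ndarray, tol: float = 0.5
) -> bool:
    """True if s @ mats @ s.T matches the rotation set (Frobenius tol)."""
    conj = np.einsum("ij,njk,kl->nil", s, mats, s.T)
    for m in conj:
        err = np.min(np.linalg.norm(rots - m, axis=(1, 2)))
        if err > tol:
            return False
    return True
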