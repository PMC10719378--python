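"""Synthetic data generation: toy subunits, ideal cubic assemblies,
fake predictor ensembles and run tables.

Everything here is deterministic under a fixed seed and passes the
structure_io validators, so the whole pipeline is testable without any
external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import geometry as geo
from . import symmetry as sym
from .ccs import CCSConfig
from .energy import AssemblyScorer, EnergyConfig
from .structure_io import (
    Assembly,
    ChainModel,
    ManifestRecord,
    ScoreManifest,
    validate_chain,
)
from .symmetry import RigidBodyParams, SymmetryDefinition

# ideal backbone internal coordinates
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_HELIX_PHI = -57.0
_HELIX_PSI = -47.0
_OMEGA = 180.0


@dataclass(frozen=True)
class ToySpec:
    n_res: int = 16
    motif: str = "helix"  # helix | hairpin
    seed: int = 0
    noise: float = 0.0

    def __post_init__(self):
        if self.n_res < 8:
            raise ValueError("toy subunits need at least 8 residues")
        if self.motif not in ("helix", "hairpin"):
            raise ValueError(f"unknown motif {self.motif!r}")


def _build_backbone(phis, psis) -> dict[str, np.ndarray]:
    """Sequential NeRF construction of N/CA/C positions from dihedrals."""
    n_res = len(phis)
    n = [np.array([0.0, 0.0, 0.0])]
    ca = [np.array([_BOND_N_CA, 0.0, 0.0])]
    c0 = geo.place_atom(
        np.array([0.0, 1.0, 0.0]), n[0], ca[0], _BOND_CA_C, _ANGLE_N_CA_C, phis[0]
    )
    c = [c0]
    for i in range(1, n_res):
        n.append(
            geo.place_atom(n[i - 1], ca[i - 1], c[i - 1], _BOND_C_N, _ANGLE_CA_C_N, psis[i - 1])
        )
        ca.append(
            geo.place_atom(ca[i - 1], c[i - 1], n[i], _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        )
        c.append(
            geo.place_atom(c[i - 1], n[i], ca[i], _BOND_CA_C, _ANGLE_N_CA_C, phis[i])
        )
    return {"N": np.array(n), "CA": np.array(ca), "C": np.array(c)}


def _virtual_cb(n, ca, c) -> np.ndarray:
    """Idealized CB reconstruction from backbone atoms (L-chirality)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _carbonyl_o(ca, c, n_next) -> np.ndarray:
    u = (ca - c) / np.linalg.norm(ca - c)
    v = (n_next - c) / np.linalg.norm(n_next - c)
    d = -(u + v)
    return c + _BOND_C_O * d / np.linalg.norm(d)


def _assemble_chain(bb: dict[str, np.ndarray], start_res: int = 1) -> ChainModel:
    n_res = len(bb["N"])
    names, coords, res_ids = [], [], []
    for i in range(n_res):
        n, ca, c = bb["N"][i], bb["CA"][i], bb["C"][i]
        if i + 1 < n_res:
            n_next = bb["N"][i + 1]
        else:  # virtual next N continuing the last psi
            n_next = geo.place_atom(n, ca, c, _BOND_C_N, _ANGLE_CA_C_N, _HELIX_PSI)
        o = _carbonyl_o(ca, c, n_next)
        cb = _virtual_cb(n, ca, c)
        for nm, xyz in (("N", n), ("CA", ca), ("C", c), ("O", o), ("CB", cb)):
            names.append(nm)
            coords.append(xyz)
            res_ids.append(start_res + i)
    coords = np.array(coords)
    return ChainModel(
        chain_id="A",
        atom_names=np.array(names),
        coords=coords,
        res_ids=np.array(res_ids),
        res_names=np.full(len(names), "ALA"),
        bfactors=np.full(len(names), 90.0),
        occupancies=np.ones(len(names)),
    )


def make_toy_subunit(spec: ToySpec) -> ChainModel:
    """An ideal helical (or helix-hairpin) toy subunit with N/CA/C/O/CB."""
    if spec.motif == "helix":
        phis = np.full(spec.n_res, _HELIX_PHI)
        psis = np.full(spec.n_res, _HELIX_PSI)
        chain = _assemble_chain(_build_backbone(phis, psis))
    else:
        chain = _make_hairpin(spec.n_res)
    chain = replace(chain, coords=chain.coords - chain.coords.mean(axis=0))
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        chain = replace(
            chain, coords=chain.coords + rng.normal(0.0, spec.noise, chain.coords.shape)
        )
    validate_chain(chain)
    return chain


def _make_hairpin(n_res: int) -> ChainModel:
    """Two antiparallel ideal helices stitched into one numbering.

    The junction geometry is not chemically ideal — the fixture exists to
    provide long-range residue contacts (|dindex| >= 10) for connectivity
    metrics, which a single straight helix cannot.
    """
    half = n_res // 2
    phis = np.full(half, _HELIX_PHI)
    psis = np.full(half, _HELIX_PSI)
    bb1 = _build_backbone(phis, psis)
    phis2 = np.full(n_res - half, _HELIX_PHI)
    psis2 = np.full(n_res - half, _HELIX_PSI)
    bb2 = _build_backbone(phis2, psis2)

    # helix axis of an ideal helix built this way: fit principal component
    def axis_of(bb):
        ca = bb["CA"]
        cac = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(cac)
        ax = vt[0]
        if np.dot(ax, ca[-1] - ca[0]) < 0:
            ax = -ax
        return ax

    ax1 = axis_of(bb1)
    r_flip = geo.align_vectors_rotation(axis_of(bb2), -ax1)
    perp = np.cross(ax1, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(ax1, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    end1 = bb1["C"][-1]
    bb2r = {}
    for key in bb2:
        pts = (r_flip @ bb2[key].T).T
        bb2r[key] = pts
    # place helix 2 start near helix 1 end, offset sideways by ~6 A
    shift = end1 + 2.5 * ax1 + 6.0 * perp - bb2r["N"][0]
    for key in bb2r:
        bb2r[key] = bb2r[key] + shift

    c1 = _assemble_chain(bb1, start_res=1)
    c2 = _assemble_chain(bb2r, start_res=half + 1)
    return ChainModel(
        chain_id="A",
        atom_names=np.concatenate([c1.atom_names, c2.atom_names]),
        coords=np.vstack([c1.coords, c2.coords]),
        res_ids=np.concatenate([c1.res_ids, c2.res_ids]),
        res_names=np.concatenate([c1.res_names, c2.res_names]),
        bfactors=np.concatenate([c1.bfactors, c2.bfactors]),
        occupancies=np.concatenate([c1.occupancies, c2.occupancies]),
    )


# -- ideal assemblies ---------------------------------------------------------

_DEFAULT_START = RigidBodyParams(psi=25.0, theta=60.0, phi=40.0, z=60.0, x=25.0, lam=0.0)

# Standard recapitulation toy: an 18-residue hairpin subunit.  The frozen
# parameters below are the surrogate-energy optima found by the docking
# search itself (derived by scripts/tune_fixtures.py), so the synthetic
# 'native' of each kind sits at the bottom of its energy funnel.
RECAP_N_RES = 16
RECAP_NATIVES: dict[tuple[str, int], tuple] = {
    ("T", 3): (13.2888, 77.0724, -2.0591, 12.4042, 5.6576, 25.4371),  # iscore -47.4
    ("O", 4): (29.7790, 132.5368, 92.3578, 14.6954, 8.8188, 6.7429),  # iscore -63.0
    ("I", 5): (39.3348, 116.8177, 125.6167, 23.8197, 9.1936, 34.9831),  # iscore -69.6
}


class AssemblyBuildError(Exception):
    pass


def make_ideal_assembly(
    kind: str,
    fold: int,
    subunit: ChainModel,
    params: RigidBodyParams | None = None,
    optimize: bool = True,
) -> tuple[Assembly, SymmetryDefinition]:
    """Build a clash-free, contact-rich ideal assembly from a toy subunit.

    With ``params=None`` the subunit is slid in along the setup axis until
    contact and the placement is then locally minimized under the surrogate
    interface energy, so the generating parameters sit at a genuine local
    optimum — the synthetic 'native' for recapitulation and evaluation.
    """
    sd = SymmetryDefinition(kind=kind, setup_fold=fold)
    scorer = AssemblyScorer(subunit, sd)
    if params is None:
        params = _derive_native_params(scorer, optimize=optimize)
    sd.params = params
    n = scorer.n_clashes(params)
    if n > 0:
        raise AssemblyBuildError(f"ideal assembly has {n} CCS clashes")
    assembly = sym.place_and_expand(subunit, params, sd)
    sym.build_subsystem(assembly, sd)  # records subsystem indices on sd
    return assembly, sd


def _derive_native_params(scorer: AssemblyScorer, optimize: bool = True) -> RigidBodyParams:
    p = _DEFAULT_START
    # move outward until the start placement is clash-free
    for _ in range(10):
        if scorer.n_clashes(p) == 0:
            break
        p = replace(p, z=p.z * 1.5, x=p.x * 1.5)
    else:
        raise AssemblyBuildError("could not find a clash-free start placement")
    # radial slide: bring the setup-fold ring into contact, then back off
    x = p.x
    while x > 1.0:
        if scorer.n_clashes(replace(p, x=x - 0.3)) > 0:
            break
        x -= 0.3
    p = replace(p, x=x + 0.6)
    # axial slide: bring the rings onto the neighboring interfaces
    z = p.z
    while z > 1.0:
        if scorer.n_clashes(replace(p, z=z - 0.3)) > 0:
            break
        z -= 0.3
    p = replace(p, z=z + 0.6)
    if not optimize:
        return p
    # coordinate descent on the surrogate Iscore, clash-free by LJ shape
    arr = p.as_array()
    lo = np.array([-180.0, -180.0, -180.0, 1.0, 1.0, -90.0])
    hi = np.array([180.0, 180.0, 180.0, 200.0, 30.0, 90.0])
    best = scorer.iscore(RigidBodyParams.from_array(arr))
    for delta in (2.0, 0.5, 0.1):
        improved = True
        sweeps = 0
        while improved and sweeps < 6:
            improved = False
            sweeps += 1
            for i in range(6):
                for sgn in (1.0, -1.0):
                    cand = arr.copy()
                    cand[i] = np.clip(cand[i] + sgn * delta, lo[i], hi[i])
                    pc = RigidBodyParams.from_array(cand)
                    s = scorer.iscore(pc)
                    if s < best - 1e-9 and scorer.n_clashes(pc) == 0:
                        best, arr = s, cand
                        improved = True
    return RigidBodyParams.from_array(arr)


@lru_cache(maxsize=8)
def cached_toy_native(kind: str, fold: int):
    """Memoized (subunit, assembly, sd) for the standard recapitulation toy.

    Uses the frozen funnel-bottom parameters when available, falling back
    to on-the-fly derivation otherwise.
    """
    subunit = make_toy_subunit(ToySpec(n_res=RECAP_N_RES, motif="hairpin"))
    frozen = RECAP_NATIVES.get((kind, fold))
    params = RigidBodyParams.from_array(np.array(frozen)) if frozen else None
    assembly, sd = make_ideal_assembly(kind, fold, subunit, params=params)
    return subunit, assembly, sd


def make_cn_oligomer(
    subunit: ChainModel, n: int, params: RigidBodyParams
) -> Assembly:
    """A single Cn ring about the Z axis at the given placement (no z use)."""
    r, t = sym.placement_transform(params)
    placed = (r @ (subunit.coords - subunit.com()).T).T + t
    chains = []
    for k in range(n):
        g = geo.rot_z(k * 360.0 / n)
        chains.append(
            replace(subunit, chain_id="ABCDEFGH"[k], coords=(g @ placed.T).T)
        )
    return Assembly(chains)


# -- fake predictor ensembles -------------------------------------------------


def make_synthetic_ensemble(
    subunit: ChainModel,
    n_models: int,
    plddt_profile: np.ndarray,
    disorder_n_term: int = 0,
    disorder_c_term: int = 0,
    seed: int = 0,
    jitter: float = 0.05,
    plddt_noise: float = 0.5,
    ptm: float = 0.95,
    iptm: float | None = 0.92,
) -> tuple[list[ChainModel], ScoreManifest]:
    """Fake predictor output: coordinate-jittered copies with pLDDT in the
    B-factor column, scrambled disordered termini, and a score manifest."""
    plddt_profile = np.asarray(plddt_profile, float)
    nres = subunit.sequence_length
    if len(plddt_profile) != nres:
        raise ValueError("pLDDT profile length must match the subunit")
    rng = np.random.default_rng(seed)
    res_nums = subunit.residue_numbers
    models = []
    records = []
    for m in range(n_models):
        coords = subunit.coords + rng.normal(0.0, jitter, subunit.coords.shape)
        bf = np.zeros(len(coords))
        for i, num in enumerate(res_nums):
            mask = subunit.res_ids == num
            bf[mask] = np.clip(
                plddt_profile[i]
                + (rng.normal(0.0, plddt_noise) if plddt_noise > 0 else 0.0),
                0.0,
                100.0,
            )
            disordered = i < disorder_n_term or i >= nres - disorder_c_term
            if disordered:
                coords[mask] += rng.uniform(-6.0, 6.0, 3)
        model_id = f"model_{m:03d}"
        chain = replace(subunit, coords=coords, bfactors=bf)
        models.append(chain)
        records.append(
            ManifestRecord(
                model_id=model_id,
                mean_plddt=float(
                    np.mean([bf[subunit.res_ids == num].mean() for num in res_nums])
                ),
                ptm=ptm,
                iptm=iptm,
            )
        )
    return models, ScoreManifest(records)


def make_runs_table(
    n_runs: int,
    n_success: int,
    rmsd_low: float,
    rmsd_high: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-run results feeding the success-probability estimator."""
    if n_success > n_runs:
        raise ValueError("n_success cannot exceed n_runs")
    rng = np.random.default_rng(seed)
    rmsd = np.concatenate(
        [
            np.full(n_success, rmsd_low) + rng.uniform(-0.1, 0.1, n_success),
            np.full(n_runs - n_success, rmsd_high)
            + rng.uniform(-0.1, 0.1, n_runs - n_success),
        ]
    )
    energy = rng.normal(-100.0, 5.0, n_runs)
    order = rng.permutation(n_runs)
    return pd.DataFrame(
        {
            "run_id": np.arange(n_runs),
            "rmsd": np.abs(rmsd[order]),
            "energy": energy,
        }
    )
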