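"""Symmetry-aware model quality metrics.

symmetric RMSD minimizes over the n cyclic chain relabelings generated by
the setup fold; DockQ is re-implemented from its published definition
(Fnat 5 A contact cutoff, 10 A interface definition, 1.5/8.5 scalings,
class cuts 0.23/0.49/0.80); the pairwise DockQ of a cubic assembly weights
each unique fold interface by its buried-surface (dSASA) share; the
TM-score uses d0(L) = 1.24 (L-15)^(1/3) - 1.8 with an iterative subset
superposition, maximized over symmetry-consistent cyclic chain mappings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from scipy.spatial.distance import cdist

from . import geometry as geo
from . import symmetry as sym
from .structure_io import Assembly, ChainModel, to_atom_array

DOCKQ_FNAT_CUTOFF = 5.0  # A, any-heavy-atom native contact
DOCKQ_INTERFACE_CUTOFF = 10.0  # A, interface residue definition
DOCKQ_IRMS_SCALE = 1.5
DOCKQ_LRMS_SCALE = 8.5
DOCKQ_ACCEPTABLE = 0.23
DOCKQ_MEDIUM = 0.49
DOCKQ_HIGH = 0.80
TM_SUCCESS = 0.9


class EvaluationError(Exception):
    pass


@dataclass
class InterfaceEval:
    fold: int
    native_pair: tuple[int, int]
    model_pair: tuple[int, int]
    dockq: float
    delta_sasa: float


@dataclass
class EvalResult:
    tm_score: float
    pairwise_dockq: float
    rmsd: float
    quality_class: str
    interfaces: list[InterfaceEval] | None = None


# -- symmetric RMSD -----------------------------------------------------------


def _cyclic_permutations(kind: str, setup_fold: int) -> list[np.ndarray]:
    """Chain relabelings induced by powers of the setup-fold rotation."""
    rots = sym.setup_rotations(kind, setup_fold)
    n = setup_fold
    perms = []
    for k in range(n):
        gz = geo.rot_z(-k * 360.0 / n)
        perm = np.empty(len(rots), dtype=int)
        for i, ri in enumerate(rots):
            target = gz @ ri
            perm[i] = int(np.argmin(np.linalg.norm(rots - target, axis=(1, 2))))
        perms.append(perm)
    return perms


def symmetric_rmsd(
    model: Assembly,
    native: Assembly,
    kind: str,
    setup_fold: int,
    tried_angles: list | None = None,
) -> float:
    """CA RMSD after optimal superposition, minimized over the n cyclic
    symmetry-equivalent chain assignments about the setup fold.

    Chains of both assemblies must follow the package's group expansion
    ordering (the output convention of place_and_expand).
    """
    if model.n_chains != native.n_chains:
        raise EvaluationError(
            f"chain count mismatch: {model.n_chains} vs {native.n_chains}"
        )
    nat = np.vstack([c.ca_coords() for c in native.chains])
    model_cas = [c.ca_coords() for c in model.chains]
    if sum(map(len, model_cas)) != len(nat):
        raise EvaluationError("CA count mismatch between model and native")
    best = math.inf
    for k, perm in enumerate(_cyclic_permutations(kind, setup_fold)):
        if tried_angles is not None:
            tried_angles.append(k * 360.0 / setup_fold)
        mod = np.vstack([model_cas[j] for j in perm])
        best = min(best, geo.superposed_rmsd(mod, nat))
    return float(best)


# -- DockQ --------------------------------------------------------------------


def _residue_atom_lists(chain: ChainModel):
    out = []
    for num in chain.residue_numbers:
        out.append((int(num), chain.coords[chain.res_ids == num]))
    return out


def _backbone_coords(chain: ChainModel, res_subset=None) -> np.ndarray:
    keep = np.isin(chain.atom_names, ("N", "CA", "C", "O"))
    if res_subset is not None:
        keep &= np.isin(chain.res_ids, list(res_subset))
    return chain.coords[keep]


def _contact_pairs(a: ChainModel, b: ChainModel, cutoff: float):
    d = cdist(a.coords, b.coords)
    close = d < cutoff
    pairs = set()
    ra = a.res_ids
    rb = b.res_ids
    ii, jj = np.nonzero(close)
    for i, j in zip(ii, jj):
        pairs.add((int(ra[i]), int(rb[j])))
    return pairs


def dockq(
    model_pair: tuple[ChainModel, ChainModel],
    native_pair: tuple[ChainModel, ChainModel],
) -> float:
    """DockQ = mean(Fnat, 1/(1+(iRMS/1.5)^2), 1/(1+(LRMS/8.5)^2))."""
    ma, mb = model_pair
    na, nb = native_pair
    native_contacts = _contact_pairs(na, nb, DOCKQ_FNAT_CUTOFF)
    if not native_contacts:
        raise EvaluationError("native chain pair has no interface contacts")
    model_contacts = _contact_pairs(ma, mb, DOCKQ_FNAT_CUTOFF)
    fnat = len(native_contacts & model_contacts) / len(native_contacts)

    # interface residues from the native pair (10 A heavy-atom criterion)
    d = cdist(na.coords, nb.coords)
    ia = set(int(r) for r in na.res_ids[np.any(d < DOCKQ_INTERFACE_CUTOFF, axis=1)])
    ib = set(int(r) for r in nb.res_ids[np.any(d < DOCKQ_INTERFACE_CUTOFF, axis=0)])
    nat_iface = np.vstack(
        [_backbone_coords(na, ia), _backbone_coords(nb, ib)]
    )
    mod_iface = np.vstack(
        [_backbone_coords(ma, ia), _backbone_coords(mb, ib)]
    )
    if len(nat_iface) != len(mod_iface):
        raise EvaluationError("model/native residue numbering mismatch")
    irms = geo.superposed_rmsd(mod_iface, nat_iface)

    # ligand RMSD: superpose on the receptor (longer chain), measure the rest
    rec_nat, lig_nat = (na, nb) if na.sequence_length >= nb.sequence_length else (nb, na)
    rec_mod, lig_mod = (ma, mb) if na.sequence_length >= nb.sequence_length else (mb, ma)
    r, t = geo.kabsch(_backbone_coords(rec_mod), _backbone_coords(rec_nat))
    lig = (r @ _backbone_coords(lig_mod).T).T + t
    lrms = geo.rmsd(lig, _backbone_coords(lig_nat))

    return float(
        (
            fnat
            + 1.0 / (1.0 + (irms / DOCKQ_IRMS_SCALE) ** 2)
            + 1.0 / (1.0 + (lrms / DOCKQ_LRMS_SCALE) ** 2)
        )
        / 3.0
    )


# -- dSASA --------------------------------------------------------------------


def _sasa_sum(chains: list[ChainModel]) -> float:
    arr = to_atom_array(Assembly(chains))
    s = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
    return float(np.nan_to_num(s).sum())


def delta_sasa(assembly: Assembly, pair: tuple[int, int]) -> float:
    """Buried surface of a chain pair: SASA(separated) - SASA(together)."""
    a = assembly.chains[pair[0]]
    b = assembly.chains[pair[1]]
    together = _sasa_sum([a, b])
    apart = _sasa_sum([a, b.translated(np.array([500.0, 0.0, 0.0]))])
    return float(apart - together)


# -- pairwise DockQ -----------------------------------------------------------


def _fold_partner(native: Assembly, kind: str, fold: int) -> int | None:
    """Chain index forming the fold interface with chain 0: the closest
    chain related to it by a rotation of 360/fold."""
    centered = native.translated(-native.all_coords().mean(axis=0))
    x0 = centered.chains[0].ca_coords()
    c0 = x0.mean(axis=0)
    target = 360.0 / fold
    best = None
    best_dist = math.inf
    for j in range(1, centered.n_chains):
        xj = centered.chains[j].ca_coords()
        if xj.shape != x0.shape:
            continue
        m = geo.rotation_about_origin(x0, xj)
        _, angle = geo.rotation_axis_angle(m)
        if abs(angle - target) < 10.0:
            dist = float(np.linalg.norm(xj.mean(axis=0) - c0))
            if dist < best_dist:
                best, best_dist = j, dist
    return best


def _best_chain_mapping(
    model: Assembly, native: Assembly, kind: str, setup_fold: int
) -> np.ndarray:
    best_perm = None
    best_r = math.inf
    nat = np.vstack([c.ca_coords() for c in native.chains])
    for perm in _cyclic_permutations(kind, setup_fold):
        mod = np.vstack([model.chains[j].ca_coords() for j in perm])
        r = geo.superposed_rmsd(mod, nat)
        if r < best_r:
            best_r, best_perm = r, perm
    return best_perm


def pairwise_dockq(
    model: Assembly,
    native: Assembly,
    kind: str,
    setup_fold: int | None = None,
) -> tuple[float, list[InterfaceEval]]:
    """dSASA-weighted mean of per-fold interface DockQ scores.

    For every unique fold of the symmetry kind the native chain pair
    forming that interface is found, the model pair best matching it by
    RMSD (via the symmetry-consistent chain mapping) is scored with DockQ,
    and the scores are combined weighted by their native dSASA share.
    """
    setup_fold = setup_fold or sym.FOLDS[kind][0]
    mapping = _best_chain_mapping(model, native, kind, setup_fold)
    evals = []
    for fold in sym.FOLDS[kind]:
        j = _fold_partner(native, kind, fold)
        if j is None:
            warnings.warn(f"no {fold}-fold interface found in native; skipped")
            continue
        dsasa = delta_sasa(native, (0, j))
        if dsasa <= 1.0:
            warnings.warn(f"{fold}-fold interface buries no surface; skipped")
            continue
        mi, mj = int(mapping[0]), int(mapping[j])
        q = dockq(
            (model.chains[mi], model.chains[mj]),
            (native.chains[0], native.chains[j]),
        )
        evals.append(
            InterfaceEval(
                fold=fold,
                native_pair=(0, j),
                model_pair=(mi, mj),
                dockq=q,
                delta_sasa=dsasa,
            )
        )
    if not evals:
        raise EvaluationError("no scoreable fold interfaces in the native")
    total = sum(e.delta_sasa for e in evals)
    score = sum(e.dockq * e.delta_sasa / total for e in evals)
    return float(score), evals


# -- TM-score -----------------------------------------------------------------


def tm_d0(length: int) -> float:
    return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5) if length > 15 else 0.5


def tm_score_assembly(
    model: Assembly,
    native: Assembly,
    kind: str | None = None,
    setup_fold: int | None = None,
) -> float:
    """Simplified assembly TM-score with d0 on the full length, maximized
    over superposition (iterative subset refinement) and, when the symmetry
    kind is given, over the cyclic symmetry-consistent chain mappings."""
    nat = np.vstack([c.ca_coords() for c in native.chains])
    mod_cas = [c.ca_coords() for c in model.chains]
    if sum(map(len, mod_cas)) != len(nat):
        raise EvaluationError("length mismatch between model and native")
    l_total = len(nat)
    d0 = tm_d0(l_total)
    if kind is not None:
        perms = _cyclic_permutations(kind, setup_fold or sym.FOLDS[kind][0])
        perms = [p for p in perms if len(p) == len(mod_cas)]
        if not perms:
            perms = [np.arange(len(mod_cas))]
    else:
        perms = [np.arange(len(mod_cas))]
    best = 0.0
    for perm in perms:
        mod = np.vstack([mod_cas[j] for j in perm])
        subset = np.arange(l_total)
        for _ in range(20):
            r, t = geo.kabsch(mod[subset], nat[subset])
            d = np.linalg.norm((r @ mod.T).T + t - nat, axis=1)
            tm = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
            best = max(best, tm)
            new_subset = np.flatnonzero(d < max(d0 * 1.5, 3.0))
            if len(new_subset) < 3 or np.array_equal(new_subset, subset):
                break
            subset = new_subset
    return best


# -- classification -----------------------------------------------------------


def classify_quality(tm: float, pairwise_dockq_score: float) -> str:
    """Quality class from TM-score and pairwise DockQ.

    successful: DockQ >= 0.23 (acceptable) and TM >= 0.9;
    highly-accurate: DockQ >= 0.80 (high) and TM >= 0.9.
    """
    if pairwise_dockq_score >= DOCKQ_HIGH and tm >= TM_SUCCESS:
        return "highly-accurate"
    if pairwise_dockq_score >= DOCKQ_ACCEPTABLE and tm >= TM_SUCCESS:
        return "successful"
    if pairwise_dockq_score >= DOCKQ_ACCEPTABLE:
        return "acceptable"
    return "none"


def evaluate_model(
    model: Assembly, native: Assembly, kind: str, setup_fold: int
) -> EvalResult:
    tm = tm_score_assembly(model, native, kind, setup_fold)
    pdq, interfaces = pairwise_dockq(model, native, kind, setup_fold)
    rmsd = symmetric_rmsd(model, native, kind, setup_fold)
    return EvalResult(
        tm_score=tm,
        pairwise_dockq=pdq,
        rmsd=rmsd,
        quality_class=classify_quality(tm, pdq),
        interfaces=interfaces,
    )


# -- success probability estimator --------------------------------------------


def success_bootstrap(
    runs,
    num_runs_range=range(1, 101),
    reps: int = 100,
    threshold: float = 4.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Resampling estimate of success probability versus number of runs.

    ``runs`` is a table with one row per independent run carrying the RMSD
    of its final lowest-energy model (column 'rmsd') and optionally that
    model's energy (column 'energy').  For each num_runs, num_runs runs are
    drawn with replacement ``reps`` times; a draw succeeds when the RMSD of
    its lowest-energy run is below the threshold (without energies, the
    minimum RMSD of the draw is used).
    """
    import pandas as pd

    if isinstance(runs, pd.DataFrame):
        rmsd = runs["rmsd"].to_numpy(float)
        energy = runs["energy"].to_numpy(float) if "energy" in runs else None
    else:
        rmsd = np.asarray(runs, float)
        energy = None
    if len(rmsd) == 0:
        raise EvaluationError("empty runs table")
    rng = rng or np.random.default_rng()
    probabilities = {}
    for num in num_runs_range:
        hits = 0
        for _ in range(reps):
            pick = rng.integers(0, len(rmsd), size=num)
            if energy is not None:
                chosen = pick[int(np.argmin(energy[pick]))]
                ok = rmsd[chosen] < threshold
            else:
                ok = bool(np.min(rmsd[pick]) < threshold)
            hits += ok
        probabilities[int(num)] = hits / reps
    runs_needed = {}
    for level in (0.80, 0.90, 0.99):
        needed = None
        for num in sorted(probabilities):
            if probabilities[num] >= level:
                needed = num
                break
        runs_needed[int(level * 100)] = needed
    return {"probabilities": probabilities, "runs_needed": runs_needed}
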