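"""Turn raw predictor outputs into docking-ready subunit ensembles.

The pipeline mirrors the confidence-driven preparation of predicted
subunits: filter by model confidence, profile per-residue metrics over
the surviving ensemble, trim disordered termini against thresholds, and
prune structurally redundant members.  Multimer confidence combines the
interface and global fold terms as 0.8 * ipTM + 0.2 * pTM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import geometry as geo
from .structure_io import Assembly, ChainModel, ScoreManifest


class EnsembleError(Exception):
    pass


@dataclass
class EnsembleConfig:
    plddt_min: float = 90.0
    confidence_min: float = 0.9
    avg_plddt_threshold: float = 90.0
    connectivity_threshold: float = 70.0  # %
    ss_threshold: float = 70.0  # %
    contact_distance: float = 8.0  # A, CA-CA
    sequence_separation: int = 10
    redundancy_rmsd: float = 0.1  # A
    redundancy_step: float = 0.005  # A
    redundancy_max_steps: int = 18
    min_ensemble: int = 50


@dataclass
class ResidueMetrics:
    avg_plddt: np.ndarray
    connectivity_pct: np.ndarray
    ss_pct: np.ndarray


def model_confidence(ptm: float, iptm: float) -> float:
    """Multimer model confidence: 0.8 * ipTM + 0.2 * pTM."""
    if not 0.0 <= ptm <= 1.0 or not 0.0 <= iptm <= 1.0:
        raise EnsembleError(f"ptm/iptm out of [0, 1]: ptm={ptm}, iptm={iptm}")
    return 0.8 * iptm + 0.2 * ptm


def filter_by_confidence(
    models: dict[str, ChainModel],
    manifest: ScoreManifest,
    cfg: EnsembleConfig | None = None,
    multimer: bool = True,
) -> dict[str, ChainModel]:
    """Keep models meeting the pLDDT floor and, for multimer predictions,
    the combined ipTM+pTM confidence floor."""
    cfg = cfg or EnsembleConfig()
    kept = {}
    for model_id, chain in models.items():
        try:
            rec = manifest.get(model_id)
        except KeyError as exc:
            raise EnsembleError(str(exc)) from exc
        ok = rec.mean_plddt >= cfg.plddt_min
        if multimer:
            if rec.iptm is None:
                raise EnsembleError(f"model {model_id}: multimer record lacks iptm")
            ok = ok and model_confidence(rec.ptm, rec.iptm) >= cfg.confidence_min
        if ok:
            kept[model_id] = chain
    if not kept:
        warnings.warn("confidence filtering removed every model")
    return kept


# -- secondary structure (internal assigner) ----------------------------------


def assign_secondary_structure(chain: ChainModel) -> np.ndarray:
    """Helix/strand/coil labels from backbone dihedral windows.

    helix: phi in [-100, -30] and psi in [-80, -5];
    strand: phi in [-180, -80] and psi in [80, 180] or [-180, -170].
    Terminal residues inherit their neighbor's label and a 3-residue
    majority smoothing is applied.
    """
    res_nums = chain.residue_numbers
    nres = len(res_nums)
    by_res = {}
    for num in res_nums:
        mask = chain.res_ids == num
        names = chain.atom_names[mask]
        coords = chain.coords[mask]
        by_res[int(num)] = {n: c for n, c in zip(names, coords)}
    raw = np.array(["C"] * nres, dtype="U1")
    for i, num in enumerate(res_nums):
        prev_c = by_res.get(int(num) - 1, {}).get("C")
        next_n = by_res.get(int(num) + 1, {}).get("N")
        res = by_res[int(num)]
        if prev_c is None or next_n is None:
            continue
        phi = geo.dihedral(prev_c, res["N"], res["CA"], res["C"])
        psi = geo.dihedral(res["N"], res["CA"], res["C"], next_n)
        if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            raw[i] = "H"
        elif -180.0 <= phi <= -80.0 and (80.0 <= psi <= 180.0 or psi <= -170.0):
            raw[i] = "E"
    # termini inherit the nearest assigned neighbor
    if nres >= 2:
        raw[0] = raw[1]
        raw[-1] = raw[-2]
    smoothed = raw.copy()
    for i in range(1, nres - 1):
        window = [raw[i - 1], raw[i], raw[i + 1]]
        for label in ("H", "E", "C"):
            if window.count(label) >= 2:
                smoothed[i] = label
                break
    return smoothed


def residue_metric_profiles(
    ensemble: list[ChainModel], cfg: EnsembleConfig | None = None
) -> ResidueMetrics:
    """Per-residue averages across an equal-length ensemble: mean pLDDT
    (B-factor), % of models with a long-range CA contact, and % assigned
    helix or strand."""
    cfg = cfg or EnsembleConfig()
    if not ensemble:
        raise EnsembleError("empty ensemble")
    nres = ensemble[0].sequence_length
    for chain in ensemble:
        if chain.sequence_length != nres:
            raise EnsembleError("ensemble models differ in length")
    plddt = np.zeros(nres)
    connected = np.zeros(nres)
    ss = np.zeros(nres)
    for chain in ensemble:
        plddt += chain.per_residue_bfactor()
        ca = chain.ca_coords()
        d = cdist(ca, ca)
        idx = np.arange(nres)
        far = np.abs(idx[:, None] - idx[None, :]) >= cfg.sequence_separation
        connected += np.any((d <= cfg.contact_distance) & far, axis=1)
        labels = assign_secondary_structure(chain)
        ss += (labels == "H") | (labels == "E")
    m = len(ensemble)
    return ResidueMetrics(
        avg_plddt=plddt / m,
        connectivity_pct=100.0 * connected / m,
        ss_pct=100.0 * ss / m,
    )


# -- trimming -----------------------------------------------------------------


def _first_pass_index(values: np.ndarray, threshold: float) -> int:
    """First index (scanning forward) meeting the threshold."""
    hits = np.flatnonzero(values >= threshold)
    if len(hits) == 0:
        raise EnsembleError("metric never reaches its threshold")
    return int(hits[0])


def trim_cut_positions(
    metrics: ResidueMetrics, cfg: EnsembleConfig | None = None
) -> tuple[int, int]:
    """(n_cut, c_cut): residues to drop from each end.

    Scanning inward from each terminus, each metric has a first residue
    meeting its threshold; everything before the innermost ("the last
    threshold to be crossed") is removed.
    """
    cfg = cfg or EnsembleConfig()
    triples = (
        (metrics.avg_plddt, cfg.avg_plddt_threshold),
        (metrics.connectivity_pct, cfg.connectivity_threshold),
        (metrics.ss_pct, cfg.ss_threshold),
    )
    n_cut = max(_first_pass_index(v, t) for v, t in triples)
    c_cut = max(_first_pass_index(v[::-1], t) for v, t in triples)
    return n_cut, c_cut


def trim_termini(
    ensemble: list[ChainModel],
    metrics: ResidueMetrics,
    cfg: EnsembleConfig | None = None,
) -> list[ChainModel]:
    """Apply the identical terminal cut to every model."""
    cfg = cfg or EnsembleConfig()
    n_cut, c_cut = trim_cut_positions(metrics, cfg)
    nres = ensemble[0].sequence_length
    if n_cut + c_cut >= nres:
        raise EnsembleError("trimming would remove every residue")
    out = []
    for chain in ensemble:
        nums = chain.residue_numbers
        keep_nums = set(int(n) for n in nums[n_cut : nres - c_cut])
        mask = np.isin(chain.res_ids, list(keep_nums))
        out.append(
            replace(
                chain,
                atom_names=chain.atom_names[mask],
                coords=chain.coords[mask],
                res_ids=chain.res_ids[mask],
                res_names=chain.res_names[mask],
                bfactors=chain.bfactors[mask],
                occupancies=chain.occupancies[mask],
                elements=chain.elements[mask],
            )
        )
    return out


# -- redundancy pruning -------------------------------------------------------


def prune_redundant(
    ensemble: list[ChainModel],
    scores: list[float],
    cfg: EnsembleConfig | None = None,
) -> list[int]:
    """Indices of surviving models after greedy pairwise-RMSD pruning.

    Pairs closer than the threshold lose their worse-scored member
    (processed in ascending RMSD order).  If fewer than min_ensemble
    survive, pruning restarts with the threshold lowered stepwise.
    """
    cfg = cfg or EnsembleConfig()
    n = len(ensemble)
    if n != len(scores):
        raise EnsembleError("scores length must match the ensemble")
    if n <= 1:
        return list(range(n))
    cas = [c.ca_coords() for c in ensemble]
    pair_rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair_rmsd[i, j] = pair_rmsd[j, i] = geo.superposed_rmsd(cas[i], cas[j])
    order = sorted(
        ((pair_rmsd[i, j], i, j) for i in range(n) for j in range(i + 1, n))
    )
    threshold = cfg.redundancy_rmsd
    for _ in range(cfg.redundancy_max_steps + 1):
        alive = np.ones(n, dtype=bool)
        for r, i, j in order:
            if r >= threshold:
                break
            if alive[i] and alive[j]:
                alive[j if scores[i] >= scores[j] else i] = False
        if alive.sum() >= min(cfg.min_ensemble, n):
            break
        threshold = max(threshold - cfg.redundancy_step, 0.0)
    return [int(i) for i in np.flatnonzero(alive)]


# -- oligomer parameter extraction --------------------------------------------


@dataclass
class OligomerParams:
    psi: float
    theta: float
    phi: float
    x: float
    subunit: ChainModel
    axis_angle: float  # measured inter-chain rotation, degrees


def extract_oligomer_params(
    oligomer: Assembly,
    kind: str,
    fold: int,
    subunit: ChainModel | None = None,
    angle_tolerance: float = 10.0,
) -> OligomerParams:
    """Starting (psi, theta, phi, x) estimates from a Cn oligomer prediction.

    The inter-chain rotation gives the oligomer symmetry axis, which is
    aligned onto the global setup-fold (+Z) axis; the first chain's radial
    offset gives x and its residual orientation relative to the reference
    subunit gives the Euler angles.  z and lambda stay free.
    """
    if oligomer.n_chains < 2:
        raise EnsembleError("oligomer needs at least two chains")
    if oligomer.n_chains != fold:
        raise EnsembleError(
            f"expected a C{fold} oligomer, got {oligomer.n_chains} chains"
        )
    x0 = oligomer.chains[0].ca_coords()
    x1 = oligomer.chains[1].ca_coords()
    if x0.shape != x1.shape:
        raise EnsembleError("oligomer chains differ in length")
    r, t = geo.kabsch(x0, x1)
    axis, angle = geo.rotation_axis_angle(r)
    target = 360.0 / fold
    if abs(angle - target) > angle_tolerance:
        raise EnsembleError(
            f"chains related by {angle:.1f} deg, expected {target:.1f} "
            f"+- {angle_tolerance} deg"
        )
    # axis support point: minimal-norm solution of (I - R) p = t
    p = np.linalg.lstsq(np.eye(3) - r, t, rcond=None)[0]
    p -= axis * np.dot(axis, p)  # keep only the component off the axis line

    s = geo.align_vectors_rotation(axis, np.array([0.0, 0.0, 1.0]))
    c0 = s @ (oligomer.chains[0].com() - p)
    x_est = float(math.hypot(c0[0], c0[1]))
    az = math.degrees(math.atan2(c0[1], c0[0])) if x_est > 1e-9 else 0.0
    s = geo.rot_z(-az) @ s

    chain0 = oligomer.chains[0].translated(-p).transformed(s)
    com0 = chain0.com()
    if subunit is not None:
        q = geo.rotation_about_origin(
            subunit.coords - subunit.com(), chain0.coords - com0
        )
        psi, theta, phi = geo.matrix_to_euler(q)
        ref = subunit
    else:
        psi = theta = phi = 0.0
        ref = chain0.translated(-com0)
    return OligomerParams(
        psi=psi, theta=theta, phi=phi, x=x_est, subunit=ref, axis_angle=float(angle)
    )
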