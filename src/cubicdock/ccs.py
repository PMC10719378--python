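"""CloudContactScore: fast backbone point-cloud contact scoring.

A subunit is reduced to its surface backbone atoms (N, C, O, CA) plus CB,
each carrying a radius and, for CB, a connection density.  Interchain
interactions are scored with four terms: a clash count, short- and
long-range backbone hydrogen-bond surrogates, and a density-weighted CB-CB
contact count.  Lower totals are better.

Clash criterion: two atoms clash when their spheres overlap by more than
the overlap fraction, i.e. d < (1 - 0.20) * (r_i + r_j); nitrogen-oxygen
pairs may hydrogen bond and instead use a reduced 1.2 A clash distance;
CB radii are reduced to 1.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.spatial.distance import cdist

from .structure_io import ChainModel, to_atom_array

# Lennard-Jones-like radii (A).  CB is overridden per the clash rules.
ATOM_RADII = {"N": 1.75, "C": 2.0, "CA": 2.0, "O": 1.55, "CB": 1.5}

KIND_INDEX = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}


class CCSError(Exception):
    pass


@dataclass
class CCSConfig:
    sasa_surface_threshold: float = 20.0  # A^2, per residue
    sasa_point_number: int = 960
    sasa_probe_radius: float = 1.4
    overlap_fraction: float = 0.20
    n_o_clash_distance: float = 1.2
    cb_radius: float = 1.5
    cb_contact_cutoff: float = 12.0
    density_neighbor_cutoff: float = 12.0
    density_denominator: float = 20.0
    clash_penalty: float = 1000.0
    # cone burial classifier (surrogate for a sidechain-neighbor count)
    cone_half_angle: float = 60.0  # degrees
    cone_length: float = 10.0  # A
    cone_burial_count: int = 12
    # term weights: clash, hbond_sr, hbond_lr, cb contacts
    w_clash: float = 1.0
    w_hb: float = 1.0
    w_cb: float = -1.0
    # hydrogen-bond surrogate window (N...O distance, A)
    hb_dmin: float = 1.9
    hb_don: float = 2.2
    hb_doff: float = 2.9
    hb_dmax: float = 3.2
    hb_sr_sep: int = 5


@dataclass
class CCSBreakdown:
    n_clashes: int = 0
    hbond_sr_bb: float = 0.0
    hbond_lr_bb: float = 0.0
    n_cb_cb_interactions: float = 0.0
    total: float = 0.0


@dataclass
class PointCloud:
    """Surface backbone/CB points of one subunit, in its own frame."""

    coords: np.ndarray  # (n, 3)
    kinds: np.ndarray  # (n,) int, KIND_INDEX codes
    radii: np.ndarray  # (n,)
    res_index: np.ndarray  # (n,) residue ordinal
    densities: np.ndarray  # (n,), 0 for non-CB points
    o_cdir: np.ndarray  # (n, 3) unit C->O direction for O points, 0 otherwise
    n_points: int = field(init=False)

    def __post_init__(self):
        self.n_points = len(self.coords)

    def transformed(self, r: np.ndarray, t: np.ndarray | None = None) -> "PointCloud":
        t = np.zeros(3) if t is None else np.asarray(t, float)
        return PointCloud(
            coords=(r @ self.coords.T).T + t,
            kinds=self.kinds,
            radii=self.radii,
            res_index=self.res_index,
            densities=self.densities,
            o_cdir=(r @ self.o_cdir.T).T,
        )


def connection_density(n_internal_neighbors: int, cfg: CCSConfig | None = None) -> float:
    """min(neighbors / 20, 1.0)."""
    cfg = cfg or CCSConfig()
    if n_internal_neighbors < 0:
        raise ValueError("neighbor count must be >= 0")
    return min(n_internal_neighbors / cfg.density_denominator, 1.0)


def _per_residue_sasa(chain: ChainModel, cfg: CCSConfig) -> np.ndarray:
    arr = to_atom_array(chain)
    atom_sasa = struc.sasa(
        arr,
        probe_radius=cfg.sasa_probe_radius,
        point_number=cfg.sasa_point_number,
        vdw_radii="Single",
    )
    atom_sasa = np.nan_to_num(atom_sasa)
    return np.array(
        [atom_sasa[chain.res_ids == num].sum() for num in chain.residue_numbers]
    )


def _atom_sasa(chain: ChainModel, cfg: CCSConfig) -> np.ndarray:
    arr = to_atom_array(chain)
    s = struc.sasa(
        arr,
        probe_radius=cfg.sasa_probe_radius,
        point_number=cfg.sasa_point_number,
        vdw_radii="Single",
    )
    return np.nan_to_num(s)


def _cone_surface_mask(chain: ChainModel, cfg: CCSConfig) -> np.ndarray:
    """Residues classified as surface by the CA->CB neighbor-cone count."""
    ca = chain.ca_coords()
    cb = chain.cb_or_ca_coords()
    nres = len(ca)
    vec = cb - ca
    norms = np.linalg.norm(vec, axis=1)
    # glycine (CB == CA) gets an outward pseudo-vector away from the COM
    degenerate = norms < 1e-6
    if degenerate.any():
        out = ca - chain.com()
        vec[degenerate] = out[degenerate]
        norms = np.linalg.norm(vec, axis=1)
    vec = vec / norms[:, None]
    cos_half = np.cos(np.radians(cfg.cone_half_angle))
    counts = np.zeros(nres, dtype=int)
    for i in range(nres):
        rel = cb - ca[i]
        d = np.linalg.norm(rel, axis=1)
        mask = (d > 1e-6) & (d <= cfg.cone_length)
        mask[i] = False
        proj = rel[mask] @ vec[i] / d[mask]
        counts[i] = int(np.sum(proj >= cos_half))
    return counts < cfg.cone_burial_count


def build_point_cloud(subunit: ChainModel, cfg: CCSConfig | None = None) -> PointCloud:
    """Reduce a subunit to its surface backbone/CB point cloud.

    Surface residues (per-residue SASA above threshold OR the cone burial
    classifier) are reduced to alanine, atoms buried to zero SASA in the
    reduced model are dropped, and per-CB connection densities computed.
    """
    cfg = cfg or CCSConfig()
    if len(subunit.coords) == 0:
        raise CCSError("empty chain")
    res_nums = subunit.residue_numbers
    res_sasa = _per_residue_sasa(subunit, cfg)
    surface = (res_sasa > cfg.sasa_surface_threshold) | _cone_surface_mask(
        subunit, cfg
    )
    surface_nums = set(res_nums[surface].tolist())

    # reduced (alanine-level) atom selection
    keep = np.array(
        [
            name in KIND_INDEX and num in surface_nums
            for name, num in zip(subunit.atom_names, subunit.res_ids)
        ]
    )
    from dataclasses import replace

    reduced = replace(
        subunit,
        atom_names=subunit.atom_names[keep],
        coords=subunit.coords[keep],
        res_ids=subunit.res_ids[keep],
        res_names=subunit.res_names[keep],
        bfactors=subunit.bfactors[keep],
        occupancies=subunit.occupancies[keep],
        elements=subunit.elements[keep],
    )
    atom_sasa = _atom_sasa(reduced, cfg)
    exposed = atom_sasa > 0.0

    names = reduced.atom_names[exposed]
    coords = reduced.coords[exposed]
    res_ids = reduced.res_ids[exposed]
    kinds = np.array([KIND_INDEX[n] for n in names], dtype=int)
    radii = np.array([ATOM_RADII[n] for n in names])
    num_to_ordinal = {int(n): i for i, n in enumerate(res_nums)}
    res_index = np.array([num_to_ordinal[int(r)] for r in res_ids], dtype=int)

    # connection density from ALL intra-subunit CBs (the internal structure)
    all_cb = subunit.cb_or_ca_coords()
    cb_mask = kinds == KIND_INDEX["CB"]
    densities = np.zeros(len(coords))
    if cb_mask.any():
        d = cdist(coords[cb_mask], all_cb)
        neigh = np.sum(
            (d <= cfg.density_neighbor_cutoff) & (d > 1e-6), axis=1
        )
        densities[cb_mask] = np.minimum(neigh / cfg.density_denominator, 1.0)

    # carbonyl direction for O points (needs the C of the same residue)
    o_cdir = np.zeros_like(coords)
    o_mask = kinds == KIND_INDEX["O"]
    c_by_res = {}
    for name, num, xyz in zip(subunit.atom_names, subunit.res_ids, subunit.coords):
        if name == "C":
            c_by_res[int(num)] = xyz
    for i in np.flatnonzero(o_mask):
        c = c_by_res.get(int(res_ids[i]))
        if c is not None:
            v = coords[i] - c
            o_cdir[i] = v / np.linalg.norm(v)

    return PointCloud(
        coords=coords,
        kinds=kinds,
        radii=radii,
        res_index=res_index,
        densities=densities,
        o_cdir=o_cdir,
    )


# -- pairwise terms -----------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _pair_terms(cloud_a: PointCloud, cloud_b: PointCloud, cfg: CCSConfig):
    """Clash count, (hb_sr, hb_lr) and weighted CB contacts between two
    placed point clouds (counted once per atom pair)."""
    d = cdist(cloud_a.coords, cloud_b.coords)

    ka = cloud_a.kinds[:, None]
    kb = cloud_b.kinds[None, :]
    thresh = (1.0 - cfg.overlap_fraction) * (
        cloud_a.radii[:, None] + cloud_b.radii[None, :]
    )
    n_i, o_i = KIND_INDEX["N"], KIND_INDEX["O"]
    no_pair = ((ka == n_i) & (kb == o_i)) | ((ka == o_i) & (kb == n_i))
    thresh = np.where(no_pair, cfg.n_o_clash_distance, thresh)
    n_clashes = int(np.sum(d < thresh))

    hb_sr, hb_lr = _hbond_terms(cloud_a, cloud_b, d, cfg)

    cb_a = ka[:, 0] == KIND_INDEX["CB"]
    cb_b = kb[0, :] == KIND_INDEX["CB"]
    contacts = 0.0
    if cb_a.any() and cb_b.any():
        sub = d[np.ix_(cb_a, cb_b)]
        w = (
            cloud_a.densities[cb_a][:, None]
            * cloud_b.densities[cb_b][None, :]
        )
        contacts = float(np.sum(w[sub <= cfg.cb_contact_cutoff]))
    return n_clashes, hb_sr, hb_lr, contacts


def hbond_pairs_energy(
    don_coords: np.ndarray,
    don_res: np.ndarray,
    acc_coords: np.ndarray,
    acc_cdir: np.ndarray,
    acc_res: np.ndarray,
    cfg: CCSConfig,
    d: np.ndarray | None = None,
) -> tuple[float, float]:
    """Vectorized surrogate H-bond energy between donor N and acceptor O
    point sets; returns (short-range, long-range) sums (negative favourable).

    The energy is a smooth distance window on the N...O separation times a
    squared-cosine angular attenuation about the carbonyl C->O direction.
    """
    if len(don_coords) == 0 or len(acc_coords) == 0:
        return 0.0, 0.0
    if d is None:
        d = cdist(don_coords, acc_coords)
    ii, jj = np.nonzero((d > cfg.hb_dmin) & (d < cfg.hb_dmax))
    if len(ii) == 0:
        return 0.0, 0.0
    dd = d[ii, jj]
    w = _smoothstep((dd - cfg.hb_dmin) / (cfg.hb_don - cfg.hb_dmin)) * (
        1.0 - _smoothstep((dd - cfg.hb_doff) / (cfg.hb_dmax - cfg.hb_doff))
    )
    u = don_coords[ii] - acc_coords[jj]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a = np.sum(u * acc_cdir[jj], axis=1)
    e = -w * ((a + 1.0) / 2.0) ** 2
    srmask = np.abs(don_res[ii] - acc_res[jj]) < cfg.hb_sr_sep
    return float(e[srmask].sum()), float(e[~srmask].sum())


def _hbond_terms(cloud_a, cloud_b, d, cfg: CCSConfig):
    n_i, o_i = KIND_INDEX["N"], KIND_INDEX["O"]
    sr = lr = 0.0
    for don, acc, dm in ((cloud_a, cloud_b, d), (cloud_b, cloud_a, d.T)):
        dons = np.flatnonzero(don.kinds == n_i)
        accs = np.flatnonzero(acc.kinds == o_i)
        s, l = hbond_pairs_energy(
            don.coords[dons],
            don.res_index[dons],
            acc.coords[accs],
            acc.o_cdir[accs],
            acc.res_index[accs],
            cfg,
            d=dm[np.ix_(dons, accs)] if len(dons) and len(accs) else None,
        )
        sr += s
        lr += l
    return sr, lr


def _as_transforms(partner_transforms):
    out = []
    for tr in partner_transforms:
        if isinstance(tr, tuple):
            r, t = tr
        else:
            r, t = tr, np.zeros(3)
        out.append((np.asarray(r, float), np.asarray(t, float)))
    return out


def count_clashes(
    cloud: PointCloud, partner_transforms, cfg: CCSConfig | None = None
) -> int:
    """Interchain clashes between the cloud and each transformed copy."""
    cfg = cfg or CCSConfig()
    total = 0
    for r, t in _as_transforms(partner_transforms):
        total += _pair_terms(cloud, cloud.transformed(r, t), cfg)[0]
    return total


def hbond_bb(
    cloud: PointCloud, partner_transforms, cfg: CCSConfig | None = None
) -> tuple[float, float]:
    """Surrogate backbone H-bond energies, (short-range, long-range)."""
    cfg = cfg or CCSConfig()
    sr = lr = 0.0
    for r, t in _as_transforms(partner_transforms):
        partner = cloud.transformed(r, t)
        d = cdist(cloud.coords, partner.coords)
        s, l = _hbond_terms(cloud, partner, d, cfg)
        sr += s
        lr += l
    return sr, lr


def ccs_score(
    cloud: PointCloud, partner_transforms, cfg: CCSConfig | None = None
) -> CCSBreakdown:
    """Total CCS score: clash penalty + H-bond terms - weighted CB contacts."""
    cfg = cfg or CCSConfig()
    bd = CCSBreakdown()
    for r, t in _as_transforms(partner_transforms):
        n, sr, lr, cb = _pair_terms(cloud, cloud.transformed(r, t), cfg)
        bd.n_clashes += n
        bd.hbond_sr_bb += sr
        bd.hbond_lr_bb += lr
        bd.n_cb_cb_interactions += cb
    bd.total = (
        cfg.w_clash * bd.n_clashes * cfg.clash_penalty
        + cfg.w_hb * (bd.hbond_sr_bb + bd.hbond_lr_bb)
        + cfg.w_cb * bd.n_cb_cb_interactions
    )
    return bd
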