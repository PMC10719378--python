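"""Surrogate interface energy (Iscore) for symmetric assemblies.

Stands in for an all-atom force field: a soft, truncated-and-shifted
Lennard-Jones term over all subunit atoms plus the surrogate backbone
H-bond term and a density-weighted CB-CB contact reward.  Only interchain
interactions of the main subunit are counted — intra-subunit energy is
excluded by construction so that selection is driven by interfaces.

The absolute scale is arbitrary; only relative ordering matters to the
docking engine, which is why the improvement threshold that triggers a
second minimization pass is configurable (default 15 surrogate units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import ccs as ccs_mod
from . import geometry as geo
from . import symmetry as sym
from .ccs import ATOM_RADII, CCSConfig, CCSBreakdown, KIND_INDEX
from .structure_io import ChainModel
from .symmetry import RigidBodyParams, SymmetryDefinition


@dataclass
class EnergyConfig:
    lj_epsilon: float = 0.2
    lj_repulsion_scale: float = 4.0  # steepens the clash wall (fa_rep-like)
    lj_cap: float = 100.0  # per-pair repulsion cap
    cutoff: float = 12.0
    hb_weight: float = 1.0
    contact_weight: float = 0.5
    contact_on: float = 6.0  # full contact reward below this CB-CB distance
    improvement_threshold: float = 15.0  # triggers the second pack-min pass


@dataclass
class ScoredModel:
    params: RigidBodyParams
    backbone_id: int
    iscore: float
    ccs: CCSBreakdown | None = None
    whole_energy: float = 0.0


class AssemblyScorer:
    """Fast evaluator of Iscore and CCS terms for one subunit backbone.

    Precomputes subunit-frame arrays once; each evaluation places the main
    subunit by the six parameters and scores it against the symmetry copies
    generated by a fixed subset of group rotations (the subsystem).  With
    bounded parameters the subsystem carries every interaction of the main
    subunit, so restricting to it is exact (oracle-tested).
    """

    def __init__(
        self,
        subunit: ChainModel,
        sd: SymmetryDefinition,
        ccs_cfg: CCSConfig | None = None,
        cfg: EnergyConfig | None = None,
        subsystem_indices: list[int] | None = None,
    ):
        self.sd = sd
        self.ccs_cfg = ccs_cfg or CCSConfig()
        self.cfg = cfg or EnergyConfig()
        self.subunit = subunit
        com = subunit.com()
        keep = np.array([n in KIND_INDEX for n in subunit.atom_names])
        self._coords = subunit.coords[keep] - com
        names = subunit.atom_names[keep]
        self._kinds = np.array([KIND_INDEX[n] for n in names], dtype=int)
        self._radii = np.array([ATOM_RADII[n] for n in names])
        res_nums = subunit.residue_numbers
        ordinal = {int(n): i for i, n in enumerate(res_nums)}
        self._res = np.array(
            [ordinal[int(r)] for r in subunit.res_ids[keep]], dtype=int
        )
        res_names_per_atom = subunit.res_names[keep]
        # drop CB pseudo-handling: glycines simply have no CB atom
        self._cb_mask = self._kinds == KIND_INDEX["CB"]
        self._n_mask = self._kinds == KIND_INDEX["N"]
        self._o_mask = self._kinds == KIND_INDEX["O"]
        del res_names_per_atom

        cloud = ccs_mod.build_point_cloud(subunit, self.ccs_cfg)
        self._cloud = cloud.transformed(np.eye(3), -com)

        # per-CB connection density for the contact reward (full atom set)
        cbs = self._coords[self._cb_mask]
        dens = np.zeros(len(cbs))
        if len(cbs):
            d = cdist(cbs, cbs)
            neigh = np.sum(
                (d <= self.ccs_cfg.density_neighbor_cutoff) & (d > 1e-6), axis=1
            )
            dens = np.minimum(neigh / self.ccs_cfg.density_denominator, 1.0)
        self._cb_density = dens

        # carbonyl directions for all O atoms
        cdirs = np.zeros_like(self._coords)
        c_pos = {int(r): c for r, c in zip(self._res[self._kinds == KIND_INDEX["C"]],
                                           self._coords[self._kinds == KIND_INDEX["C"]])}
        for i in np.flatnonzero(self._o_mask):
            c = c_pos.get(int(self._res[i]))
            if c is not None:
                v = self._coords[i] - c
                cdirs[i] = v / np.linalg.norm(v)
        self._o_cdir = cdirs

        self.rotations = sym.setup_rotations(sd.kind, sd.setup_fold)
        self.set_subsystem(subsystem_indices)

    # -- configuration --------------------------------------------------------

    def set_subsystem(self, indices: list[int] | None) -> None:
        """Fix the group-element subset used as interaction partners.

        ``None`` means every non-identity element (always exact, slower).
        Precomputes the tiled pairwise constants used by every evaluation.
        """
        if indices is None:
            idx = list(range(1, len(self.rotations)))
        else:
            idx = [i for i in indices if i != 0]
        self._partner_rots = self.rotations[idx]
        self.subsystem_indices = [0] + idx
        k = len(idx)
        n = len(self._coords)
        # (3, 3K) stack of transposed rotations: partners = main @ stack
        self._gT = (
            np.concatenate([g.T for g in self._partner_rots], axis=1)
            if k
            else np.zeros((3, 0))
        )
        radii_t = np.tile(self._radii, k)
        self._radsum = self._radii[:, None] + radii_t[None, :]
        self._sigma6 = (self._radsum / (2.0 ** (1.0 / 6.0))) ** 6
        sc6 = self._sigma6 / (self.cfg.cutoff ** 6)
        self._lj_shift = (
            4.0
            * self.cfg.lj_epsilon
            * (self.cfg.lj_repulsion_scale * sc6 * sc6 - sc6)
        )
        self._res_t = np.tile(self._res, k)
        self._n_rows = np.flatnonzero(self._n_mask)
        self._o_rows = np.flatnonzero(self._o_mask)
        self._n_cols = np.flatnonzero(np.tile(self._n_mask, k))
        self._o_cols = np.flatnonzero(np.tile(self._o_mask, k))
        self._cb_rows = np.flatnonzero(self._cb_mask)
        self._cb_cols = np.flatnonzero(np.tile(self._cb_mask, k))
        dens_t = np.tile(self._cb_density, k)
        self._w_cb = self._cb_density[:, None] * dens_t[None, :]
        # cloud clash thresholds (overlap rule with the N-O override)
        cl = self._cloud
        m = cl.n_points
        cl_rad_t = np.tile(cl.radii, k)
        thresh = (1.0 - self.ccs_cfg.overlap_fraction) * (
            cl.radii[:, None] + cl_rad_t[None, :]
        )
        n_i, o_i = KIND_INDEX["N"], KIND_INDEX["O"]
        ka = cl.kinds[:, None]
        kb = np.tile(cl.kinds, k)[None, :]
        no_pair = ((ka == n_i) & (kb == o_i)) | ((ka == o_i) & (kb == n_i))
        self._cl_thresh = np.where(no_pair, self.ccs_cfg.n_o_clash_distance, thresh)
        self._cl_res_t = np.tile(cl.res_index, k)
        self._cl_n_rows = np.flatnonzero(cl.kinds == n_i)
        self._cl_o_rows = np.flatnonzero(cl.kinds == o_i)
        self._cl_n_cols = np.flatnonzero(np.tile(cl.kinds == n_i, k))
        self._cl_o_cols = np.flatnonzero(np.tile(cl.kinds == o_i, k))
        cl_dens_t = np.tile(cl.densities, k)
        self._cl_w_cb = (
            cl.densities[cl.kinds == KIND_INDEX["CB"]][:, None]
            * cl_dens_t[np.tile(cl.kinds == KIND_INDEX["CB"], k)][None, :]
        )
        self._cl_cb_rows = np.flatnonzero(cl.kinds == KIND_INDEX["CB"])
        self._cl_cb_cols = np.flatnonzero(np.tile(cl.kinds == KIND_INDEX["CB"], k))

    def subsystem_from_params(self, params: RigidBodyParams, margin: float = 2.0):
        idx = sym.subsystem_rotation_indices(
            self.subunit,
            params,
            self.sd,
            cutoff=max(self.cfg.cutoff, self.ccs_cfg.cb_contact_cutoff),
            margin=margin,
        )
        self.set_subsystem(idx)
        return idx

    # -- placement ------------------------------------------------------------

    def _copies(self, placed: np.ndarray) -> np.ndarray:
        """Group copies of already-placed points, k-major flat (K*n, 3)."""
        k = len(self._partner_rots)
        n = len(placed)
        if k == 0:
            return np.zeros((0, 3))
        p = placed @ self._gT  # (n, 3K)
        return np.ascontiguousarray(
            p.reshape(n, k, 3).transpose(1, 0, 2).reshape(k * n, 3)
        )

    def _place(self, coords: np.ndarray, params: RigidBodyParams, flipped: bool):
        r, t = sym.placement_transform(params, flipped=flipped)
        main = coords @ r.T + t
        return main, self._copies(main), r

    def com(self, params: RigidBodyParams, flipped: bool = False) -> np.ndarray:
        _, t = sym.placement_transform(params, flipped=flipped)
        return t  # subunit frame is COM-centered

    # -- CCS ------------------------------------------------------------------

    def ccs_breakdown(
        self, params: RigidBodyParams, flipped: bool = False
    ) -> CCSBreakdown:
        cl = self._cloud
        main, partners, r = self._place(cl.coords, params, flipped)
        bd = CCSBreakdown()
        if len(partners) == 0:
            return bd
        d = cdist(main, partners)
        bd.n_clashes = int(np.count_nonzero(d < self._cl_thresh))
        cdir = cl.o_cdir @ r.T
        part_cdir = np.einsum(
            "kij,nj->kni", self._partner_rots, cdir
        ).reshape(len(partners), 3)
        sr1, lr1 = ccs_mod.hbond_pairs_energy(
            main[self._cl_n_rows], cl.res_index[self._cl_n_rows],
            partners[self._cl_o_cols], part_cdir[self._cl_o_cols],
            self._cl_res_t[self._cl_o_cols],
            self.ccs_cfg, d=d[np.ix_(self._cl_n_rows, self._cl_o_cols)],
        )
        sr2, lr2 = ccs_mod.hbond_pairs_energy(
            partners[self._cl_n_cols], self._cl_res_t[self._cl_n_cols],
            main[self._cl_o_rows], cdir[self._cl_o_rows],
            cl.res_index[self._cl_o_rows],
            self.ccs_cfg, d=d[np.ix_(self._cl_o_rows, self._cl_n_cols)].T,
        )
        bd.hbond_sr_bb = sr1 + sr2
        bd.hbond_lr_bb = lr1 + lr2
        if len(self._cl_cb_rows):
            sub = d[np.ix_(self._cl_cb_rows, self._cl_cb_cols)]
            bd.n_cb_cb_interactions = float(
                np.sum(self._cl_w_cb[sub <= self.ccs_cfg.cb_contact_cutoff])
            )
        cfg = self.ccs_cfg
        bd.total = (
            cfg.w_clash * bd.n_clashes * cfg.clash_penalty
            + cfg.w_hb * (bd.hbond_sr_bb + bd.hbond_lr_bb)
            + cfg.w_cb * bd.n_cb_cb_interactions
        )
        return bd

    def n_clashes(self, params: RigidBodyParams, flipped: bool = False) -> int:
        main, partners, _ = self._place(self._cloud.coords, params, flipped)
        if len(partners) == 0:
            return 0
        d = cdist(main, partners)
        return int(np.count_nonzero(d < self._cl_thresh))

    # -- Iscore ---------------------------------------------------------------

    def iscore(self, params: RigidBodyParams, flipped: bool = False) -> float:
        main, partners, r = self._place(self._coords, params, flipped)
        if len(partners) == 0:
            return 0.0
        d = cdist(main, partners)
        cfg = self.cfg

        within = d < cfg.cutoff
        e_lj = 0.0
        if within.any():
            dd = d[within]
            sr6 = self._sigma6[within] / (dd ** 6)
            e = (
                4.0
                * cfg.lj_epsilon
                * (cfg.lj_repulsion_scale * sr6 * sr6 - sr6)
                - self._lj_shift[within]
            )
            e_lj = float(np.minimum(e, cfg.lj_cap).sum())
        else:
            return 0.0

        # H-bonds in both donor/acceptor directions (small dedicated point
        # subsets; carbonyl directions rotate with placement, then per copy)
        main_n = main[self._n_rows]
        main_o = main[self._o_rows]
        part_n = self._copies(main_n)
        part_o = self._copies(main_o)
        cdir_o = self._o_cdir[self._o_rows] @ r.T
        part_cdir_o = self._copies(cdir_o)
        res_n = self._res[self._n_rows]
        res_o = self._res[self._o_rows]
        k = len(self._partner_rots)
        res_n_t = np.tile(res_n, k)
        res_o_t = np.tile(res_o, k)
        sr1, lr1 = ccs_mod.hbond_pairs_energy(
            main_n, res_n, part_o, part_cdir_o, res_o_t, self.ccs_cfg
        )
        sr2, lr2 = ccs_mod.hbond_pairs_energy(
            part_n, res_n_t, main_o, cdir_o, res_o, self.ccs_cfg
        )
        e_hb = sr1 + lr1 + sr2 + lr2

        # smooth density-weighted CB-CB contact reward: full weight below
        # contact_on, fading smoothly to zero at the contact cutoff, so the
        # optimum is well defined instead of a plateau of equal counts
        contacts = 0.0
        if len(self._cb_rows):
            sub = cdist(main[self._cb_rows], self._copies(main[self._cb_rows]))
            cut = self.ccs_cfg.cb_contact_cutoff
            s = (cut - sub) / (cut - cfg.contact_on)
            np.clip(s, 0.0, 1.0, out=s)
            s *= s * (3.0 - 2.0 * s)
            contacts = float(np.sum(self._w_cb * s))
        return e_lj + cfg.hb_weight * e_hb - cfg.contact_weight * contacts


def interface_score(
    subunit: ChainModel,
    params: RigidBodyParams,
    sd: SymmetryDefinition,
    cfg: EnergyConfig | None = None,
    ccs_cfg: CCSConfig | None = None,
    subsystem_indices: list[int] | None = None,
    flipped: bool = False,
) -> float:
    """Interface-only energy of the main subunit at the given placement."""
    scorer = AssemblyScorer(
        subunit, sd, ccs_cfg=ccs_cfg, cfg=cfg, subsystem_indices=subsystem_indices
    )
    return scorer.iscore(params, flipped=flipped)


def whole_energy(iscore: float, sd: SymmetryDefinition) -> float:
    """Whole-assembly interface energy: (group order / 2) * Iscore.

    Every interchain interaction appears in exactly two subunits' interface
    sums of a homomer, hence the factor of one half.
    """
    return sym.GROUP_ORDER[sd.kind] / 2.0 * iscore
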