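"""Post-docking selection funnel.

Harvest the best individuals by Iscore, cluster on the six rigid-body
parameters with k-means, locally refine the cluster representatives with
the surrogate energy, and emit five ranked final models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from . import symmetry as sym
from .energy import AssemblyScorer
from .engine import DockingContext, Individual, _packmin
from .symmetry import PARAM_NAMES, RigidBodyParams


@dataclass
class SelectionConfig:
    harvest_n: int = 1000
    refine_clusters: int = 100
    final_clusters: int = 5
    kmeans_restarts: int = 10
    refine_deltas: tuple[float, ...] = (1.0, 0.25, 0.05)
    refine_sweeps: int = 4

    def __post_init__(self):
        if not self.harvest_n >= self.refine_clusters >= self.final_clusters:
            raise ValueError("harvest_n >= refine_clusters >= final_clusters required")


def harvest(records: list[dict], cfg: SelectionConfig | None = None) -> list[dict]:
    """Top harvest_n individuals by Iscore, ties broken by (run, generation)."""
    cfg = cfg or SelectionConfig()
    if not records:
        raise ValueError("no individuals to harvest")
    ordered = sorted(
        records,
        key=lambda r: (r["iscore"], r.get("run_id", 0), r.get("generation", 0)),
    )
    if len(ordered) < cfg.harvest_n:
        warnings.warn(
            f"only {len(ordered)} individuals available for a harvest of {cfg.harvest_n}"
        )
    return ordered[: cfg.harvest_n]


def _param_matrix(records: list[dict]) -> np.ndarray:
    return np.array([[r[name] for name in PARAM_NAMES] for r in records])


def cluster_params(
    records: list[dict],
    k: int,
    rng: np.random.Generator | int | None = None,
    restarts: int = 10,
) -> tuple[np.ndarray, list[int]]:
    """k-means over the six parameters; the representative of each cluster
    is its best member by Iscore.  Returns (labels, representative indices)."""
    if not records:
        raise ValueError("nothing to cluster")
    if len(records) < k:
        warnings.warn(f"only {len(records)} models for k={k}; reducing k")
        k = len(records)
    seed = rng if isinstance(rng, (int, np.integer)) else (
        int(rng.integers(2**31)) if rng is not None else 0
    )
    x = _param_matrix(records)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    reps = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            continue
        reps.append(int(min(members, key=lambda i: records[i]["iscore"])))
    return labels, reps


def refine(
    records: list[dict],
    ctx: DockingContext,
    cfg: SelectionConfig | None = None,
) -> list[dict]:
    """Surrogate relax: bounded local minimization of the Iscore over the
    six parameters plus best-backbone re-selection; never worsens."""
    cfg = cfg or SelectionConfig()
    refined = []
    de_cfg = replace(
        ctx.cfg, packmin_deltas=cfg.refine_deltas, packmin_sweeps=cfg.refine_sweeps
    )
    rctx = replace(ctx, cfg=de_cfg)
    for rec in records:
        ind = Individual(
            backbone_id=int(rec.get("backbone_id", 0)),
            params=RigidBodyParams(**{n: rec[n] for n in PARAM_NAMES}),
            flipped=bool(rec.get("flipped", False)),
            iscore=float(rec["iscore"]),
        )
        out = _packmin(ind, rctx)
        # backbone re-selection from the ensemble at the refined placement
        for bb in range(len(rctx.ensemble)):
            if bb == out.backbone_id:
                continue
            cand = rctx.evaluate(replace(out, backbone_id=bb, iscore=math.inf))
            if cand.iscore < out.iscore:
                out = cand
        new = dict(rec)
        new.update(
            backbone_id=out.backbone_id,
            iscore=min(out.iscore, float(rec["iscore"])),
            **{n: getattr(out.params, n) for n in PARAM_NAMES},
        )
        refined.append(new)
    return refined


def final_five(
    records: list[dict],
    cfg: SelectionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """Cluster into final_clusters sets, take each cluster's best model by
    Iscore, rank the representatives by Iscore (rank 1 = Best Ranked)."""
    cfg = cfg or SelectionConfig()
    if len(records) < cfg.final_clusters:
        warnings.warn(
            f"only {len(records)} models for {cfg.final_clusters} final clusters"
        )
    _, reps = cluster_params(
        records, min(cfg.final_clusters, len(records)), rng, cfg.kmeans_restarts
    )
    chosen = sorted((records[i] for i in reps), key=lambda r: r["iscore"])
    out = []
    for rank, rec in enumerate(chosen, start=1):
        entry = dict(rec)
        entry["rank"] = rank
        out.append(entry)
    return out


def run_selection_funnel(
    records: list[dict],
    ctx: DockingContext,
    cfg: SelectionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """harvest -> k-means(refine_clusters) -> refine -> final five."""
    cfg = cfg or SelectionConfig()
    top = harvest(records, cfg)
    _, reps = cluster_params(
        top, min(cfg.refine_clusters, len(top)), rng, cfg.kmeans_restarts
    )
    refined = refine([top[i] for i in reps], ctx, cfg)
    return final_five(refined, cfg, rng)
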