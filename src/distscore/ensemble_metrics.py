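"""Ensemble-level diagnostics: pairwise superposition RMSD and distance-vector
correlation.

RMSD uses least-squares (Kabsch) superposition over the Cα positions present
in both chains; the distance-vector correlation is superposition-free, since
intramolecular distances are invariant under rigid motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle_model import DataError, PairIndex, enumerate_pairs
from .dsa_core import chain_distance_vector
from .structure_io import ChainBundle

logger = logging.getLogger("distscore")

MIN_SUPERPOSE_POINTS = 3


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # (3, 3) proper rotation, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, over the masked positions


def superpose(
    mobile: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rotation R and translation t minimising
    ||R·mobile + t − target||² over the masked positions, and the resulting
    RMSD.  Reflections are never returned: if the optimal orthogonal transform
    is improper, the smallest singular direction is flipped.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        mobile, target = mobile[mask], target[mask]
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DataError("superpose: coordinate sets must both be (n, 3)")
    n = len(mobile)
    if n < MIN_SUPERPOSE_POINTS:
        raise DataError(f"superpose: need ≥ {MIN_SUPERPOSE_POINTS} common points, got {n}")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    x, y = mobile - mc, target - tc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # collinear sets make the rotation ill-determined
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DataError("superpose: degenerate (collinear) coordinate configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    diff = x @ rot.T - y
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _chain_names(ensemble: list[ChainBundle]) -> list[str]:
    names = [f"{c.structure_id}/{c.chain_id}" for c in ensemble]
    if len(set(names)) != len(names):
        names = [f"{n}#{k}" for k, n in enumerate(names)]
    return names


def pairwise_rmsd_matrix(ensemble: list[ChainBundle]) -> pd.DataFrame:
    """Symmetric chain-by-chain matrix of superposition RMSDs (Å).

    Entry (a, b) is the Kabsch RMSD over bundle positions present in both
    chains.
    """
    if len(ensemble) < 2:
        raise DataError("pairwise RMSD needs ≥ 2 chains")
    names = _chain_names(ensemble)
    m = len(ensemble)
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            ca, cb = ensemble[a], ensemble[b]
            mask = ca.present & cb.present
            try:
                sup = superpose(ca.coords, cb.coords, mask)
            except DataError as exc:
                raise DataError(f"superposing {names[a]} onto {names[b]}: {exc}") from exc
            out[a, b] = out[b, a] = sup.rmsd
    return pd.DataFrame(out, index=names, columns=names)


def distance_correlation_matrix(
    ensemble: list[ChainBundle], pairs: PairIndex | None = None
) -> pd.DataFrame:
    """Symmetric matrix of Pearson correlations between chains' distance vectors.

    Superposition-free; computed over pairs defined in both chains.  Entries
    with < 2 overlapping defined pairs are NaN and flagged in the log.
    """
    if len(ensemble) < 2:
        raise DataError("distance correlation needs ≥ 2 chains")
    if pairs is None:
        pairs = enumerate_pairs(ensemble[0].bundle)
    names = _chain_names(ensemble)
    vecs = [chain_distance_vector(c, pairs) for c in ensemble]
    m = len(ensemble)
    out = np.ones((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            va, vb = vecs[a], vecs[b]
            ok = ~np.isnan(va) & ~np.isnan(vb)
            if ok.sum() < 2:
                logger.warning(
                    "correlation %s vs %s undefined: < 2 overlapping pairs",
                    names[a],
                    names[b],
                )
                r = np.nan
            else:
                r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=names, columns=names)
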